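"""Downstream summaries of activity tables.

Per-state activity fractions and means, overlap of active tiles with
accessibility peaks, cross-sample correlation of activity, dose-response
of synthetic motif-combination enhancers, and genome-browser track export.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .design import ComboDesign

KNOWN_CLASSES = ("MEL", "MES", "other")


def class_summary(
    records: pd.DataFrame,
    classes: Mapping[str, str],
    known_classes: Sequence[str] = KNOWN_CLASSES,
) -> pd.DataFrame:
    """Tested/active counts, percent active and mean activity per state class.

    The mean log2 FC is taken over ALL tested members of a class, active or
    not.  Classes with no tested member are omitted with a warning; a class
    label outside *known_classes* is an error.
    """
    for enh in records["enhancer_id"]:
        if enh not in classes:
            raise ValueError(f"no class for enhancer {enh!r}")
        if classes[enh] not in known_classes:
            raise ValueError(f"unknown class label {classes[enh]!r} for {enh!r}")
    rows = []
    labels = [classes[e] for e in records["enhancer_id"]]
    frame = records.assign(class_label=labels)
    for label in known_classes:
        sub = frame[frame["class_label"] == label]
        if sub.empty:
            warnings.warn(f"class {label!r} has no tested enhancer; omitted")
            continue
        n_tested = int(len(sub))
        n_active = int(sub["active"].sum())
        rows.append(
            {
                "class_label": label,
                "n_tested": n_tested,
                "n_active": n_active,
                "percent_active": 100.0 * n_active / n_tested,
                "mean_log2fc": float(sub["log2fc"].mean()),
            }
        )
    return pd.DataFrame(rows)


def tile_peak_overlap(
    active_tiles: Sequence[tuple[str, int, int]],
    peaks: Sequence[tuple[str, int, int]],
    min_overlap: int = 1,
) -> float:
    """Percent of active tiles overlapping any peak by >= min_overlap bp.

    Intervals are 0-based half-open.  An empty active set is undefined and
    returned as NaN.
    """
    if not active_tiles:
        warnings.warn("no active tiles; overlap undefined")
        return float("nan")
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in peaks:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    n_overlapping = 0
    for chrom, start, end in active_tiles:
        tree = trees.get(chrom)
        if tree is None:
            continue
        best = max(
            (min(end, iv.end) - max(start, iv.begin) for iv in tree.overlap(start, end)),
            default=0,
        )
        if best >= min_overlap:
            n_overlapping += 1
    return 100.0 * n_overlapping / len(active_tiles)


def sample_correlation(
    tables: Mapping[str, Mapping[str, float]],
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-enhancer activities across samples.

    Each cell is computed on the pairwise-complete enhancer intersection;
    pairs sharing fewer than *min_shared* enhancers give NaN with a warning.
    """
    samples = list(tables)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    mat = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            shared = sorted(set(tables[a]) & set(tables[b]))
            if len(shared) < min_shared:
                warnings.warn(
                    f"samples {a!r} and {b!r} share only {len(shared)} enhancers"
                )
                r = float("nan")
            else:
                x = np.array([tables[a][e] for e in shared])
                y = np.array([tables[b][e] for e in shared])
                r = float(np.corrcoef(x, y)[0, 1])
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def motif_count_response(
    records: pd.DataFrame,
    designs: Sequence[ComboDesign],
) -> pd.DataFrame:
    """Mean/SD activity grouped by motif copy number and background.

    Every record must join to a combo design via ``enhancer_id``; the
    zero-motif rows are each background's baseline (flagged
    ``is_baseline``).
    """
    by_id = {d.combo_id: d for d in designs}
    missing = [e for e in records["enhancer_id"] if e not in by_id]
    if missing:
        raise ValueError(f"records without a combo design: {sorted(missing)}")
    rows = []
    for row in records.itertuples(index=False):
        design = by_id[row.enhancer_id]
        motifs = [m for m, _ in design.layout.placements]
        rows.append(
            {
                "background_id": design.background_id,
                "n_sox": motifs.count("SOX_dimer"),
                "n_mitf": motifs.count("MITF"),
                "log2fc": row.log2fc,
            }
        )
    frame = pd.DataFrame(rows)
    grouped = (
        frame.groupby(["background_id", "n_sox", "n_mitf"])["log2fc"]
        .agg(mean_log2fc="mean", sd_log2fc="std", n="size")
        .reset_index()
    )
    grouped["is_baseline"] = (grouped["n_sox"] == 0) & (grouped["n_mitf"] == 0)
    return grouped


def export_tiling_track(
    records: pd.DataFrame,
    tile_intervals: Mapping[str, tuple[str, int, int]],
) -> str:
    """bedGraph of per-tile activity (0-based half-open, sorted).

    *tile_intervals* maps enhancer_id to a (chrom, start, end) 1-based
    inclusive genomic interval; a record without coordinates is an error.
    Overlapping tiles are emitted as-is.
    """
    lines = []
    for row in records.itertuples(index=False):
        if row.enhancer_id not in tile_intervals:
            raise ValueError(f"no genomic coordinates for tile {row.enhancer_id!r}")
        chrom, start1, end1 = tile_intervals[row.enhancer_id]
        lines.append((chrom, start1 - 1, end1, float(row.log2fc)))
    lines.sort(key=lambda t: (t[0], t[1], t[2]))
    return "".join(f"{c}\t{s}\t{e}\t{v:g}\n" for c, s, e, v in lines)


def parse_bedgraph(text: str) -> list[tuple[str, int, int, float]]:
    """Inverse of :func:`export_tiling_track` (round-trip checks)."""
    out = []
    for line in text.strip().splitlines():
        if not line or line.startswith(("track", "#")):
            continue
        chrom, start, end, value = line.split("\t")
        out.append((chrom, int(start), int(end), float(value)))
    return out
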