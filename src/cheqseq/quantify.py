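"""Enhancer-activity estimation from barcoded reporter counts.

The quantification model is deliberately simple and count-based:

1. barcodes are extracted from plasmid (input) and cDNA (output) reads,
   quality-filtered (Q > 30) and matched exactly against the barcode map;
2. enhancers seen with fewer distinct barcodes than a library-dependent
   threshold (5 / 10 / 20) are dropped per sample;
3. barcode counts are aggregated per enhancer and CPM-normalised; the
   cDNA/plasmid CPM ratio is the fold change (FC);
4. FC is divided by the median FC of the shuffled negative controls and
   log2-transformed, so controls centre at 0 by construction;
5. a robust Gaussian null (median / Gaussian-consistent MAD) is fitted to
   the control activities; every enhancer gets an upper-tail p-value,
   Benjamini–Hochberg adjusted over all tested enhancers, and is called
   active when adj_p < 0.05.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .assignment import BarcodeLayout, BarcodeMap, barcode_qualities, extract_barcode
from .io import Read


@dataclass
class BarcodeCountTable:
    """Reads per uniquely identified barcode in one sample."""

    sample_id: str
    role: str  # plasmid | cdna
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.role not in ("plasmid", "cdna"):
            raise ValueError("role must be 'plasmid' or 'cdna'")
        self.counts = {bc: int(n) for bc, n in self.counts.items() if n > 0}

    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items())
        return pd.DataFrame(rows, columns=["barcode", "count"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, sample_id: str, role: str) -> "BarcodeCountTable":
        frame = pd.read_csv(path, sep="\t", dtype={"barcode": str})
        return cls(sample_id=sample_id, role=role,
                   counts=dict(zip(frame["barcode"], frame["count"])))


@dataclass(frozen=True)
class NullModel:
    """Gaussian null for control activities."""

    mu: float
    sigma: float
    method: str
    n_controls: int
    tail: str = "upper"

    def to_json(self) -> str:
        return json.dumps(
            {"mu": self.mu, "sigma": self.sigma, "method": self.method,
             "n_controls": self.n_controls, "tail": self.tail}, indent=2,
        )


def count_barcodes(
    reads: Iterable[Read],
    layout: BarcodeLayout,
    barcode_map: BarcodeMap,
    min_q: float = 30.0,
    quality_mode: str = "mean",
    sample_id: str = "",
    role: str = "cdna",
) -> tuple[BarcodeCountTable, Counter]:
    """Count reads per mapped barcode; unmapped/low-quality reads are tallied.

    Quality gating is strict (Q > min_q) on the barcode bases, either their
    mean (default) or their per-base minimum.
    """
    counts: Counter[str] = Counter()
    rejections: Counter[str] = Counter()
    n_reads = 0
    for read in reads:
        n_reads += 1
        ex = extract_barcode(read, layout)
        if not ex.ok:
            rejections[ex.reject_reason] += 1
            continue
        quals = barcode_qualities(read, layout)
        if quals is not None:
            q = float(np.min(quals)) if quality_mode == "min" else float(np.mean(quals))
            if not q > min_q:
                rejections["low_quality"] += 1
                continue
        if ex.barcode not in barcode_map.entries:
            rejections["unassigned"] += 1
            continue
        counts[ex.barcode] += 1
    if n_reads == 0:
        warnings.warn("empty read stream: returning empty count table")
    return (
        BarcodeCountTable(sample_id=sample_id, role=role, counts=dict(counts)),
        rejections,
    )


def barcodes_per_enhancer(table: BarcodeCountTable, barcode_map: BarcodeMap) -> pd.Series:
    """Distinct barcodes observed per enhancer in one sample."""
    enh = [barcode_map.enhancer_of(bc) for bc in table.counts]
    enh = [e for e in enh if e is not None]
    return pd.Series(Counter(enh), dtype=int).sort_index()


def filter_min_barcodes(
    table: BarcodeCountTable, barcode_map: BarcodeMap, min_bcs: int
) -> set[str]:
    """Enhancers with >= min_bcs distinct observed barcodes in this sample."""
    if min_bcs < 1:
        raise ValueError("min_bcs must be >= 1")
    per_enh = barcodes_per_enhancer(table, barcode_map)
    return set(per_enh.index[per_enh >= min_bcs])


def aggregate_cpm(
    table: BarcodeCountTable, barcode_map: BarcodeMap, passing: set[str]
) -> dict[str, float]:
    """Aggregate barcode counts per passing enhancer and CPM-normalise.

    The CPM denominator is the total count over passing enhancers, so the
    returned values sum to 1e6.
    """
    if not passing:
        raise ValueError("no enhancers pass the barcode filter")
    agg: Counter[str] = Counter()
    for bc, n in table.counts.items():
        enh = barcode_map.enhancer_of(bc)
        if enh in passing:
            agg[enh] += n
    total = sum(agg.values())
    if total == 0:
        raise ValueError("zero total count over passing enhancers")
    return {enh: n / total * 1e6 for enh, n in agg.items()}


def fold_change(
    plasmid_cpm: Mapping[str, float], cdna_cpm: Mapping[str, float]
) -> dict[str, float]:
    """cDNA/plasmid CPM ratio over enhancers present in both samples."""
    if not plasmid_cpm or not cdna_cpm:
        raise ValueError("both CPM maps must be nonempty")
    shared = sorted(set(plasmid_cpm) & set(cdna_cpm))
    if not shared:
        raise ValueError("no enhancer passed filtering in both samples")
    return {e: cdna_cpm[e] / plasmid_cpm[e] for e in shared}


def normalize_to_controls(
    fc: Mapping[str, float], control_ids: Iterable[str]
) -> dict[str, float]:
    """log2 of FC divided by the median control FC (controls centre at 0).

    For libraries without shuffled sequences, *control_ids* should name
    user-supplied negative regions instead.
    """
    ctrl = [fc[c] for c in control_ids if c in fc]
    if not ctrl:
        raise ValueError(
            "no control in the fold-change table; supply negative-control "
            "region ids for libraries without shuffled sequences"
        )
    med = float(np.median(ctrl))
    return {e: float(np.log2(v / med)) for e, v in fc.items()}


def fit_null(
    control_log2fc: Sequence[float],
    method: str = "robust",
    min_n: int = 30,
) -> NullModel:
    """Gaussian null from control activities.

    ``robust``: location = median, scale = 1.4826 x MAD (consistent for a
    Gaussian); ``huber``: Huber's joint M-estimate of location and scale;
    ``classic``: mean and SD.  Degenerate (constant) controls are an error.
    """
    x = np.asarray(list(control_log2fc), dtype=float)
    if x.size < min_n:
        raise ValueError(f"{x.size} controls < required minimum {min_n}")
    if method == "robust":
        mu = float(np.median(x))
        sigma = float(stats.median_abs_deviation(x, scale="normal"))
    elif method == "huber":
        from statsmodels.robust.scale import Huber

        mu_, sigma_ = Huber()(x)
        mu, sigma = float(mu_), float(sigma_)
    elif method == "classic":
        mu = float(np.mean(x))
        sigma = float(np.std(x, ddof=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    if sigma <= 0:
        raise ValueError("degenerate controls: estimated null scale is zero")
    return NullModel(mu=mu, sigma=sigma, method=method, n_controls=int(x.size))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_activity(
    log2fc: Mapping[str, float],
    null: NullModel,
    alpha: float = 0.05,
    tail: str = "upper",
) -> pd.DataFrame:
    """Per-enhancer Gaussian p-values, BH adjustment, and active calls.

    ``upper`` tests activation only (P[X >= x] under the null); ``two_sided``
    doubles the smaller tail.
    """
    enh = sorted(log2fc)
    x = np.array([log2fc[e] for e in enh])
    z = (x - null.mu) / null.sigma
    if tail == "upper":
        p = stats.norm.sf(z)
    elif tail == "two_sided":
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        raise ValueError("tail must be 'upper' or 'two_sided'")
    adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "enhancer_id": enh,
            "log2fc": x,
            "p_value": p,
            "adj_p": adj,
            "active": adj < alpha,
        }
    )


def activity_table(
    plasmid: BarcodeCountTable,
    cdna: BarcodeCountTable,
    barcode_map: BarcodeMap,
    control_ids: Iterable[str],
    min_bcs: int = 5,
    alpha: float = 0.05,
    tail: str = "upper",
    null_method: str = "robust",
    min_controls: int = 30,
) -> tuple[pd.DataFrame, NullModel]:
    """Full per-sample activity estimation.

    Returns one row per enhancer quantified in both samples (controls
    included, flagged by ``is_control``) and the fitted null model.
    """
    control_ids = set(control_ids)
    p_pass = filter_min_barcodes(plasmid, barcode_map, min_bcs)
    c_pass = filter_min_barcodes(cdna, barcode_map, min_bcs)
    p_cpm = aggregate_cpm(plasmid, barcode_map, p_pass)
    c_cpm = aggregate_cpm(cdna, barcode_map, c_pass)
    fc = fold_change(p_cpm, c_cpm)
    log2fc = normalize_to_controls(fc, control_ids)
    ctrl_values = [v for e, v in log2fc.items() if e in control_ids]
    null = fit_null(ctrl_values, method=null_method, min_n=min_controls)
    calls = call_activity(log2fc, null, alpha=alpha, tail=tail)

    p_bcs = barcodes_per_enhancer(plasmid, barcode_map)
    c_bcs = barcodes_per_enhancer(cdna, barcode_map)
    n_bcs = [
        int(min(p_bcs.get(e, 0), c_bcs.get(e, 0))) for e in calls["enhancer_id"]
    ]
    calls.insert(1, "n_barcodes", n_bcs)
    calls.insert(2, "plasmid_cpm", [p_cpm[e] for e in calls["enhancer_id"]])
    calls.insert(3, "cdna_cpm", [c_cpm[e] for e in calls["enhancer_id"]])
    calls.insert(4, "fc", [fc[e] for e in calls["enhancer_id"]])
    calls["is_control"] = calls["enhancer_id"].isin(control_ids)
    return calls, null


def sample_qc(
    records: pd.DataFrame,
    min_coverage: int = 450,
    extreme_z: float = 3.0,
    null: NullModel | None = None,
) -> dict:
    """Per-sample QC: coverage gate plus reported extreme-value fraction.

    A sample fails when fewer than *min_coverage* enhancers were quantified.
    The fraction of |z| > extreme_z activities is reported (not gating).
    """
    n_quantified = int(len(records))
    n_controls = int(records["is_control"].sum()) if "is_control" in records else 0
    if null is not None and n_quantified:
        z = (records["log2fc"].to_numpy() - null.mu) / null.sigma
        extreme_fraction = float(np.mean(np.abs(z) > extreme_z))
    else:
        extreme_fraction = float("nan")
    return {
        "pass": n_quantified >= min_coverage,
        "n_quantified": n_quantified,
        "n_controls": n_controls,
        "min_coverage": int(min_coverage),
        "extreme_fraction": extreme_fraction,
    }
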