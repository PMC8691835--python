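"""Reporter oligo library design.

Builds the four library flavours used in enhancer MPRA screens:

* **tiling** — fixed-length tiles (default 190 bp) sliding across candidate
  regions in 20 bp steps, with a second sublibrary offset by 10 bp so the
  union reaches 10 bp resolution;
* **motif mutants** — per-motif tiles in which every occurrence of one PWM
  is destroyed at its most informative positions;
* **shuffled negatives** — dinucleotide-preserving shuffles of the designed
  tiles, homopolymer-filtered and re-scanned to be motif-free;
* **accessibility-peak oligos** — summit-centred 501 bp regions with a
  spacer and region-identifying barcode; and **synthetic combinations** of
  SOX-dimer / MITF binding sites placed on neutral backgrounds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from math import ceil, floor
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import PWM, MotifHit, collapse_palindromic, mutate_hit, mutation_positions, scan

TILE_LEN = 190
TILE_STEP = 20
SUBLIBRARY_OFFSETS = {"A": 1, "B": 11}

SOX_DIMER_SITE = "ACAAAGACGGCTTTGT"
MITF_SITE = "CACGTG"
COMBO_MOTIF_SEQUENCES = {"SOX_dimer": SOX_DIMER_SITE, "MITF": MITF_SITE}
COMBO_BACKGROUND_LEN = 259
COMBO_BC_LEN = 11
COMBO_ADAPTOR5 = "GAGCATGCACCGGTG"
COMBO_ADAPTOR3 = "CGCTTCGAGCAGACA"


@dataclass(frozen=True)
class RegionRecord:
    """A candidate regulatory region submitted to tiling."""

    region_id: str
    sequence: str
    state_class: str = "other"
    genomic_interval: tuple[str, int, int, str] | None = None  # chrom, start1, end1, strand


@dataclass(frozen=True)
class TileRecord:
    """One designed oligo insert (wild-type, motif-mutant, or shuffled)."""

    tile_id: str
    region_id: str
    start: int  # 1-based offset within the region
    length: int
    sequence: str
    category: str  # WT | mutated | shuffled
    mutated_motif: str | None = None
    mutated_positions: tuple[int, ...] | None = None  # region-relative, 1-based
    sublibrary: str = "single"
    skipped_hits: int = 0


def expected_tile_count(region_len: int, tile_len: int = TILE_LEN,
                        step: int = TILE_STEP, start_offset: int = 1) -> int:
    """Closed-form number of tiles the sliding design emits.

    A tile starting at s covers s..s+tile_len-1 and is emitted iff its final
    base does not pass the region end.
    """
    if region_len < start_offset + tile_len - 1:
        return 0
    return floor((region_len - start_offset + 1 - tile_len) / step) + 1


def generate_tiles(
    region: RegionRecord,
    tile_len: int = TILE_LEN,
    step: int = TILE_STEP,
    start_offset: int = 1,
    sublibrary: str | None = None,
) -> list[TileRecord]:
    """Tile a region with fixed-length windows every *step* bp.

    Tiling starts at *start_offset* (1-based) and stops once a window would
    run past the region's final nucleotide.
    """
    L = len(region.sequence)
    if L < start_offset + tile_len - 1:
        raise ValueError(
            f"region {region.region_id!r} (length {L}) too short for a "
            f"{tile_len} bp tile at offset {start_offset}"
        )
    if sublibrary is None:
        sublibrary = {1: "A", 11: "B"}.get(start_offset, "single")
    tiles = []
    start = start_offset
    while start + tile_len - 1 <= L:
        seq = region.sequence[start - 1 : start + tile_len - 1]
        tiles.append(
            TileRecord(
                tile_id=f"{region.region_id}__{sublibrary}__{start}__WT",
                region_id=region.region_id,
                start=start,
                length=tile_len,
                sequence=seq,
                category="WT",
                sublibrary=sublibrary,
            )
        )
        start += step
    return tiles


def generate_mutant_tiles(
    tiles: Sequence[TileRecord],
    pwms: Sequence[PWM],
    threshold: float,
) -> list[TileRecord]:
    """One mutant tile per (WT tile, motif) with >= 1 occurrence.

    All occurrences of that single motif are destroyed in the mutant so each
    mutant isolates one factor's contribution.  Overlapping occurrences of
    the same motif are mutated left to right; a hit whose window was already
    modified is skipped and counted in ``skipped_hits``.
    """
    out: list[TileRecord] = []
    for tile in tiles:
        if tile.category != "WT":
            raise ValueError(f"tile {tile.tile_id!r} is not category WT")
        for pwm in pwms:
            hits = collapse_palindromic(
                scan(tile.sequence, pwm, threshold=threshold, sequence_id=tile.tile_id)
            )
            if not hits:
                continue
            seq = tile.sequence
            modified: set[int] = set()
            skipped = 0
            for hit in hits:
                window = set(range(hit.start, hit.end + 1))
                if window & modified:
                    skipped += 1
                    continue
                positions = mutation_positions(hit, pwm)
                seq = mutate_hit(seq, hit, pwm)
                modified.update(positions)
            region_positions = tuple(sorted(tile.start - 1 + p for p in modified))
            out.append(
                TileRecord(
                    tile_id=(
                        f"{tile.region_id}__{tile.sublibrary}__{tile.start}"
                        f"__mutated__{pwm.name}"
                    ),
                    region_id=tile.region_id,
                    start=tile.start,
                    length=tile.length,
                    sequence=seq,
                    category="mutated",
                    mutated_motif=pwm.name,
                    mutated_positions=region_positions,
                    sublibrary=tile.sublibrary,
                    skipped_hits=skipped,
                )
            )
    return out


# ---------------------------------------------------------------------------
# k-let-preserving shuffle (Altschul–Erickson Eulerian-path construction)
# ---------------------------------------------------------------------------

def shuffle_klet(sequence: str, k: int = 2,
                 seed: int | None = None,
                 rng: np.random.Generator | None = None) -> str:
    """Random permutation of *sequence* preserving all k-let counts exactly.

    For k=2 the output has the identical dinucleotide count table.  The
    (k-1)-mers are vertices of a multigraph whose edges are the k-lets; a
    uniform random Eulerian path that starts and ends on the original
    terminal vertices is drawn by choosing random "last-exit" edges that
    form an arborescence into the final vertex, then walking the graph.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(sequence)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds sequence length {n}")
    if k == 1:
        return "".join(rng.permutation(list(sequence)))
    order = k - 1
    verts = [sequence[i : i + order] for i in range(n - order + 1)]
    first, last = verts[0], verts[-1]
    # out-edge target lists per vertex
    edges: dict[str, list[str]] = {}
    for u, v in zip(verts[:-1], verts[1:]):
        edges.setdefault(u, []).append(v)
    vertices = list(edges)
    if last not in edges:
        edges[last] = []

    non_terminal = [u for u in vertices if u != last and edges[u]]
    while True:
        last_exit = {u: edges[u][rng.integers(len(edges[u]))] for u in non_terminal}
        if all(_reaches(u, last, last_exit) for u in non_terminal):
            break

    walk_edges: dict[str, list[str]] = {}
    for u in vertices:
        outs = list(edges[u])
        if u in last_exit:
            outs.remove(last_exit[u])
            perm = [outs[i] for i in rng.permutation(len(outs))]
            perm.append(last_exit[u])
        else:
            perm = [outs[i] for i in rng.permutation(len(outs))]
        walk_edges[u] = perm

    ptr = {u: 0 for u in walk_edges}
    out = [first]
    u = first
    for _ in range(len(verts) - 1):
        v = walk_edges[u][ptr[u]]
        ptr[u] += 1
        out.append(v[-1])
        u = v
    return "".join(out)


def _reaches(u: str, target: str, nxt: Mapping[str, str]) -> bool:
    seen = set()
    while u != target:
        if u in seen or u not in nxt:
            return False
        seen.add(u)
        u = nxt[u]
    return True


def klet_counts(sequence: str, k: int = 2) -> dict[str, int]:
    """Count table of all k-lets in a sequence (shuffle-contract oracle)."""
    counts: dict[str, int] = {}
    for i in range(len(sequence) - k + 1):
        w = sequence[i : i + k]
        counts[w] = counts.get(w, 0) + 1
    return counts


def has_homopolymer(sequence: str, min_run: int = 6) -> bool:
    """True iff any base repeats *min_run* or more times consecutively."""
    if not sequence:
        raise ValueError("empty sequence")
    return re.search(r"(.)\1{%d,}" % (min_run - 1), sequence) is not None


def select_shuffled_controls(
    candidates: Sequence[TileRecord],
    pwms: Sequence[PWM],
    threshold: float,
    n: int = 800,
    seed: int | None = None,
) -> list[TileRecord]:
    """Sample *n* motif-free candidates as shuffled negative controls.

    Every candidate is re-scanned with all PWMs at the design threshold;
    only candidates with zero hits enter the pool, from which *n* are drawn
    without replacement (seeded).
    """
    pool = [
        t for t in candidates
        if all(not scan(t.sequence, p, threshold=threshold) for p in pwms)
    ]
    if len(pool) < n:
        raise ValueError(
            f"only {len(pool)} motif-free candidates available, {n} requested"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(chosen)]


def make_shuffled_controls(
    source_tiles: Sequence[TileRecord],
    pwms: Sequence[PWM],
    threshold: float,
    n: int = 800,
    seed: int | None = None,
    k: int = 2,
    min_run: int = 6,
) -> list[TileRecord]:
    """Shuffle designed tiles, drop homopolymer runs, keep n motif-free ones."""
    rng = np.random.default_rng(seed)
    candidates = []
    for i, tile in enumerate(source_tiles):
        shuffled = shuffle_klet(tile.sequence, k=k, rng=rng)
        if has_homopolymer(shuffled, min_run=min_run):
            continue
        candidates.append(
            TileRecord(
                tile_id=f"shuffle_{i:05d}__{tile.tile_id}",
                region_id="shuffled",
                start=1,
                length=len(shuffled),
                sequence=shuffled,
                category="shuffled",
                sublibrary=tile.sublibrary,
            )
        )
    return select_shuffled_controls(
        candidates, pwms, threshold, n=n, seed=int(rng.integers(2**31))
    )


# ---------------------------------------------------------------------------
# Accessibility-peak (summit-centred) oligo design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtacOligo:
    """Summit-centred genomic oligo: 501 bp region + 16 bp spacer + 8 bp barcode."""

    region_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    sequence: str  # genomic part
    barcode: str
    oligo: str


def design_atac_regions(
    summits: Sequence[tuple[str, str, int]],  # (region_id, chrom, summit position, 1-based)
    genome: Mapping[str, str],
    barcodes: Mapping[str, str],
    flank: int = 250,
    spacer: str = "CGATGCTAGCTCACTG",
) -> list[AtacOligo]:
    """Extend each peak summit by *flank* bp both sides and append spacer+barcode.

    *genome* is any chrom -> sequence mapping (e.g. a ``pyfaidx.Fasta`` works
    via ``str(genome[chrom][a:b])``; plain dicts are used directly).
    """
    if len(set(barcodes.values())) != len(barcodes):
        dupes = pd.Series(list(barcodes.values()))
        dup = sorted(dupes[dupes.duplicated()].unique())
        raise ValueError(f"duplicate region barcodes: {dup}")
    out = []
    for region_id, chrom, summit in summits:
        contig = genome[chrom]
        clen = len(contig)
        start, end = summit - flank, summit + flank
        if start < 1 or end > clen:
            raise ValueError(
                f"region {region_id!r}: summit {summit} too close to the edge "
                f"of {chrom} (length {clen})"
            )
        seq = str(contig[start - 1 : end])
        bc = barcodes[region_id]
        out.append(
            AtacOligo(
                region_id=region_id,
                chrom=chrom,
                start=start,
                end=end,
                sequence=seq,
                barcode=bc,
                oligo=seq + spacer + bc,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Synthetic SOX/MITF combination design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComboLayout:
    """Named arrangement of motifs on a background.

    ``placements`` holds (motif_name, centre_offset) pairs where the offset
    is in bp relative to the central anchor base of the background.
    """

    name: str
    placements: tuple[tuple[str, int], ...]


@dataclass(frozen=True)
class ComboDesign:
    combo_id: str
    background_id: int
    layout: ComboLayout
    barcode: str
    designed_sequence: str
    oligo: str


def _combo_anchor(background_len: int) -> int:
    """1-based position of the central anchor base (130 for 259 bp)."""
    return ceil(background_len / 2)


def _motif_span(motif_seq: str, offset: int, background_len: int) -> tuple[int, int]:
    """1-based inclusive span of a motif whose central base sits at anchor+offset."""
    anchor = _combo_anchor(background_len)
    centre = anchor + offset
    start = centre - ceil(len(motif_seq) / 2) + 1
    return start, start + len(motif_seq) - 1


def layout_from_spacing(
    name: str,
    motif_names: Sequence[str],
    spacing: int,
    motif_sequences: Mapping[str, str] = COMBO_MOTIF_SEQUENCES,
    background_len: int = COMBO_BACKGROUND_LEN,
) -> ComboLayout:
    """Build a layout with one motif centred and the rest at fixed edge gaps.

    Motifs are given 5'->3'; the middle one (left-of-centre for even counts)
    is anchored at the background centre and neighbours are placed with
    *spacing* bp between adjacent motif edges.
    """
    if not motif_names:
        return ComboLayout(name=name, placements=())
    lens = [len(motif_sequences[m]) for m in motif_names]
    mid = (len(motif_names) - 1) // 2
    anchor = _combo_anchor(background_len)
    starts = [0] * len(motif_names)
    starts[mid] = anchor - ceil(lens[mid] / 2) + 1
    for i in range(mid + 1, len(motif_names)):
        starts[i] = starts[i - 1] + lens[i - 1] + spacing
    for i in range(mid - 1, -1, -1):
        starts[i] = starts[i + 1] - spacing - lens[i]
    placements = tuple(
        (m, starts[i] + ceil(lens[i] / 2) - 1 - anchor)
        for i, m in enumerate(motif_names)
    )
    return ComboLayout(name=name, placements=placements)


def design_sox_mitf_combos(
    backgrounds: Sequence[str],
    layouts: Sequence[ComboLayout],
    barcodes: Sequence[str],
    adaptor5: str = COMBO_ADAPTOR5,
    adaptor3: str = COMBO_ADAPTOR3,
    motif_sequences: Mapping[str, str] = COMBO_MOTIF_SEQUENCES,
) -> list[ComboDesign]:
    """Place binding sites onto neutral backgrounds and assemble full oligos.

    Motifs REPLACE background bases at their computed spans (the synthesis
    length is fixed), one design per (background, layout); the final oligo
    is ``adaptor5 + barcode + designed sequence + adaptor3``.
    """
    designs_needed = len(backgrounds) * len(layouts)
    if len(barcodes) < designs_needed:
        raise ValueError(
            f"{designs_needed} designs but only {len(barcodes)} barcodes"
        )
    if len(set(barcodes[:designs_needed])) != designs_needed:
        raise ValueError("combo barcodes must be unique")
    out = []
    bc_iter = iter(barcodes)
    for bg_idx, background in enumerate(backgrounds, start=1):
        L = len(background)
        for layout in layouts:
            spans = []
            for motif, offset in layout.placements:
                seq = motif_sequences[motif]
                s, e = _motif_span(seq, offset, L)
                if s < 1 or e > L:
                    raise ValueError(
                        f"layout {layout.name!r}: motif {motif} at offset "
                        f"{offset} falls outside the {L} bp background"
                    )
                spans.append((s, e, seq, motif))
            spans.sort()
            for (s1, e1, *_), (s2, e2, *_) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"layout {layout.name!r}: overlapping motifs at "
                        f"{s1}-{e1} and {s2}-{e2}"
                    )
            chars = list(background)
            for s, e, seq, _ in spans:
                chars[s - 1 : e] = list(seq)
            designed = "".join(chars)
            bc = next(bc_iter)
            out.append(
                ComboDesign(
                    combo_id=f"bg{bg_idx}__{layout.name}",
                    background_id=bg_idx,
                    layout=layout,
                    barcode=bc,
                    designed_sequence=designed,
                    oligo=adaptor5 + bc + designed + adaptor3,
                )
            )
    return out


def add_adaptors(tiles: Sequence[TileRecord], adaptor5: str, adaptor3: str) -> list[str]:
    """Flank each tile with synthesis adaptors, preserving order."""
    if not adaptor5 or not adaptor3:
        raise ValueError("adaptors must be nonempty")
    return [adaptor5 + t.sequence + adaptor3 for t in tiles]


# ---------------------------------------------------------------------------
# Manifest / FASTA round-trip
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "tile_id", "region_id", "start", "length", "category",
    "mutated_motif", "mutated_positions", "sublibrary", "skipped_hits",
    "sequence",
]


def tiles_to_manifest(tiles: Sequence[TileRecord]) -> pd.DataFrame:
    rows = []
    for t in tiles:
        d = asdict(t)
        d["mutated_motif"] = t.mutated_motif or ""
        d["mutated_positions"] = (
            ",".join(str(p) for p in t.mutated_positions)
            if t.mutated_positions is not None else ""
        )
        rows.append(d)
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def manifest_to_tiles(frame: pd.DataFrame) -> list[TileRecord]:
    tiles = []
    for row in frame.itertuples(index=False):
        positions = (
            tuple(int(x) for x in str(row.mutated_positions).split(","))
            if str(row.mutated_positions) else None
        )
        tiles.append(
            TileRecord(
                tile_id=row.tile_id,
                region_id=row.region_id,
                start=int(row.start),
                length=int(row.length),
                sequence=row.sequence,
                category=row.category,
                mutated_motif=(row.mutated_motif or None),
                mutated_positions=positions,
                sublibrary=row.sublibrary,
                skipped_hits=int(row.skipped_hits),
            )
        )
    return tiles


def write_design(tiles: Sequence[TileRecord], fasta_path, manifest_path) -> None:
    """Export a design as oligo FASTA plus a TSV manifest."""
    from .io import write_fasta

    write_fasta(((t.tile_id, t.sequence) for t in tiles), fasta_path)
    tiles_to_manifest(tiles).to_csv(manifest_path, sep="\t", index=False)


def read_design(manifest_path) -> list[TileRecord]:
    frame = pd.read_csv(
        manifest_path, sep="\t",
        dtype={"mutated_positions": str, "mutated_motif": str},
        keep_default_na=False,
    )
    return manifest_to_tiles(frame)
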