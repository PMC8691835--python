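"""Barcode-to-enhancer assignment.

Reporter vectors carry a random barcode (17/18 bp) transcribed with the
reporter; before activity can be quantified each barcode must be linked to
the enhancer it was cloned with.  Two read layouts support this:

* **long reads** spanning enhancer and barcode on one molecule — the insert
  is matched against the designed sequences by alignment;
* **paired short reads** where read 1 carries a design-identifying barcode
  (8/11 bp) and read 2 the random barcode.

Assignment ends with per-barcode majority voting: a barcode observed with
several enhancers is kept for the dominant one only if its read share
reaches a dominance threshold (default 0.75), otherwise dropped.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .io import Read

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class LongReadLayout:
    """Structure of an assignment long read: adaptor5 + insert + linker + BC."""

    adaptor5: str
    linker: str
    bc_len: int = 17
    max_mismatch: int = 2


@dataclass(frozen=True)
class BarcodeLayout:
    """Structure of a barcode-bearing short read: adaptor5 + BC [+ adaptor3]."""

    adaptor5: str
    bc_len: int = 17
    adaptor3: str = ""
    max_mismatch: int = 2


@dataclass(frozen=True)
class Extraction:
    insert: str | None
    barcode: str | None
    reject_reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.reject_reason is None


def find_adaptor(sequence: str, adaptor: str, max_mismatch: int,
                 start: int = 0) -> int | None:
    """Leftmost start of *adaptor* in *sequence* with <= max_mismatch substitutions."""
    n, m = len(sequence), len(adaptor)
    if m == 0 or n - start < m:
        return None
    seq = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    ad = np.frombuffer(adaptor.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq[start:], m)
    mismatches = (windows != ad).sum(axis=1)
    hits = np.nonzero(mismatches <= max_mismatch)[0]
    if hits.size == 0:
        return None
    return start + int(hits[0])


def extract_insert_and_barcode(read: Read, layout: LongReadLayout) -> Extraction:
    """Pull (enhancer insert, random barcode) out of a long read.

    Both flanks must be found (allowing substitutions up to the layout's
    ``max_mismatch``) and the barcode must run to its full expected length;
    otherwise the read is rejected with a reason, never an exception.
    """
    seq = read.sequence.upper()
    p5 = find_adaptor(seq, layout.adaptor5, layout.max_mismatch)
    if p5 is None:
        return Extraction(None, None, "flank_not_found")
    insert_start = p5 + len(layout.adaptor5)
    plink = find_adaptor(seq, layout.linker, layout.max_mismatch, start=insert_start)
    if plink is None:
        return Extraction(None, None, "flank_not_found")
    bc_start = plink + len(layout.linker)
    barcode = seq[bc_start : bc_start + layout.bc_len]
    if len(barcode) != layout.bc_len:
        return Extraction(None, None, "barcode_truncated")
    if not set(barcode) <= VALID_BASES:
        return Extraction(None, None, "barcode_ambiguous_base")
    insert = seq[insert_start:plink]
    if not insert:
        return Extraction(None, None, "empty_insert")
    return Extraction(insert=insert, barcode=barcode)


def extract_barcode(read: Read, layout: BarcodeLayout) -> Extraction:
    """Pull a barcode from a short read given its flanking adaptor(s)."""
    seq = read.sequence.upper()
    p5 = find_adaptor(seq, layout.adaptor5, layout.max_mismatch)
    if p5 is None:
        return Extraction(None, None, "flank_not_found")
    bc_start = p5 + len(layout.adaptor5)
    barcode = seq[bc_start : bc_start + layout.bc_len]
    if len(barcode) != layout.bc_len:
        return Extraction(None, None, "barcode_truncated")
    if layout.adaptor3:
        p3 = find_adaptor(seq, layout.adaptor3, layout.max_mismatch,
                          start=bc_start + layout.bc_len)
        if p3 != bc_start + layout.bc_len:
            return Extraction(None, None, "flank_not_found")
    if not set(barcode) <= VALID_BASES:
        return Extraction(None, None, "barcode_ambiguous_base")
    return Extraction(insert=None, barcode=barcode)


def barcode_qualities(read: Read, layout: BarcodeLayout) -> np.ndarray | None:
    """Phred qualities over the extracted barcode window (None if not found)."""
    seq = read.sequence.upper()
    p5 = find_adaptor(seq, layout.adaptor5, layout.max_mismatch)
    if p5 is None or read.qualities is None:
        return None
    bc_start = p5 + len(layout.adaptor5)
    if bc_start + layout.bc_len > len(seq):
        return None
    return read.qualities[bc_start : bc_start + layout.bc_len]


# ---------------------------------------------------------------------------
# Insert-to-design matching
# ---------------------------------------------------------------------------

class ReferenceIndex:
    """k-mer-seeded edit-distance matcher over the designed sequences.

    Candidate references sharing seeds with the query are aligned with
    edlib; the best hit is returned only when its identity reaches
    ``min_identity`` and its edit distance beats the runner-up by at least
    ``ambiguity_margin`` (the stand-in for a mapping-quality cutoff).
    """

    def __init__(self, references: Mapping[str, str], kmer: int = 11):
        if not references:
            raise ValueError("empty reference set")
        self.references = dict(references)
        self.kmer = kmer
        self._index: dict[str, set[str]] = defaultdict(set)
        for ref_id, seq in self.references.items():
            seq = seq.upper()
            for i in range(0, len(seq) - kmer + 1):
                self._index[seq[i : i + kmer]].add(ref_id)

    def candidates(self, query: str, max_candidates: int = 50) -> list[str]:
        counts: Counter[str] = Counter()
        q = query.upper()
        for i in range(0, len(q) - self.kmer + 1, max(1, self.kmer // 2)):
            for ref_id in self._index.get(q[i : i + self.kmer], ()):
                counts[ref_id] += 1
        if not counts:
            return list(self.references)
        return [r for r, _ in counts.most_common(max_candidates)]


def match_enhancer(
    insert: str,
    references: Mapping[str, str] | ReferenceIndex,
    min_identity: float = 0.9,
    ambiguity_margin: int = 2,
) -> str | None:
    """Assign an insert to the unique best-matching designed sequence.

    Returns None (unassigned) when no reference reaches *min_identity* or
    when the best edit distance does not beat the second best by
    *ambiguity_margin* — e.g. for inserts equally consistent with two
    overlapping tiles.
    """
    index = references if isinstance(references, ReferenceIndex) else ReferenceIndex(references)
    best_id, best_d, second_d = None, None, None
    for ref_id in index.candidates(insert):
        ref = index.references[ref_id]
        d = edlib.align(insert.upper(), ref.upper(), mode="NW", task="distance")[
            "editDistance"
        ]
        if best_d is None or d < best_d:
            best_id, best_d, second_d = ref_id, d, best_d
        elif second_d is None or d < second_d:
            second_d = d
    assert best_id is not None and best_d is not None
    identity = 1.0 - best_d / max(len(insert), len(index.references[best_id]))
    if identity < min_identity:
        return None
    if second_d is not None and second_d - best_d < ambiguity_margin:
        return None
    return best_id


def extract_paired_barcodes(
    read1: Read,
    read2: Read,
    layout1: BarcodeLayout,
    layout2: BarcodeLayout,
    design_bc_table: Mapping[str, str],
    min_q: float = 30.0,
    quality_mode: str = "mean",
) -> tuple[str, str] | tuple[None, str]:
    """(enhancer_id, random barcode) from a read pair, or (None, reason).

    Read 1 carries the design-identifying barcode (matched exactly against
    *design_bc_table*), read 2 the random barcode.  Both barcodes must
    exceed the quality cutoff strictly (Q > min_q, mean or per-base minimum
    depending on *quality_mode*).
    """
    ex1 = extract_barcode(read1, layout1)
    if not ex1.ok:
        return None, f"read1_{ex1.reject_reason}"
    ex2 = extract_barcode(read2, layout2)
    if not ex2.ok:
        return None, f"read2_{ex2.reject_reason}"
    for read, layout, label in ((read1, layout1, "read1"), (read2, layout2, "read2")):
        quals = barcode_qualities(read, layout)
        if quals is None:
            return None, f"{label}_no_quality"
        q = float(np.min(quals)) if quality_mode == "min" else float(np.mean(quals))
        if not q > min_q:
            return None, f"{label}_low_quality"
    enhancer = design_bc_table.get(ex1.barcode)
    if enhancer is None:
        return None, "design_bc_unknown"
    return enhancer, ex2.barcode


# ---------------------------------------------------------------------------
# Barcode map
# ---------------------------------------------------------------------------

@dataclass
class BarcodeMap:
    """Many-to-one map random barcode -> (enhancer_id, supporting reads)."""

    entries: dict[str, tuple[str, int]]
    library_id: str = ""
    bc_length: int = 17

    def __post_init__(self) -> None:
        for bc in self.entries:
            if len(bc) != self.bc_length or not set(bc) <= VALID_BASES:
                raise ValueError(f"invalid barcode {bc!r} for bc_length {self.bc_length}")

    def __len__(self) -> int:
        return len(self.entries)

    def enhancer_of(self, barcode: str) -> str | None:
        hit = self.entries.get(barcode)
        return hit[0] if hit else None

    def enhancers(self) -> set[str]:
        return {e for e, _ in self.entries.values()}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            (bc, enh, n) for bc, (enh, n) in self.entries.items()
        )
        return pd.DataFrame(rows, columns=["barcode", "enhancer_id", "n_reads"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, library_id: str = "") -> "BarcodeMap":
        frame = pd.read_csv(path, sep="\t", dtype={"barcode": str, "enhancer_id": str})
        entries = {
            row.barcode: (row.enhancer_id, int(row.n_reads))
            for row in frame.itertuples(index=False)
        }
        bc_length = len(next(iter(entries))) if entries else 17
        return cls(entries=entries, library_id=library_id, bc_length=bc_length)


@dataclass(frozen=True)
class AssignmentStats:
    """Recovery statistics over the designed set."""

    n_designed: int
    n_recovered: int
    fraction_recovered: float
    mean_bcs_per_enhancer: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_designed": self.n_designed,
                "n_recovered": self.n_recovered,
                "fraction_recovered": self.fraction_recovered,
                "mean_bcs_per_enhancer": self.mean_bcs_per_enhancer,
            },
            indent=2,
        )


def build_barcode_map(
    pairs: Iterable[tuple[str, str]],
    designed_ids: Sequence[str] | None = None,
    min_support: int = 1,
    dominance: float = 0.75,
    library_id: str = "",
) -> tuple[BarcodeMap, AssignmentStats]:
    """Resolve (enhancer, barcode) observations into a one-to-one barcode map.

    Reads for the same barcode vote: the majority enhancer keeps the
    barcode iff its read share is >= *dominance* and its read count is
    >= *min_support*; ties can never reach a dominance of 0.75 and are
    dropped.
    """
    votes: dict[str, Counter[str]] = defaultdict(Counter)
    bc_length = None
    for enhancer, barcode in pairs:
        votes[barcode][enhancer] += 1
        bc_length = len(barcode)
    entries: dict[str, tuple[str, int]] = {}
    for barcode, counter in votes.items():
        total = sum(counter.values())
        (top_enh, top_n), = counter.most_common(1)
        if top_n < min_support:
            continue
        if top_n / total >= dominance:
            entries[barcode] = (top_enh, top_n)
    bmap = BarcodeMap(
        entries=entries, library_id=library_id,
        bc_length=bc_length if bc_length is not None else 17,
    )
    recovered = bmap.enhancers()
    if designed_ids is not None:
        n_designed = len(set(designed_ids))
        recovered = recovered & set(designed_ids)
    else:
        n_designed = len(recovered)
    n_recovered = len(recovered)
    stats = AssignmentStats(
        n_designed=n_designed,
        n_recovered=n_recovered,
        fraction_recovered=(n_recovered / n_designed) if n_designed else float("nan"),
        mean_bcs_per_enhancer=(len(entries) / n_recovered) if n_recovered else float("nan"),
    )
    return bmap, stats


def assign_long_reads(
    reads: Iterable[Read],
    layout: LongReadLayout,
    references: Mapping[str, str],
    min_identity: float = 0.9,
    ambiguity_margin: int = 2,
    min_support: int = 1,
    dominance: float = 0.75,
    library_id: str = "",
) -> tuple[BarcodeMap, AssignmentStats, Counter]:
    """Full long-read assignment: extract, match, vote.

    Returns the barcode map, recovery statistics over the reference set,
    and a counter of rejection reasons.
    """
    index = ReferenceIndex(references)
    rejections: Counter[str] = Counter()
    pairs: list[tuple[str, str]] = []
    for read in reads:
        ex = extract_insert_and_barcode(read, layout)
        if not ex.ok:
            rejections[ex.reject_reason] += 1
            continue
        enh = match_enhancer(ex.insert, index, min_identity=min_identity,
                             ambiguity_margin=ambiguity_margin)
        if enh is None:
            rejections["unassigned_insert"] += 1
            continue
        pairs.append((enh, ex.barcode))
    bmap, stats = build_barcode_map(
        pairs, designed_ids=list(references), min_support=min_support,
        dominance=dominance, library_id=library_id,
    )
    return bmap, stats, rejections
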