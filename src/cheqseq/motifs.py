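"""Position-weight-matrix models, motif scanning, and targeted mutagenesis.

A :class:`PWM` is a per-position probability model over {A, C, G, T} for a
transcription-factor binding site, read from Cluster-Buster-style count
matrix files.  Scanning scores every window of a sequence with the log-odds
(in bits) of the PWM against a background composition and reports windows
above a threshold as :class:`MotifHit` objects.  The mutagenesis operator
destroys a hit by rewriting its most informative positions — two for a
monomeric site, four for a dimeric one — with the least favourable base,
which is the operation used to build motif-mutant reporter tiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

BASES = "ACGT"
_BASE_INDEX = {c: i for i, c in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Default log-odds cutoff, in bits, for calling a motif occurrence.
DEFAULT_SCAN_THRESHOLD = 5.0

UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string (N-aware, case preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Positional probability model of a binding motif.

    Parameters
    ----------
    name : str
        Motif identifier (taken from the ``>`` header of the matrix file).
    matrix : ndarray of shape (L, 4)
        Per-position probabilities over A, C, G, T; each row sums to 1.
    pseudocount : float
        Pseudocount that was added to each count during normalisation.
    background : ndarray of shape (4,)
        Background base composition used for log-odds scoring.
    arity : str
        ``"monomer"`` or ``"dimer"``; controls how many positions the
        mutagenesis operator rewrites (2 or 4).
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = 0.0
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    arity: str = "monomer"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"PWM {self.name!r}: matrix must be (L, 4)")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name!r}: rows must each sum to 1")
        if np.any(m < 0):
            raise ValueError(f"PWM {self.name!r}: negative probability")
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError(f"PWM {self.name!r}: background must sum to 1")
        if self.arity not in ("monomer", "dimer"):
            raise ValueError(f"PWM {self.name!r}: arity must be monomer or dimer")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """(L, 4) log2(p/background); zero probabilities map to -inf."""
        with np.errstate(divide="ignore"):
            return np.where(
                self.matrix > 0.0,
                np.log2(np.maximum(self.matrix, 1e-300) / self.background),
                -np.inf,
            )

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: 1-based inclusive coordinates on the scanned sequence."""

    sequence_id: str
    start: int
    end: int
    strand: str
    score: float
    motif_name: str


def parse_pwms(
    text: str,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    arities: Mapping[str, str] | str = "monomer",
) -> list[PWM]:
    """Parse Cluster-Buster-style count matrices into PWMs.

    The format is a ``>name`` header followed by one whitespace-separated
    ``A C G T`` count row per motif position; ``#`` lines are comments.
    Counts are converted to probabilities after adding *pseudocount* to
    every cell.  *arities* is either a single arity applied to all motifs
    or a mapping from motif name to arity (missing names default to
    ``"monomer"``).
    """
    if background is None:
        background = UNIFORM_BACKGROUND
    pwms: list[PWM] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush(lineno: int) -> None:
        nonlocal name, rows
        if name is None:
            return
        if not rows:
            raise ValueError(f"motif {name!r}: empty matrix block (line {lineno})")
        counts = np.asarray(rows, dtype=float) + pseudocount
        if np.any(counts.sum(axis=1) == 0):
            raise ValueError(f"motif {name!r}: all-zero row with zero pseudocount")
        matrix = counts / counts.sum(axis=1, keepdims=True)
        arity = arities if isinstance(arities, str) else arities.get(name, "monomer")
        pwms.append(
            PWM(name=name, matrix=matrix, pseudocount=pseudocount,
                background=np.asarray(background, dtype=float), arity=arity)
        )
        name, rows = None, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush(lineno)
            name = line[1:].strip().split()[0]
            continue
        if name is None:
            raise ValueError(f"line {lineno}: matrix row before any '>' header")
        fields_ = line.split()
        if len(fields_) != 4:
            raise ValueError(
                f"line {lineno}: expected 4 count fields (A C G T), got {len(fields_)}"
            )
        try:
            row = [float(x) for x in fields_]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric count field") from exc
        if any(x < 0 for x in row):
            raise ValueError(f"line {lineno}: negative count")
        rows.append(row)
    flush(lineno=-1)
    if not pwms:
        raise ValueError("no matrix blocks found")
    return pwms


def load_pwms(path, pseudocount: float = 0.5, **kwargs) -> list[PWM]:
    """Read PWMs from a Cluster-Buster-style matrix file."""
    with open(path) as fh:
        return parse_pwms(fh.read(), pseudocount=pseudocount, **kwargs)


def load_pwm(path, pseudocount: float = 0.5, **kwargs) -> PWM:
    """Read a single-motif matrix file (error if it holds several)."""
    pwms = load_pwms(path, pseudocount=pseudocount, **kwargs)
    if len(pwms) != 1:
        raise ValueError(f"{path}: expected exactly one matrix, found {len(pwms)}")
    return pwms[0]


def pwm_from_consensus(
    consensus: str,
    name: str = "consensus",
    p_consensus: float = 0.97,
    arity: str = "monomer",
) -> PWM:
    """Build a sharp PWM matching a consensus string (testing/design helper)."""
    L = len(consensus)
    off = (1.0 - p_consensus) / 3.0
    matrix = np.full((L, 4), off)
    for i, c in enumerate(consensus.upper()):
        matrix[i, _BASE_INDEX[c]] = p_consensus
    return PWM(name=name, matrix=matrix, arity=arity)


def information_content(pwm: PWM) -> np.ndarray:
    """Per-position information content in bits: sum_b p log2(p/q).

    With a uniform background this equals ``2 + sum_b p log2 p``; fully
    certain positions carry 2 bits, uniform positions 0.  The convention
    0·log 0 = 0 applies.
    """
    p = pwm.matrix
    q = pwm.background
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.maximum(p, 1e-300) / q), 0.0)
    return terms.sum(axis=1)


def encode(sequence: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and anything else (N) as 4."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def scan(
    sequence: str,
    pwm: PWM,
    threshold: float = DEFAULT_SCAN_THRESHOLD,
    strands: str = "both",
    sequence_id: str = "",
) -> list[MotifHit]:
    """All windows scoring >= *threshold* bits, sorted by start then strand.

    Windows containing N are skipped.  Sequences shorter than the motif
    yield an empty list.  Reverse-strand hits are reported in forward
    coordinates with ``strand='-'``.
    """
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    L = pwm.length
    if len(sequence) < L:
        return []
    idx = encode(sequence)
    win = sliding_window_view(idx, L)
    valid = (win != 4).all(axis=1)
    safe = np.where(win == 4, 0, win).astype(np.intp)
    lo = pwm.log_odds()
    pos = np.arange(L)
    with np.errstate(invalid="ignore"):
        fwd = lo[pos[None, :], safe].sum(axis=1)
    hits: list[tuple[int, int, float]] = []  # (start0, strand_rank, score)
    ok_f = valid & (fwd >= threshold)
    for i in np.nonzero(ok_f)[0]:
        hits.append((int(i), 0, float(fwd[i])))
    if strands == "both":
        # scoring the window's reverse complement == scoring with the
        # position-reversed, base-complemented matrix
        rc_lo = lo[::-1, ::-1]
        with np.errstate(invalid="ignore"):
            rev = rc_lo[pos[None, :], safe].sum(axis=1)
        ok_r = valid & (rev >= threshold)
        for i in np.nonzero(ok_r)[0]:
            hits.append((int(i), 1, float(rev[i])))
    hits.sort()
    return [
        MotifHit(
            sequence_id=sequence_id,
            start=i + 1,
            end=i + L,
            strand="+" if rank == 0 else "-",
            score=score,
            motif_name=pwm.name,
        )
        for i, rank, score in hits
    ]


def collapse_palindromic(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Collapse same-window, both-strand duplicate hits to the forward one."""
    seen: dict[tuple[str, int, int, str], MotifHit] = {}
    for h in sorted(hits, key=lambda h: (h.start, 0 if h.strand == "+" else 1)):
        key = (h.sequence_id, h.start, h.end, h.motif_name)
        if key not in seen:
            seen[key] = h
    return sorted(seen.values(), key=lambda h: (h.start, h.strand))


def mutation_positions(hit: MotifHit, pwm: PWM, k: int | None = None) -> list[int]:
    """1-based sequence positions the mutagenesis operator will rewrite.

    The k highest-information-content motif positions are chosen (k = 2 for
    monomers, 4 for dimers); ties break toward the leftmost motif position.
    Positions are mapped through the hit's strand onto the scanned sequence.
    """
    if k is None:
        k = 4 if pwm.arity == "dimer" else 2
    if k > pwm.length:
        raise ValueError(f"k={k} exceeds motif length {pwm.length}")
    ic = information_content(pwm)
    order = np.argsort(-ic, kind="stable")[:k]
    if hit.strand == "+":
        seq_pos = [hit.start + int(j) for j in order]
    else:
        seq_pos = [hit.end - int(j) for j in order]
    return sorted(seq_pos)


def _replacement_base(pwm: PWM, motif_pos: int, current: str) -> str:
    """Lowest-probability base at a motif position, never the observed base.

    Probability ties break in A < C < G < T order.
    """
    probs = pwm.matrix[motif_pos]
    candidates = sorted(
        (b for b in BASES if b != current),
        key=lambda b: (probs[_BASE_INDEX[b]], b),
    )
    return candidates[0]


def mutate_hit(sequence: str, hit: MotifHit, pwm: PWM, k: int | None = None) -> str:
    """Destroy a motif occurrence by rewriting its most informative bases.

    Exactly k characters change (k = 2 monomer / 4 dimer), all inside the
    hit window; each is replaced by the least-probable alternative base at
    that motif position, complemented for reverse-strand hits.
    """
    if hit.start < 1 or hit.end > len(sequence):
        raise ValueError(
            f"hit {hit.start}-{hit.end} out of bounds for sequence of "
            f"length {len(sequence)}"
        )
    if k is None:
        k = 4 if pwm.arity == "dimer" else 2
    chars = list(sequence)
    for pos in mutation_positions(hit, pwm, k=k):
        if hit.strand == "+":
            motif_pos = pos - hit.start
            current = chars[pos - 1].upper()
            chars[pos - 1] = _replacement_base(pwm, motif_pos, current)
        else:
            motif_pos = hit.end - pos
            current = chars[pos - 1].upper().translate(_COMPLEMENT)
            repl = _replacement_base(pwm, motif_pos, current)
            chars[pos - 1] = repl.translate(_COMPLEMENT)
    return "".join(chars)


def hits_to_bed6(hits: Iterable[MotifHit]) -> str:
    """Render hits as BED6 (0-based half-open; score = bits x 100, rounded)."""
    lines = []
    for h in hits:
        lines.append(
            f"{h.sequence_id}\t{h.start - 1}\t{h.end}\t{h.motif_name}\t"
            f"{round(h.score * 100)}\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
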