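"""Ground-truthed synthetic data for every pipeline stage.

The generative model mirrors the structure of barcoded reporter data:

* each enhancer is represented by many random barcodes; per-barcode plasmid
  abundance is log-normal (cloning and amplification are uneven);
* cDNA propensity multiplies plasmid abundance by 2^(true log2 activity)
  with per-barcode multiplicative noise (log-normal on the log2 scale);
* plasmid and cDNA counts are multinomial draws at fixed sequencing depth,
  so column totals are exact and CPM denominators sharp;
* reads carry adaptor-flanked barcodes with constant Phred-37 qualities and
  optional seeded substitution errors.

Shuffled-control enhancers have true activity exactly 0.  All generators
are pure functions of (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assignment import BarcodeLayout, LongReadLayout
from .design import RegionRecord
from .io import Read

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default simulated Phred quality (well above the Q>30 gate).
DEFAULT_PHRED = 37


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic reporter experiment.

    ``activity`` is a distribution spec for the true log2 activity of test
    enhancers: ``("point", v)``, ``("uniform", lo, hi)`` or
    ``("mixture", fraction_active, effect)`` (the rest sit at 0).
    Controls always have true activity 0.
    """

    seed: int
    n_enhancers: int = 200
    n_controls: int = 800
    activity: tuple = ("point", 0.0)
    bcs_per_enhancer: int = 50
    depth_plasmid: int = 2_000_000
    depth_cdna: int = 2_000_000
    bc_abundance_sd: float = 1.0   # ln-scale SD of per-barcode plasmid abundance
    activity_noise_sd: float = 0.75  # log2-scale SD of per-barcode activity noise
    read_error_rate: float = 0.0
    bc_len: int = 17

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.n_enhancers + self.n_controls, self.bcs_per_enhancer,
               self.depth_plasmid, self.depth_cdna) <= 0:
            raise ValueError("counts and depths must be positive")
        if min(self.bc_abundance_sd, self.activity_noise_sd, self.read_error_rate) < 0:
            raise ValueError("SDs and error rates must be >= 0")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated enhancer."""

    enhancer_id: str
    cls: str  # test | shuffled_control
    true_log2fc: float
    barcodes: tuple[str, ...]


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    draws = rng.integers(0, 4, size=(n, length))
    return [bytes(BASES[row]).decode("ascii") for row in draws]


def _unique_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < n:
        for bc in _random_seqs(rng, n - len(barcodes), length):
            if bc not in seen:
                seen.add(bc)
                barcodes.append(bc)
    return barcodes


def _draw_activities(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    kind = spec[0]
    if kind == "point":
        return np.full(n, float(spec[1]))
    if kind == "uniform":
        return rng.uniform(float(spec[1]), float(spec[2]), size=n)
    if kind == "mixture":
        fraction, effect = float(spec[1]), float(spec[2])
        n_active = int(round(fraction * n))
        acts = np.zeros(n)
        acts[:n_active] = effect
        return acts
    raise ValueError(f"unknown activity spec {spec!r}")


def simulate_truth(config: SimConfig) -> list[SimTruth]:
    """Enhancer identities, true activities, and globally unique barcodes."""
    rng = np.random.default_rng(config.seed)
    n_total = config.n_enhancers + config.n_controls
    all_bcs = _unique_barcodes(rng, n_total * config.bcs_per_enhancer, config.bc_len)
    activities = _draw_activities(rng, config.activity, config.n_enhancers)
    truths = []
    for i in range(n_total):
        is_test = i < config.n_enhancers
        bcs = tuple(
            all_bcs[i * config.bcs_per_enhancer : (i + 1) * config.bcs_per_enhancer]
        )
        truths.append(
            SimTruth(
                enhancer_id=(f"enh_{i:05d}" if is_test else
                             f"shuffle_{i - config.n_enhancers:05d}"),
                cls="test" if is_test else "shuffled_control",
                true_log2fc=float(activities[i]) if is_test else 0.0,
                barcodes=bcs,
            )
        )
    return truths


def truth_barcode_map(truth: Sequence[SimTruth]):
    """The true barcode -> enhancer assignment as a BarcodeMap."""
    from .assignment import BarcodeMap

    entries = {}
    bc_len = len(truth[0].barcodes[0]) if truth and truth[0].barcodes else 17
    for t in truth:
        for bc in t.barcodes:
            entries[bc] = (t.enhancer_id, 1)
    return BarcodeMap(entries=entries, library_id="sim", bc_length=bc_len)


def simulate_counts(truth: Sequence[SimTruth], config: SimConfig):
    """Plasmid and cDNA barcode count tables under the noise model.

    Per-barcode plasmid abundance a_b ~ LogNormal(0, bc_abundance_sd);
    plasmid counts ~ Multinomial(depth_plasmid, a / sum a); cDNA propensity
    a_b * 2^(t_e + eps_b) with eps_b ~ Normal(0, activity_noise_sd); cDNA
    counts ~ Multinomial(depth_cdna, normalised propensity).
    """
    from .quantify import BarcodeCountTable

    rng = np.random.default_rng(config.seed + 1)
    barcodes: list[str] = []
    t_per_bc: list[float] = []
    for t in truth:
        barcodes.extend(t.barcodes)
        t_per_bc.extend([t.true_log2fc] * len(t.barcodes))
    n = len(barcodes)
    if config.depth_plasmid < 10 * n or config.depth_cdna < 10 * n:
        warnings.warn(
            f"sequencing depth below 10x the {n} barcodes; estimates will be noisy"
        )
    abundance = np.exp(rng.normal(0.0, config.bc_abundance_sd, size=n))
    p_plasmid = abundance / abundance.sum()
    plasmid_counts = rng.multinomial(config.depth_plasmid, p_plasmid)
    eps = rng.normal(0.0, config.activity_noise_sd, size=n)
    propensity = abundance * np.exp2(np.asarray(t_per_bc) + eps)
    p_cdna = propensity / propensity.sum()
    cdna_counts = rng.multinomial(config.depth_cdna, p_cdna)
    plasmid = BarcodeCountTable(
        sample_id="sim_plasmid", role="plasmid",
        counts={bc: int(c) for bc, c in zip(barcodes, plasmid_counts) if c > 0},
    )
    cdna = BarcodeCountTable(
        sample_id="sim_cdna", role="cdna",
        counts={bc: int(c) for bc, c in zip(barcodes, cdna_counts) if c > 0},
    )
    return plasmid, cdna


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = BASES[BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return bytes(arr).decode("ascii")


def simulate_reads(
    table,
    layout: BarcodeLayout,
    config: SimConfig,
    phred: int = DEFAULT_PHRED,
    seed: int | None = None,
) -> list[Read]:
    """Barcode-bearing reads realising a count table exactly.

    One read per counted molecule: adaptor5 + barcode + adaptor3, constant
    Phred qualities, substitution errors at ``config.read_error_rate``.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    reads = []
    i = 0
    for bc in sorted(table.counts):
        for _ in range(table.counts[bc]):
            seq = layout.adaptor5 + bc + layout.adaptor3
            seq = _apply_errors(rng, seq, config.read_error_rate)
            reads.append(
                Read(
                    name=f"{table.sample_id}_{i:08d}",
                    sequence=seq,
                    qualities=np.full(len(seq), phred, dtype=np.int16),
                )
            )
            i += 1
    return reads


def simulate_long_reads(
    oligos: Mapping[str, str],
    truth_map: Mapping[str, str],
    layout: LongReadLayout,
    n_reads_per_bc: int = 3,
    error_rate: float = 0.0,
    seed: int = 0,
    phred: int = DEFAULT_PHRED,
) -> list[Read]:
    """Assignment-style long reads: adaptor5 + enhancer + linker + barcode.

    *oligos* maps enhancer_id to designed insert sequence; *truth_map* maps
    each random barcode to its true enhancer_id.
    """
    rng = np.random.default_rng(seed)
    reads = []
    i = 0
    for bc in sorted(truth_map):
        enh = truth_map[bc]
        template = layout.adaptor5 + oligos[enh] + layout.linker + bc
        for _ in range(n_reads_per_bc):
            seq = _apply_errors(rng, template, error_rate)
            reads.append(
                Read(
                    name=f"long_{i:08d}",
                    sequence=seq,
                    qualities=np.full(len(seq), phred, dtype=np.int16),
                )
            )
            i += 1
    return reads


def simulate_regions(
    n_regions: int,
    length: int,
    seed: int,
    planted_motif: str | None = None,
    planted_position: int | None = None,
) -> tuple[list[RegionRecord], list[int | None]]:
    """Random regions, optionally with a consensus site planted per region.

    Returns the regions and the 1-based plant position per region (None
    when nothing was planted).  A motif longer than the region is an error.
    """
    rng = np.random.default_rng(seed)
    if planted_motif is not None and len(planted_motif) > length:
        raise ValueError("planted motif longer than region")
    regions, positions = [], []
    for i, seq in enumerate(_random_seqs(rng, n_regions, length)):
        pos: int | None = None
        if planted_motif is not None:
            pos = (
                planted_position
                if planted_position is not None
                else int(rng.integers(1, length - len(planted_motif) + 2))
            )
            seq = (
                seq[: pos - 1] + planted_motif + seq[pos - 1 + len(planted_motif):]
            )
        regions.append(RegionRecord(region_id=f"region_{i:04d}", sequence=seq))
        positions.append(pos)
    return regions, positions


def truth_to_frame(truth: Sequence[SimTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "enhancer_id": [t.enhancer_id for t in truth],
            "class": [t.cls for t in truth],
            "true_log2fc": [t.true_log2fc for t in truth],
            "barcodes": [",".join(t.barcodes) for t in truth],
        }
    )


def frame_to_truth(frame: pd.DataFrame) -> list[SimTruth]:
    return [
        SimTruth(
            enhancer_id=row["enhancer_id"],
            cls=row["class"],
            true_log2fc=float(row["true_log2fc"]),
            barcodes=tuple(row["barcodes"].split(",")) if row["barcodes"] else (),
        )
        for row in frame.to_dict("records")
    ]
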