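import numpy as np
import pytest

from cheqseq import motifs


@pytest.fixture
def palindromic_pwm():
    """Sharp CACGTG model (its own reverse complement)."""
    return motifs.pwm_from_consensus("CACGTG", name="EBOX", p_consensus=0.97)


@pytest.fixture
def graded_pwm():
    """Monomer PWM whose positions 3 and 4 dominate the information content.

    At both high-IC positions T is the strictly least probable base, so the
    mutagenesis operator must rewrite sequence positions 5 and 6 of a hit
    starting at position 3 with T.
    """
    lo = [0.4, 0.2, 0.2, 0.2]
    matrix = np.array(
        [
            [0.2, 0.4, 0.2, 0.2],        # weak C
            [0.4, 0.2, 0.2, 0.2],        # weak A
            [0.012, 0.970, 0.012, 0.006],  # strong C, min T
            [0.012, 0.012, 0.970, 0.006],  # strong G, min T
            [0.2, 0.2, 0.2, 0.4],        # weak T
            [0.2, 0.2, 0.4, 0.2],        # weak G
        ]
    )
    return motifs.PWM(name="graded", matrix=matrix, arity="monomer")


def brute_force_scan(sequence, pwm, threshold, strands="both"):
    """Score-every-window oracle independent of the vectorised scanner."""
    hits = []
    L = pwm.length
    seq = sequence.upper()
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        if "N" in window:
            continue
        for strand in ("+", "-") if strands == "both" else ("+",):
            w = window if strand == "+" else motifs.reverse_complement(window)
            score = 0.0
            for j, base in enumerate(w):
                p = pwm.matrix[j, "ACGT".index(base)]
                q = pwm.background["ACGT".index(base)]
                score += float(np.log2(p / q)) if p > 0 else float("-inf")
            if score >= threshold:
                hits.append((start + 1, start + L, strand, round(score, 9)))
    return hits


def random_sequence(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
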