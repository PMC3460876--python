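"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (pure-Python loops, statistics
module) and never call the vectorized library paths they are used to check.
"""

from __future__ import annotations

import statistics

import numpy as np
import pytest

from pcdt.aaindex import NormalizedIndexSet
from pcdt.alphabet import AAINDEX_ORDER
from pcdt.pdt import ProteinSequence
from pcdt.synthetic import make_toy_indices

# A small AAIndex1 flat-file fixture: three well-formed records, the second
# with one NA (missing) value, the third all-zero.  Written inline so parser
# tests do not depend on the package's own writer.
AAINDEX_FIXTURE = """\
H TEST0001
D toy hydrophobicity scale
R PMID:0
A Nobody, A.
T A made-up scale for testing
J None (2020)
C TEST0002    0.5
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.62   -2.53   -0.78   -0.90    0.29   -0.85   -0.74    0.48   -0.40    1.38
     1.06   -1.50    0.64    1.19    0.12   -0.18   -0.05    0.81    0.26    1.08
//
H TEST0002
D scale with a missing tryptophan value
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.00    2.00    3.00    4.00    5.00    6.00    7.00    8.00    9.00   10.00
    11.00   12.00   13.00   14.00   15.00   16.00   17.00      NA   19.00   20.00
//
H TEST0003
D all-zero scale
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.00    0.00    0.00    0.00    0.00    0.00    0.00    0.00    0.00    0.00
     0.00    0.00    0.00    0.00    0.00    0.00    0.00    0.00    0.00    0.00
//
"""

# Same grammar but the first row of the I block has only nine values.
AAINDEX_BROKEN_FIXTURE = """\
H BAD0001
D nineteen values only
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.62   -2.53   -0.78   -0.90    0.29   -0.85   -0.74    0.48   -0.40
     1.06   -1.50    0.64    1.19    0.12   -0.18   -0.05    0.81    0.26    1.08
//
"""


@pytest.fixture
def aaindex_file(tmp_path):
    path = tmp_path / "aaindex1.txt"
    path.write_text(AAINDEX_FIXTURE)
    return path


@pytest.fixture
def broken_aaindex_file(tmp_path):
    path = tmp_path / "aaindex1_broken.txt"
    path.write_text(AAINDEX_BROKEN_FIXTURE)
    return path


@pytest.fixture(scope="session")
def toy_indices():
    return make_toy_indices(5, seed=1)


@pytest.fixture(scope="session")
def index_set(toy_indices):
    return NormalizedIndexSet.build(toy_indices)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequences(n, rng, min_len=20, max_len=200, prefix="rand"):
    """Seeded random standard-residue sequences."""
    seqs = []
    for i in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        letters = rng.integers(0, 20, size=L)
        seqs.append(
            ProteinSequence(
                id=f"{prefix}{i:03d}",
                residues="".join(AAINDEX_ORDER[c] for c in letters),
            )
        )
    return seqs


# ---------------------------------------------------------------------------
# independent oracles


def zscore_oracle(values):
    """Population z-score via the statistics module (no numpy)."""
    mu = statistics.mean(values)
    sigma = statistics.pstdev(values)
    return [(v - mu) / sigma for v in values]


def normalize_index_oracle(idx):
    """Z-normalized residue->value map computed with pure Python."""
    residues = list(AAINDEX_ORDER)
    normed = zscore_oracle([idx.raw_values[aa] for aa in residues])
    return dict(zip(residues, normed))


def pdt_oracle(residues, norm_maps, beta):
    """Brute-force triple-loop PDT over (index, lag, position).

    ``norm_maps`` is a list of residue->normalized-value dicts in layout
    order; returns a flat list, index-major then lag.
    """
    L = len(residues)
    out = []
    for norm in norm_maps:
        for lam in range(1, beta + 1):
            total = 0.0
            for i in range(L - lam):
                a = norm.get(residues[i], 0.0)
                b = norm.get(residues[i + lam], 0.0)
                total += (a - b) ** 2
            out.append(total / (L - lam))
    return out


def roc_oracle(scores, labels):
    """Mann-Whitney concordant-pair count; ties get half credit."""
    pos = [s for s, l in zip(scores, labels) if l > 0]
    neg = [s for s, l in zip(scores, labels) if l <= 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def roc50_oracle(scores, labels, max_fp=50):
    """Rank-walk truncated ROC area for tie-free score lists.

    Sorts descending, accumulates the true-positive count at each false
    positive up to the cutoff, and normalizes by P * min(max_fp, N).
    """
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    P = sum(1 for l in labels if l > 0)
    N = len(labels) - P
    cap = min(max_fp, N)
    tp = fp = 0
    area = 0.0
    for i in order:
        if labels[i] > 0:
            tp += 1
        else:
            fp += 1
            area += tp
            if fp == cap:
                break
    return area / (P * cap)


def pseudo_count_oracle(freqs, background, q, mode):
    """Explicit 20-term double loop for the pseudo-count vector."""
    g = []
    for i in range(20):
        acc = 0.0
        for j in range(20):
            if mode == "frequency":
                acc += freqs[j] * q[i][j] / background[j]
            else:
                acc += freqs[j] * q[i][j]
        g.append(acc)
    return g


def target_frequency_oracle(freqs, distinct_count, background, q, mode, beta_pc=10.0):
    """Blend-and-renormalize oracle mirroring the published formula."""
    alpha = distinct_count - 1
    g = pseudo_count_oracle(freqs, background, q, mode)
    blended = [
        max((alpha * f + beta_pc * gi) / (alpha + beta_pc), 0.0)
        for f, gi in zip(freqs, g)
    ]
    total = sum(blended)
    return [b / total for b in blended]
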