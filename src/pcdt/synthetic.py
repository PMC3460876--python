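"""Synthetic fixtures: toy index tables, planted-signal protein families and
degenerate single-sequence profiles.

Families are planted so that the classes differ only in residue *order*:
positive sequences alternate between high-property and low-property residue
groups (groups defined by one designated toy index) with period lambda*, and
each negative is a seeded shuffle of a positive — identical composition,
destroyed order.  Only sequence-order-aware descriptors can separate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aaindex import AminoAcidIndex, normalize_index
from .alphabet import AAINDEX_ORDER
from .evaluate import BenchmarkSplit
from .pdt import ProteinSequence
from .profiles import FrequencyProfile

__all__ = [
    "SyntheticFamilySpec",
    "make_toy_indices",
    "make_family_dataset",
    "make_degenerate_profile",
]


def make_toy_indices(k: int, seed: int = 0) -> list[AminoAcidIndex]:
    """k random, non-degenerate, non-all-zero property indices (seeded)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    rng = np.random.default_rng(seed)
    indices = []
    for i in range(k):
        values = rng.normal(size=20)
        while np.allclose(values.std(), 0):  # pragma: no cover - vanishing odds
            values = rng.normal(size=20)
        indices.append(
            AminoAcidIndex(
                accession=f"TOY{i:04d}",
                title=f"synthetic toy index {i}",
                raw_values=dict(zip(AAINDEX_ORDER, values.tolist())),
            )
        )
    return indices


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Parameters of one planted-signal family.

    ``signal_index`` selects which toy index (by list position) defines the
    high/low residue groups; ``signal_lambda`` is the planted period; an
    ``effect_size`` of 1 plants a clean alternation, 0 plants nothing
    (negative control).
    """

    n_pos: int = 60
    n_neg: int = 60
    min_length: int = 150
    max_length: int = 250
    signal_index: int = 0
    signal_lambda: int = 2
    effect_size: float = 1.0
    seed: int = 0
    family_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.signal_lambda > self.min_length - 1:
            raise ValueError("signal_lambda must be <= min_length - 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.min_length < 2 or self.max_length < self.min_length:
            raise ValueError("invalid length range")


def _signal_groups(index: AminoAcidIndex) -> tuple[list[str], list[str]]:
    """Split the 20 residues into the top-10 (high) and bottom-10 (low)
    by the normalized value of the signal index."""
    norm = normalize_index(index)
    ranked = sorted(AAINDEX_ORDER, key=lambda aa: -norm[aa])
    return ranked[:10], ranked[10:]


def make_family_dataset(
    spec: SyntheticFamilySpec,
    indices: list[AminoAcidIndex] | None = None,
) -> BenchmarkSplit:
    """Generate one family's disjoint train/test split (seeded, deterministic).

    Positives carry a period-``signal_lambda`` alternation of the signal
    index's high/low residue groups; each negative is a shuffle of its
    positive counterpart, so counterpart compositions match exactly.
    """
    if indices is None:
        indices = make_toy_indices(max(spec.signal_index + 1, 5), seed=spec.seed)
    high, low = _signal_groups(indices[spec.signal_index])
    rng = np.random.default_rng(spec.seed)
    n_templates = max(spec.n_pos, spec.n_neg)

    templates: list[str] = []
    for _ in range(n_templates):
        L = int(rng.integers(spec.min_length, spec.max_length + 1))
        chars = []
        p_signal = min(1.0, spec.effect_size)
        for i in range(L):
            group = high if (i // spec.signal_lambda) % 2 == 0 else low
            if rng.random() < p_signal:
                chars.append(group[rng.integers(len(group))])
            else:
                chars.append(AAINDEX_ORDER[rng.integers(20)])
        templates.append("".join(chars))

    fam = spec.family_id
    positives = [
        ProteinSequence(id=f"{fam}_pos{i:03d}", residues=templates[i])
        for i in range(spec.n_pos)
    ]
    negatives = [
        ProteinSequence(
            id=f"{fam}_neg{i:03d}",
            residues="".join(rng.permutation(list(templates[i])).tolist()),
        )
        for i in range(spec.n_neg)
    ]

    # alternate into train/test so ids stay disjoint and classes balanced
    return BenchmarkSplit(
        family_id=fam,
        train_pos=positives[0::2],
        test_pos=positives[1::2],
        train_neg=negatives[0::2],
        test_neg=negatives[1::2],
    )


def make_degenerate_profile(seq: ProteinSequence) -> FrequencyProfile:
    """Single-sequence profile: row i puts probability 1 on residue A_i."""
    matrix = np.zeros((len(seq), 20))
    for i, aa in enumerate(seq.residues):
        col = AAINDEX_ORDER.index(aa)
        matrix[i, col] = 1.0
    return FrequencyProfile(id=seq.id, matrix=matrix)
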