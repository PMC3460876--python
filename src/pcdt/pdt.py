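"""The physicochemical distance transformation (PDT).

A protein of length L is converted, for each normalized amino-acid property
index j and each lag lam = 1..beta, into the mean squared difference of the
property over all residue pairs separated by lam positions:

    component(j, lam) = (1 / (L - lam)) * sum_i (I_j(A_i) - I_j(A_{i+lam}))^2

The feature vector concatenates these components index-major, lag-minor, so
its length is n_indices * beta (sequence mode).  Non-standard residues
contribute the normalized value 0 (the index mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .alphabet import encode, nonstandard_letters
from .aaindex import NormalizedIndexSet

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinSequence",
    "PDTParams",
    "FeatureAnnotation",
    "FeatureMatrix",
    "DistanceExceedsLengthError",
    "pair_distance",
    "pdt_component",
    "transform",
    "transform_batch",
    "feature_annotations",
    "write_feature_tsv",
    "write_feature_npz",
    "read_feature_npz",
]


class DistanceExceedsLengthError(ValueError):
    """Raised when a lag lam >= L leaves no residue pair to average over."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein chain: an id and an ordered residue string A_1..A_L."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PDTParams:
    """Transform parameters; ``beta`` is the maximum lag (lam = 1..beta)."""

    beta: int = 8

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError(f"beta must be >= 1, got {self.beta}")


class FeatureAnnotation(NamedTuple):
    """Identity of one feature position: (index accession, lag, profile rank n)."""

    accession: str
    lam: int
    n: int


def feature_annotations(
    indices: NormalizedIndexSet, params: PDTParams, n_max: int = 1
) -> list[FeatureAnnotation]:
    """Annotations for the pinned layout: n-major, then index-major, lag-minor."""
    return [
        FeatureAnnotation(acc, lam, n)
        for n in range(1, n_max + 1)
        for acc in indices.accessions
        for lam in range(1, params.beta + 1)
    ]


def pair_distance(a: str, b: str, norm_index: Mapping[str, float]) -> float:
    """Squared difference of normalized property values of residues *a*, *b*.

    Non-standard residues take the value 0 (the index mean).
    """
    return (norm_index.get(a, 0.0) - norm_index.get(b, 0.0)) ** 2


def pdt_component(
    seq: ProteinSequence, norm_index: Mapping[str, float], lam: int
) -> float:
    """Average pair distance over all residue pairs at lag *lam* (1 <= lam <= L-1)."""
    L = len(seq)
    if lam < 1:
        raise ValueError(f"lam must be >= 1, got {lam}")
    if lam >= L:
        raise DistanceExceedsLengthError(
            f"sequence {seq.id!r}: lag {lam} >= length {L}"
        )
    x = np.array([norm_index.get(c, 0.0) for c in seq.residues], dtype=float)
    d = x[lam:] - x[:-lam]
    return float(np.mean(d * d))


def _warn_nonstandard(seq: ProteinSequence) -> None:
    extra = nonstandard_letters(seq.residues)
    if extra:
        logger.warning(
            "sequence %r: non-standard residues %s assigned normalized value 0",
            seq.id, "".join(sorted(extra)),
        )


def transform(
    seq: ProteinSequence, indices: NormalizedIndexSet, params: PDTParams
) -> np.ndarray:
    """Transform one sequence into its PDT feature vector.

    Layout is index-major, lag-minor: block j holds components for
    lam = 1..beta of index j.  Length = ``len(indices) * params.beta``.
    """
    L = len(seq)
    if params.beta >= L:
        raise DistanceExceedsLengthError(
            f"sequence {seq.id!r}: beta {params.beta} >= length {L}"
        )
    _warn_nonstandard(seq)
    codes = encode(seq.residues)
    series = indices.lookup_table()[:, codes]  # (n_idx, L)
    out = np.empty((indices.n_indices, params.beta), dtype=float)
    for lam in range(1, params.beta + 1):
        d = series[:, lam:] - series[:, :-lam]
        out[:, lam - 1] = np.mean(d * d, axis=1)
    return out.ravel()


@dataclass
class FeatureMatrix:
    """Batch transform output: one row per surviving sequence, input order."""

    ids: list[str]
    values: np.ndarray
    annotations: list[FeatureAnnotation]
    skipped: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def transform_batch(
    seqs: Sequence[ProteinSequence],
    indices: NormalizedIndexSet,
    params: PDTParams,
    strict: bool = True,
) -> FeatureMatrix:
    """Transform a batch of sequences; row order follows input order.

    In strict mode any sequence with L <= beta aborts the batch; in lenient
    mode such sequences are skipped and logged.
    """
    rows: list[np.ndarray] = []
    ids: list[str] = []
    skipped: list[str] = []
    for seq in seqs:
        try:
            rows.append(transform(seq, indices, params))
        except DistanceExceedsLengthError:
            if strict:
                raise
            skipped.append(seq.id)
            logger.warning(
                "transform_batch: skipping %r (length %d <= beta %d)",
                seq.id, len(seq), params.beta,
            )
            continue
        ids.append(seq.id)
    n_feat = indices.n_indices * params.beta
    values = np.vstack(rows) if rows else np.empty((0, n_feat))
    return FeatureMatrix(
        ids=ids,
        values=values,
        annotations=feature_annotations(indices, params),
        skipped=skipped,
    )


def write_feature_npz(matrix: FeatureMatrix, path: str | Path) -> None:
    """Dense binary container for large runs; layout travels in the archive."""
    np.savez_compressed(
        path,
        ids=np.array(matrix.ids),
        values=matrix.values,
        accessions=np.array([a.accession for a in matrix.annotations]),
        lams=np.array([a.lam for a in matrix.annotations]),
        ns=np.array([a.n for a in matrix.annotations]),
    )


def read_feature_npz(path: str | Path) -> FeatureMatrix:
    with np.load(path, allow_pickle=False) as archive:
        annotations = [
            FeatureAnnotation(str(acc), int(lam), int(n))
            for acc, lam, n in zip(
                archive["accessions"], archive["lams"], archive["ns"]
            )
        ]
        return FeatureMatrix(
            ids=[str(i) for i in archive["ids"]],
            values=archive["values"],
            annotations=annotations,
        )


def write_feature_tsv(
    matrix: FeatureMatrix,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a feature matrix as TSV with layout metadata in '#' header lines."""
    with open(path, "w") as out:
        for key, val in (metadata or {}).items():
            out.write(f"# {key}={val}\n")
        cols = [f"{a.accession}:lam{a.lam}:n{a.n}" for a in matrix.annotations]
        out.write("id\t" + "\t".join(cols) + "\n")
        for sid, row in zip(matrix.ids, matrix.values):
            out.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
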