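"""Frequency profiles: pseudo-count-smoothed target frequencies from a
query-anchored multiple alignment, and the n-th-most-frequent-residue
sequences consumed by profile-based PDT.

Per alignment column the observed residue frequencies f are blended with
pseudo-counts g:

    target_i = (alpha * f_i + beta_pc * g_i) / (alpha + beta_pc)

where alpha = (number of distinct residues in the column) - 1 and beta_pc is
a constant 10.  Pseudo-counts derive from BLOSUM62: by default g_i =
sum_j f_j * q_ij / p_j with q the BLOSUM62-implied pair (target)
frequencies and p the background frequencies; a literal "score" mode using
the raw log-odds scores is available.  Rows are renormalized to sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import AAINDEX_ORDER, RESIDUE_TO_COLUMN, STANDARD_RESIDUES
from .aaindex import NormalizedIndexSet
from .pdt import PDTParams, ProteinSequence, transform

logger = logging.getLogger(__name__)

__all__ = [
    "GAP_CHARACTERS",
    "ROBINSON_BACKGROUND",
    "AlignmentColumn",
    "PseudoCountModel",
    "FrequencyProfile",
    "EmptyColumnError",
    "PseudoCountModelError",
    "blosum62_matrices",
    "default_pseudo_count_model",
    "column_frequencies",
    "filter_alignment",
    "pseudo_counts",
    "target_frequencies",
    "profile_from_alignment",
    "nth_sequence",
    "profile_pdt",
    "psiblast_command",
]

GAP_CHARACTERS = frozenset("-.*")

# Robinson–Robinson amino-acid background frequencies (the PSI-BLAST
# background), keyed in canonical order; normalized to sum exactly 1.
ROBINSON_BACKGROUND: dict[str, float] = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


class EmptyColumnError(ValueError):
    """Raised for an alignment column with no residues after gap removal."""


class PseudoCountModelError(ValueError):
    """Raised for invalid pseudo-count model parameters (e.g. zero background)."""


def blosum62_matrices() -> tuple[np.ndarray, np.ndarray]:
    """Return (scores, target_frequencies), both (20, 20) in canonical order.

    Scores are the raw BLOSUM62 half-bit log-odds integers.  Target
    frequencies are reconstructed from them as q_ij proportional to
    p_i * p_j * 2**(s_ij / 2) and normalized to sum 1; the matrix is
    symmetric because the score matrix is.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    scores = np.array(
        [[blosum[a, b] for b in AAINDEX_ORDER] for a in AAINDEX_ORDER], dtype=float
    )
    p = np.array([ROBINSON_BACKGROUND[a] for a in AAINDEX_ORDER])
    p = p / p.sum()
    q = np.outer(p, p) * np.exp2(scores / 2.0)
    q /= q.sum()
    return scores, q


@dataclass(frozen=True)
class PseudoCountModel:
    """Pseudo-count parameters: weight, background and BLOSUM62-derived q.

    ``mode`` selects the meaning of q_ij: "frequency" (default) uses the
    BLOSUM62-implied pair frequencies; "score" uses the raw log-odds scores
    literally (may yield negative pseudo-counts, clipped downstream).
    """

    beta_pc: float = 10.0
    background: np.ndarray = field(default_factory=lambda: np.zeros(20))
    q: np.ndarray = field(default_factory=lambda: np.zeros((20, 20)))
    mode: str = "frequency"

    def __post_init__(self) -> None:
        if self.mode not in ("frequency", "score"):
            raise PseudoCountModelError(f"unknown pseudo-count mode {self.mode!r}")
        if self.beta_pc <= 0:
            raise PseudoCountModelError(f"beta_pc must be > 0, got {self.beta_pc}")


def default_pseudo_count_model(mode: str = "frequency") -> PseudoCountModel:
    """The pinned model: beta_pc = 10, Robinson background, BLOSUM62 q."""
    scores, q_freq = blosum62_matrices()
    p = np.array([ROBINSON_BACKGROUND[a] for a in AAINDEX_ORDER])
    p = p / p.sum()
    q = q_freq if mode == "frequency" else scores
    return PseudoCountModel(beta_pc=10.0, background=p, q=q, mode=mode)


@dataclass(frozen=True)
class AlignmentColumn:
    """Observed residue frequencies at one query position.

    ``freqs`` is a length-20 vector in canonical order summing to 1 over the
    residues present; ``distinct_count`` counts residue types observed.
    """

    freqs: np.ndarray
    distinct_count: int


def column_frequencies(msa_column: Sequence[str]) -> AlignmentColumn:
    """Count one alignment column, ignoring gaps and non-standard letters."""
    counts = np.zeros(20)
    for ch in msa_column:
        ch = ch.upper()
        if ch in GAP_CHARACTERS:
            continue
        col = RESIDUE_TO_COLUMN.get(ch)
        if col is None:
            logger.debug("column_frequencies: ignoring non-standard letter %r", ch)
            continue
        counts[col] += 1
    total = counts.sum()
    if total == 0:
        raise EmptyColumnError("alignment column contains no standard residues")
    return AlignmentColumn(
        freqs=counts / total, distinct_count=int(np.count_nonzero(counts))
    )


def filter_alignment(
    msa: Sequence[str], query: str, max_identity: float = 98.0
) -> list[str]:
    """Drop alignment rows with identity to the query >= ``max_identity`` %.

    Identity = matching positions / aligned positions where both the query
    and the row hold a residue.  The query row itself (first exact copy of
    ``query``) is always retained; later exact duplicates are removed.
    """
    kept: list[str] = []
    query_kept = False
    for row in msa:
        if row == query and not query_kept:
            kept.append(row)
            query_kept = True
            continue
        matches = aligned = 0
        for q, r in zip(query, row):
            if q in GAP_CHARACTERS or r in GAP_CHARACTERS:
                continue
            aligned += 1
            if q == r:
                matches += 1
        identity = 100.0 * matches / aligned if aligned else 0.0
        if identity < max_identity:
            kept.append(row)
        else:
            logger.debug("filter_alignment: dropping row at %.1f%% identity", identity)
    return kept


def pseudo_counts(col: AlignmentColumn, model: PseudoCountModel) -> np.ndarray:
    """Pseudo-count vector g for one column.

    frequency mode: g_i = sum_j f_j * q_ij / p_j;
    score mode:     g_i = sum_j f_j * s_ij  (raw BLOSUM62 scores).
    """
    if np.any(model.background <= 0):
        raise PseudoCountModelError("background frequencies must all be positive")
    f = col.freqs
    if model.mode == "frequency":
        g = model.q @ (f / model.background)
    else:
        g = model.q @ f
    if not np.all(np.isfinite(g)):
        raise PseudoCountModelError("non-finite pseudo-counts")
    return g


def target_frequencies(col: AlignmentColumn, model: PseudoCountModel) -> np.ndarray:
    """Blend observed frequencies with pseudo-counts and renormalize to sum 1.

    The observed weight is alpha = distinct_count - 1, the pseudo-count
    weight is model.beta_pc; a single-residue column (alpha = 0) is fully
    pseudo-count-driven.  Negative blended values (possible only in score
    mode) are clipped at 0 before renormalization.
    """
    alpha = col.distinct_count - 1
    g = pseudo_counts(col, model)
    blended = (alpha * col.freqs + model.beta_pc * g) / (alpha + model.beta_pc)
    blended = np.clip(blended, 0.0, None)
    total = blended.sum()
    if total <= 0:
        logger.warning("target_frequencies: degenerate blend, using background")
        return model.background.copy()
    return blended / total


@dataclass
class FrequencyProfile:
    """L x 20 matrix of position-specific target frequencies.

    Row order follows query positions; columns follow the canonical residue
    order.  Every row sums to 1.
    """

    id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError(f"profile matrix must be L x 20, got {self.matrix.shape}")
        if np.any(self.matrix < 0):
            raise ValueError("profile contains negative frequencies")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("profile rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write(f"# id={self.id}\n")
            out.write("pos\t" + "\t".join(AAINDEX_ORDER) + "\n")
            for i, row in enumerate(self.matrix, start=1):
                out.write(str(i) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyProfile":
        rows: list[list[float]] = []
        pid = str(path)
        with open(path) as handle:
            for line in handle:
                if line.startswith("# id="):
                    pid = line.rstrip("\n")[5:]
                    continue
                if line.startswith("pos\t") or not line.strip():
                    continue
                rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
        return cls(id=pid, matrix=np.array(rows, dtype=float))


def profile_from_alignment(
    msa: Sequence[str],
    query: str,
    model: PseudoCountModel | None = None,
    max_identity: float = 98.0,
    query_id: str = "query",
) -> FrequencyProfile:
    """Build a frequency profile over the query's residue positions.

    The alignment is identity-filtered first; columns left all-gap inherit
    the background distribution (warned).
    """
    if model is None:
        model = default_pseudo_count_model()
    rows = filter_alignment(msa, query, max_identity=max_identity)
    matrix_rows: list[np.ndarray] = []
    for j, q_char in enumerate(query):
        if q_char in GAP_CHARACTERS:
            continue
        column = [row[j] for row in rows if j < len(row)]
        try:
            col = column_frequencies(column)
        except EmptyColumnError:
            logger.warning(
                "profile_from_alignment: all-gap column at query position %d, "
                "using background", j + 1,
            )
            matrix_rows.append(model.background.copy())
            continue
        matrix_rows.append(target_frequencies(col, model))
    return FrequencyProfile(id=query_id, matrix=np.array(matrix_rows))


def nth_sequence(profile: FrequencyProfile, n: int) -> ProteinSequence:
    """Per position, the residue with the n-th highest target frequency.

    Residues are ranked by frequency descending, ties broken alphabetically.
    """
    if not 1 <= n <= 20:
        raise ValueError(f"n must be in 1..20, got {n}")
    letters = list(AAINDEX_ORDER)
    chars = []
    for row in profile.matrix:
        order = sorted(range(20), key=lambda c: (-row[c], letters[c]))
        chars.append(letters[order[n - 1]])
    return ProteinSequence(id=f"{profile.id}|n={n}", residues="".join(chars))


def profile_pdt(
    profile: FrequencyProfile,
    indices: NormalizedIndexSet,
    params: PDTParams,
    n_max: int = 1,
) -> np.ndarray:
    """Profile-based PDT: concatenated transforms of the n = 1..n_max
    most-frequent-residue sequences.  Length = n_indices * beta * n_max."""
    if not 1 <= n_max <= 20:
        raise ValueError(f"n_max must be in 1..20, got {n_max}")
    parts = [
        transform(nth_sequence(profile, n), indices, params)
        for n in range(1, n_max + 1)
    ]
    return np.concatenate(parts)


def psiblast_command(
    query_fasta: str, database: str = "nr", iterations: int = 10,
    evalue: float = 0.001, out_alignment: str = "alignment.fasta",
) -> list[str]:
    """Format the PSI-BLAST command line used to produce alignments.

    Untested convenience helper; the tested contract starts from an
    alignment, never from the aligner.
    """
    return [
        "psiblast", "-query", query_fasta, "-db", database,
        "-num_iterations", str(iterations), "-evalue", str(evalue),
        "-out", out_alignment,
    ]
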