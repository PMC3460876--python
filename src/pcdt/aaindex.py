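"""AAIndex1 parsing, filtering and per-index z-normalization.

AAIndex1 is a flat-file database of per-residue numerical property scales.
Each record carries an ``H`` accession line, a ``D`` title line and an ``I``
block holding 20 values in the canonical A R N D C Q E G H I / L K M F P S T
W Y V order, with ``NA`` marking missing values; records end with ``//``.

Indices with missing values or with all-zero raw values are unusable for the
distance transform and are dropped by :func:`filter_indices`.  Surviving
indices are z-normalized over the 20 standard residues (population standard
deviation, i.e. divide by 20) so that every property scale has mean 0 and
standard deviation 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .alphabet import AAINDEX_ORDER, STANDARD_RESIDUES

logger = logging.getLogger(__name__)

__all__ = [
    "AminoAcidIndex",
    "NormalizedIndexSet",
    "AAIndexParseError",
    "DegenerateIndexError",
    "parse_aaindex1",
    "filter_indices",
    "normalize_index",
    "write_aaindex1",
]


class AAIndexParseError(ValueError):
    """Raised when an AAIndex1 record violates the flat-file grammar."""


class DegenerateIndexError(ValueError):
    """Raised when an index has zero variance and cannot be normalized."""


@dataclass(frozen=True)
class AminoAcidIndex:
    """One AAIndex1 entry: up to 20 raw property values keyed by residue.

    Missing (``NA``) values are simply absent from :attr:`raw_values`.
    """

    accession: str
    title: str = ""
    raw_values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.raw_values) - STANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: non-standard residues in index: {sorted(bad)}"
            )

    @property
    def is_complete(self) -> bool:
        return len(self.raw_values) == 20

    @property
    def is_all_zero(self) -> bool:
        return self.is_complete and all(v == 0.0 for v in self.raw_values.values())

    def as_array(self) -> np.ndarray:
        """Raw values as a length-20 array in canonical order (requires complete)."""
        if not self.is_complete:
            missing = sorted(STANDARD_RESIDUES - set(self.raw_values))
            raise ValueError(f"{self.accession}: missing values for {missing}")
        return np.array([self.raw_values[aa] for aa in AAINDEX_ORDER], dtype=float)


def parse_aaindex1(path: str | Path) -> list[AminoAcidIndex]:
    """Parse an AAIndex1 flat file into a list of :class:`AminoAcidIndex`.

    Record order is preserved.  ``NA`` entries are recorded as absent values.

    Raises
    ------
    AAIndexParseError
        If an ``I`` block does not contain exactly 20 tokens, or a token is
        neither ``NA`` nor a parseable number.  The error names the offending
        accession and line.
    """
    indices: list[AminoAcidIndex] = []
    accession: str | None = None
    title_parts: list[str] = []
    tokens: list[tuple[str, int]] = []  # (token, lineno)
    in_i_block = False
    i_block_line = 0

    def finish(end_line: int) -> None:
        nonlocal accession, title_parts, tokens, in_i_block
        if accession is None:
            return
        if len(tokens) != 20:
            raise AAIndexParseError(
                f"record {accession!r}: I block starting at line {i_block_line} "
                f"has {len(tokens)} values, expected 20 (record ends line {end_line})"
            )
        raw: dict[str, float] = {}
        for (tok, lineno), aa in zip(tokens, AAINDEX_ORDER):
            if tok.upper().rstrip(".") == "NA":
                continue
            try:
                raw[aa] = float(tok)
            except ValueError as exc:
                raise AAIndexParseError(
                    f"record {accession!r}: unparseable value {tok!r} "
                    f"at line {lineno}"
                ) from exc
        indices.append(
            AminoAcidIndex(accession=accession, title=" ".join(title_parts), raw_values=raw)
        )
        accession, title_parts, tokens, in_i_block = None, [], [], False

    with open(path) as handle:
        lineno = 0
        for lineno, rawline in enumerate(handle, start=1):
            line = rawline.rstrip("\n")
            if line.startswith("//"):
                finish(lineno)
            elif line.startswith("H "):
                accession = line[2:].strip()
                in_i_block = False
            elif line.startswith("D "):
                title_parts.append(line[2:].strip())
                in_i_block = False
            elif line.startswith("I ") or line.rstrip() == "I":
                in_i_block = True
                i_block_line = lineno
                tokens = []
            elif in_i_block:
                tokens.extend((tok, lineno) for tok in line.split())
        if accession is not None:
            # file ended without the trailing record delimiter
            finish(lineno)
    return indices


def filter_indices(raw: Iterable[AminoAcidIndex]) -> list[AminoAcidIndex]:
    """Drop incomplete indices and indices whose raw values are all zero.

    Survivor order is preserved.  An empty result is permitted (warned).
    """
    survivors: list[AminoAcidIndex] = []
    n_incomplete = n_all_zero = 0
    for idx in raw:
        if not idx.is_complete:
            n_incomplete += 1
        elif idx.is_all_zero:
            n_all_zero += 1
        else:
            survivors.append(idx)
    logger.info(
        "filter_indices: kept %d, dropped %d incomplete, %d all-zero",
        len(survivors), n_incomplete, n_all_zero,
    )
    if not survivors:
        logger.warning("filter_indices: no indices survived filtering")
    return survivors


def normalize_index(idx: AminoAcidIndex) -> dict[str, float]:
    """Z-normalize one complete index over the 20 standard residues.

    Uses the population standard deviation (divide by 20).  The result has
    mean 0 and population standard deviation 1.

    Raises
    ------
    ValueError
        If the index is incomplete.
    DegenerateIndexError
        If all 20 values are equal (zero variance).
    """
    values = idx.as_array()
    mu = values.mean()
    sigma = values.std(ddof=0)
    if sigma == 0.0 or not np.isfinite(sigma):
        raise DegenerateIndexError(
            f"{idx.accession}: all 20 values equal ({values[0]}); zero variance"
        )
    normalized = (values - mu) / sigma
    return dict(zip(AAINDEX_ORDER, normalized.tolist()))


@dataclass
class NormalizedIndexSet:
    """Filtered, z-normalized index collection in stable file order.

    ``values`` is an (n_indices, 20) array in canonical residue order; row
    order matches ``accessions`` and the source file order, and determines
    feature-vector layout downstream.
    """

    accessions: list[str]
    values: np.ndarray
    titles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.accessions), 20):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.accessions)} accessions x 20 residues"
            )
        if not self.titles:
            self.titles = [""] * len(self.accessions)

    @classmethod
    def build(cls, raw: Iterable[AminoAcidIndex]) -> "NormalizedIndexSet":
        """Filter unusable indices, z-normalize the rest, preserve order."""
        kept = filter_indices(raw)
        rows = []
        accs = []
        titles = []
        for idx in kept:
            norm = normalize_index(idx)
            rows.append([norm[aa] for aa in AAINDEX_ORDER])
            accs.append(idx.accession)
            titles.append(idx.title)
        values = np.array(rows, dtype=float) if rows else np.empty((0, 20))
        return cls(accessions=accs, values=values, titles=titles)

    @classmethod
    def from_file(cls, path: str | Path) -> "NormalizedIndexSet":
        return cls.build(parse_aaindex1(path))

    def __len__(self) -> int:
        return len(self.accessions)

    @property
    def n_indices(self) -> int:
        return len(self.accessions)

    def normalized_values(self, accession: str) -> dict[str, float]:
        row = self.values[self.accessions.index(accession)]
        return dict(zip(AAINDEX_ORDER, row.tolist()))

    def lookup_table(self) -> np.ndarray:
        """(n_indices, 21) table: columns 0..19 canonical residues, column 20
        the value assigned to non-standard letters (0 = the index mean)."""
        return np.hstack([self.values, np.zeros((self.n_indices, 1))])

    def to_tsv(self, path: str | Path) -> None:
        """Export the normalized table: accession + 20 canonical columns."""
        with open(path, "w") as out:
            out.write("accession\t" + "\t".join(AAINDEX_ORDER) + "\n")
            for acc, row in zip(self.accessions, self.values):
                out.write(acc + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NormalizedIndexSet":
        accs: list[str] = []
        rows: list[list[float]] = []
        with open(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            if header[1:] != list(AAINDEX_ORDER):
                raise ValueError(f"{path}: unexpected residue column order")
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                accs.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(accessions=accs, values=np.array(rows, dtype=float))


def write_aaindex1(indices: Iterable[AminoAcidIndex], path: str | Path) -> None:
    """Write indices back out in AAIndex1 flat-file grammar.

    Values are written with full float precision so a parse round-trip is
    exact.  Missing residues are written as ``NA``.
    """
    with open(path, "w") as out:
        for idx in indices:
            out.write(f"H {idx.accession}\n")
            if idx.title:
                out.write(f"D {idx.title}\n")
            out.write(
                "I    A/L     R/K     N/M     D/F     C/P     Q/S     "
                "E/T     G/W     H/Y     I/V\n"
            )
            toks = [
                repr(idx.raw_values[aa]) if aa in idx.raw_values else "NA"
                for aa in AAINDEX_ORDER
            ]
            out.write("    " + "  ".join(toks[:10]) + "\n")
            out.write("    " + "  ".join(toks[10:]) + "\n")
            out.write("//\n")
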