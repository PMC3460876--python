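"""FASTA and aligned-FASTA readers/writers (thin wrappers around Bio.SeqIO)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pdt import ProteinSequence

__all__ = ["read_fasta", "write_fasta", "read_aligned_fasta"]


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file, preserving record order."""
    return [
        ProteinSequence(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_aligned_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a query-anchored alignment; returns (ids, aligned rows).

    Rows must share one coordinate system (equal lengths); the first record
    is conventionally the query.
    """
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if rows and len({len(r) for r in rows}) != 1:
        raise ValueError(f"{path}: aligned rows have unequal lengths")
    return ids, rows
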