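"""Canonical amino-acid alphabet and residue encoding.

The canonical residue order used throughout the package is the AAIndex1
``I``-line order (A R N D C Q E G H I / L K M F P S T W Y V).  Feature
layouts, profile columns and TSV exports all follow this ordering.
"""

from __future__ import annotations

import numpy as np

#: Canonical 20-residue order (AAIndex1 I-line order).
AAINDEX_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: Set of the 20 standard one-letter residue codes.
STANDARD_RESIDUES: frozenset[str] = frozenset(AAINDEX_ORDER)

#: Column position of each standard residue in the canonical order.
RESIDUE_TO_COLUMN: dict[str, int] = {aa: i for i, aa in enumerate(AAINDEX_ORDER)}

#: Code assigned to non-standard letters (X, B, Z, U, O, ...).
UNKNOWN_CODE: int = 20

_ENCODE_LUT = np.full(128, UNKNOWN_CODE, dtype=np.int64)
for _aa, _i in RESIDUE_TO_COLUMN.items():
    _ENCODE_LUT[ord(_aa)] = _i
    _ENCODE_LUT[ord(_aa.lower())] = _i


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as integer codes 0..19; non-standard -> 20."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def nonstandard_letters(residues: str) -> set[str]:
    """Return the set of letters in *residues* outside the standard alphabet."""
    return {c for c in residues.upper() if c not in STANDARD_RESIDUES}
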