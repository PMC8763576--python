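"""Amino-acid naming helpers shared across the package.

One- and three-letter codes for the 20 standard residues plus the stop
symbol. HGVS protein notation uses three-letter codes with ``*`` (or
``Ter``) for stop codons.
"""

from __future__ import annotations

from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

STOP = "*"

AA1 = tuple(sorted(protein_letters_1to3))  # 20 standard residues
AA3_TO_1 = {k: v for k, v in protein_letters_3to1.items()}
AA3_TO_1["Ter"] = STOP
AA1_TO_3 = {one: three for three, one in protein_letters_3to1.items()}
AA1_TO_3[STOP] = "Ter"


class UnknownResidueError(ValueError):
    """A residue token is not a standard amino acid (or stop)."""


def to_one_letter(aa: str) -> str:
    """Normalise an amino-acid token to its one-letter code.

    Accepts one-letter codes, three-letter codes (``Cys``), ``Ter`` and
    ``*``. Raises :class:`UnknownResidueError` otherwise.
    """
    if aa == STOP:
        return STOP
    if len(aa) == 1:
        if aa.upper() in AA1:
            return aa.upper()
        raise UnknownResidueError(f"unknown amino acid {aa!r}")
    token = aa.capitalize()
    try:
        return AA3_TO_1[token]
    except KeyError:
        raise UnknownResidueError(f"unknown amino acid {aa!r}") from None


def to_three_letter(aa: str) -> str:
    """Normalise an amino-acid token to its three-letter code (``Ter`` for stop)."""
    return AA1_TO_3[to_one_letter(aa)]
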