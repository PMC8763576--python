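"""Substitution metrics: genetic-code reachability, the 20x20 missense
substitution grid, and the Grantham amino-acid distance.

The Grantham distance scores the physicochemical dissimilarity of an
amino-acid exchange from three side-chain properties -- atomic
composition ``c``, polarity ``p`` and molecular volume ``v``::

    D(i, j) = rho * [ alpha*(c_i - c_j)^2
                    + beta *(p_i - p_j)^2
                    + gamma*(v_i - v_j)^2 ] ** 0.5

with alpha = 1.833, beta = 0.1018, gamma = 0.000399 and the scale
``rho`` fixed so that the mean over the 190 unordered pairs equals 100.
Rounded to integers this reproduces the conventional published matrix:
identical residues score 0, Leu-Ile is the smallest non-trivial distance
(5) and Cys-Trp the largest (215).

Reachability asks whether one amino acid can mutate into another through
a single nucleotide change under the standard nuclear genetic code; the
substitution grid only ever populates reachable cells when fed true
single-nucleotide variants.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .aminoacids import AA1, STOP, UnknownResidueError, to_one_letter

__all__ = [
    "GENETIC_CODE",
    "GranthamProperties",
    "SubstitutionGrid",
    "single_nt_reachable",
    "reachability_matrix",
    "build_grid",
    "grantham_distance",
    "grantham_matrix",
]

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
#: Standard nuclear genetic code, codon -> one-letter amino acid ('*' = stop).
GENETIC_CODE: dict[str, str] = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

_CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in GENETIC_CODE.items():
    _CODONS_BY_AA.setdefault(_aa, ())
    _CODONS_BY_AA[_aa] += (_codon,)


@lru_cache(maxsize=None)
def _reachable_1(ref: str, alt: str) -> bool:
    for ca in _CODONS_BY_AA[ref]:
        for cb in _CODONS_BY_AA[alt]:
            if sum(x != y for x, y in zip(ca, cb)) == 1:
                return True
    return False


def single_nt_reachable(ref_aa: str, alt_aa: str) -> bool:
    """True iff some codon of ``ref_aa`` differs from some codon of
    ``alt_aa`` at exactly one position (standard genetic code).

    Accepts one- or three-letter codes and the stop symbol. Identity is
    reachable by convention (synonymous identity); silent changes are
    excluded from the substitution grid regardless.
    """
    ref = to_one_letter(ref_aa)
    alt = to_one_letter(alt_aa)
    if ref == alt:
        return True
    return _reachable_1(ref, alt)


def reachability_matrix(include_stop: bool = False) -> pd.DataFrame:
    """Boolean matrix of single-nucleotide reachability over the 20
    residues (optionally including the stop symbol)."""
    labels = list(AA1) + ([STOP] if include_stop else [])
    mat = pd.DataFrame(
        [[single_nt_reachable(a, b) for b in labels] for a in labels],
        index=labels,
        columns=labels,
    )
    return mat


# ---------------------------------------------------------------------------
# Grantham distance
# ---------------------------------------------------------------------------

ALPHA = 1.833
BETA = 0.1018
GAMMA = 0.000399


@dataclass(frozen=True)
class GranthamProperties:
    """Per-residue composition/polarity/volume table plus formula constants.

    ``rho`` normalises the mean distance over the 190 unordered pairs to
    100; it is derived from the table, never stored.
    """

    table: pd.DataFrame  # index: one-letter aa; columns c, p, v
    alpha: float = ALPHA
    beta: float = BETA
    gamma: float = GAMMA
    rho: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        missing = set(AA1) - set(self.table.index)
        if missing:
            raise ValueError(f"property table missing residues: {sorted(missing)}")
        raw = self._raw_matrix()
        iu = np.triu_indices_from(raw, k=1)
        object.__setattr__(self, "rho", 100.0 / raw[iu].mean())

    @classmethod
    def default(cls) -> "GranthamProperties":
        """The 1974 property table bundled with the package."""
        with resources.files("fxivar.data").joinpath("grantham_properties.csv").open() as fh:
            table = pd.read_csv(fh, index_col="aa")
        return cls(table=table)

    def _raw_matrix(self) -> np.ndarray:
        t = self.table.loc[list(AA1), ["c", "p", "v"]].to_numpy(float)
        d2 = np.zeros((20, 20))
        for coef, col in zip((self.alpha, self.beta, self.gamma), range(3)):
            diff = t[:, col][:, None] - t[:, col][None, :]
            d2 += coef * diff**2
        return np.sqrt(d2)


_DEFAULT_PROPS: GranthamProperties | None = None


def _default_props() -> GranthamProperties:
    global _DEFAULT_PROPS
    if _DEFAULT_PROPS is None:
        _DEFAULT_PROPS = GranthamProperties.default()
    return _DEFAULT_PROPS


def grantham_matrix(props: GranthamProperties | None = None) -> pd.DataFrame:
    """Integer 20x20 Grantham distance matrix (symmetric, zero diagonal)."""
    props = props or _default_props()
    raw = props.rho * props._raw_matrix()
    mat = pd.DataFrame(
        np.rint(raw).astype(int), index=list(AA1), columns=list(AA1)
    )
    np.fill_diagonal(mat.values, 0)
    return mat


def grantham_distance(
    ref_aa: str, alt_aa: str, props: GranthamProperties | None = None
) -> int:
    """Grantham distance between two residues (0 for identical residues).

    Raises :class:`UnknownResidueError` for a stop codon: the distance is
    defined only between standard amino acids.
    """
    ref = to_one_letter(ref_aa)
    alt = to_one_letter(alt_aa)
    if STOP in (ref, alt):
        raise UnknownResidueError("Grantham distance is undefined for stop codons")
    if ref == alt:
        return 0
    return int(grantham_matrix(props).loc[ref, alt])


# ---------------------------------------------------------------------------
# Substitution grid
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionGrid:
    """20x20 count grid of distinct missense changes (ref x alt)."""

    counts: pd.DataFrame  # int counts, ref_aa rows x alt_aa columns
    reachable: pd.DataFrame  # boolean mask of single-nt-accessible cells
    suspects: list[tuple[str, str]]  # observed changes in unreachable cells

    @property
    def row_totals(self) -> pd.Series:
        """Distinct variant count per reference residue."""
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="ref/alt")


def build_grid(missense_changes) -> SubstitutionGrid:
    """Build the substitution grid from missense changes.

    Parameters
    ----------
    missense_changes
        Iterable of ``(ref_aa, alt_aa)`` pairs or of
        :class:`~fxivar.census.VariantRecord` with ``effect == missense``;
        each **distinct** protein change increments its cell once.

    Changes that land in a cell unreachable by a single nucleotide change
    are flagged as suspect (with a warning) but still counted: census
    entries are trusted over the filter.
    """
    counts = pd.DataFrame(0, index=list(AA1), columns=list(AA1), dtype=int)
    seen: set[tuple] = set()
    suspects: list[tuple[str, str]] = []
    for item in missense_changes:
        key = None
        if hasattr(item, "ref_aa"):
            # variant records: one count per distinct protein change
            key = (item.ref_aa, item.residue_hgvs, item.alt_aa)
            ref, alt = item.ref_aa, item.alt_aa
        else:
            ref, alt = item  # bare pairs: caller guarantees distinctness
        ref = to_one_letter(ref)
        alt = to_one_letter(alt)
        if STOP in (ref, alt) or ref == alt:
            raise ValueError(f"not a missense change: {ref}->{alt}")
        if key is not None:
            if key in seen:
                continue
            seen.add(key)
        if not single_nt_reachable(ref, alt):
            suspects.append((ref, alt))
            warnings.warn(
                f"substitution {ref}->{alt} needs more than one nucleotide change",
                stacklevel=2,
            )
        counts.loc[ref, alt] += 1
    mask = reachability_matrix()
    return SubstitutionGrid(counts=counts, reachable=mask, suspects=suspects)
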