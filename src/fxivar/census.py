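"""The F11 variant census: records, parsing, classification, tabulation.

Residue numbering follows HGVS protein convention, codon +1 at the
initiator Met of the 18-residue signal peptide; the mature-protein
("legacy") numbering starts at Glu19, so the two differ by a fixed
offset of 18. Phenotypes follow the CRM nomenclature: Type I (CRM-)
variants depress both coagulant activity (FXI:C) and antigen (FXI:Ag),
Type II (CRM+) depress activity with normal antigen, operationally a
FXI:C/FXI:Ag ratio below 0.7.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .aminoacids import STOP, UnknownResidueError, to_three_letter

__all__ = [
    "EventType",
    "Effect",
    "Phenotype",
    "PhenotypeCall",
    "VariantRecord",
    "DomainMap",
    "CensusSummary",
    "SignalPeptideError",
    "hgvs_to_legacy",
    "legacy_to_hgvs",
    "classify_phenotype",
    "parse_protein_change",
    "expand_shorthand",
    "assign_domain",
    "rarity_filter",
    "tabulate_census",
    "cys_census",
    "load_census",
    "percent",
]

SIGNAL_PEPTIDE_LENGTH = 18
MATURE_LENGTH = 607
PROTEIN_LENGTH = SIGNAL_PEPTIDE_LENGTH + MATURE_LENGTH  # 625
NORMAL_FXI_C_RANGE = (70.0, 150.0)  # IU/dL in unaffected individuals
TYPE_II_RATIO = 0.7


class EventType(str, enum.Enum):
    POINT = "point"
    DELETION = "deletion"
    INSERTION = "insertion"
    DUPLICATION = "duplication"
    POLYMORPHISM = "polymorphism"
    UNDEFINED = "undefined"


class Effect(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SILENT = "silent"
    UNDEFINED = "undefined"


class Phenotype(str, enum.Enum):
    TYPE_I = "type_I"
    TYPE_II = "type_II"
    UNKNOWN = "unknown"
    POLYMORPHISM = "polymorphism"


class PhenotypeCall(str, enum.Enum):
    """Outcome of the activity/antigen classification rule."""

    TYPE_I = "type_I"
    TYPE_II = "type_II"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class SignalPeptideError(ValueError):
    """Raised when a signal-peptide residue (1-18) has no legacy number."""


def hgvs_to_legacy(residue_hgvs: int) -> int:
    """Convert an HGVS residue number to mature-protein (legacy) numbering.

    Legacy codon +1 is Glu19 of the precursor, so the conversion
    subtracts the 18-residue signal peptide. Signal-peptide residues
    have no legacy equivalent and raise :class:`SignalPeptideError`.
    """
    if residue_hgvs < 1:
        raise ValueError(f"residue number must be positive, got {residue_hgvs}")
    if residue_hgvs <= SIGNAL_PEPTIDE_LENGTH:
        raise SignalPeptideError(
            f"residue {residue_hgvs} lies in the signal peptide (1-18); "
            "no legacy equivalent"
        )
    return residue_hgvs - SIGNAL_PEPTIDE_LENGTH


def legacy_to_hgvs(residue_legacy: int) -> int:
    """Inverse of :func:`hgvs_to_legacy` (adds the 18-residue offset)."""
    if residue_legacy < 1:
        raise ValueError(f"legacy residue number must be positive, got {residue_legacy}")
    return residue_legacy + SIGNAL_PEPTIDE_LENGTH


def classify_phenotype(
    fxi_c: float | None,
    fxi_ag: float | None,
    normal_range: tuple[float, float] = NORMAL_FXI_C_RANGE,
) -> PhenotypeCall:
    """Classify a patient measurement pair into Type I / Type II / unaffected.

    FXI:C within the normal range (default 70-150 IU/dL) is unaffected;
    otherwise a FXI:C/FXI:Ag ratio < 0.7 is Type II (functional defect,
    CRM+) and >= 0.7 is Type I (parallel loss of protein, CRM-).
    A missing antigen measurement yields ``UNKNOWN``.
    """
    if fxi_c is None or (isinstance(fxi_c, float) and math.isnan(fxi_c)):
        return PhenotypeCall.UNKNOWN
    if fxi_c <= 0:
        raise ValueError("FXI:C must be positive")
    lo, hi = normal_range
    if lo <= fxi_c <= hi:
        return PhenotypeCall.UNAFFECTED
    if fxi_ag is None or (isinstance(fxi_ag, float) and math.isnan(fxi_ag)):
        return PhenotypeCall.UNKNOWN
    if fxi_ag <= 0:
        raise ValueError("FXI:Ag must be positive")
    return PhenotypeCall.TYPE_II if fxi_c / fxi_ag < TYPE_II_RATIO else PhenotypeCall.TYPE_I


_CHANGE_RE = re.compile(
    r"^(?:p\.)?(?P<ref>[A-Z][a-z]{2}|[A-Z])(?P<pos>\d+)(?P<alt>[A-Z][a-z]{2}|[A-Z]|\*|Ter)$"
)


def parse_protein_change(text: str) -> tuple[str, int, str, Effect]:
    """Parse an HGVS protein change like ``Cys56Arg`` or ``Glu135*``.

    Returns ``(ref_aa, residue_hgvs, alt_aa, effect)`` with three-letter
    residue codes (``*`` for stop). The effect follows directly from the
    notation: stop alternate -> nonsense, identical residues -> silent,
    otherwise missense.
    """
    m = _CHANGE_RE.match(text.strip())
    if m is None:
        raise ValueError(f"unparseable protein change: {text!r}")
    try:
        ref = to_three_letter(m.group("ref"))
        alt_raw = m.group("alt")
        alt = STOP if alt_raw in (STOP, "Ter") else to_three_letter(alt_raw)
    except UnknownResidueError as exc:
        raise ValueError(f"unparseable protein change {text!r}: {exc}") from None
    pos = int(m.group("pos"))
    if ref == "Ter":
        raise ValueError(f"unparseable protein change {text!r}: stop as reference")
    if alt == STOP:
        effect = Effect.NONSENSE
    elif ref == alt:
        effect = Effect.SILENT
    else:
        effect = Effect.MISSENSE
    return ref, pos, alt, effect


def expand_shorthand(text: str) -> list[str]:
    """Expand slashed multi-substitution shorthand.

    ``"Cys56Arg/Trp"`` denotes two variants at the same codon and expands
    to ``["Cys56Arg", "Cys56Trp"]``; input order is preserved.
    """
    parts = text.strip().split("/")
    first = parts[0]
    m = _CHANGE_RE.match(first)
    if m is None:
        raise ValueError(f"unparseable protein change: {first!r}")
    stem = (m.group("ref") + m.group("pos"))
    out = [first]
    for alt in parts[1:]:
        alt = alt.strip()
        if not re.fullmatch(r"[A-Z][a-z]{2}|[A-Z]|\*|Ter", alt):
            raise ValueError(f"unparseable alternate residue {alt!r} in {text!r}")
        out.append(stem + alt)
    return out


@dataclass
class VariantRecord:
    """One F11 variant (or one aggregate line standing for ``count`` of them).

    ``aggregate`` rows transcribe printed tallies for which per-variant
    detail is not published; they carry classification fields and a
    ``count`` but no protein change.
    """

    protein_change_hgvs: str | None = None
    cdna_change: str | None = None
    residue_hgvs: int | None = None
    ref_aa: str | None = None  # three-letter
    alt_aa: str | None = None  # three-letter or '*'
    event_type: EventType = EventType.UNDEFINED
    effect: Effect = Effect.UNDEFINED
    phenotype: Phenotype = Phenotype.UNKNOWN
    fxi_c: float | None = None
    fxi_ag: float | None = None
    allele_frequency: float | None = None
    n_patient_records: int = 0
    aggregate: bool = False
    count: int = 1
    external_scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.event_type = EventType(self.event_type)
        self.effect = Effect(self.effect)
        self.phenotype = Phenotype(self.phenotype)
        if self.protein_change_hgvs and self.residue_hgvs is None:
            ref, pos, alt, effect = parse_protein_change(self.protein_change_hgvs)
            self.ref_aa, self.residue_hgvs, self.alt_aa = ref, pos, alt
            if self.effect == Effect.UNDEFINED:
                self.effect = effect
        if self.residue_hgvs is not None and not (
            1 <= self.residue_hgvs <= PROTEIN_LENGTH
        ):
            raise ValueError(
                f"residue {self.residue_hgvs} outside 1..{PROTEIN_LENGTH}"
            )
        if self.allele_frequency is not None and not (
            0.0 <= self.allele_frequency <= 1.0
        ):
            raise ValueError("allele frequency must lie in [0, 1]")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.alt_aa is not None:
            if (self.effect == Effect.NONSENSE) != (self.alt_aa == STOP):
                raise ValueError(
                    f"{self.protein_change_hgvs}: nonsense iff the alternate is a stop"
                )
            if (self.effect == Effect.SILENT) != (self.ref_aa == self.alt_aa):
                raise ValueError(
                    f"{self.protein_change_hgvs}: silent iff ref equals alt"
                )

    @property
    def disease_associated(self) -> bool:
        """Polymorphism labelling comes from the source, never from AF."""
        return self.phenotype != Phenotype.POLYMORPHISM

    @property
    def residue_legacy(self) -> int | None:
        if self.residue_hgvs is None or self.residue_hgvs <= SIGNAL_PEPTIDE_LENGTH:
            return None
        return hgvs_to_legacy(self.residue_hgvs)


# ---------------------------------------------------------------------------
# Domain map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainMap:
    """Ordered, contiguous, non-overlapping intervals over residues 1..625."""

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for name, start, end in self.intervals:
            if start != prev_end + 1:
                raise ValueError(
                    f"domain {name}: intervals must be contiguous and ascending"
                )
            if end < start:
                raise ValueError(f"domain {name}: end before start")
            prev_end = end

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.intervals)

    def assign(self, residue_hgvs: int) -> str:
        for name, start, end in self.intervals:
            if start <= residue_hgvs <= end:
                return name
        raise ValueError(f"residue {residue_hgvs} outside the domain map")

    def span(self, name: str) -> tuple[int, int]:
        for n, start, end in self.intervals:
            if n == name:
                return start, end
        raise KeyError(name)


def assign_domain(residue_hgvs: int, domain_map: DomainMap) -> str:
    """Name of the unique domain interval containing ``residue_hgvs``."""
    return domain_map.assign(residue_hgvs)


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """Percentage rounded half-up to ``ndigits`` (matches printed tallies)."""
    if whole == 0:
        return 0.0
    q = Decimal(1).scaleb(-ndigits)
    ratio = Decimal(str(part)) / Decimal(str(whole)) * 100
    return float(ratio.quantize(q, rounding=ROUND_HALF_UP))


def _weight(rec: VariantRecord) -> int:
    return rec.count if rec.aggregate else 1


@dataclass
class CensusSummary:
    """Counts and percentages of the census by event, effect, phenotype, domain."""

    n_total: int
    n_disease: int
    n_point: int
    by_event: pd.DataFrame  # index event_type; count, percent (of all)
    by_effect: pd.DataFrame  # index effect; count, percent (of point variants)
    by_phenotype: pd.DataFrame  # index phenotype; count, percent (of disease-assoc.)
    by_domain: pd.DataFrame  # index domain; count, percent (of all)

    def table(self) -> pd.DataFrame:
        """Single long-format table of all groupings."""
        frames = []
        for group, df in (
            ("event_type", self.by_event),
            ("effect_of_point", self.by_effect),
            ("phenotype_of_disease", self.by_phenotype),
            ("domain", self.by_domain),
        ):
            d = df.reset_index(names="category")
            d.insert(0, "grouping", group)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)


def _tally(pairs, denominator: float) -> pd.DataFrame:
    counts: dict[str, int] = {}
    for key, w in pairs:
        counts[key] = counts.get(key, 0) + w
    df = pd.DataFrame(
        {
            "count": pd.Series(counts, dtype=int),
            "percent": pd.Series(
                {k: percent(v, denominator) for k, v in counts.items()}
            ),
        }
    )
    return df.sort_values("count", ascending=False)


def tabulate_census(
    census: list[VariantRecord], domain_map: DomainMap | None = None
) -> CensusSummary:
    """Tabulate the census the way the database reports do.

    Event-type percentages are over all variants; effect percentages over
    the point variants only; phenotype percentages over disease-associated
    variants; domain percentages over all variants (records without a
    residue position count as domain ``undefined``).
    """
    n_total = sum(_weight(r) for r in census)
    n_point = sum(_weight(r) for r in census if r.event_type == EventType.POINT)
    n_disease = sum(_weight(r) for r in census if r.disease_associated)

    by_event = _tally(((r.event_type.value, _weight(r)) for r in census), n_total)
    by_effect = _tally(
        (
            (r.effect.value, _weight(r))
            for r in census
            if r.event_type == EventType.POINT
        ),
        n_point,
    )
    by_phenotype = _tally(
        ((r.phenotype.value, _weight(r)) for r in census if r.disease_associated),
        n_disease,
    )

    def _domain(r: VariantRecord) -> str:
        if r.residue_hgvs is None or domain_map is None:
            return "undefined"
        return domain_map.assign(r.residue_hgvs)

    by_domain = _tally(((_domain(r), _weight(r)) for r in census), n_total)
    return CensusSummary(
        n_total=n_total,
        n_disease=n_disease,
        n_point=n_point,
        by_event=by_event,
        by_effect=by_effect,
        by_phenotype=by_phenotype,
        by_domain=by_domain,
    )


def rarity_filter(
    census: list[VariantRecord], af_cutoff: float = 0.01
) -> tuple[int, int, int]:
    """Split records by gnomAD allele frequency.

    Returns ``(n_common, n_rare, n_no_af)`` where common means AF strictly
    above the cutoff; records without an AF are counted separately.
    """
    if not (0.0 < af_cutoff < 1.0):
        raise ValueError("AF cutoff must lie in (0, 1)")
    n_common = n_rare = n_no_af = 0
    for r in census:
        w = _weight(r)
        if r.allele_frequency is None:
            n_no_af += w
        elif r.allele_frequency > af_cutoff:
            n_common += w
        else:
            n_rare += w
    return n_common, n_rare, n_no_af


# ---------------------------------------------------------------------------
# Cysteine census
# ---------------------------------------------------------------------------


@dataclass
class CysCensus:
    n_cys_loss: int
    n_cys_loss_apple: int
    n_cys_loss_sp: int
    n_cys_gain: int
    loss_by_phenotype: dict[str, int]
    gain_by_phenotype: dict[str, int]
    loss_variants: list[VariantRecord]
    gain_variants: list[VariantRecord]


def cys_census(
    census: list[VariantRecord],
    domain_map: DomainMap,
    apple_domains: tuple[str, ...] = ("Ap1", "Ap2", "Ap3", "Ap4"),
    sp_domain: str = "SP",
) -> CysCensus:
    """Census of cysteine-affecting variants.

    Cys-loss variants substitute or truncate a native Cys codon (missense
    or nonsense with ``ref_aa == Cys``); Cys-gain variants introduce a new
    Cys. Distinct protein changes are counted once.
    """
    seen: set[tuple] = set()
    loss: list[VariantRecord] = []
    gain: list[VariantRecord] = []
    for r in census:
        if r.aggregate or r.ref_aa is None:
            continue
        key = (r.ref_aa, r.residue_hgvs, r.alt_aa)
        if key in seen:
            continue
        seen.add(key)
        if r.ref_aa == "Cys" and r.effect in (Effect.MISSENSE, Effect.NONSENSE):
            loss.append(r)
        if r.alt_aa == "Cys" and r.effect == Effect.MISSENSE:
            gain.append(r)

    def _by_phen(records: list[VariantRecord]) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in records:
            out[r.phenotype.value] = out.get(r.phenotype.value, 0) + 1
        return out

    n_apple = sum(
        1 for r in loss if domain_map.assign(r.residue_hgvs) in apple_domains
    )
    n_sp = sum(1 for r in loss if domain_map.assign(r.residue_hgvs) == sp_domain)
    return CysCensus(
        n_cys_loss=len(loss),
        n_cys_loss_apple=n_apple,
        n_cys_loss_sp=n_sp,
        n_cys_gain=len(gain),
        loss_by_phenotype=_by_phen(loss),
        gain_by_phenotype=_by_phen(gain),
        loss_variants=loss,
        gain_variants=gain,
    )


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

CENSUS_COLUMNS = [
    "protein_change",
    "cdna_change",
    "event_type",
    "effect",
    "phenotype",
    "fxi_c",
    "fxi_ag",
    "allele_frequency",
    "n_patients",
    "aggregate",
    "count",
]


def load_census(path) -> list[VariantRecord]:
    """Read a variant census CSV (see :data:`CENSUS_COLUMNS`).

    Slashed shorthand in ``protein_change`` (``Cys56Arg/Trp``) expands to
    one record per alternate. Malformed rows raise ``ValueError`` naming
    the row number and offending token.
    """
    df = pd.read_csv(path, dtype={"protein_change": "string", "cdna_change": "string"})
    missing = set(CENSUS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"census file missing columns: {sorted(missing)}")
    records: list[VariantRecord] = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based with header
        try:
            changes: list[str | None]
            if pd.isna(row["protein_change"]) or row["protein_change"] == "":
                changes = [None]
            else:
                changes = expand_shorthand(str(row["protein_change"]))
            for change in changes:
                records.append(
                    VariantRecord(
                        protein_change_hgvs=change,
                        cdna_change=None
                        if pd.isna(row["cdna_change"])
                        else str(row["cdna_change"]),
                        event_type=EventType(row["event_type"]),
                        effect=Effect(row["effect"]),
                        phenotype=Phenotype(row["phenotype"]),
                        fxi_c=None if pd.isna(row["fxi_c"]) else float(row["fxi_c"]),
                        fxi_ag=None if pd.isna(row["fxi_ag"]) else float(row["fxi_ag"]),
                        allele_frequency=None
                        if pd.isna(row["allele_frequency"])
                        else float(row["allele_frequency"]),
                        n_patient_records=0
                        if pd.isna(row["n_patients"])
                        else int(row["n_patients"]),
                        aggregate=bool(row["aggregate"]),
                        count=1 if pd.isna(row["count"]) else int(row["count"]),
                    )
                )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"census row {rownum}: {exc}") from exc
    return records


def write_census(records: list[VariantRecord], path) -> None:
    """Write records back out in the census CSV schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "protein_change": r.protein_change_hgvs or "",
                "cdna_change": r.cdna_change or "",
                "event_type": r.event_type.value,
                "effect": r.effect.value,
                "phenotype": r.phenotype.value,
                "fxi_c": r.fxi_c,
                "fxi_ag": r.fxi_ag,
                "allele_frequency": r.allele_frequency,
                "n_patients": r.n_patient_records,
                "aggregate": r.aggregate,
                "count": r.count,
            }
        )
    pd.DataFrame(rows, columns=CENSUS_COLUMNS).to_csv(path, index=False)
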