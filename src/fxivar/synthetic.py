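"""Synthetic structures and censuses with known ground truth.

Every analysis stage in this package can be exercised without any
download through the generators here:

* ideal alpha-helices (1.5 A rise, 100 degrees per residue) with one
  pseudo-sidechain sphere per non-Gly residue (a C-beta-like carbon of
  radius 1.9 A, radially extended so contact geometry is analytic) —
  deliberately not biophysical, but exactly controllable;
* packed helix pairs whose designed contact residues are emitted
  alongside the coordinates;
* S-gamma scaffolds that encode an arbitrary disulfide-bridge topology
  as real geometry (2.05 A covalent pairs) so bridge detection is
  always a computation, never a lookup;
* variant censuses with exact requested marginals.

All generators are deterministic: helices and scaffolds have no random
element at all, censuses take an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aminoacids import AA1_TO_3, to_one_letter
from .census import EventType, Effect, Phenotype, VariantRecord
from .structure import Structure, VDW_RADII
from .substitution import _CODONS_BY_AA, single_nt_reachable

__all__ = [
    "make_helix",
    "make_packed_pair",
    "make_disulfide_scaffold",
    "make_census",
    "PackedPair",
]

HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # CA distance from axis
SIDECHAIN_RADIUS = 1.9  # pseudo C-beta sphere
SIDECHAIN_EXTENSION = 2.0  # CA -> pseudo-sidechain centre, radially out
SS_BOND_LENGTH = 2.05  # covalent S-S


def _normalize_restypes(n_res: int, residue_types) -> list[str]:
    if residue_types is None:
        residue_types = "ALA"
    valid3 = {v.upper() for v in AA1_TO_3.values() if v != "Ter"}

    def three(token: str) -> str:
        if len(token) == 3:
            if token.upper() not in valid3:
                raise ValueError(f"unknown residue type {token!r}")
            return token.upper()
        return AA1_TO_3[to_one_letter(token)].upper()

    if isinstance(residue_types, str):
        if len(residue_types) == 3 and residue_types.isalpha():
            names = [three(residue_types)] * n_res
        else:  # one-letter string
            names = [three(c) for c in residue_types]
    else:
        names = [three(r) for r in residue_types]
    if len(names) == 1:
        names = names * n_res
    if len(names) != n_res:
        raise ValueError(f"expected {n_res} residue types, got {len(names)}")
    return names


def make_helix(
    n_res: int,
    residue_types="ALA",
    chain_id: str = "A",
    start_resnum: int = 1,
) -> Structure:
    """Ideal alpha-helix with pseudo-sidechains, deterministic.

    Backbone N/CA/C/O plus one radially pointing pseudo C-beta per
    non-Gly residue. ``residue_types`` may be a single three-letter
    name, a one-letter sequence string, or a list.
    """
    if n_res < 3:
        raise ValueError("a helix needs at least 3 residues")
    names = _normalize_restypes(n_res, residue_types)
    chains, resnums, resnames, atom_names, elements, coords, radii = (
        [], [], [], [], [], [], [],
    )

    def add(i: int, name: str, element: str, pos: np.ndarray, radius: float) -> None:
        chains.append(chain_id)
        resnums.append(start_resnum + i)
        resnames.append(names[i])
        atom_names.append(name)
        elements.append(element)
        coords.append(pos)
        radii.append(radius)

    for i in range(n_res):
        theta = np.deg2rad(HELIX_TWIST * i)
        u = np.array([np.cos(theta), np.sin(theta), 0.0])  # radial
        t = np.array([-np.sin(theta), np.cos(theta), 0.0])  # tangential
        k = np.array([0.0, 0.0, 1.0])
        ca = HELIX_RADIUS * u + HELIX_RISE * i * k
        add(i, "N", "N", ca - 0.85 * u - 0.85 * t - 0.85 * k, VDW_RADII["N"])
        add(i, "CA", "C", ca, VDW_RADII["C"])
        c = ca - 0.5 * u + 1.0 * t + 1.0 * k
        add(i, "C", "C", c, VDW_RADII["C"])
        add(i, "O", "O", c + 1.23 * k, VDW_RADII["O"])
        if names[i] != "GLY":
            add(i, "CB", "C", ca + SIDECHAIN_EXTENSION * u, SIDECHAIN_RADIUS)
    return Structure(
        chain=np.array(chains, dtype=object),
        resnum=np.array(resnums, dtype=int),
        resname=np.array(resnames, dtype=object),
        atom_name=np.array(atom_names, dtype=object),
        element=np.array(elements, dtype=object),
        xyz=np.array(coords, dtype=float),
        radius=np.array(radii, dtype=float),
    )


@dataclass
class PackedPair:
    """A packed two-helix toy plus its designed ground truth."""

    assembly: Structure
    contacts_a: list[int]  # resnums in the first unit facing the partner
    contacts_b: list[int]
    gap: float


def _designed_contacts(part: Structure, partner: Structure, gap: float) -> list[int]:
    """Residues whose pseudo-sidechain surface lies within gap+2 A of the
    partner's nearest atom surface.

    The threshold is capped at one probe diameter (2.8 A): beyond that
    separation a water probe passes freely between the surfaces, so no
    burial can occur and a widely spaced pair designs no contacts.
    """
    threshold = min(gap + 2.0, 2.8)
    out = []
    cb = part.atom_name == "CB"
    for chain, resnum in part.residue_keys():
        mask = cb & (part.chain == chain) & (part.resnum == resnum)
        if not mask.any():
            continue
        center = part.xyz[mask][0]
        r = part.radius[mask][0]
        d = np.linalg.norm(partner.xyz - center, axis=1) - partner.radius - r
        if d.min() <= threshold:
            out.append(int(resnum))
    return sorted(out)


def make_packed_pair(
    helix_a: Structure,
    helix_b: Structure,
    axial_offset: float = 0.0,
    gap: float = 0.5,
    as_chains: bool = True,
) -> PackedPair:
    """Pack two helices face to face with a controlled surface gap.

    The second helix is rotated 180 degrees about the global z axis and
    translated along +x so that the closest facing pseudo-sidechain
    surfaces end up ``gap`` apart. With ``as_chains`` the units become
    chains A and B (interface analysis); otherwise they form one chain
    with the second unit renumbered after the first (two-domain toy for
    the separation analysis).

    The designed contact residues — those whose pseudo-sidechain faces
    the partner within gap + 2 A — are returned as ground truth.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    flip = np.diag([-1.0, -1.0, 1.0])
    b = helix_b.transformed(flip, np.zeros(3))

    # radial reach of the pseudo-sidechain centres toward the partner
    reach_a = helix_a.xyz[:, 0].max()
    reach_b = -b.xyz[:, 0].min()
    d = reach_a + reach_b + 2.0 * SIDECHAIN_RADIUS + gap
    b = b.transformed(np.eye(3), np.array([d, 0.0, axial_offset]))

    if as_chains:
        a = helix_a.with_chain_id("A")
        b = b.with_chain_id("B")
    else:
        a = helix_a
        shift = int(helix_a.resnum.max()) - int(b.resnum.min()) + 1
        b = Structure(
            chain=np.full(len(b), str(a.chain[0]), dtype=object),
            resnum=b.resnum + shift,
            resname=b.resname,
            atom_name=b.atom_name,
            element=b.element,
            xyz=b.xyz,
            radius=b.radius,
        )
    contacts_a = _designed_contacts(a, b, gap)
    contacts_b = _designed_contacts(b, a, gap)
    return PackedPair(
        assembly=Structure.merge(a, b),
        contacts_a=contacts_a,
        contacts_b=contacts_b,
        gap=gap,
    )


def make_disulfide_scaffold(
    bridges,
    free_cys=(),
    chain_id: str = "A",
    spacing: float = 12.0,
) -> Structure:
    """Encode a disulfide topology as geometry.

    Each ``(resnum_a, resnum_b)`` bridge becomes a Cys pair whose SG
    atoms sit ``SS_BOND_LENGTH`` apart; bridges occupy well-separated
    grid cells so no spurious pairs arise. ``free_cys`` residues get an
    isolated SG. Residue numbers keep their given (HGVS) values.
    """
    chains, resnums, resnames, atom_names, elements, coords, radii = (
        [], [], [], [], [], [], [],
    )

    def add_cys(resnum: int, base: np.ndarray, dx: float) -> None:
        sg = base + np.array([dx, 0.0, 0.0])
        side = 1.0 if dx > 0 else -1.0
        ca = sg + np.array([side, 2.0, 0.0])  # CA off to the residue's own side
        for name, el, pos in (
            ("N", "N", ca + np.array([0.0, 1.2, 0.8])),
            ("CA", "C", ca),
            ("C", "C", ca + np.array([side, 0.9, -0.8])),
            ("O", "O", ca + np.array([side, 2.0, -1.2])),
            ("SG", "S", sg),
        ):
            chains.append(chain_id)
            resnums.append(resnum)
            resnames.append("CYS")
            atom_names.append(name)
            elements.append(el)
            coords.append(pos)
            radii.append(VDW_RADII[el])

    cells_per_row = 6
    cell = 0
    for a, b in bridges:
        base = np.array(
            [spacing * (cell % cells_per_row), spacing * (cell // cells_per_row), 0.0]
        )
        add_cys(a, base, -SS_BOND_LENGTH / 2)
        add_cys(b, base, +SS_BOND_LENGTH / 2)
        cell += 1
    for resnum in free_cys:
        base = np.array(
            [spacing * (cell % cells_per_row), spacing * (cell // cells_per_row), 0.0]
        )
        add_cys(resnum, base, 0.0)
        cell += 1
    return Structure(
        chain=np.array(chains, dtype=object),
        resnum=np.array(resnums, dtype=int),
        resname=np.array(resnames, dtype=object),
        atom_name=np.array(atom_names, dtype=object),
        element=np.array(elements, dtype=object),
        xyz=np.array(coords, dtype=float),
        radius=np.array(radii, dtype=float),
    )


# ---------------------------------------------------------------------------
# Synthetic census
# ---------------------------------------------------------------------------

_STOP_REACHABLE = sorted(
    aa for aa in _CODONS_BY_AA if aa != "*" and single_nt_reachable(aa, "*")
)
_MULTI_CODON = sorted(
    aa for aa in _CODONS_BY_AA if aa != "*" and len(_CODONS_BY_AA[aa]) > 1
)


def make_census(
    event_counts: dict,
    effect_counts: dict | None = None,
    phenotype_counts: dict | None = None,
    af_strata=(),
    seed: int = 0,
    residue_range: tuple[int, int] = (19, 625),
) -> list[VariantRecord]:
    """Generate a synthetic census with exact requested marginals.

    Parameters
    ----------
    event_counts
        ``EventType`` (or its value) -> count over all variants.
    effect_counts
        ``Effect`` -> count over the point variants; must sum to the
        point count. Defaults to all-missense.
    phenotype_counts
        ``Phenotype`` (excluding polymorphism) -> count over the
        disease-associated variants (all non-polymorphism events); must
        sum to that total. Defaults to all-unknown.
    af_strata
        Iterable of ``(n_records, allele_frequency)`` pairs; assigned to
        distinct records in order. The rest carry no AF.

    Tabulating the output reproduces the requested marginals exactly;
    infeasible marginals raise ``ValueError``. Same seed, same output.
    """
    rng = np.random.default_rng(seed)
    events = {EventType(k): int(v) for k, v in event_counts.items()}
    if any(v < 0 for v in events.values()):
        raise ValueError("event counts must be non-negative")
    n_point = events.get(EventType.POINT, 0)
    n_poly = events.get(EventType.POLYMORPHISM, 0)
    n_total = sum(events.values())
    n_disease = n_total - n_poly

    if effect_counts is None:
        effects = {Effect.MISSENSE: n_point}
    else:
        effects = {Effect(k): int(v) for k, v in effect_counts.items()}
    if sum(effects.values()) != n_point:
        raise ValueError("effect counts must sum to the point-variant count")

    if phenotype_counts is None:
        phens = {Phenotype.UNKNOWN: n_disease}
    else:
        phens = {Phenotype(k): int(v) for k, v in phenotype_counts.items()}
    if Phenotype.POLYMORPHISM in phens:
        raise ValueError("phenotype counts cover disease-associated records only")
    if sum(phens.values()) != n_disease:
        raise ValueError(
            "phenotype counts must sum to the disease-associated total "
            f"({n_disease})"
        )

    lo, hi = residue_range
    positions = rng.permutation(np.arange(lo, hi + 1))
    needed = sum(effects.get(e, 0) for e in (Effect.MISSENSE, Effect.NONSENSE, Effect.SILENT))
    if needed > len(positions):
        raise ValueError("more protein changes requested than available codons")
    pos_iter = iter(positions.tolist())

    phen_pool = [p for p, n in sorted(phens.items(), key=lambda kv: kv[0].value) for _ in range(n)]
    rng.shuffle(phen_pool)
    phen_iter = iter(phen_pool)

    records: list[VariantRecord] = []

    def _point(effect: Effect) -> VariantRecord:
        pos = next(pos_iter)
        if effect == Effect.MISSENSE:
            ref = str(rng.choice(_MULTI_CODON))
            alts = sorted(
                a for a in _CODONS_BY_AA
                if a not in ("*", ref) and single_nt_reachable(ref, a)
            )
            alt = str(rng.choice(alts))
            change = f"{AA1_TO_3[ref]}{pos}{AA1_TO_3[alt]}"
        elif effect == Effect.NONSENSE:
            ref = str(rng.choice(_STOP_REACHABLE))
            change = f"{AA1_TO_3[ref]}{pos}*"
        elif effect == Effect.SILENT:
            ref = str(rng.choice(_MULTI_CODON))
            change = f"{AA1_TO_3[ref]}{pos}{AA1_TO_3[ref]}"
        else:
            return VariantRecord(
                event_type=EventType.POINT,
                effect=Effect.UNDEFINED,
                phenotype=next(phen_iter),
            )
        return VariantRecord(
            protein_change_hgvs=change,
            event_type=EventType.POINT,
            effect=effect,
            phenotype=next(phen_iter),
        )

    for effect in (Effect.MISSENSE, Effect.NONSENSE, Effect.SILENT, Effect.UNDEFINED):
        for _ in range(effects.get(effect, 0)):
            records.append(_point(effect))
    for ev in (EventType.DELETION, EventType.DUPLICATION, EventType.INSERTION,
               EventType.UNDEFINED):
        for _ in range(events.get(ev, 0)):
            records.append(
                VariantRecord(event_type=ev, effect=Effect.UNDEFINED,
                              phenotype=next(phen_iter))
            )
    for _ in range(n_poly):
        records.append(
            VariantRecord(event_type=EventType.POLYMORPHISM,
                          effect=Effect.UNDEFINED,
                          phenotype=Phenotype.POLYMORPHISM)
        )

    total_af = sum(int(n) for n, _ in af_strata)
    if total_af > len(records):
        raise ValueError("more AF assignments than records")
    order = rng.permutation(len(records))
    pos = 0
    for n, af in af_strata:
        for _ in range(int(n)):
            records[order[pos]].allele_frequency = float(af)
            pos += 1
    return records
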