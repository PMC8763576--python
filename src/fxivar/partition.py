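"""Domain separation, interdomain contacts, dimer interface, disulfides.

Two complementary burial comparisons drive this module:

* *domain separation* — recompute residue accessibility after cutting the
  protein into its isolated domains; a residue whose accessibility bin
  rises on isolation was packed against a neighbouring domain. Because
  isolation only removes occluding atoms (the sampling lattice is
  deterministic), the per-residue delta is non-negative by construction.
* *interface buried surface area* — per-residue BSA of an assembly is the
  SASA of the residue in its own chain alone minus its SASA in the full
  assembly; residues with BSA above a cutoff (default 5 A^2) form the
  interface set.

Disulfide bridges are detected geometrically from S-gamma/S-gamma
distances (covalent bond ~2.05 A; cutoff 2.3 A tolerates refinement
noise while excluding van der Waals contacts), resolving each cysteine
to at most one partner by nearest distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .accessibility import (
    DEFAULT_N_POINTS,
    DEFAULT_PROBE_RADIUS,
    compute_sasa,
    relative_accessibility,
    residue_sasa,
)
from .census import DomainMap
from .structure import Structure

__all__ = [
    "split_domains",
    "separation_delta",
    "interface_residues",
    "find_disulfides",
    "build_dimer",
    "salt_bridges",
    "DisulfideBond",
    "DEFAULT_BSA_CUTOFF",
    "DEFAULT_SG_CUTOFF",
]

DEFAULT_BSA_CUTOFF = 5.0  # A^2
DEFAULT_SG_CUTOFF = 2.3  # A, S-gamma pair distance
DEFAULT_CONTACT_DELTA = 1  # accessibility bins


def split_domains(structure: Structure, domain_map: DomainMap) -> dict[str, Structure]:
    """Cut a structure into isolated per-domain substructures.

    Every residue must fall inside exactly one interval of the map;
    atoms are untouched. Domains with no resolved residues are omitted.
    """
    out: dict[str, Structure] = {}
    assigned = np.zeros(len(structure), dtype=bool)
    for name, start, end in domain_map.intervals:
        mask = (structure.resnum >= start) & (structure.resnum <= end)
        assigned |= mask
        if mask.any():
            out[name] = structure.subset(mask)
    if not assigned.all():
        stray = sorted(set(structure.resnum[~assigned].tolist()))
        raise ValueError(f"residues outside the domain map: {stray[:10]}")
    return out


def separation_delta(
    structure: Structure,
    domain_map: DomainMap,
    max_asa: dict[str, float] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    contact_delta: int = DEFAULT_CONTACT_DELTA,
) -> pd.DataFrame:
    """Accessibility change of every residue upon domain isolation.

    Returns a per-residue frame with ``bin_intact``, ``bin_isolated``,
    ``delta`` (isolated minus intact, always >= 0) and ``contact``
    (delta >= ``contact_delta``, default one bin = 10 percentage
    points). The same sampling lattice is used for both states, so
    removing occluders can only increase each atom's accessible
    fraction; a negative delta would indicate a bug and is asserted
    against.
    """
    intact = relative_accessibility(
        structure, max_asa=max_asa, state="intact",
        probe_radius=probe_radius, n_points=n_points,
    ).set_index(["chain", "resnum"])
    pieces = []
    for name, sub in split_domains(structure, domain_map).items():
        prof = relative_accessibility(
            sub, max_asa=max_asa, state="isolated_domain",
            probe_radius=probe_radius, n_points=n_points,
        )
        prof["domain"] = name
        pieces.append(prof)
    isolated = pd.concat(pieces, ignore_index=True).set_index(["chain", "resnum"])

    joined = intact.join(
        isolated[["bin", "percent", "domain"]], rsuffix="_isolated"
    ).reset_index()
    joined = joined.rename(
        columns={"bin": "bin_intact", "bin_isolated": "bin_isolated",
                 "percent": "percent_intact", "percent_isolated": "percent_isolated"}
    )
    ok = joined["bin_intact"].notna() & joined["bin_isolated"].notna()
    delta = joined.loc[ok, "bin_isolated"].astype(int) - joined.loc[
        ok, "bin_intact"
    ].astype(int)
    if (delta < 0).any():
        raise AssertionError(
            "separation delta went negative; occlusion can only decrease on isolation"
        )
    joined["delta"] = pd.array([pd.NA] * len(joined), dtype="Int64")
    joined.loc[ok, "delta"] = delta.to_numpy()
    joined["contact"] = joined["delta"].map(
        lambda d: bool(d >= contact_delta) if d is not pd.NA else pd.NA
    )
    return joined


def interface_residues(
    assembly: Structure,
    bsa_cutoff: float = DEFAULT_BSA_CUTOFF,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> pd.DataFrame:
    """Per-residue buried surface area of a multi-chain assembly.

    BSA(residue) = SASA(residue in its own chain alone) - SASA(residue
    in the assembly), over all atoms of the residue. The returned frame
    carries ``sasa_monomer``, ``sasa_assembly``, ``bsa`` and
    ``interface`` (BSA > cutoff). A single-chain input yields an empty
    interface set.
    """
    chains = sorted(set(assembly.chain.tolist()))
    asm_sasa = residue_sasa(
        assembly, compute_sasa(assembly, probe_radius, n_points), sidechain_only=False
    )["sasa_total"]
    frames = []
    for ch in chains:
        mono = assembly.select_chain(ch)
        mono_sasa = residue_sasa(
            mono, compute_sasa(mono, probe_radius, n_points), sidechain_only=False
        )
        df = mono_sasa.rename(columns={"sasa_total": "sasa_monomer"})[
            ["resname", "sasa_monomer"]
        ]
        frames.append(df)
    out = pd.concat(frames)
    out["sasa_assembly"] = asm_sasa
    out["bsa"] = out["sasa_monomer"] - out["sasa_assembly"]
    # sampling noise can give tiny negative values for untouched residues
    out.loc[out["bsa"].abs() < 1e-9, "bsa"] = 0.0
    out["interface"] = (out["bsa"] > bsa_cutoff) & (len(chains) > 1)
    return out.reset_index()


@dataclass(frozen=True)
class DisulfideBond:
    cys_a: tuple[str, int]  # (chain, resnum)
    cys_b: tuple[str, int]
    distance: float
    interchain: bool


def find_disulfides(
    structure: Structure, sg_cutoff: float = DEFAULT_SG_CUTOFF
) -> tuple[list[DisulfideBond], list[tuple[str, int]]]:
    """Detect disulfide bridges from S-gamma geometry.

    Pairs cysteines whose SG atoms lie within ``sg_cutoff`` (nearest
    neighbour wins when a SG has several candidates); every Cys joins at
    most one bridge. Returns ``(bonds, free_cys)`` where ``free_cys``
    lists cysteines left unpaired.
    """
    mask = (structure.resname == "CYS") & (structure.atom_name == "SG")
    keys = [
        (str(c), int(r))
        for c, r in zip(structure.chain[mask], structure.resnum[mask])
    ]
    xyz = structure.xyz[mask]
    if len(keys) == 0:
        return [], []
    d = cdist(xyz, xyz)
    candidates = [
        (d[i, j], i, j)
        for i in range(len(keys))
        for j in range(i + 1, len(keys))
        if d[i, j] <= sg_cutoff
    ]
    candidates.sort()
    used: set[int] = set()
    bonds: list[DisulfideBond] = []
    for dist, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        bonds.append(
            DisulfideBond(
                cys_a=keys[i],
                cys_b=keys[j],
                distance=float(dist),
                interchain=keys[i][0] != keys[j][0],
            )
        )
    free = [k for n, k in enumerate(keys) if n not in used]
    return bonds, free


def build_dimer(
    monomer: Structure,
    rotation: np.ndarray,
    translation: np.ndarray,
    chain_ids: tuple[str, str] = ("A", "B"),
    min_distance: float = 1.0,
) -> Structure:
    """Assemble a two-chain dimer by applying a rigid-body transform.

    The original monomer becomes the first chain and its transformed
    copy the second. If the transform collapses the chains onto each
    other (closest interatomic distance below ``min_distance``) a
    warning is raised — an identity transform is the canonical offender.
    """
    a = monomer.with_chain_id(chain_ids[0])
    b = monomer.transformed(rotation, translation).with_chain_id(chain_ids[1])
    dmin = cdist(a.xyz, b.xyz).min()
    if dmin < min_distance:
        warnings.warn(
            f"dimer transform brings chains within {dmin:.2f} A; "
            "chains may be superposed",
            stacklevel=2,
        )
    return Structure.merge(a, b)


def salt_bridges(
    assembly: Structure,
    cutoff: float = 4.0,
    interchain_only: bool = True,
) -> pd.DataFrame:
    """Demo-level salt-bridge screen: basic-N to acidic-O within ``cutoff``.

    Pairs Arg/Lys/His sidechain nitrogens with Asp/Glu sidechain
    oxygens. Geometric distance check only — no hydrogen placement or
    energetics.
    """
    basic_n = (
        np.isin(assembly.resname, ["ARG", "LYS", "HIS"])
        & (assembly.element == "N")
        & ~assembly.is_backbone
    )
    acidic_o = (
        np.isin(assembly.resname, ["ASP", "GLU"])
        & (assembly.element == "O")
        & ~assembly.is_backbone
    )
    rows = []
    bi = np.where(basic_n)[0]
    ai = np.where(acidic_o)[0]
    if len(bi) and len(ai):
        d = cdist(assembly.xyz[bi], assembly.xyz[ai])
        for x, y in zip(*np.where(d <= cutoff)):
            i, j = bi[x], ai[y]
            if interchain_only and assembly.chain[i] == assembly.chain[j]:
                continue
            rows.append(
                {
                    "chain_basic": str(assembly.chain[i]),
                    "res_basic": int(assembly.resnum[i]),
                    "name_basic": str(assembly.resname[i]),
                    "chain_acidic": str(assembly.chain[j]),
                    "res_acidic": int(assembly.resnum[j]),
                    "name_acidic": str(assembly.resname[j]),
                    "distance": float(d[x, y]),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "chain_basic", "res_basic", "name_basic",
            "chain_acidic", "res_acidic", "name_acidic", "distance",
        ],
    )
    if not df.empty:
        df = (
            df.sort_values("distance")
            .drop_duplicates(
                subset=["chain_basic", "res_basic", "chain_acidic", "res_acidic"]
            )
            .reset_index(drop=True)
        )
    return df
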