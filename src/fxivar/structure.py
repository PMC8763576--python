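"""Coordinate container and structure I/O.

A :class:`Structure` is a flat, array-backed set of heavy atoms with
chain/residue identity, element van der Waals radii and a
backbone/sidechain partition — the minimal representation the
accessibility and interface analyses need. Reading PDB and mmCIF goes
through gemmi (first model, highest-occupancy altloc, hydrogens/waters/
ligands dropped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Structure", "VDW_RADII", "BACKBONE_ATOMS", "read_structure"]

#: Fixed published van der Waals radii per element (Angstrom).
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class UnknownElementError(ValueError):
    """Element without a configured van der Waals radius."""


@dataclass
class Structure:
    """Array-backed heavy-atom model.

    All arrays share the atom axis. ``resnum`` follows the author (HGVS-
    aligned) numbering of the source file. ``incomplete`` lists residues
    retained despite missing backbone atoms.
    """

    chain: np.ndarray  # str
    resnum: np.ndarray  # int
    resname: np.ndarray  # str, three-letter upper case
    atom_name: np.ndarray  # str
    element: np.ndarray  # str
    xyz: np.ndarray  # (n, 3) float, Angstrom
    radius: np.ndarray  # float, Angstrom
    incomplete: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        self.radius = np.asarray(self.radius, dtype=float)
        if np.any(self.radius <= 0):
            raise ValueError("radii must be positive")
        for name in ("chain", "resnum", "resname", "atom_name", "element"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != self.xyz.shape[0]:
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)

    # -- basic queries ------------------------------------------------------

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain, resnum) pairs in file order."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain, self.resnum):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys())

    def residue_name(self, chain: str, resnum: int) -> str:
        mask = (self.chain == chain) & (self.resnum == resnum)
        names = set(self.resname[mask])
        if not names:
            raise KeyError((chain, resnum))
        return names.pop()

    @property
    def is_backbone(self) -> np.ndarray:
        return np.isin(self.atom_name, list(BACKBONE_ATOMS))

    @property
    def is_sidechain(self) -> np.ndarray:
        """Sidechain atom mask; for Gly the CA stands in as the sidechain
        (DSSP-style convention), so its CA is included here."""
        mask = ~self.is_backbone
        gly_ca = (self.resname == "GLY") & (self.atom_name == "CA")
        return mask | gly_ca

    # -- manipulation -------------------------------------------------------

    def subset(self, mask: np.ndarray) -> "Structure":
        kept = {
            (str(c), int(r))
            for c, r, m in zip(self.chain, self.resnum, mask)
            if m
        }
        inc = frozenset(k for k in self.incomplete if k in kept)
        return Structure(
            chain=self.chain[mask],
            resnum=self.resnum[mask],
            resname=self.resname[mask],
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            xyz=self.xyz[mask],
            radius=self.radius[mask],
            incomplete=inc,
        )

    def select_chain(self, chain: str) -> "Structure":
        return self.subset(self.chain == chain)

    def select_residues(self, start: int, end: int, chain: str | None = None) -> "Structure":
        mask = (self.resnum >= start) & (self.resnum <= end)
        if chain is not None:
            mask &= self.chain == chain
        return self.subset(mask)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigid-body copy: ``x -> R x + t``."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        return replace(self, xyz=self.xyz @ R.T + t)

    def with_chain_id(self, chain_id: str) -> "Structure":
        return replace(
            self,
            chain=np.full(len(self), chain_id, dtype=object),
            incomplete=frozenset((chain_id, r) for _, r in self.incomplete),
        )

    @staticmethod
    def merge(*parts: "Structure") -> "Structure":
        return Structure(
            chain=np.concatenate([p.chain for p in parts]),
            resnum=np.concatenate([p.resnum for p in parts]),
            resname=np.concatenate([p.resname for p in parts]),
            atom_name=np.concatenate([p.atom_name for p in parts]),
            element=np.concatenate([p.element for p in parts]),
            xyz=np.vstack([p.xyz for p in parts]),
            radius=np.concatenate([p.radius for p in parts]),
            incomplete=frozenset().union(*(p.incomplete for p in parts)),
        )

    # -- I/O ----------------------------------------------------------------

    def write_pdb(self, path) -> None:
        """Write a minimal PDB file (toy structures and reports)."""
        with open(path, "w") as fh:
            for i in range(len(self)):
                name = str(self.atom_name[i])
                pad = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    "ATOM  {serial:>5d} {name:<4s} {res:<3s} {ch:1s}{num:>4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                        serial=i + 1,
                        name=pad,
                        res=str(self.resname[i])[:3],
                        ch=str(self.chain[i])[:1],
                        num=int(self.resnum[i]),
                        x=self.xyz[i, 0],
                        y=self.xyz[i, 1],
                        z=self.xyz[i, 2],
                        occ=1.0,
                        b=0.0,
                        el=str(self.element[i])[:2],
                    )
                )
            fh.write("END\n")


def read_structure(
    path,
    fmt: str | None = None,
    keep_hetero: bool = False,
    radii: dict[str, float] | None = None,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Uses the first model; for alternate locations the highest-occupancy
    conformer is kept. Hydrogens, waters and (by default) hetero ligands
    are excluded. An element without a configured radius raises
    :class:`UnknownElementError`; residues with missing backbone atoms are
    retained and flagged in ``incomplete``.
    """
    import gemmi

    radii = radii or VDW_RADII
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    st.remove_waters()
    model = st[0]

    chains, resnums, resnames, atom_names, elements, coords, rads = (
        [], [], [], [], [], [], [],
    )
    incomplete = set()
    for chain in model:
        for residue in chain:
            std_aa = residue.name.upper() in _AA3
            if not std_aa and not keep_hetero:
                continue
            atom_set = set()
            for atom in residue:
                el = atom.element.name.upper()
                if el == "H":
                    continue
                if el not in radii:
                    raise UnknownElementError(
                        f"{path}: element {el!r} in {residue.name}{residue.seqid.num} "
                        "has no configured radius"
                    )
                chains.append(chain.name)
                resnums.append(residue.seqid.num)
                resnames.append(residue.name.upper())
                atom_names.append(atom.name)
                elements.append(el)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                rads.append(radii[el])
                atom_set.add(atom.name)
            if std_aa and not {"N", "CA", "C"} <= atom_set:
                incomplete.add((chain.name, residue.seqid.num))
                warnings.warn(
                    f"{path}: residue {chain.name}/{residue.name}"
                    f"{residue.seqid.num} is missing backbone atoms",
                    stacklevel=2,
                )
    if not coords:
        raise ValueError(f"{path}: no usable atoms")
    return Structure(
        chain=np.array(chains, dtype=object),
        resnum=np.array(resnums, dtype=int),
        resname=np.array(resnames, dtype=object),
        atom_name=np.array(atom_names, dtype=object),
        element=np.array(elements, dtype=object),
        xyz=np.array(coords, dtype=float),
        radius=np.array(rads, dtype=float),
        incomplete=frozenset(incomplete),
    )
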