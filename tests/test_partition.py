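"""Domain separation, interface BSA, disulfide detection, dimer assembly."""

import numpy as np
import pytest

from fxivar import fxi
from fxivar.census import DomainMap
from fxivar.partition import (
    build_dimer,
    find_disulfides,
    interface_residues,
    salt_bridges,
    separation_delta,
    split_domains,
)
from fxivar.structure import Structure
from fxivar.synthetic import make_disulfide_scaffold, make_helix, make_packed_pair

TWO_DOMAIN_MAP = DomainMap(intervals=(("D1", 1, 12), ("D2", 13, 24)))


class TestSplitDomains:
    def test_two_domain_toy_preserves_atoms(self, packed_pair_domains):
        st = packed_pair_domains.assembly
        parts = split_domains(st, TWO_DOMAIN_MAP)
        assert set(parts) == {"D1", "D2"}
        assert sum(len(p) for p in parts.values()) == len(st)

    def test_single_domain_identity(self, toy_helix):
        parts = split_domains(toy_helix, DomainMap(intervals=(("all", 1, 12),)))
        assert len(parts["all"]) == len(toy_helix)

    def test_residue_outside_map_rejected(self, toy_helix):
        with pytest.raises(ValueError, match="outside"):
            split_domains(toy_helix, DomainMap(intervals=(("short", 1, 5),)))


@pytest.fixture(scope="module")
def delta(packed_pair_domains):
    return separation_delta(
        packed_pair_domains.assembly, TWO_DOMAIN_MAP, max_asa={"ALA": 136.8}
    )


class TestSeparationDelta:
    def test_delta_nonnegative_everywhere(self, delta):
        assert (delta["delta"].dropna() >= 0).all()

    def test_far_surface_residues_unchanged(self, delta, packed_pair_domains):
        contacts = set(packed_pair_domains.contacts_a) | set(
            packed_pair_domains.contacts_b
        )
        far = delta[~delta["resnum"].isin(contacts)]
        assert (far["delta"] == 0).all()

    def test_packed_residue_transitions(self, delta):
        # the face-on residue of each unit is buried against the partner:
        # isolation frees at least two accessibility bins
        face = delta[delta["resnum"].isin([1, 13])]
        assert (face["delta"] >= 2).all()

    def test_contact_flag_matches_designed_interface(self, delta,
                                                     packed_pair_domains):
        contacts = set(packed_pair_domains.contacts_a) | set(
            packed_pair_domains.contacts_b
        )
        flagged = set(delta.loc[delta["contact"] == True, "resnum"])  # noqa: E712
        assert flagged == contacts

    def test_helix_alone_all_zero(self, toy_helix):
        d = separation_delta(
            toy_helix, DomainMap(intervals=(("all", 1, 12),)),
            max_asa={"ALA": 136.8},
        )
        assert (d["delta"] == 0).all()


class TestInterfaceResidues:
    def test_isolated_monomer_empty(self, toy_helix):
        df = interface_residues(toy_helix.with_chain_id("A"))
        assert not df["interface"].any()

    def test_designed_contacts_recovered_exactly(self, packed_pair_chains):
        df = interface_residues(packed_pair_chains.assembly)
        got_a = sorted(df.loc[(df["chain"] == "A") & df["interface"], "resnum"])
        got_b = sorted(df.loc[(df["chain"] == "B") & df["interface"], "resnum"])
        assert got_a == packed_pair_chains.contacts_a
        assert got_b == packed_pair_chains.contacts_b

    def test_symmetric_homodimer_symmetric_interface(self, packed_pair_chains):
        df = interface_residues(packed_pair_chains.assembly)
        a = df[df["chain"] == "A"].set_index("resnum")["bsa"]
        b = df[df["chain"] == "B"].set_index("resnum")["bsa"]
        assert np.allclose(a, b, atol=1.5)

    def test_bsa_totals_consistent(self, packed_pair_chains):
        from fxivar.accessibility import compute_sasa

        st = packed_pair_chains.assembly
        df = interface_residues(st)
        total_bsa = df["bsa"].sum()
        mono_total = sum(
            compute_sasa(st.select_chain(c)).sum() for c in ("A", "B")
        )
        asm_total = compute_sasa(st).sum()
        assert total_bsa == pytest.approx(mono_total - asm_total, rel=0.02)

    def test_distant_pair_no_interface(self):
        pair = make_packed_pair(make_helix(8), make_helix(8), gap=30.0)
        df = interface_residues(pair.assembly)
        assert pair.contacts_a == [] and pair.contacts_b == []
        assert not df["interface"].any()


class TestDisulfides:
    def test_simple_pair(self):
        st = make_disulfide_scaffold([(10, 20)])
        bonds, free = find_disulfides(st)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.05, abs=0.01)
        assert not bonds[0].interchain
        assert free == []

    def test_monomer_census_17_bridges_cys29_free(self):
        scaffold = make_disulfide_scaffold(
            fxi.FXI_DISULFIDES, free_cys=(fxi.FXI_FREE_CYS, 339)
        )
        bonds, free = find_disulfides(scaffold)
        assert len(bonds) == 17
        assert all(not b.interchain for b in bonds)
        assert ("A", fxi.FXI_FREE_CYS) in free
        detected = {tuple(sorted((b.cys_a[1], b.cys_b[1]))) for b in bonds}
        assert detected == {tuple(sorted(p)) for p in fxi.FXI_DISULFIDES}

    def test_distance_beyond_cutoff_ignored(self):
        st = make_disulfide_scaffold([(1, 2)])
        # stretch the pair: move one SG 3 A away
        mask = (st.resnum == 2) & (st.atom_name == "SG")
        st.xyz[mask] += np.array([3.0, 0.0, 0.0])
        bonds, free = find_disulfides(st)
        assert bonds == []
        assert len(free) == 2

    def test_no_cys_structure(self, toy_helix):
        assert find_disulfides(toy_helix) == ([], [])


class TestBuildDimer:
    @staticmethod
    def _fxi_dimer():
        scaffold = make_disulfide_scaffold(
            fxi.FXI_DISULFIDES, free_cys=(fxi.FXI_FREE_CYS, 339)
        )
        sg = scaffold.xyz[
            (scaffold.resnum == 339) & (scaffold.atom_name == "SG")
        ][0]
        mid = sg + np.array([1.025, 0.0, 0.0])
        R = np.diag([-1.0, -1.0, 1.0])  # two-fold about z through mid
        t = np.array([2 * mid[0], 2 * mid[1], 0.0])
        return build_dimer(scaffold, R, t)

    def test_identity_transform_warns(self, toy_helix):
        with pytest.warns(UserWarning, match="superposed"):
            build_dimer(toy_helix, np.eye(3), np.zeros(3))

    def test_two_fold_gives_two_chains(self, toy_helix):
        dimer = build_dimer(
            toy_helix, np.diag([-1.0, -1.0, 1.0]), np.array([30.0, 0.0, 0.0])
        )
        assert set(dimer.chain) == {"A", "B"}
        assert len(dimer) == 2 * len(toy_helix)

    def test_dimer_interchain_cys339_flagged(self):
        dimer = self._fxi_dimer()
        bonds, free = find_disulfides(dimer)
        inter = [b for b in bonds if b.interchain]
        assert len(bonds) == 35  # 17 per chain + 1 interchain
        assert len(inter) == 1
        assert {inter[0].cys_a, inter[0].cys_b} == {("A", 339), ("B", 339)}
        assert set(free) == {("A", fxi.FXI_FREE_CYS), ("B", fxi.FXI_FREE_CYS)}


class TestSaltBridges:
    def test_interchain_pair_found(self):
        def residue(chain, num, name, atoms):
            n = len(atoms)
            return Structure(
                chain=np.array([chain] * n, object),
                resnum=np.array([num] * n),
                resname=np.array([name] * n, object),
                atom_name=np.array([a for a, _, _ in atoms], object),
                element=np.array([e for _, e, _ in atoms], object),
                xyz=np.array([p for _, _, p in atoms], float),
                radius=np.array([1.6] * n),
            )

        arg = residue("A", 349, "LYS", [
            ("CA", "C", [0, 0, 0]), ("NZ", "N", [2.0, 0, 0]),
        ])
        glu = residue("B", 305, "GLU", [
            ("CA", "C", [8, 0, 0]), ("OE1", "O", [5.2, 0, 0]),
        ])
        df = salt_bridges(Structure.merge(arg, glu))
        assert len(df) == 1
        assert df.loc[0, "res_basic"] == 349
        assert df.loc[0, "res_acidic"] == 305
        assert df.loc[0, "distance"] == pytest.approx(3.2)
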