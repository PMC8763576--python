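"""Sphere-sampling SASA, percent accessibility, binning and annotation."""

import numpy as np
import pandas as pd
import pytest

from conftest import single_atom, structure_from_points
from fxivar.accessibility import (
    accessibility_bin,
    annotate_variants,
    compute_sasa,
    read_dssp,
    relative_accessibility,
    residue_sasa,
)
from fxivar.census import EventType, VariantRecord
from fxivar.structure import Structure
from fxivar.synthetic import make_helix

PROBE = 1.4


def sphere_area(r):
    return 4.0 * np.pi * (r + PROBE) ** 2


class TestComputeSasa:
    def test_isolated_sphere_analytic(self):
        st = single_atom(radius=1.7)
        area = compute_sasa(st)[0]
        assert area == pytest.approx(sphere_area(1.7), rel=0.005)

    def test_two_distant_atoms_unperturbed(self):
        st = structure_from_points([[0, 0, 0], [20, 0, 0]])
        areas = compute_sasa(st)
        assert areas == pytest.approx([sphere_area(1.7)] * 2, rel=0.005)

    def test_caged_atom_nearly_buried(self):
        # central atom inside a tight 12-neighbour icosahedral cage
        phi = (1 + np.sqrt(5)) / 2
        verts = np.array(
            [
                [0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
                [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
                [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1],
            ],
            float,
        )
        verts = 2.2 * verts / np.linalg.norm(verts[0])
        st = structure_from_points(np.vstack([[0, 0, 0], verts]))
        area = compute_sasa(st, n_points=10000)[0]
        assert area < 1.0

    def test_translation_rotation_invariance(self, toy_helix):
        base = compute_sasa(toy_helix)
        theta = 1.1
        R = np.array(
            [
                [np.cos(theta), 0, np.sin(theta)],
                [0, 1, 0],
                [-np.sin(theta), 0, np.cos(theta)],
            ]
        )
        moved = toy_helix.transformed(R, np.array([5.0, -3.0, 11.0]))
        per_res = residue_sasa(toy_helix, base)["sasa"]
        per_res_moved = residue_sasa(moved, compute_sasa(moved))["sasa"]
        assert np.allclose(per_res, per_res_moved, rtol=0.01)

    def test_total_sasa_monotone_under_addition(self):
        pts = [[0, 0, 0], [3.0, 0, 0], [0, 3.0, 0], [1.5, 1.5, 1.0]]
        prev_atoms = None
        for n in (1, 2, 3, 4):
            st = structure_from_points(pts[:n])
            areas = compute_sasa(st)
            if prev_atoms is not None:
                # every pre-existing atom can only lose area
                assert (areas[: n - 1] <= prev_atoms + 1e-9).all()
            prev_atoms = areas

    def test_dense_oracle_agreement_per_residue(self, toy_helix):
        """Default sampling agrees with a 10x denser run within 2%."""
        coarse = residue_sasa(toy_helix, compute_sasa(toy_helix, n_points=960))
        dense = residue_sasa(toy_helix, compute_sasa(toy_helix, n_points=10000))
        rel = (coarse["sasa"] - dense["sasa"]).abs() / dense["sasa"]
        assert (rel <= 0.02).all()

    def test_independent_library_oracle(self, toy_helix):
        """Cross-check against biotite's Shrake-Rupley implementation."""
        biotite_struct = pytest.importorskip("biotite.structure")
        arr = biotite_struct.AtomArray(len(toy_helix))
        arr.coord = toy_helix.xyz.astype(np.float32)
        arr.chain_id = toy_helix.chain.astype(str)
        arr.res_id = toy_helix.resnum
        arr.res_name = toy_helix.resname.astype(str)
        arr.atom_name = toy_helix.atom_name.astype(str)
        arr.element = toy_helix.element.astype(str)
        ref_atom = biotite_struct.sasa(
            arr, probe_radius=PROBE, point_number=1000,
            vdw_radii=toy_helix.radius,
        )
        ours = compute_sasa(toy_helix)
        ref = residue_sasa(toy_helix, ref_atom)["sasa"]
        got = residue_sasa(toy_helix, ours)["sasa"]
        assert np.allclose(got, ref, rtol=0.02, atol=0.5)

    def test_guards(self):
        with pytest.raises(ValueError, match="n_points"):
            compute_sasa(single_atom(), n_points=50)
        st = structure_from_points([[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError, match="coincident"):
            compute_sasa(st)


class TestBinning:
    @pytest.mark.parametrize(
        "pct,expected_bin,buried",
        [(5, 0, True), (15, 1, True), (25, 2, False), (99, 9, False),
         (130, 9, False), (0, 0, True)],
    )
    def test_bin_rule(self, pct, expected_bin, buried):
        b = accessibility_bin(pct)
        assert b == expected_bin
        assert (b <= 1) == buried

    def test_profile_columns_and_burial(self, toy_helix):
        prof = relative_accessibility(toy_helix, max_asa={"ALA": 136.8})
        assert set(prof.columns) >= {
            "chain", "resnum", "resname", "sasa", "percent", "bin", "buried",
            "state",
        }
        assert (prof["buried"] == (prof["bin"] <= 1)).all()

    def test_unknown_residue_type_not_classified(self, toy_helix):
        prof = relative_accessibility(toy_helix, max_asa={"GLY": 47.0})
        assert prof["percent"].isna().all()
        assert prof["buried"].isna().all()


class TestAnnotateVariants:
    @pytest.fixture
    def toy_profile(self):
        # hand-built profile: residues 20 buried, 21 exposed
        return pd.DataFrame(
            {
                "chain": ["A", "A"],
                "resnum": [20, 21],
                "resname": ["ALA", "ALA"],
                "sasa": [5.0, 80.0],
                "percent": [7.0, 80.0],
                "bin": [0, 8],
                "buried": [True, False],
                "state": ["intact", "intact"],
            }
        )

    def test_exact_contingency(self, toy_profile):
        census = [
            VariantRecord(protein_change_hgvs="Ala20Val", event_type=EventType.POINT,
                          phenotype="type_I"),
            VariantRecord(protein_change_hgvs="Ala21Val", event_type=EventType.POINT,
                          phenotype="type_I"),
            VariantRecord(protein_change_hgvs="Ala20Gly", event_type=EventType.POINT,
                          phenotype="type_II"),
        ]
        per_variant, crosstab = annotate_variants(census, toy_profile)
        assert crosstab.loc["type_I", "buried"] == 1
        assert crosstab.loc["type_I", "exposed"] == 1
        assert crosstab.loc["type_II", "buried"] == 1

    def test_unresolved_residue_not_classified(self, toy_profile):
        census = [VariantRecord(protein_change_hgvs="Ala99Val",
                                event_type=EventType.POINT)]
        per_variant, crosstab = annotate_variants(census, toy_profile)
        assert per_variant["accessibility_class"].tolist() == ["not_classified"]

    def test_empty_census(self, toy_profile):
        per_variant, crosstab = annotate_variants([], toy_profile)
        assert per_variant.empty and crosstab.empty


DSSP_SNIPPET = """\
==== Secondary Structure Definition by the program DSSP ====
  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA
    1   20 A C  E           0   0   10     0, 0.0    2,-0.3     0, 0.0    0, 0.0   0.0  360.0 360.0-120.0 140.0   10.0   10.0   10.0
    2   21 A A  H           0   0  105     0, 0.0    2,-0.3     0, 0.0    0, 0.0   0.0  360.0 360.0 -60.0 -45.0   11.0   11.0   11.0
"""


class TestDsspReader:
    def test_reads_classic_dialect(self, tmp_path):
        path = tmp_path / "toy.dssp"
        path.write_text(DSSP_SNIPPET)
        df = read_dssp(path)
        assert df["resnum"].tolist() == [20, 21]
        assert df["ss"].tolist() == ["E", "H"]
        assert df["acc"].tolist() == [10.0, 105.0]

    def test_non_dssp_rejected(self, tmp_path):
        path = tmp_path / "not.dssp"
        path.write_text("hello\n")
        with pytest.raises(ValueError):
            read_dssp(path)
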