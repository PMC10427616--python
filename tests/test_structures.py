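"""Structure parsing, contact/distance maps, RBF encoding, SASA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmcontact import structures as sx
from tmcontact import synthdata


def _single_atom_residue(idx, xyz, name="CA", aa="A", element="C"):
    return sx.Residue(index=idx, name=sx.ONE_TO_THREE[aa], aa=aa,
                      author_seq_id=idx + 1, atom_names=[name],
                      coords=np.array([xyz], dtype=float), elements=[element])


def _two_chain_complex(dist):
    """Two single-residue chains with nearest atoms `dist` apart."""
    a = sx.Chain("A", [_single_atom_residue(0, (0.0, 0.0, 0.0))])
    b = sx.Chain("B", [_single_atom_residue(0, (dist, 0.0, 0.0))])
    return sx.ComplexStructure([a, b], name="pair", symmetry_order=2)


class TestParsing:
    def test_roundtrip_of_generated_complex(self, toy_c3, tmp_path):
        path = tmp_path / "c3.pdb"
        synthdata.write_pdb(toy_c3, path)
        parsed = sx.parse_structure(path)
        assert parsed.n_chains == 3
        assert [len(ch) for ch in parsed.chains] == [48, 48, 48]
        assert parsed.chains[0].sequence == toy_c3.chains[0].sequence
        # coordinates survive at PDB precision (1e-3 A)
        np.testing.assert_allclose(parsed.chains[1].all_coords(),
                                   toy_c3.chains[1].all_coords(), atol=2e-3)

    def test_hydrogens_are_dropped(self, tmp_path):
        pdb = tmp_path / "h.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  H   ALA A   1       1.000   0.000   0.000  1.00  0.00           H\n"
            "ATOM      3  CB  ALA A   1       1.500   0.000   0.000  1.00  0.00           C\n"
            "END\n")
        c = sx.parse_structure(pdb)
        assert c.chains[0].residues[0].atom_names == ["CA", "CB"]

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        pdb = tmp_path / "alt.pdb"
        pdb.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70  0.00           C\n"
            "END\n")
        c = sx.parse_structure(pdb)
        assert c.chains[0].residues[0].coords[0, 0] == pytest.approx(5.0)

    def test_unreadable_file_raises_named_error(self, tmp_path):
        bad = tmp_path / "missing.pdb"
        with pytest.raises(sx.StructureParseError, match="missing.pdb"):
            sx.parse_structure(bad)

    def test_empty_structure_rejected(self, tmp_path):
        empty = tmp_path / "empty.pdb"
        empty.write_text("END\n")
        with pytest.raises(sx.StructureParseError):
            sx.parse_structure(empty)


class TestContactMap:
    @pytest.mark.parametrize("dist,expected", [(7.99, True), (8.0, True), (8.01, False)])
    def test_inclusive_cutoff_boundary(self, dist, expected):
        cm = sx.interchain_contact_map(_two_chain_complex(dist))
        assert bool(cm.union[0, 0]) is expected

    def test_union_invariant_under_cyclic_relabeling(self, toy_c3):
        cm = sx.interchain_contact_map(toy_c3)
        rotated = sx.ComplexStructure(
            [toy_c3.chains[1], toy_c3.chains[2], toy_c3.chains[0]],
            name="rot", symmetry_order=3)
        cm2 = sx.interchain_contact_map(rotated)
        assert np.array_equal(cm.union, cm2.union)

    def test_single_chain_rejected(self, toy_c3):
        with pytest.raises(ValueError):
            sx.interchain_contact_map(toy_c3.monomer())

    def test_union_is_symmetric(self, toy_c3):
        cm = sx.interchain_contact_map(toy_c3)
        assert np.array_equal(cm.union, cm.union.T)


class TestDistanceMap:
    def test_diagonal_zero_and_construction(self):
        r0 = _single_atom_residue(0, (0, 0, 0), name="CB")
        r1 = _single_atom_residue(1, (5, 0, 0), name="CB")
        mono = sx.ComplexStructure([sx.Chain("A", [r0, r1])])
        dm = sx.intrachain_distance_map(mono)
        assert dm.values[0, 0] == 0.0
        assert dm.values[0, 1] == pytest.approx(5.0)

    def test_matches_bruteforce_oracle(self, toy_c3):
        mono = toy_c3.monomer()
        dm = sx.intrachain_distance_map(mono)
        reps = np.array([r.representative_atom() for r in mono.chains[0].residues])
        L = len(reps)
        oracle = np.zeros((L, L))
        for i in range(L):
            for j in range(L):
                oracle[i, j] = np.linalg.norm(reps[i] - reps[j])
        np.testing.assert_allclose(dm.values, oracle, atol=1e-12)

    def test_glycine_falls_back_to_ca(self):
        g = sx.Residue(index=0, name="GLY", aa="G", author_seq_id=1,
                       atom_names=["CA"], coords=np.zeros((1, 3)), elements=["C"])
        assert np.array_equal(g.representative_atom(), np.zeros(3))

    def test_missing_representative_flagged_with_inf(self):
        r0 = sx.Residue(index=0, name="ALA", aa="A", author_seq_id=1,
                        atom_names=["N"], coords=np.zeros((1, 3)), elements=["N"])
        r1 = _single_atom_residue(1, (3, 0, 0), name="CB")
        mono = sx.ComplexStructure([sx.Chain("A", [r0, r1])])
        dm = sx.intrachain_distance_map(mono)
        assert dm.missing[0] and not dm.missing[1]
        assert np.isinf(dm.values[0, 1])


class TestRBFEncoding:
    def test_channel_count_and_bin_center_values(self):
        centers = sx.rbf_bin_centers()
        assert len(centers) == 64
        enc = sx.encode_distance_rbf(np.array([[centers[10]]]))
        assert enc.values.shape == (1, 1, 64)
        assert enc.values[0, 0, 10] == pytest.approx(1.0)

    def test_one_sigma_gives_inverse_e(self):
        d = sx.rbf_bin_centers()[0] + sx.RBF_SIGMA
        enc = sx.encode_distance_rbf(np.array([[d]]))
        assert enc.values[0, 0, 0] == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_far_distance_vanishes(self):
        enc = sx.encode_distance_rbf(np.array([[60.0]]))
        assert enc.values.max() < 1e-100

    def test_infinite_sentinel_encodes_to_zeros(self):
        enc = sx.encode_distance_rbf(np.array([[np.inf, 5.0]]))
        assert np.all(enc.values[0, 0] == 0.0)
        assert enc.values[0, 1].max() > 0.0

    @given(st.floats(min_value=0.0, max_value=24.0))
    @settings(max_examples=50, deadline=None)
    def test_values_in_unit_interval_and_argmax_is_nearest_bin(self, d):
        enc = sx.encode_distance_rbf(np.array([[d]]))
        v = enc.values[0, 0]
        # mathematically in (0, 1]; bins many sigma away underflow to +0.0
        assert np.all(v >= 0.0) and np.all(v <= 1.0) and v.max() > 0.0
        assert np.argmax(v) == np.argmin(np.abs(sx.rbf_bin_centers() - d))


class TestSASA:
    def test_isolated_atom_matches_closed_form(self):
        mono = sx.ComplexStructure([sx.Chain("A", [_single_atom_residue(0, (0, 0, 0))])])
        ann = sx.compute_sasa(mono, n_points=200)
        expected = 4.0 * math.pi * (1.70 + 1.4) ** 2
        assert ann.sasa[0] == pytest.approx(expected, rel=1e-9)

    def test_fully_enclosed_atom_has_zero_sasa(self):
        shell_pts = sx._fibonacci_sphere(80) * 2.2
        residues = [_single_atom_residue(0, (0, 0, 0))]
        for k, p in enumerate(shell_pts):
            residues.append(_single_atom_residue(k + 1, tuple(p)))
        mono = sx.ComplexStructure([sx.Chain("A", residues)])
        ann = sx.compute_sasa(mono, n_points=100)
        assert ann.sasa[0] == 0.0

    def test_quadrature_converges_against_finer_lattice(self, toy_c3):
        mono = toy_c3.monomer()
        coarse = sx.compute_sasa(mono, n_points=400)
        fine = sx.compute_sasa(mono, n_points=4000)
        rel = np.abs(coarse.sasa - fine.sasa) / np.maximum(fine.sasa, 1.0)
        assert rel.max() < 0.02

    def test_surface_flag_follows_relative_threshold(self, toy_c3):
        ann = sx.compute_sasa(toy_c3.monomer())
        assert np.array_equal(ann.surface, ann.rel_sasa >= sx.SURFACE_REL_SASA)
        assert np.all(ann.sasa >= 0.0)


class TestInterfaceArea:
    def test_distant_chains_have_zero_area(self):
        c = _two_chain_complex(100.0)
        assert sx.interface_area(c, "A", "B") == 0.0

    def test_equals_delta_sasa_of_components(self, toy_dimer):
        area = sx.interface_area(toy_dimer, "A", "B")
        sa = sx.compute_sasa(toy_dimer, ["A"]).sasa.sum()
        sb = sx.compute_sasa(toy_dimer, ["B"]).sasa.sum()
        sab = sx.compute_sasa(toy_dimer, ["A", "B"]).sasa.sum()
        assert area == pytest.approx(max(0.0, (sa + sb - sab) / 2.0))
        assert area > 0.0

    def test_area_nonincreasing_with_separation(self, toy_dimer):
        areas = []
        for shift in (0.0, 4.0, 8.0, 20.0):
            chains = []
            for ci, ch in enumerate(toy_dimer.chains):
                residues = []
                for r in ch.residues:
                    # chain B sits across the interface on the -x side;
                    # shifting it further along -x separates the pair
                    coords = r.coords + (np.array([-shift, 0, 0]) if ci == 1 else 0.0)
                    residues.append(sx.Residue(r.index, r.name, r.aa, r.author_seq_id,
                                               list(r.atom_names), coords,
                                               list(r.elements)))
                chains.append(sx.Chain(ch.chain_id, residues))
            c = sx.ComplexStructure(chains, symmetry_order=2)
            areas.append(sx.interface_area(c, "A", "B"))
        assert all(a1 >= a2 - 1e-9 for a1, a2 in zip(areas, areas[1:]))
        assert areas[-1] == 0.0


class TestOutput:
    def test_h5_and_text_writers(self, tmp_path, toy_c3):
        import h5py
        cm = sx.interchain_contact_map(toy_c3)
        h5 = tmp_path / "maps.h5"
        sx.write_map_h5(h5, "union", cm.union.astype(np.uint8), attrs={"cutoff": 8.0})
        with h5py.File(h5) as f:
            assert f["union"].attrs["cutoff"] == 8.0
            assert np.array_equal(np.asarray(f["union"], dtype=bool), cm.union)
        txt = tmp_path / "maps.txt"
        sx.write_map_text(txt, cm.union.astype(int), threshold=0.5)
        lines = txt.read_text().strip().splitlines()
        assert len(lines) == int(cm.union.sum())
        i, j, v = lines[0].split("\t")
        assert int(i) >= 1 and int(j) >= 1 and v == "1"
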