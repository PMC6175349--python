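"""Membrane builders: flakes, pore cutting, graphdiyne, diameters, rims."""

from collections import Counter

import numpy as np
import pytest

from chirasieve.molsys import RigidTransform, Structure, apply_transform
from chirasieve.porelib import (LatticeSpec, PoreError, PoreModel, bond_graph,
                                build_graphdiyne_pore, build_graphene_flake,
                                build_preset, cut_pore, detect_rim,
                                pore_diameter, read_pore, ring_neighbors,
                                substitute_nitrogen, write_pore)

CORONENE_RINGS = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)]


def carbon_neighbor_counts(st):
    g = bond_graph(st)
    return {i: len(list(g.neighbors(i))) for i, e in enumerate(st.elements)
            if e == "C"}


class TestGrapheneFlake:
    def test_single_ring_is_benzene(self):
        st = build_graphene_flake([(0, 0)]).structure
        assert Counter(st.elements) == {"C": 6, "H": 6}
        cc = [np.linalg.norm(st.coords[i] - st.coords[j])
              for i in range(6) for j in range(i + 1, 6)]
        nearest = sorted(cc)[:6]
        assert np.allclose(nearest, 1.42, atol=1e-9)

    def test_seven_ring_flake_has_coronene_stoichiometry(self):
        st = build_graphene_flake(CORONENE_RINGS).structure
        assert Counter(st.elements) == {"C": 24, "H": 12}

    def test_every_carbon_is_threefold_coordinated(self):
        st = build_graphene_flake(CORONENE_RINGS).structure
        assert set(carbon_neighbor_counts(st).values()) == {3}

    def test_flake_is_planar(self):
        st = build_graphene_flake([(0, 0), (1, 0), (0, 1)]).structure
        assert np.max(np.abs(st.coords[:, 2])) < 1e-6

    def test_disconnected_layout_rejected(self):
        with pytest.raises(PoreError, match="disconnected"):
            build_graphene_flake([(0, 0), (3, 3)])

    def test_bond_length_outside_sane_range_rejected(self):
        with pytest.raises(PoreError):
            LatticeSpec(cc_bond=4.0)


class TestCutPore:
    def test_one_ring_hole_atom_bookkeeping(self):
        flake = build_graphene_flake(CORONENE_RINGS)
        pore = cut_pore(flake, [(0, 0)])
        # all 6 ring carbons deleted, 6 new rim hydrogens added
        assert Counter(pore.structure.elements) == {"C": 18, "H": 18}
        rim_els = Counter(pore.structure.elements[i]
                          for i in pore.rim_indices)
        assert rim_els == {"C": 6, "H": 6}

    def test_no_removal_flags_non_porous(self):
        flake = build_graphene_flake(CORONENE_RINGS)
        pore = cut_pore(flake, [])
        assert not pore.porous
        assert pore.structure.elements == flake.structure.elements
        assert np.allclose(pore.structure.coords, flake.structure.coords)

    def test_cut_is_deterministic_and_idempotent(self):
        flake = build_graphene_flake(CORONENE_RINGS)
        a = cut_pore(flake, [(0, 0)])
        b = cut_pore(flake, [(0, 0)])
        assert a.structure.elements == b.structure.elements
        assert np.array_equal(a.structure.coords, b.structure.coords)
        assert a.rim_indices == b.rim_indices

    def test_removal_that_splits_flake_rejected(self):
        rings = [(0, 0), (1, 0), (2, 0)]
        flake = build_graphene_flake(rings)
        with pytest.raises(PoreError, match="disconnect"):
            cut_pore(flake, [(1, 0)])

    def test_detect_rim_errors_on_pristine_flake(self):
        flake = build_graphene_flake(CORONENE_RINGS)
        pristine = cut_pore(flake, [])
        with pytest.raises(PoreError, match="no hole"):
            detect_rim(pristine)


class TestGraphdiyne:
    def test_threefold_symmetry(self, graphdiyne):
        st = graphdiyne.structure
        th = 2 * np.pi / 3
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        rot = st.coords @ R.T
        # re-match rotated atoms to nearest original of the same element
        for i, e in enumerate(st.elements):
            d = np.linalg.norm(st.coords - rot[i], axis=1)
            d[[j for j, ej in enumerate(st.elements) if ej != e]] = np.inf
            assert d.min() < 1e-6

    def test_sp_carbons_have_two_neighbors(self, graphdiyne):
        st = graphdiyne.structure
        counts = carbon_neighbor_counts(st)
        assert sorted(set(counts.values())) == [2, 3]
        assert sum(1 for v in counts.values() if v == 2) == 12  # 3 chains x 4

    def test_rim_includes_all_sp_carbons(self, graphdiyne):
        st = graphdiyne.structure
        counts = carbon_neighbor_counts(st)
        sp = {i for i, v in counts.items() if v == 2}
        assert sp <= set(graphdiyne.rim_indices)

    def test_planar(self, graphdiyne):
        assert np.max(np.abs(graphdiyne.structure.coords[:, 2])) < 1e-6


class TestDiameter:
    @staticmethod
    def ring_of_atoms(element, radius, n=6):
        ang = 2 * np.pi * np.arange(n) / n
        coords = np.stack([radius * np.cos(ang), radius * np.sin(ang),
                           np.zeros(n)], axis=1)
        st = Structure([element] * n, coords)
        return PoreModel(st, np.zeros(3), [0, 0, 1.0], list(range(n)))

    def test_geometric_convention_on_atom_ring(self):
        pore = self.ring_of_atoms("C", 3.0)
        assert pore_diameter(pore, "geometric") == pytest.approx(6.0,
                                                                 abs=1e-6)

    def test_vdw_convention_subtracts_hydrogen_radii(self):
        pore = self.ring_of_atoms("H", 3.0)
        assert pore_diameter(pore, "vdw") == pytest.approx(6.0 - 2 * 1.20,
                                                           abs=1e-6)

    def test_unknown_convention_rejected(self, graphene3):
        with pytest.raises(PoreError, match="convention"):
            pore_diameter(graphene3, "magic")

    def test_invariant_under_rigid_transform(self, graphene3):
        d0 = pore_diameter(graphene3, "geometric")
        tf = RigidTransform.from_rotvec([0.4, -0.2, 0.9], [3.0, -1.0, 2.0])
        moved = PoreModel(apply_transform(graphene3.structure, tf),
                          tf.apply(graphene3.center[None])[0],
                          tf.rotation @ graphene3.normal,
                          list(graphene3.rim_indices))
        assert pore_diameter(moved, "geometric") == pytest.approx(d0,
                                                                  abs=1e-6)

    def test_moving_rim_atom_inward_never_enlarges(self):
        pore = self.ring_of_atoms("C", 3.0)
        d0 = pore_diameter(pore, "geometric")
        coords = pore.structure.coords.copy()
        coords[0] *= 0.8  # pull one rim atom toward the center
        shrunk = PoreModel(pore.structure.with_coords(coords), np.zeros(3),
                           [0, 0, 1.0], list(range(6)))
        assert pore_diameter(shrunk, "geometric") <= d0 + 1e-9


class TestPresets:
    @pytest.mark.parametrize("name,expected", [
        ("graphene4", 6.0), ("graphene3", 5.6), ("graphdiyne", 5.6)])
    def test_calibrated_diameters(self, name, expected):
        pore = build_preset(name)
        assert pore.convention == "geometric"
        assert pore.diameter == pytest.approx(expected, abs=0.1)

    def test_unknown_preset_rejected(self):
        with pytest.raises(PoreError, match="unknown preset"):
            build_preset("graphene99")

    def test_gatekeeper_preset_attaches_aminoethanol(self):
        plain = build_preset("graphene5")
        gk = build_preset("graphene5-gatekeeper")
        # one rim H replaced by the 11-atom gatekeeper fragment
        assert gk.structure.n_atoms == plain.structure.n_atoms - 1 + 11
        assert "N" in gk.structure.elements and "O" in gk.structure.elements


class TestNitrogenSubstitution:
    def test_two_site_substitution_bookkeeping(self):
        plain = build_preset("graphene5")
        sub = build_preset("graphene5", nsub="opposite")
        c0 = Counter(plain.structure.elements)
        c1 = Counter(sub.structure.elements)
        assert sub.structure.n_atoms == plain.structure.n_atoms - 2
        assert c1["C"] == c0["C"] - 2
        assert c1["H"] == c0["H"] - 2
        assert c1["N"] == c0["N"] + 2

    def test_substitution_enlarges_geometric_opening(self):
        plain = build_preset("graphene5")
        sub = build_preset("graphene5", nsub="opposite")
        assert sub.diameter > plain.diameter

    def test_empty_index_list_is_identity(self, graphene3):
        assert substitute_nitrogen(graphene3, []) is graphene3

    def test_non_rim_carbon_rejected(self, graphene3):
        non_rim = next(i for i in range(graphene3.structure.n_atoms)
                       if i not in graphene3.rim_indices
                       and graphene3.structure.elements[i] == "C")
        with pytest.raises(PoreError, match="rim carbon"):
            substitute_nitrogen(graphene3, [non_rim])


def test_sidecar_round_trip(tmp_path, graphene3):
    path = tmp_path / "pore.xyz"
    write_pore(graphene3, path)
    back = read_pore(path)
    assert back.preset == graphene3.preset
    assert back.rim_indices == graphene3.rim_indices
    assert back.diameter == pytest.approx(graphene3.diameter, abs=1e-6)
    assert np.allclose(back.center, graphene3.center, atol=1e-8)
    assert np.allclose(back.structure.coords, graphene3.structure.coords,
                       atol=1e-6)


def test_ring_neighbors_of_single_ring():
    assert len(ring_neighbors([(0, 0)])) == 6
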