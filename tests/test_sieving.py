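"""Scans, splines, pathway extrema, NEB and the Boltzmann estimators."""

import math

import numpy as np
import pytest

from chirasieve.energetics import (KB_KCAL_PER_MOL_K, LJCoulombEngine,
                                   NonbondedParams, interaction_energy)
from chirasieve.molsys import RigidTransform, Structure, center_of_mass
from chirasieve.porelib import PoreModel
from chirasieve.sieving import (EnergyProfile, PathwayExtrema, ScanProtocol,
                                classify_extrema, double_well_2d,
                                find_extrema, interpolate_profile, neb,
                                neb_path, permeance_indicator, rigid_scan,
                                selectivity_estimate)
from oracles import grid_extrema_1d, minimax_barrier_2d


class TestScanProtocol:
    def test_grid_covers_range_with_step(self):
        g = ScanProtocol(step=0.25, z_range=(-8.0, 8.0)).grid()
        assert len(g) == 65
        assert g[0] == -8.0 and g[-1] == 8.0
        assert np.allclose(np.diff(g), 0.25)

    def test_validation(self):
        with pytest.raises(ValueError):
            ScanProtocol(step=-0.1)
        with pytest.raises(ValueError):
            ScanProtocol(z_range=(3.0, -3.0))


class TestInterpolation:
    def test_cubic_polynomial_reproduced_exactly(self):
        z = np.arange(-4.0, 4.01, 0.5)
        f = lambda x: 0.3 * x ** 3 - x ** 2 + 2 * x - 1
        spl = interpolate_profile(z, f(z))
        mid = z[:-1] + 0.25
        assert np.allclose(spl(mid), f(mid), atol=1e-9)

    def test_interpolation_condition(self):
        z = np.arange(-2.0, 2.01, 0.25)
        e = np.sin(z)
        spl = interpolate_profile(z, e)
        assert np.allclose(spl(z), e, atol=1e-10)

    def test_quarter_angstrom_grid_resolves_sine(self):
        z = np.arange(-5.0, 5.01, 0.25)
        spl = interpolate_profile(z, np.sin(z))
        dense = np.linspace(-5.0, 5.0, 4001)
        assert np.max(np.abs(spl(dense) - np.sin(dense))) < 1e-3

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 4"):
            interpolate_profile([0, 1, 2], [0, 1, 2])
        with pytest.raises(ValueError, match="increasing"):
            interpolate_profile([0, 1, 1, 2], [0, 1, 2, 3])


def profile_from(f, z):
    z = np.asarray(z, float)
    e = np.array([f(x) for x in z])
    return EnergyProfile(z, e, interpolate_profile(z, e),
                         np.zeros(len(z), bool))


class TestFindExtrema:
    def test_symmetric_double_well_closed_form(self):
        # E(z) = (z^2-4)^2/16 - 1: minima at z=±2 (E=-1), maximum at 0 (E=0)
        f = lambda z: (z * z - 4.0) ** 2 / 16.0 - 1.0
        prof = profile_from(f, np.arange(-4.0, 4.01, 0.25))
        schema = find_extrema(prof)
        (zl, el), (zt, et), (zr, er) = (schema.left_minimum, schema.ts1,
                                        schema.right_minimum)
        assert zl == pytest.approx(-2.0, abs=1e-3)
        assert zr == pytest.approx(2.0, abs=1e-3)
        assert zt == pytest.approx(0.0, abs=1e-3)
        assert el == pytest.approx(-1.0, abs=1e-3)
        assert er == pytest.approx(-1.0, abs=1e-3)
        assert et == pytest.approx(0.0, abs=1e-3)
        assert schema.rate_determining == schema.ts1

    def test_monotone_profile_has_no_extrema(self):
        prof = profile_from(lambda z: 0.5 * z, np.arange(-4, 4.01, 0.25))
        schema = find_extrema(prof)
        assert prof.extrema == []
        assert all(v is None for v in schema.slots().values())
        assert schema.rate_determining is None

    def test_five_slot_pathway_matches_dense_grid_oracle(self):
        # asymmetric double-well / double-barrier profile: three
        # adsorption wells of different depth separated by two barriers
        def f(z):
            return (-3.0 * math.exp(-((z + 3.0) ** 2) / 2.0)
                    - 1.0 * math.exp(-(z ** 2) / 2.0)
                    - 2.5 * math.exp(-((z - 3.0) ** 2) / 2.0))
        prof = profile_from(f, np.arange(-8.0, 8.01, 0.25))
        schema = find_extrema(prof)
        slots = schema.slots()
        assert all(v is not None for v in slots.values())
        # alternating min/max in z-order
        zs = [slots[k][0] for k in ("left_minimum", "ts1", "intermediate",
                                    "ts2", "right_minimum")]
        assert zs == sorted(zs)
        oracle = grid_extrema_1d(np.vectorize(f), -8.0, 8.0)
        omin = [x for x in oracle if x[2] == "minimum"]
        omax = [x for x in oracle if x[2] == "maximum"]
        assert slots["left_minimum"][0] == pytest.approx(omin[0][0],
                                                         abs=1e-2)
        assert slots["intermediate"][0] == pytest.approx(omin[1][0],
                                                         abs=1e-2)
        assert slots["right_minimum"][0] == pytest.approx(omin[2][0],
                                                          abs=1e-2)
        # rate-determining = argmax over maxima on the dense grid
        o_rd = max(omax, key=lambda t: t[1])
        assert schema.rate_determining[0] == pytest.approx(o_rd[0], abs=1e-2)
        assert schema.rate_determining[1] == pytest.approx(o_rd[1], abs=1e-3)

    def test_classification_orders_table_rows(self):
        ext = [(-3.0, -21.0, "minimum"), (-1.5, -8.3, "maximum"),
               (0.0, -10.9, "minimum"), (1.5, -10.4, "maximum"),
               (3.0, -18.0, "minimum")]
        schema = classify_extrema(ext)
        assert schema.left_minimum == (-3.0, -21.0)
        assert schema.ts1 == (-1.5, -8.3)
        assert schema.intermediate == (0.0, -10.9)
        assert schema.ts2 == (1.5, -10.4)
        assert schema.right_minimum == (3.0, -18.0)
        assert schema.rate_determining == (-1.5, -8.3)


class TestRigidScan:
    def test_each_sample_matches_independent_energy_evaluation(
            self, graphene3, co2, engine):
        proto = ScanProtocol(z_range=(-4.0, 4.0))
        prof = rigid_scan(graphene3, co2, proto, engine)
        com = center_of_mass(co2)
        for i in range(0, len(prof.z_values), 7):
            z = prof.z_values[i]
            target = graphene3.center + z * graphene3.normal
            moved = co2.with_coords(co2.coords - com + target)
            e = interaction_energy(graphene3.structure, moved, engine.params)
            assert prof.energies[i] == pytest.approx(e, abs=1e-9)

    def test_non_interacting_pore_gives_flat_zero_profile(self, co2):
        # a 'ghost' pore: parameters with zero well depth and zero charge
        ghost = NonbondedParams({"C": (0.0, 3.4, 0.0), "O": (0.0, 3.0, 0.0),
                                 "G": (0.0, 3.0, 0.0)}, cutoff=12.0)
        ring = Structure(["C"] * 6,
                         [[3 * np.cos(a), 3 * np.sin(a), 0.0]
                          for a in np.linspace(0, 2 * np.pi, 6,
                                               endpoint=False)],
                         charges=np.zeros(6), atom_types=["G"] * 6)
        pore = PoreModel(ring, np.zeros(3), [0, 0, 1.0], list(range(6)))
        prof = rigid_scan(pore, co2, ScanProtocol(),
                          LJCoulombEngine(ghost))
        assert np.allclose(prof.energies, 0.0, atol=1e-12)

    def test_symmetric_probe_symmetric_profile(self, graphene4, co2, engine):
        prof = rigid_scan(graphene4, co2, ScanProtocol(), engine)
        assert np.allclose(prof.energies, prof.energies[::-1], atol=1e-8)

    def test_tetrahedral_probe_asymmetric_with_tip_side_minimum(
            self, graphene4, ch4, engine):
        prof = rigid_scan(graphene4, ch4, ScanProtocol(), engine)
        assert not np.allclose(prof.energies, prof.energies[::-1],
                               atol=1e-8)
        z_min = prof.z_values[int(np.argmin(prof.energies))]
        assert z_min < 0.0  # tip (pointing +z) reaches the pore first

    def test_zero_reference_exact_beyond_cutoff_plus_extents(
            self, graphene3, co2, engine):
        from chirasieve.molsys import max_extent
        far = engine.params.cutoff + max_extent(graphene3.structure) \
            + max_extent(co2)
        proto = ScanProtocol(step=1.0, z_range=(-far - 3.0, far + 3.0))
        prof = rigid_scan(graphene3, co2, proto, engine)
        outside = np.abs(prof.z_values) >= far
        assert outside.any()
        assert np.all(prof.energies[outside] == 0.0)

    def test_overlap_region_capped_and_flagged(self, graphene3, engine):
        fat = Structure(["Br"] * 2, [[-3.0, 0, 0], [3.0, 0, 0]],
                        charges=[0.0, 0.0])
        prof = rigid_scan(graphene3, fat, ScanProtocol(), engine)
        assert prof.capped.any() or prof.energies.max() <= 1e4
        assert np.all(prof.energies <= 1e4)


class TestNEB:
    def test_identical_endpoints_collapse(self):
        res = neb(double_well_2d, [1.0, 0.5], [1.0, 0.5], n_images=7)
        assert res.converged
        assert res.saddle_energy == pytest.approx(0.0, abs=1e-10)

    def test_double_well_saddle_matches_minimax_oracle(self):
        oracle = minimax_barrier_2d(double_well_2d, (-1.0, -0.5),
                                    (1.0, 0.5))
        res = neb(double_well_2d, [-1.0, -0.5], [1.0, 0.5], n_images=13,
                  climbing=True, fmax=1e-4, max_iterations=3000)
        assert res.converged
        assert res.saddle_energy == pytest.approx(oracle, abs=1e-2)
        assert res.saddle_energy == pytest.approx(1.0, abs=1e-2)

    def test_plain_band_saddle_close_to_climbing(self):
        res = neb(double_well_2d, [-1.0, -0.5], [1.0, 0.5], n_images=13,
                  climbing=False, fmax=1e-4, max_iterations=3000)
        assert res.saddle_energy == pytest.approx(1.0, abs=1e-2)

    def test_band_maximum_not_below_endpoints(self):
        res = neb(double_well_2d, [-1.0, -0.5], [0.2, 0.1], n_images=9,
                  fmax=1e-3, max_iterations=1500)
        ends = max(double_well_2d([-1.0, -0.5]), double_well_2d([0.2, 0.1]))
        assert res.energies.max() >= ends - 1e-9

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError):
            neb(double_well_2d, [-1, -0.5], [1, 0.5], n_images=2)

    def test_pose_neb_saddle_below_constrained_scan_maximum(
            self, graphene4, co2, engine):
        # the unconstrained 6-DOF path can only lower the barrier found
        # by the fixed-orientation axial scan
        prof = rigid_scan(graphene4, co2, ScanProtocol(), engine)
        schema = find_extrema(prof)
        zl, zr = schema.left_minimum[0], schema.right_minimum[0]
        p0 = np.concatenate([np.zeros(3),
                             graphene4.center + zl * graphene4.normal])
        p1 = np.concatenate([np.zeros(3),
                             graphene4.center + zr * graphene4.normal])
        res = neb_path(graphene4, co2, p0, p1, engine, n_images=9,
                       climbing=True, fmax=1e-3, max_iterations=800)
        assert res.saddle_energy <= schema.rate_determining[1] + 1e-6


class TestBoltzmannEstimates:
    def mk(self, barrier, z=0.0):
        return PathwayExtrema(left_minimum=(z - 2.0, barrier - 5.0),
                              ts1=(z, barrier),
                              rate_determining=(z, barrier))

    def test_equal_barriers_give_unit_ratio(self):
        est = selectivity_estimate(self.mk(3.0), self.mk(3.0))
        assert est.ratio == pytest.approx(1.0, abs=1e-12)

    def test_ten_fold_disfavoring_closed_form(self):
        est = selectivity_estimate(self.mk(4.3645), self.mk(3.0),
                                   temperature=298.15)
        expected = math.exp(-1.3645 / (KB_KCAL_PER_MOL_K * 298.15))
        assert est.ddE == pytest.approx(1.3645, abs=1e-12)
        assert est.ratio == pytest.approx(expected, abs=1e-12)
        assert est.ratio == pytest.approx(0.1, abs=1e-3)

    def test_infinite_temperature_limit(self):
        est = selectivity_estimate(self.mk(10.0), self.mk(2.0),
                                   temperature=1e9)
        assert est.ratio == pytest.approx(1.0, abs=1e-5)

    def test_barrier_from_preceding_minimum_reported(self):
        est = selectivity_estimate(self.mk(4.0), self.mk(1.0))
        assert est.barrier_A_from_minimum == pytest.approx(5.0)
        assert est.barrier_B_from_minimum == pytest.approx(5.0)

    def test_permeance_closed_forms(self):
        assert permeance_indicator(self.mk(0.0)) == pytest.approx(1.0)
        ind = permeance_indicator(self.mk(5.925), temperature=298.15)
        assert ind == pytest.approx(
            math.exp(-5.925 / (KB_KCAL_PER_MOL_K * 298.15)), abs=1e-12)
        assert ind == pytest.approx(math.exp(-10.0), rel=1e-3)

    def test_permeance_ratio_consistent_with_selectivity(self):
        a, b = self.mk(4.0), self.mk(2.5)
        est = selectivity_estimate(a, b)
        ratio = permeance_indicator(a) / permeance_indicator(b)
        assert ratio == pytest.approx(est.ratio, rel=1e-12)

    def test_missing_barrier_rejected(self):
        empty = PathwayExtrema()
        with pytest.raises(ValueError, match="rate-determining"):
            permeance_indicator(empty)
        with pytest.raises(ValueError, match="rate-determining"):
            selectivity_estimate(empty, self.mk(1.0))
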