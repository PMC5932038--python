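"""Generator physics: equipartition, mobility, restraints, determinism."""

import math

import numpy as np
import pytest

import permeon as pm
from permeon.units import (FIELD_FORCE_KJ_PER_MOL_NM_PER_E_V_NM,
                           thermal_energy)

KT = thermal_energy(300.0)


class TestPotential1D:
    def test_force_is_negative_gradient(self):
        for pot, grid in [
            (pm.Potential1D.sine_squared(10.0, 5.0), np.linspace(0, 5, 101)),
            (pm.Potential1D.cosine_double_well(10.0, 5.1),
             np.linspace(0, 5.1, 101)),
            (pm.Potential1D.harmonic(500.0), np.linspace(-1, 1, 101)),
            (pm.Potential1D.gaussian_well(8.0, 2.0, 0.4, 8.0),
             np.linspace(0, 8, 101)),
        ]:
            pot.validate(grid)

    def test_inconsistent_force_rejected(self):
        bad = pm.Potential1D(energy=lambda z: 0.5 * z**2,
                             force=lambda z: -2.0 * z)
        with pytest.raises(ValueError, match="negative gradient"):
            bad.validate(np.linspace(-1, 1, 11))

    def test_default_force_from_numerical_gradient(self):
        pot = pm.Potential1D(energy=lambda z: 3.0 * np.asarray(z) ** 2)
        grid = np.linspace(-2, 2, 41)
        assert np.allclose(pot.force(grid), -6.0 * grid, atol=1e-5)


class TestLangevin:
    def test_no_noise_no_force_is_static(self):
        # D -> 0 limit approximated by vanishing diffusion
        params = pm.SimulationParams(1e-12, 1e-3, 500, seed=0)
        z = pm.simulate_langevin_1d(pm.Potential1D.flat(), params, start=1.3)
        assert len(z) == 500
        assert np.allclose(z, 1.3, atol=1e-4)

    @pytest.mark.parametrize("k", [100.0, 500.0, 1000.0])
    def test_equipartition_in_harmonic_bias(self, k):
        """Sample variance in a harmonic bias equals kT/k (equipartition)."""
        D = 0.1
        dt = 0.02 / ((1.0 / KT) * D * k)      # drift fraction 2% per step
        params = pm.SimulationParams(D, dt, 400_000, seed=12)
        z = pm.simulate_langevin_1d(pm.Potential1D.flat(), params,
                                    bias=(0.0, k))
        assert z.var() == pytest.approx(KT / k, rel=0.05)

    def test_drift_velocity_matches_mobility(self):
        """Mean drift in a constant field is beta*D*q*E (Einstein relation)."""
        L, D, E = 10.0, 1.0, 0.1
        params = pm.SimulationParams(D, 1e-4, 1_000_000, seed=3,
                                     box_length=L, field=E, charge=1.0)
        z = pm.simulate_langevin_1d(pm.Potential1D.flat(L), params)
        dz = np.diff(np.concatenate([[0.0], z]))
        dz -= L * np.round(dz / L)
        v = dz.sum() / (params.n_steps * params.time_step)
        v_expected = (1 / KT) * D * 1.0 * E * FIELD_FORCE_KJ_PER_MOL_NM_PER_E_V_NM
        assert v == pytest.approx(v_expected, rel=0.05)

    def test_msd_recovers_diffusion_coefficient(self):
        D = 0.8
        params = pm.SimulationParams(D, 1e-3, 200_000, seed=4)
        z = pm.simulate_langevin_1d(pm.Potential1D.flat(), params)
        lag = 1000
        msd = np.mean((z[lag:] - z[:-lag]) ** 2)
        assert msd / (2 * lag * params.time_step) == pytest.approx(D, rel=0.05)

    def test_identical_seeds_identical_trajectories(self):
        pot = pm.Potential1D.sine_squared(5.0, 4.0)
        mk = lambda: pm.simulate_langevin_1d(
            pot, pm.SimulationParams(1.0, 5e-4, 2000, seed=7, box_length=4.0))
        a, b = mk(), mk()
        np.testing.assert_array_equal(a, b)

    def test_divergent_step_aborts(self):
        pot = pm.Potential1D.harmonic(1e7)
        params = pm.SimulationParams(1.0, 1e-3, 100, seed=0, box_length=2.0)
        with pytest.raises(pm.TimestepError), pytest.warns(RuntimeWarning):
            pm.simulate_langevin_1d(pot, params, start=1.5)

    def test_coarse_time_step_warns(self):
        pot = pm.Potential1D.harmonic(500.0, center=1.0)
        params = pm.SimulationParams(1.0, 5e-3, 10, seed=0)
        with pytest.warns(RuntimeWarning, match="time step"):
            pm.simulate_langevin_1d(pot, params, start=3.0)


class TestStepRestraint:
    def test_force_profile(self):
        r = pm.StepRestraint(boundary_position=0.0, transition_half_width=0.1,
                             force_magnitude=10_000.0)
        z = np.array([-0.5, -0.05, 0.05, 0.5])
        f = r.force(z, box_length=10.0)
        # zero outside the transition region, repulsive inside
        np.testing.assert_allclose(f, [0.0, -10_000.0, 10_000.0, 0.0])
        # periodic image of the boundary acts near z = L
        assert r.force(np.array([9.95]), box_length=10.0)[0] == -10_000.0

    def test_no_boundary_crossings_in_a_million_steps(self):
        """10000 kJ/mol/nm over 0.1 nm is a ~1000 kJ/mol wall: at 300 K a
        restrained ion never escapes its compartment."""
        L = 10.0
        restraint = pm.StepRestraint(boundary_position=0.0)
        params = pm.SimulationParams(0.5, 1e-5, 1_000_000, seed=9,
                                     box_length=L)
        z = pm.simulate_langevin_1d(pm.Potential1D.flat(L), params,
                                    restraint=restraint, start=5.0)
        dz = np.diff(np.concatenate([[5.0], z]))
        dz -= L * np.round(dz / L)
        crossings = np.abs(np.diff(np.floor(
            np.cumsum(np.concatenate([[5.0], dz])) / L))).sum()
        assert crossings == 0


class TestUmbrellaDataset:
    def test_window_layout_matches_pore_scale(self):
        """209 windows at 0.07 nm spacing tile a 14.626 nm periodic box."""
        L = 14.626
        pot = pm.Potential1D.flat(L)
        params = pm.SimulationParams(1.0, 1e-3, 60, seed=0, box_length=L)
        wins = pm.generate_umbrella_dataset(pot, 209, 0.07, 500.0, params)
        assert len(wins) == 209
        span = 209 * 0.07
        assert span == pytest.approx(L, abs=0.07)
        centers = sorted(w.center for w in wins)
        assert centers[0] == pytest.approx(0.0)
        assert max(centers) < L

    def test_windows_exceeding_period_rejected(self):
        pot = pm.Potential1D.flat(5.0)
        params = pm.SimulationParams(1.0, 1e-3, 60, seed=0, box_length=5.0)
        with pytest.raises(ValueError, match="exceed"):
            pm.generate_umbrella_dataset(pot, 100, 0.1, 500.0, params)

    def test_equilibration_discard_flagged(self, small_windows):
        w = small_windows[0]
        assert w.discard_fraction == pytest.approx(1 / 6)
        assert w.n_retained == len(w.samples) - len(w.samples) // 6

    def test_perp_samples_have_requested_spread(self):
        pot = pm.Potential1D.flat(5.0)
        params = pm.SimulationParams(1.0, 5e-4, 20_000, seed=11,
                                     box_length=5.0)
        wins = pm.generate_umbrella_dataset(pot, 5, 1.0, 100.0, params,
                                            perp_spread=(1.5, 0.5))
        pooled = np.vstack([w.perp_samples for w in wins])
        assert pooled[:, 0].std() == pytest.approx(1.5, rel=0.05)
        assert pooled[:, 1].std() == pytest.approx(0.5, rel=0.05)


class TestPermeationEnsemble:
    def test_degenerate_mixture_all_axial(self, channel_geometry):
        params = pm.SimulationParams(1.0, 0.01, 200, seed=1, charge=1.0)
        trajs = pm.generate_permeation_ensemble(
            channel_geometry, params, (1.0, 0.0, 0.0), n_ions=25)
        assert all(t.meta["true_pathway"] == "A" for t in trajs)

    def test_empty_ensemble(self, channel_geometry):
        params = pm.SimulationParams(1.0, 0.01, 200, seed=1, charge=1.0)
        assert pm.generate_permeation_ensemble(
            channel_geometry, params, (0.5, 0.3, 0.1), n_ions=0) == []

    def test_label_counts_within_binomial_intervals(self, channel_geometry):
        """Realised counts of the requested (0.53, 0.25, 0.17) mixture stay
        inside exact binomial 99% intervals."""
        from scipy.stats import binom

        n = 400
        params = pm.SimulationParams(1.0, 0.01, 400, seed=5, charge=1.0)
        trajs = pm.generate_permeation_ensemble(
            channel_geometry, params, (0.53, 0.25, 0.17), n_ions=n)
        counts = {}
        for t in trajs:
            lab = t.meta["true_pathway"]
            counts[lab] = counts.get(lab, 0) + 1
        for lab, p in zip("ABC", (0.53, 0.25, 0.17)):
            lo, hi = binom.ppf([0.005, 0.995], n, p)
            assert lo <= counts[lab] <= hi

    def test_fraction_validation(self, channel_geometry):
        params = pm.SimulationParams(1.0, 0.01, 200, seed=1, charge=1.0)
        with pytest.raises(ValueError, match="sum"):
            pm.generate_permeation_ensemble(channel_geometry, params,
                                            (0.8, 0.3, 0.2), n_ions=5)

    def test_geometry_invariants(self):
        with pytest.raises(ValueError, match="landmarks"):
            pm.ChannelGeometry(z_lumen=1.0, z_basin2=0.0, z_top=3.0)
        with pytest.raises(ValueError, match="radii"):
            pm.ChannelGeometry(r_cleft=3.0, r_lateral=1.0)


class TestSolventCloud:
    def test_zero_density_empty(self):
        assert pm.generate_solvent_cloud(0.0, (5, 5, 5), seed=1).size == 0

    def test_poisson_count_at_bulk_density(self):
        """Bulk-water density in a 10^3 nm^3 box: N ~ Poisson(33400)."""
        pts = pm.generate_solvent_cloud(33.4, (10, 10, 10), seed=2)
        mean = 33.4 * 1000
        assert abs(len(pts) - mean) <= 3 * math.sqrt(mean)
        assert pts.min() >= 0 and (pts.max(axis=0) <= [10, 10, 10]).all()

    def test_fixed_seed_bit_identical(self):
        a = pm.generate_solvent_cloud(5.0, (4, 4, 4), seed=42)
        b = pm.generate_solvent_cloud(5.0, (4, 4, 4), seed=42)
        np.testing.assert_array_equal(a, b)
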