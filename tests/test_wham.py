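"""WHAM solver: ground-truth recovery, gauge symmetry, bootstrap errors."""

import numpy as np
import pytest

import permeon as pm
from permeon.units import thermal_energy

from conftest import wham_reference_solution

KT = thermal_energy(300.0)


def _flat_window(n=5000, L=5.0, seed=0, k=1e-9):
    """Single near-unbiased window with uniform samples on [0, L)."""
    rng = np.random.default_rng(seed)
    return pm.UmbrellaWindow(center=L / 2, spring_constant=k,
                             samples=rng.uniform(0, L, n),
                             discard_fraction=0.0)


class TestSolveWham:
    def test_single_unbiased_window_gives_flat_profile(self):
        """k -> 0 limit reduces WHAM to Boltzmann inversion of a flat
        histogram; W is flat at the sampling-noise scale."""
        n, n_bins = 40_000, 40
        prof = pm.solve_wham([_flat_window(n=n)], n_bins=n_bins,
                             periodic_length=5.0)
        noise_scale = KT * np.sqrt(n_bins / n)
        assert np.std(prof.values) <= 3 * noise_scale

    def test_duplicate_window_equals_doubled_samples(self):
        """Two identical windows are the same evidence as one window with
        twice the samples (WHAM weight symmetry)."""
        rng = np.random.default_rng(8)
        samples = 2.0 + 0.12 * rng.standard_normal(4000)
        w1 = pm.UmbrellaWindow(2.0, 200.0, samples, discard_fraction=0.0)
        w2 = pm.UmbrellaWindow(2.0, 200.0, samples, discard_fraction=0.0)
        double = pm.UmbrellaWindow(2.0, 200.0, np.concatenate([samples] * 2),
                                   discard_fraction=0.0)
        kw = dict(n_bins=60, bin_range=(1.0, 3.0), tol=1e-10)
        a = pm.solve_wham([w1, w2], **kw)
        b = pm.solve_wham([double], **kw)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_recovers_double_well_ground_truth(self, double_well_potential,
                                               double_well_pmf):
        u = double_well_potential.energy(double_well_pmf.bin_centers)
        d = double_well_pmf.values - u
        d -= d.mean()
        assert np.abs(d).max() <= 1.0

    def test_probability_conservation(self, small_windows):
        """Recomputed bin probabilities sum to 1 at convergence."""
        prof = pm.solve_wham(small_windows, n_bins=80, periodic_length=5.0)
        assert np.isfinite(prof.values).all()
        assert prof.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert prof.final_residual < 1e-6
        assert prof.n_iterations >= 1

    def test_gauge_invariance_against_spring_scaled_windows(self,
                                                            small_windows):
        """Shifting every window's bias by a constant cannot change W; the
        bias enters only through differences, so re-solving after relabeling
        centers by a full period gives the same profile."""
        L = 5.0
        shifted = [pm.UmbrellaWindow(w.center + L, w.spring_constant,
                                     w.samples, w.perp_samples,
                                     w.discard_fraction)
                   for w in small_windows]
        a = pm.solve_wham(small_windows, n_bins=80, periodic_length=L)
        b = pm.solve_wham(shifted, n_bins=80, periodic_length=L)
        np.testing.assert_allclose(a.values, b.values, atol=1e-6)

    def test_cyclic_profile_joins_at_the_seam(self, double_well_pmf):
        w = double_well_pmf.values
        neighbour_fluct = np.abs(np.diff(w)).max()
        assert abs(w[0] - w[-1]) <= max(3 * neighbour_fluct, 0.5)

    def test_non_overlapping_windows_error(self):
        rng = np.random.default_rng(0)
        w1 = pm.UmbrellaWindow(1.0, 500.0,
                               1.0 + 0.05 * rng.standard_normal(500),
                               discard_fraction=0.0)
        w2 = pm.UmbrellaWindow(4.0, 500.0,
                               4.0 + 0.05 * rng.standard_normal(500),
                               discard_fraction=0.0)
        with pytest.raises(pm.OverlapError, match="share no occupied bin"):
            pm.solve_wham([w1, w2], n_bins=100, bin_range=(0.5, 4.5))

    def test_max_iter_exhaustion_reports_residual(self, small_windows):
        with pytest.raises(pm.ConvergenceError, match="residual"):
            pm.solve_wham(small_windows, n_bins=80, periodic_length=5.0,
                          tol=1e-13, max_iter=5)

    def test_agrees_with_independent_reference_implementation(self):
        """Fixed-point WHAM matches direct likelihood minimisation to
        within 0.1 kJ/mol on seeded synthetic datasets."""
        L = 5.0
        pot = pm.Potential1D.sine_squared(6.0, L)
        for seed in (1, 2, 3):
            params = pm.SimulationParams(1.0, 5e-4, 12_000, seed=seed,
                                         box_length=L)
            wins = pm.generate_umbrella_dataset(pot, 25, 0.2, 100.0, params,
                                                perp_spread=(1.0, 1.0))
            prof = pm.solve_wham(wins, n_bins=80, periodic_length=L)
            _, w_ref = wham_reference_solution(wins, 80, L)
            d = prof.values - w_ref
            d -= np.nanmean(d)
            assert np.nanmax(np.abs(d)) <= 0.1

    def test_discarded_samples_never_enter_histograms(self):
        """A wild equilibration transient must leave W untouched."""
        rng = np.random.default_rng(5)
        good = 2.0 + 0.1 * rng.standard_normal(6000)
        burn = np.full(1200, 40.0)          # far outside the binned range
        w_clean = pm.UmbrellaWindow(2.0, 300.0, good, discard_fraction=0.0)
        w_burn = pm.UmbrellaWindow(2.0, 300.0, np.concatenate([burn, good]),
                                   discard_fraction=1200 / 7200)
        kw = dict(n_bins=50, bin_range=(1.5, 2.5))
        np.testing.assert_allclose(pm.solve_wham([w_clean], **kw).values,
                                   pm.solve_wham([w_burn], **kw).values,
                                   atol=1e-12)


class TestBootstrap:
    def test_degenerate_constant_windows_zero_error(self):
        wins = [pm.UmbrellaWindow(2.0, 500.0, np.full(100, 2.0),
                                  discard_fraction=0.0)
                for _ in range(4)]
        err = pm.bootstrap_pmf(wins, n_boot=20, seed=0, n_bins=10,
                               bin_range=(1.5, 2.5))
        occupied = np.isfinite(err)
        assert np.all(err[occupied] == 0.0)

    def test_fixed_seed_identical_errors(self, small_windows):
        kw = dict(n_bins=60, periodic_length=5.0)
        a = pm.bootstrap_pmf(small_windows, n_boot=20, seed=17, **kw)
        b = pm.bootstrap_pmf(small_windows, n_boot=20, seed=17, **kw)
        np.testing.assert_array_equal(a, b)

    def test_error_scales_with_sample_size(self):
        """Halving per-window samples inflates the mean bootstrap error by
        about sqrt(2) (standard-error scaling), averaged over repeats."""
        L = 5.0
        pot = pm.Potential1D.sine_squared(4.0, L)
        ratios = []
        for rep in range(10):
            params_full = pm.SimulationParams(1.0, 5e-4, 12_000,
                                              seed=300 + rep, box_length=L)
            wins_full = pm.generate_umbrella_dataset(
                pot, 25, 0.2, 100.0, params_full, perp_spread=(1, 1))
            wins_half = [pm.UmbrellaWindow(w.center, w.spring_constant,
                                           w.samples[::2],
                                           discard_fraction=w.discard_fraction)
                         for w in wins_full]
            kw = dict(n_bins=50, periodic_length=L)
            e_full = pm.bootstrap_pmf(wins_full, n_boot=40,
                                      seed=400 + rep, **kw)
            e_half = pm.bootstrap_pmf(wins_half, n_boot=40,
                                      seed=500 + rep, **kw)
            ratios.append(np.nanmean(e_half) / np.nanmean(e_full))
        assert np.mean(ratios) == pytest.approx(np.sqrt(2), rel=0.25)

    def test_n_boot_validation(self, small_windows):
        with pytest.raises(ValueError, match="n_boot"):
            pm.bootstrap_pmf(small_windows, n_boot=1)


class TestPmfExtremum:
    def _profile(self, values, bulk=(4.0, 5.0)):
        z = np.linspace(0.05, 4.95, len(values))
        vals = np.asarray(values, dtype=float)
        m = (z >= bulk[0]) & (z <= bulk[1])
        vals = vals - vals[m].mean()
        return pm.PMFProfile(z, vals, np.zeros_like(vals),
                             reference="bulk_zero", bulk_interval=bulk)

    def test_flat_profile_zero_barrier(self):
        prof = self._profile(np.zeros(50))
        ext = pm.pmf_extremum(prof)
        assert ext.kind == "barrier"
        assert ext.value == 0.0

    def test_deep_well_sign_convention(self):
        """A single -30.9 kJ/mol bin reports a well of -30.9 (negative)."""
        vals = np.zeros(50)
        vals[20] = -30.9
        ext = pm.pmf_extremum(self._profile(vals, bulk=(4.0, 4.95)))
        assert ext.kind == "well"
        assert ext.value == pytest.approx(-30.9, abs=1e-9)

    def test_pure_barrier_positive(self):
        """A repulsive (anion-style) profile reports +25.9 with the barrier
        flag — no negative well exists."""
        vals = np.zeros(50)
        vals[10:15] = 25.9
        ext = pm.pmf_extremum(self._profile(vals, bulk=(4.0, 4.95)))
        assert ext.kind == "barrier"
        assert ext.value == pytest.approx(25.9, abs=1e-9)

    def test_tie_broken_toward_smallest_abs_z(self):
        z = np.linspace(-2, 2, 41)
        vals = np.zeros(41)
        vals[5] = vals[30] = -4.0           # z = -1.5 and z = +1.0
        prof = pm.PMFProfile(z, vals - vals[[0, -1]].mean(),
                             np.zeros(41), reference="bulk_zero",
                             bulk_interval=(1.8, 2.0))
        ext = pm.pmf_extremum(prof)
        assert ext.position == pytest.approx(1.0)

    def test_requires_bulk_reference(self, small_windows):
        prof = pm.solve_wham(small_windows, n_bins=40, periodic_length=5.0)
        with pytest.raises(ValueError, match="bulk_zero"):
            pm.pmf_extremum(prof)
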