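"""Shared fixtures: small synthetic datasets and an independent WHAM oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

import permeon as pm
from permeon.units import thermal_energy


def wham_reference_solution(windows, n_bins, periodic_length,
                            temperature=300.0):
    """Independent WHAM route: direct convex minimisation of the binned
    log-likelihood (BFGS on the window free energies), not the package's
    fixed-point iteration.  Returns (bin_centers, W)."""
    L = periodic_length
    kT = thermal_energy(temperature)
    beta = 1.0 / kT
    edges = np.linspace(0, L, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_ib = np.array([
        np.histogram(np.mod(w.retained_samples, L), bins=edges)[0]
        for w in windows], dtype=float)
    N = n_ib.sum(axis=1)
    M = n_ib.sum(axis=0)
    c = np.array([w.center for w in windows])
    k = np.array([w.spring_constant for w in windows])
    d = centers[None, :] - c[:, None]
    d -= L * np.round(d / L)
    w_ib = 0.5 * k[:, None] * d * d
    lnN = np.log(N)
    occ = M > 0

    def fun(g):
        a = lnN[:, None] + g[:, None] - beta * w_ib
        ls = logsumexp(a, axis=0)
        return float(np.sum(M[occ] * ls[occ]) - np.sum(N * g))

    def grad(g):
        a = lnN[:, None] + g[:, None] - beta * w_ib
        ls = logsumexp(a, axis=0)
        r = np.exp(a - ls[None, :])
        return (r[:, occ] * M[occ]).sum(axis=1) - N

    res = minimize(fun, np.zeros(len(windows)), jac=grad, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 5000})
    g = res.x
    a = lnN[:, None] + g[:, None] - beta * w_ib
    denom = np.exp(logsumexp(a, axis=0))
    p = np.where(occ, M / denom, np.nan)
    p = p / np.nansum(p)
    return centers, -kT * np.log(p)


# ---------------------------------------------------------------------------
# canonical study conditions (shared between unit and acceptance tests)
# ---------------------------------------------------------------------------

DOUBLE_WELL = dict(barrier=10.0, periodic_length=5.1, n_windows=51,
                   spacing=0.1, spring_constant=500.0,
                   diffusion=0.5, time_step=5e-4, n_steps=57_600, n_bins=200)

FLAT_NULL = dict(periodic_length=5.1, n_windows=51, spacing=0.1,
                 spring_constant=100.0, diffusion=1.0, time_step=2.5e-4,
                 n_steps=172_800, n_bins=150)


def make_umbrella_dataset(potential, cfg, seed):
    params = pm.SimulationParams(
        diffusion_coefficient=cfg["diffusion"], time_step=cfg["time_step"],
        n_steps=cfg["n_steps"], seed=seed,
        box_length=cfg["periodic_length"])
    return pm.generate_umbrella_dataset(
        potential, cfg["n_windows"], cfg["spacing"], cfg["spring_constant"],
        params, perp_spread=(1.0, 1.0))


@pytest.fixture(scope="session")
def double_well_potential():
    return pm.Potential1D.cosine_double_well(
        DOUBLE_WELL["barrier"], DOUBLE_WELL["periodic_length"])


@pytest.fixture(scope="session")
def double_well_windows(double_well_potential):
    """51 umbrella windows (k = 500 kJ/mol/nm^2) on the periodic
    double-well: 48000 retained samples per window after the 1/6 discard."""
    return make_umbrella_dataset(double_well_potential, DOUBLE_WELL, seed=1)


@pytest.fixture(scope="session")
def double_well_pmf(double_well_windows):
    return pm.solve_wham(double_well_windows, n_bins=DOUBLE_WELL["n_bins"],
                         periodic_length=DOUBLE_WELL["periodic_length"])


@pytest.fixture(scope="session")
def small_windows():
    """Light sine-squared dataset for fast solver behaviour tests."""
    pot = pm.Potential1D.sine_squared(6.0, 5.0)
    params = pm.SimulationParams(1.0, 5e-4, 12_000, seed=3, box_length=5.0)
    return pm.generate_umbrella_dataset(pot, 25, 0.2, 100.0, params,
                                        perp_spread=(1.0, 1.0))


@pytest.fixture(scope="session")
def channel_geometry():
    return pm.ChannelGeometry()
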