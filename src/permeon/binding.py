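"""Standard binding free energy from a 1-D PMF.

Implements the no-orthogonal-restraint correction for converting a
bulk-referenced 1-D PMF W(z) into a standard (1 mol/L) free energy of
binding:

    dG0 = -kT ln( C0 * A * Int_bound exp(-beta W(z)) dz )

where C0 is one molecule per 1.6606 nm^3 and A is the effectively sampled
area perpendicular to the reaction coordinate, estimated from the in-plane
positions sampled in the bulk-phase windows:

    A = 2 pi xi1 xi2,

with xi1^2, xi2^2 the eigenvalues of the 2x2 covariance matrix of those
positions.  Using eigenvalues rather than marginal variances makes the area
invariant under rotation of the in-plane axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import STANDARD_VOLUME_NM3, thermal_energy
from .wham import PMFProfile

__all__ = [
    "BindingConfig",
    "BindingResult",
    "effective_area",
    "standard_binding_free_energy",
    "AREA_PRESETS_NM2",
    "DEFAULT_BOUND_INTERVAL_NM",
]

#: Axial interval of the bound state used for the RyR1 pore, nm.
DEFAULT_BOUND_INTERVAL_NM: tuple[float, float] = (-6.0, 7.5)

#: Effectively sampled areas per ion species, nm^2 (documented presets; the
#: analysis recomputes A from data whenever bulk-window samples are given).
AREA_PRESETS_NM2: dict[str, float] = {
    "Ba2+": 3.09,
    "Ca2+": 3.04,
    "Mg2+": 5.15,
    "K+": 9.09,
    "Na+": 3.30,
}


@dataclass(frozen=True)
class BindingConfig:
    """Definition of the bound state and the thermodynamic reference."""

    bound_interval: tuple[float, float] = DEFAULT_BOUND_INTERVAL_NM
    standard_volume: float = STANDARD_VOLUME_NM3     # nm^3 per molecule
    temperature: float = 300.0                       # K

    def __post_init__(self):
        lo, hi = self.bound_interval
        if not lo < hi:
            raise ValueError("bound_interval lower bound must be below upper")
        if self.standard_volume <= 0:
            raise ValueError("standard_volume must be positive")


@dataclass(frozen=True)
class BindingResult:
    """dG0 together with every ingredient that produced it."""

    delta_g0: float                       # kJ/mol
    delta_g0_error: float                 # kJ/mol (0 if PMF had no errors)
    effective_area: float                 # nm^2
    eigenvalues: tuple[float, float]      # nm^2 (xi1^2, xi2^2)
    boltzmann_integral: float             # nm
    bound_interval: tuple[float, float]   # nm

    def __post_init__(self):
        e1, e2 = self.eigenvalues
        if not np.isnan(e1):
            expected = 2.0 * math.pi * math.sqrt(e1 * e2)
            if abs(self.effective_area - expected) > 1e-12 * max(1.0, expected):
                raise ValueError("effective_area inconsistent with eigenvalues")
        if not self.boltzmann_integral > 0:
            raise ValueError("boltzmann_integral must be positive")


def effective_area(perp_samples: np.ndarray) -> tuple[float, float, float]:
    """Effectively sampled in-plane area A = 2 pi xi1 xi2.

    Parameters
    ----------
    perp_samples : (N, 2) in-plane positions pooled over all bulk-phase
        windows, nm.

    Returns
    -------
    (A, xi1_sq, xi2_sq) : area in nm^2 and the covariance eigenvalues in
        nm^2, largest first.
    """
    x = np.asarray(perp_samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("perp_samples must have shape (N, 2)")
    if x.shape[0] < 10:
        raise ValueError("need at least 10 pooled in-plane samples")
    cov = np.cov(x, rowvar=False)
    return area_from_covariance(cov)


def area_from_covariance(cov: np.ndarray) -> tuple[float, float, float]:
    """Area from an explicit 2x2 in-plane covariance matrix (nm^2)."""
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("covariance must be 2x2")
    e2, e1 = np.linalg.eigvalsh(cov)          # ascending
    if e2 <= 1e-15 * max(e1, 1.0):
        raise ValueError("degenerate in-plane covariance (zero eigenvalue)")
    area = 2.0 * math.pi * math.sqrt(e1 * e2)
    return float(area), float(e1), float(e2)


def standard_binding_free_energy(
    pmf: PMFProfile,
    config: BindingConfig = BindingConfig(),
    area: float | None = None,
    perp_samples: np.ndarray | None = None,
    n_error_resamples: int = 200,
    seed: int | None = None,
) -> BindingResult:
    """Standard free energy of binding from a bulk-referenced PMF.

    Exactly one of ``area`` (nm^2, e.g. a species preset) or
    ``perp_samples`` (bulk-window in-plane positions, pooled) must be given.
    The Boltzmann integral runs over ``config.bound_interval`` using
    trapezoidal quadrature on the PMF grid, with the interval endpoints
    included by linear interpolation.

    When the PMF carries bootstrap errors, dG0's error is propagated by
    resampling W per-bin from independent Gaussians and taking the standard
    deviation of the recomputed dG0 over ``n_error_resamples`` draws.
    """
    if (area is None) == (perp_samples is None):
        raise ValueError("give exactly one of area= or perp_samples=")
    if pmf.reference != "bulk_zero":
        raise ValueError(
            "PMF must be bulk_zero-referenced (the unbound state defines "
            "the zero of W); call profile.with_reference('bulk_zero', ...)"
        )
    if perp_samples is not None:
        area, e1, e2 = effective_area(perp_samples)
    else:
        if area <= 0:
            raise ValueError("area must be positive")
        e1 = e2 = float("nan")

    lo, hi = config.bound_interval
    z, w = pmf.bin_centers, pmf.values
    zmin, zmax = float(z[0]), float(z[-1])
    if pmf.periodic_length is not None:
        # a cyclic profile supports any interval no longer than a period
        if hi - lo > pmf.periodic_length + 1e-9:
            raise ValueError("bound interval longer than the PMF period")
        span = np.arange(math.floor((lo - zmin) / pmf.periodic_length),
                         math.ceil((hi - zmin) / pmf.periodic_length) + 1)
        z = np.concatenate([z + s * pmf.periodic_length for s in span])
        order = np.argsort(z)
        z = z[order]
        w = np.tile(w, len(span))[order]
    elif lo < zmin - 1e-9 or hi > zmax + 1e-9:
        raise ValueError(
            f"bound interval ({lo}, {hi}) exceeds the PMF support "
            f"({zmin:.3f}, {zmax:.3f})"
        )

    kT = thermal_energy(config.temperature)

    def integral(values: np.ndarray) -> float:
        zz, ww = _clip_to_interval(z, values, lo, hi)
        return float(np.trapezoid(np.exp(-ww / kT), zz))

    I = integral(w)
    c0 = 1.0 / config.standard_volume
    dg0 = -kT * math.log(c0 * area * I)

    dg0_err = 0.0
    if np.any(pmf.errors > 0):
        rng = np.random.default_rng(seed)
        errs = pmf.errors
        if pmf.periodic_length is not None:
            errs = np.tile(errs, len(span))[order]
        draws = np.empty(n_error_resamples)
        for r in range(n_error_resamples):
            w_r = w + rng.standard_normal(len(w)) * errs
            draws[r] = -kT * math.log(c0 * area * integral(w_r))
        dg0_err = float(np.std(draws, ddof=1))

    return BindingResult(
        delta_g0=dg0,
        delta_g0_error=dg0_err,
        effective_area=float(area),
        eigenvalues=(e1, e2),
        boltzmann_integral=I,
        bound_interval=(lo, hi),
    )


def _clip_to_interval(z: np.ndarray, w: np.ndarray,
                      lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Grid restricted to [lo, hi] with interpolated endpoint values."""
    if not np.all(np.isfinite(w)):
        m = np.isfinite(w)
        z, w = z[m], w[m]
    inside = (z > lo) & (z < hi)
    zz = np.concatenate([[lo], z[inside], [hi]])
    ww = np.interp(zz, z, w)
    return zz, ww
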