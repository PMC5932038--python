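"""Weighted histogram analysis method (WHAM) for 1-D umbrella sampling.

Reconstructs the potential of mean force W(z) from harmonically biased
umbrella windows by the standard self-consistent iteration

    p(b)      = sum_i n_i(b) / sum_i N_i exp(beta (f_i - w_i(b)))
    exp(-beta f_i) = sum_b p(b) exp(-beta w_i(b))

with bias w_i(b) = k_i/2 * d(z_b, z_i)^2, where d is the minimum-image
distance for cyclic profiles (periodic simulation box) and the plain
difference otherwise.  Convergence is monitored on the maximum change of
the window free energies kT ln f_i between iterations.  Error bars come
from a window-level bootstrap: windows are resampled with replacement and
the per-bin standard deviation over re-solved profiles is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .units import thermal_energy

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "PMFExtremum",
    "WhamError",
    "ConvergenceError",
    "OverlapError",
    "solve_wham",
    "bootstrap_pmf",
    "pmf_extremum",
]


class WhamError(RuntimeError):
    pass


class ConvergenceError(WhamError):
    """The self-consistent iteration did not reach the tolerance."""


class OverlapError(WhamError):
    """Neighbouring window histograms share no occupied bin."""


@dataclass
class UmbrellaWindow:
    """One biased sampling record.

    Attributes
    ----------
    center : bias center z_i in nm
    spring_constant : harmonic spring k in kJ/mol/nm^2 (axial direction)
    samples : time series of the axial reaction coordinate, nm
    perp_samples : optional (N, 2) in-plane positions, nm (for the
        effective-area estimate of the binding correction)
    discard_fraction : leading fraction of the series treated as
        equilibration and excluded from every histogram
    """

    center: float
    spring_constant: float
    samples: np.ndarray
    perp_samples: np.ndarray | None = None
    discard_fraction: float = 1.0 / 6.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        if not 0 <= self.discard_fraction < 1:
            raise ValueError("discard_fraction must be in [0, 1)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.perp_samples is not None:
            self.perp_samples = np.asarray(self.perp_samples, dtype=float)
            if self.perp_samples.ndim != 2 or self.perp_samples.shape[1] != 2:
                raise ValueError("perp_samples must have shape (N, 2)")
        if self.n_retained < 10:
            raise ValueError(
                f"window at {self.center}: fewer than 10 samples retained "
                "after the equilibration discard"
            )

    @property
    def n_discard(self) -> int:
        return int(len(self.samples) * self.discard_fraction)

    @property
    def n_retained(self) -> int:
        return len(self.samples) - self.n_discard

    @property
    def retained_samples(self) -> np.ndarray:
        """Production part of the series (equilibration excluded)."""
        return self.samples[self.n_discard:]

    @property
    def retained_perp_samples(self) -> np.ndarray | None:
        if self.perp_samples is None:
            return None
        n = int(len(self.perp_samples) * self.discard_fraction)
        return self.perp_samples[n:]


Reference = Literal["min_zero", "bulk_zero"]


@dataclass
class PMFProfile:
    """Binned free-energy profile W(z) with errors and its zero convention.

    ``reference`` records how the arbitrary additive constant was fixed:
    ``"min_zero"`` (minimum at zero, for display) or ``"bulk_zero"`` with
    ``bulk_interval`` (mean of W over the declared unbound region at zero,
    required by the binding analysis).
    """

    bin_centers: np.ndarray
    values: np.ndarray
    errors: np.ndarray
    periodic_length: float | None = None
    reference: Reference = "min_zero"
    bulk_interval: tuple[float, float] | None = None
    n_iterations: int = 0
    final_residual: float = float("nan")
    probabilities: np.ndarray | None = None   # normalised p(b) at convergence

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if not (len(self.bin_centers) == len(self.values) == len(self.errors)):
            raise ValueError("bin_centers, values and errors must align")
        if self.reference == "bulk_zero":
            if self.bulk_interval is None:
                raise ValueError("bulk_zero reference needs bulk_interval")
            m = self._bulk_mask()
            if not m.any():
                raise ValueError("no bins inside the bulk interval")
            if abs(float(np.mean(self.values[m]))) > 1e-9:
                raise ValueError("bulk_zero profile has nonzero bulk mean")

    def _bulk_mask(self) -> np.ndarray:
        lo, hi = self.bulk_interval
        return (self.bin_centers >= lo) & (self.bin_centers <= hi)

    def with_reference(self, reference: Reference,
                       bulk_interval: tuple[float, float] | None = None
                       ) -> "PMFProfile":
        """Copy of the profile shifted to a different zero convention."""
        w = self.values.copy()
        if reference == "min_zero":
            w -= np.nanmin(w)
            return replace(self, values=w, reference="min_zero",
                           bulk_interval=None)
        if reference == "bulk_zero":
            if bulk_interval is None:
                raise ValueError("bulk_zero requires a bulk interval")
            lo, hi = bulk_interval
            m = (self.bin_centers >= lo) & (self.bin_centers <= hi)
            if not m.any():
                raise ValueError(
                    f"no bins fall inside the bulk interval ({lo}, {hi})")
            w -= float(np.nanmean(w[m]))
            return replace(self, values=w, reference="bulk_zero",
                           bulk_interval=(lo, hi))
        raise ValueError(f"unknown reference convention {reference!r}")


@dataclass(frozen=True)
class PMFExtremum:
    """Signed extremal free energy: deepest well (<0) or highest barrier (>0)."""

    position: float          # nm
    value: float             # kJ/mol, signed
    kind: Literal["well", "barrier"]


# ---------------------------------------------------------------------------
# core solver
# ---------------------------------------------------------------------------

def _bias_matrix(centers: np.ndarray, springs: np.ndarray,
                 bin_centers: np.ndarray,
                 periodic_length: float | None) -> np.ndarray:
    """w[i, b] = k_i/2 * d(z_b, z_i)^2 with minimum-image d when cyclic."""
    d = bin_centers[None, :] - centers[:, None]
    if periodic_length is not None:
        d = d - periodic_length * np.round(d / periodic_length)
    return 0.5 * springs[:, None] * d * d


def _histograms(windows: Sequence[UmbrellaWindow], edges: np.ndarray,
                periodic_length: float | None) -> np.ndarray:
    n_ib = np.empty((len(windows), len(edges) - 1))
    for i, w in enumerate(windows):
        s = w.retained_samples
        if periodic_length is not None:
            s = np.mod(s, periodic_length)
        n_ib[i], _ = np.histogram(s, bins=edges)
    return n_ib


def _check_overlap(windows: Sequence[UmbrellaWindow], n_ib: np.ndarray,
                   periodic_length: float | None) -> None:
    occupied = n_ib > 0
    order = np.argsort([w.center for w in windows])
    pairs = (list(zip(order, np.roll(order, -1))) if periodic_length
             else list(zip(order[:-1], order[1:])))
    if len(windows) < 2:
        return
    for a, b in pairs:
        if not np.any(occupied[a] & occupied[b]):
            raise OverlapError(
                f"windows at {windows[a].center:.4f} and "
                f"{windows[b].center:.4f} nm share no occupied bin — "
                "sampling gap between them"
            )


def solve_wham(
    windows: Sequence[UmbrellaWindow],
    n_bins: int = 200,
    temperature: float = 300.0,
    periodic_length: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    bin_range: tuple[float, float] | None = None,
    reference: Reference = "min_zero",
    bulk_interval: tuple[float, float] | None = None,
    window_multiplicity: np.ndarray | None = None,
) -> PMFProfile:
    """Self-consistent WHAM solve of the unbiased PMF.

    Parameters
    ----------
    windows : umbrella windows (equilibration-discarded samples are used)
    n_bins : number of reaction-coordinate bins
    periodic_length : period L in nm for a cyclic PMF, or ``None``
    tol : convergence threshold on max |Delta kT ln f_i|, kJ/mol
    reference, bulk_interval : zero convention of the returned profile
    window_multiplicity : optional integer weights per window (used by the
        window-level bootstrap; a multiplicity-m window counts as m copies)

    Raises
    ------
    OverlapError : neighbouring histograms share no occupied bin
    ConvergenceError : ``max_iter`` reached before ``tol``
    """
    if not windows:
        raise ValueError("no umbrella windows given")
    if tol <= 0:
        raise ValueError("tol must be positive")
    kT = thermal_energy(temperature)
    beta = 1.0 / kT

    centers = np.array([w.center for w in windows], dtype=float)
    springs = np.array([w.spring_constant for w in windows], dtype=float)

    if bin_range is not None:
        lo, hi = bin_range
    elif periodic_length is not None:
        lo, hi = 0.0, periodic_length
    else:
        lo = min(w.retained_samples.min() for w in windows)
        hi = max(w.retained_samples.max() for w in windows)
        pad = 1e-9 * max(1.0, abs(hi - lo))
        lo, hi = lo - pad, hi + pad
    edges = np.linspace(lo, hi, n_bins + 1)
    bin_centers = 0.5 * (edges[:-1] + edges[1:])

    n_ib = _histograms(windows, edges, periodic_length)
    _check_overlap(windows, n_ib, periodic_length)

    mult = (np.ones(len(windows)) if window_multiplicity is None
            else np.asarray(window_multiplicity, dtype=float))
    n_ib = n_ib * mult[:, None]
    N_i = n_ib.sum(axis=1)
    M_b = n_ib.sum(axis=0)

    w_ib = _bias_matrix(centers, springs, bin_centers, periodic_length)
    # exp(-beta w) underflows harmlessly to 0 for far-away bins
    with np.errstate(under="ignore"):
        B_ib = np.exp(-beta * np.minimum(w_ib, 700.0 / beta))

    g = np.zeros(len(windows))          # beta * f_i
    active = N_i > 0
    occ = M_b > 0
    residual = np.inf
    it = 0
    with np.errstate(divide="ignore", invalid="ignore", under="ignore"):
        for it in range(1, max_iter + 1):
            denom = (N_i * np.exp(g)) @ B_ib          # per-bin normaliser
            p = np.where(occ, M_b / np.where(denom > 0, denom, 1.0), 0.0)
            p /= p.sum()
            z_i = B_ib @ p
            g_new = np.where(active, -np.log(np.where(z_i > 0, z_i, 1.0)), 0.0)
            g_new -= g_new[active][0]                 # fix the gauge
            residual = kT * float(np.max(np.abs(g_new - g)))
            g = g_new
            if residual < tol:
                break
        else:
            raise ConvergenceError(
                f"WHAM did not converge in {max_iter} iterations "
                f"(residual {residual:.3g} kJ/mol > tol {tol:g})"
            )
        denom = (N_i * np.exp(g)) @ B_ib
        p = np.where(occ, M_b / np.where(denom > 0, denom, 1.0), 0.0)
        p /= p.sum()
        W = np.where(p > 0, -kT * np.log(np.where(p > 0, p, 1.0)), np.nan)

    prof = PMFProfile(
        bin_centers=bin_centers,
        values=W,
        errors=np.zeros_like(W),
        periodic_length=periodic_length,
        reference="min_zero",
        n_iterations=it,
        final_residual=residual,
        probabilities=p,
    )
    prof.values -= np.nanmin(prof.values)
    if reference == "bulk_zero":
        prof = prof.with_reference("bulk_zero", bulk_interval)
    return prof


# ---------------------------------------------------------------------------
# bootstrap errors
# ---------------------------------------------------------------------------

def bootstrap_pmf(
    windows: Sequence[UmbrellaWindow],
    n_boot: int = 200,
    seed: int | None = None,
    max_failure_fraction: float = 0.10,
    **solver_kwargs,
) -> np.ndarray:
    """Per-bin PMF error bars from a window-level bootstrap.

    Windows are resampled with replacement ``n_boot`` times and the PMF is
    re-solved for each replica; the per-bin standard deviation over replicas
    (after aligning every replica to the common reference) is returned.
    Complete windows are the resampling unit because within-window samples
    are autocorrelated.

    A replica whose solve fails to converge is retried once with a fresh
    resampling; persistent failures are counted and more than 10% of them
    abort the estimate.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    n_win = len(windows)
    solver_kwargs.setdefault("reference", "min_zero")

    replicas = []
    failures = 0
    for _ in range(n_boot):
        prof = None
        for _attempt in range(2):
            idx = rng.integers(0, n_win, size=n_win)
            mult = np.bincount(idx, minlength=n_win)
            try:
                prof = solve_wham(windows, window_multiplicity=mult,
                                  **solver_kwargs)
                break
            except WhamError:
                prof = None
        if prof is None:
            failures += 1
            continue
        replicas.append(_aligned_values(prof))
    if failures:
        warnings.warn(f"{failures}/{n_boot} bootstrap replicas failed",
                      RuntimeWarning, stacklevel=2)
    if failures > max_failure_fraction * n_boot:
        raise WhamError(
            f"bootstrap aborted: {failures}/{n_boot} replicas failed to solve")
    stack = np.vstack(replicas)
    with warnings.catch_warnings():
        # bins occupied in no replica legitimately yield NaN errors
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(stack, axis=0, ddof=1)


def _aligned_values(prof: PMFProfile) -> np.ndarray:
    """Replica profile aligned to its zero convention for sd pooling."""
    w = prof.values.copy()
    if prof.reference == "bulk_zero":
        return w                      # already aligned on the bulk mean
    # min_zero's minimum is noisy; align on the occupied-bin mean instead
    w -= np.nanmean(w)
    return w


# ---------------------------------------------------------------------------
# extremal free energy
# ---------------------------------------------------------------------------

def pmf_extremum(
    profile: PMFProfile,
    search_interval: tuple[float, float] | None = None,
) -> PMFExtremum:
    """Deepest well or, failing that, highest barrier of a bulk-zero PMF.

    Returns the most negative W (a binding well) when any bin dips below
    zero inside the interval, otherwise the most positive W (a repulsive
    barrier), with its location.  Exact value ties are broken toward the
    smallest |z|.
    """
    if profile.reference != "bulk_zero":
        raise ValueError("pmf_extremum requires a bulk_zero-referenced profile")
    z = profile.bin_centers
    w = profile.values
    if search_interval is not None:
        lo, hi = search_interval
        m = (z >= lo) & (z <= hi) & np.isfinite(w)
    else:
        m = np.isfinite(w)
    if not m.any():
        raise ValueError("search interval contains no finite PMF bins")
    z, w = z[m], w[m]
    if np.min(w) < 0:
        target, kind = np.min(w), "well"
    else:
        target, kind = np.max(w), "barrier"
    ties = np.isclose(w, target, rtol=0, atol=0)
    zt = z[ties]
    pos = zt[np.argmin(np.abs(zt))]
    return PMFExtremum(position=float(pos), value=float(target), kind=kind)
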