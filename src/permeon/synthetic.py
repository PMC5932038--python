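"""Synthetic Brownian-dynamics data with known ground truth.

Every input class that the analysis stages consume can be generated here
with a known answer attached: overdamped-Langevin (Brownian) trajectories in
prescribed 1-D potentials, umbrella-biased window samples, applied-field
permeation ensembles in a branching channel geometry with ground-truth exit
labels, and homogeneous solvent point clouds for hydration and pore-radius
tests.

The integrator is the Euler–Maruyama discretisation of the overdamped
Langevin equation

    z' = z + beta * D * F(z) * dt + sqrt(2 D dt) * eta,   eta ~ N(0, 1),

whose stationary distribution is the Boltzmann distribution exp(-beta U(z))
up to O(dt) discretisation bias.  Only the statistics of z(t) matter to the
downstream free-energy and crossing analyses, so this is the cheapest
generator with the correct equilibrium behaviour.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, FrozenSet, Sequence

import numpy as np

from .units import FIELD_FORCE_KJ_PER_MOL_NM_PER_E_V_NM, thermal_energy
from .wham import UmbrellaWindow
from .permeation import IonTrajectory

__all__ = [
    "generate_field_ensemble",
    "Potential1D",
    "SimulationParams",
    "StepRestraint",
    "ChannelGeometry",
    "TimestepError",
    "simulate_langevin_1d",
    "simulate_langevin_batch",
    "generate_umbrella_dataset",
    "generate_permeation_ensemble",
    "generate_solvent_cloud",
]

#: Simulated noise chunk size (steps) — bounds peak memory for long runs.
_NOISE_CHUNK = 65536

#: Drift length per step (nm) above which the time step is flagged.
_STEP_QUALITY_WARN_NM = 0.1


class TimestepError(RuntimeError):
    """A single integration step moved a particle more than half a box."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Potential1D:
    """A 1-D potential energy profile U(z) with its force F(z) = -dU/dz.

    Parameters
    ----------
    energy
        Vectorised callable, kJ/mol as a function of z in nm.
    force
        Vectorised callable, kJ/mol/nm.  If omitted, a central-difference
        numerical gradient of ``energy`` is used.
    periodic_length
        Period L in nm for cyclic potentials, or ``None``.
    """

    energy: Callable[[np.ndarray], np.ndarray]
    force: Callable[[np.ndarray], np.ndarray] | None = None
    periodic_length: float | None = None

    def __post_init__(self):
        if self.force is None:
            u = self.energy
            h = 1e-6

            def _force(z, _u=u, _h=h):
                z = np.asarray(z, dtype=float)
                return -(_u(z + _h) - _u(z - _h)) / (2.0 * _h)

            object.__setattr__(self, "force", _force)

    def validate(self, grid: np.ndarray, rtol: float = 1e-6) -> None:
        """Check F = -dU/dz on ``grid`` and periodicity if declared."""
        grid = np.asarray(grid, dtype=float)
        h = 1e-6
        f_num = -(self.energy(grid + h) - self.energy(grid - h)) / (2 * h)
        f = self.force(grid)
        scale = max(float(np.max(np.abs(f_num))), 1.0)
        if np.max(np.abs(f - f_num)) > rtol * scale:
            raise ValueError("force is not the negative gradient of energy")
        if self.periodic_length is not None:
            u0 = self.energy(grid)
            u1 = self.energy(grid + self.periodic_length)
            if np.max(np.abs(u1 - u0)) > 1e-9 * max(1.0, np.max(np.abs(u0))):
                raise ValueError("energy is not periodic with the declared period")

    # -- common analytic potentials used as ground truths -------------------

    @staticmethod
    def flat(periodic_length: float | None = None) -> "Potential1D":
        return Potential1D(
            energy=lambda z: np.zeros_like(np.asarray(z, dtype=float)),
            force=lambda z: np.zeros_like(np.asarray(z, dtype=float)),
            periodic_length=periodic_length,
        )

    @staticmethod
    def harmonic(k: float, center: float = 0.0) -> "Potential1D":
        return Potential1D(
            energy=lambda z: 0.5 * k * (np.asarray(z, dtype=float) - center) ** 2,
            force=lambda z: -k * (np.asarray(z, dtype=float) - center),
        )

    @staticmethod
    def sine_squared(barrier: float, periodic_length: float) -> "Potential1D":
        """U(z) = barrier * sin^2(pi z / L): one well, one barrier per period."""
        L = periodic_length
        w = math.pi / L
        return Potential1D(
            energy=lambda z: barrier * np.sin(w * np.asarray(z, dtype=float)) ** 2,
            force=lambda z: -barrier * w * np.sin(2 * w * np.asarray(z, dtype=float)),
            periodic_length=L,
        )

    @staticmethod
    def cosine_double_well(barrier: float, periodic_length: float) -> "Potential1D":
        """U(z) = (barrier/2) * (1 - cos(4 pi z / L)): two wells, barrier between."""
        L = periodic_length
        w = 4.0 * math.pi / L
        a = 0.5 * barrier
        return Potential1D(
            energy=lambda z: a * (1.0 - np.cos(w * np.asarray(z, dtype=float))),
            force=lambda z: -a * w * np.sin(w * np.asarray(z, dtype=float)),
            periodic_length=L,
        )

    @staticmethod
    def gaussian_well(depth: float, center: float, width: float,
                      periodic_length: float | None = None) -> "Potential1D":
        """U(z) = -depth * exp(-(z-c)^2 / (2 width^2)) (plus periodic images)."""

        def _images(z):
            z = np.asarray(z, dtype=float)
            d = z - center
            if periodic_length is not None:
                d = d - periodic_length * np.round(d / periodic_length)
            return d

        def energy(z):
            d = _images(z)
            return -depth * np.exp(-0.5 * (d / width) ** 2)

        def force(z):
            d = _images(z)
            return -depth * np.exp(-0.5 * (d / width) ** 2) * d / width**2

        return Potential1D(energy=energy, force=force,
                           periodic_length=periodic_length)


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one overdamped-Langevin run.

    ``field`` is the axial electric field in V/nm; the force it exerts on a
    charge of ``charge`` elementary charges is q * E * 96.485 kJ/mol/nm.
    """

    diffusion_coefficient: float          # nm^2/ns
    time_step: float                      # ns
    n_steps: int
    temperature: float = 300.0            # K
    seed: int | None = None
    box_length: float | None = None       # nm, axial box (periodic wrap)
    field: float = 0.0                    # V/nm
    charge: float = 0.0                   # e

    def __post_init__(self):
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature)

    def check_step_quality(self, f_max: float) -> float:
        """Drift length beta*F_max*D*dt in nm; warns when it is not small."""
        drift = (f_max / self.kT) * self.diffusion_coefficient * self.time_step
        if drift > _STEP_QUALITY_WARN_NM:
            warnings.warn(
                f"time step too coarse: drift per step {drift:.3g} nm at the "
                f"maximum force {f_max:.3g} kJ/mol/nm; reduce dt",
                RuntimeWarning,
                stacklevel=3,
            )
        return drift


@dataclass(frozen=True)
class StepRestraint:
    """Step-shaped compartment restraint around a periodic boundary.

    A constant repulsive force of ``force_magnitude`` acts on restrained
    species inside a narrow transition region of half-width
    ``transition_half_width`` around ``boundary_position``, always pointing
    away from the boundary into the ion's current compartment.  Outside the
    transition region the force is exactly zero, so the potential is a step
    of height force_magnitude * transition_half_width on either side.
    """

    boundary_position: float                     # nm
    transition_half_width: float = 0.1           # nm
    force_magnitude: float = 10000.0             # kJ/mol/nm
    restrained_species: FrozenSet[str] = frozenset({"cation"})

    def __post_init__(self):
        if self.transition_half_width <= 0:
            raise ValueError("transition_half_width must be positive")
        if self.force_magnitude < 0:
            raise ValueError("force_magnitude must be non-negative")

    def force(self, z: np.ndarray, box_length: float | None = None) -> np.ndarray:
        """Restraint force at positions ``z`` (minimum image if periodic)."""
        z = np.asarray(z, dtype=float)
        d = z - self.boundary_position
        if box_length is not None:
            d = d - box_length * np.round(d / box_length)
        inside = np.abs(d) < self.transition_half_width
        return np.where(inside, self.force_magnitude * np.sign(d), 0.0)


@dataclass(frozen=True)
class ChannelGeometry:
    """Stylised branching channel used for pathway-classification tests.

    The pore runs along z from the luminal vestibule (below ``z_lumen``)
    through the constriction up to the cytoplasmic exit plane ``z_top``.
    Between ``z_basin2`` (the level of the second free-energy basin) and
    ``z_top`` the central pore is flanked by ``n_clefts`` lateral clefts
    between protomers: an ion at radius r > ``r_cleft`` in that z band is in
    a cleft, and leaving past r > ``r_lateral`` is a lateral exit.
    """

    z_lumen: float = -3.0                 # nm
    z_basin2: float = 0.0                 # nm
    z_top: float = 3.0                    # nm
    r_cleft: float = 1.0                  # nm
    r_lateral: float = 3.0                # nm
    n_clefts: int = 4
    pore_radius_function: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if not (self.z_lumen < self.z_basin2 < self.z_top):
            raise ValueError("landmarks must satisfy z_lumen < z_basin2 < z_top")
        if not (0 < self.r_cleft < self.r_lateral):
            raise ValueError("radii must satisfy 0 < r_cleft < r_lateral")
        if self.pore_radius_function is None:
            rc = self.r_cleft

            def _wall(z, _rc=rc):
                return np.full_like(np.asarray(z, dtype=float), 2.0 * _rc)

            object.__setattr__(self, "pore_radius_function", _wall)
        zs = np.linspace(self.z_lumen - 2, self.z_top + 2, 64)
        if np.any(self.pore_radius_function(zs) <= 0):
            raise ValueError("pore wall radius must be positive everywhere")


# ---------------------------------------------------------------------------
# Brownian-dynamics integration
# ---------------------------------------------------------------------------

def simulate_langevin_batch(
    potential: Potential1D,
    params: SimulationParams,
    starts: np.ndarray,
    bias_centers: np.ndarray | None = None,
    bias_k: float = 0.0,
    restraint: StepRestraint | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Integrate many independent 1-D Brownian particles in lockstep.

    Returns an array of shape (n_steps, n_particles) holding the position
    after each step; the start positions are not included.  All particles
    share ``params``; harmonic biases differ only in their centers.
    """
    starts = np.atleast_1d(np.asarray(starts, dtype=float)).copy()
    n_part = starts.size
    if bias_centers is not None:
        bias_centers = np.asarray(bias_centers, dtype=float)
        if bias_centers.shape != starts.shape:
            raise ValueError("bias_centers must match starts in shape")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    L = params.box_length
    periodic = L is not None
    if periodic:
        starts %= L

    beta = 1.0 / params.kT
    D = params.diffusion_coefficient
    dt = params.time_step
    mob = beta * D * dt
    sigma = math.sqrt(2.0 * D * dt)
    f_field = params.charge * params.field * FIELD_FORCE_KJ_PER_MOL_NM_PER_E_V_NM

    # step-quality diagnostic on a probe of the force field
    probe = np.linspace(0.0, L, 256) if L else np.linspace(
        starts.min() - 5, starts.max() + 5, 256)
    f_probe = np.abs(potential.force(probe)) + abs(f_field)
    if bias_k > 0:
        f_probe = f_probe + bias_k * (3.0 * sigma + 0.5)
    params.check_step_quality(float(np.max(f_probe)))

    out = np.empty((params.n_steps, n_part), dtype=float)
    z = starts
    done = 0
    while done < params.n_steps:
        n = min(_NOISE_CHUNK, params.n_steps - done)
        noise = rng.standard_normal((n, n_part))
        for i in range(n):
            f = potential.force(z) + f_field
            if bias_k > 0.0 and bias_centers is not None:
                d = z - bias_centers
                if periodic:
                    d = d - L * np.round(d / L)
                f = f - bias_k * d
            if restraint is not None:
                f = f + restraint.force(z, L)
            dz = mob * f + sigma * noise[i]
            if L is not None and np.max(np.abs(dz)) > 0.5 * L:
                raise TimestepError(
                    f"step {done + i}: displacement {np.max(np.abs(dz)):.3g} nm "
                    f"exceeds half the box ({0.5 * L:.3g} nm); reduce time_step"
                )
            z = z + dz
            if L is not None:
                z %= L
            out[done + i] = z
        done += n
    return out


def simulate_langevin_1d(
    potential: Potential1D,
    params: SimulationParams,
    bias: tuple[float, float] | None = None,
    restraint: StepRestraint | None = None,
    start: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Single overdamped-Langevin trajectory of the axial coordinate z.

    Parameters
    ----------
    bias
        Optional harmonic umbrella bias ``(center, k)`` with k in
        kJ/mol/nm^2; the bias force uses the minimum-image displacement
        when the run is periodic.
    restraint
        Optional step-shaped compartment restraint.

    Returns
    -------
    ndarray of shape (n_steps,) — position in nm after each step.
    """
    centers = None
    k = 0.0
    if bias is not None:
        c, k = bias
        centers = np.array([c], dtype=float)
        if k < 0:
            raise ValueError("bias spring constant must be non-negative")
    traj = simulate_langevin_batch(
        potential, params, np.array([start], dtype=float),
        bias_centers=centers, bias_k=k, restraint=restraint, rng=rng,
    )
    return traj[:, 0]


# ---------------------------------------------------------------------------
# umbrella-sampling datasets
# ---------------------------------------------------------------------------

def generate_umbrella_dataset(
    potential: Potential1D,
    n_windows: int,
    spacing: float,
    k: float,
    params: SimulationParams,
    perp_spread: tuple[float, float] = (1.0, 1.0),
    discard_fraction: float = 1.0 / 6.0,
    origin: float = 0.0,
) -> list[UmbrellaWindow]:
    """Umbrella windows sampled from biased Brownian dynamics.

    One window is produced per bias center ``origin + i * spacing``
    (i = 0 .. n_windows-1), each holding ``params.n_steps`` samples of the
    biased axial coordinate plus independent in-plane Gaussian samples with
    standard deviations ``perp_spread`` (used by the effective-area
    estimate).  The first ``discard_fraction`` of each series is flagged as
    equilibration and excluded from all downstream histograms.
    """
    if n_windows <= 0:
        raise ValueError("n_windows must be positive")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    L = potential.periodic_length
    # the last center may wrap to within one spacing of the first
    if L is not None and n_windows * spacing > L + spacing * (1 - 1e-9):
        raise ValueError(
            f"{n_windows} windows at {spacing} nm spacing exceed the "
            f"periodic length {L} nm"
        )
    rng = np.random.default_rng(params.seed)
    centers = origin + spacing * np.arange(n_windows)
    run_params = replace(params, box_length=L) if L is not None else params
    series = simulate_langevin_batch(
        potential, run_params, starts=centers.copy(),
        bias_centers=centers, bias_k=k, rng=rng,
    )
    xi1, xi2 = perp_spread
    windows: list[UmbrellaWindow] = []
    for i, c in enumerate(centers):
        perp = rng.standard_normal((params.n_steps, 2)) * np.array([xi1, xi2])
        windows.append(UmbrellaWindow(
            center=float(c % L) if L is not None else float(c),
            spring_constant=k,
            samples=series[:, i].copy(),
            perp_samples=perp,
            discard_fraction=discard_fraction,
        ))
    _check_window_overlap(windows, L)
    return windows


def _check_window_overlap(windows: Sequence[UmbrellaWindow],
                          periodic_length: float | None) -> None:
    """Warn when neighbouring windows' sample ranges do not overlap."""
    order = np.argsort([w.center for w in windows])
    n = len(order)
    pairs = zip(order, np.roll(order, -1)) if periodic_length else zip(
        order[:-1], order[1:])
    for a, b in pairs:
        wa, wb = windows[a], windows[b]
        if periodic_length is not None:
            # on the circle: do the two reaches bridge the center gap?
            L = periodic_length
            rel_a = wa.retained_samples - wa.center
            rel_a -= L * np.round(rel_a / L)
            rel_b = wb.retained_samples - wb.center
            rel_b -= L * np.round(rel_b / L)
            gap = (wb.center - wa.center) % L
            overlap = rel_a.max() - rel_b.min() >= gap
        else:
            overlap = wa.retained_samples.max() >= wb.retained_samples.min()
        if not overlap:
            warnings.warn(
                f"umbrella windows at {wa.center:.3f} and {wb.center:.3f} nm "
                "have non-overlapping histograms; WHAM may fail",
                RuntimeWarning,
                stacklevel=3,
            )


# ---------------------------------------------------------------------------
# applied-field permeation ensembles
# ---------------------------------------------------------------------------

def _pathway_probabilities(
    base: tuple[float, float, float],
    geometry: ChannelGeometry,
    params: SimulationParams,
) -> np.ndarray:
    """Exit-mode probabilities, tilted toward the axial mode by the field.

    Modes that linger in or leave through the clefts forgo part of the axial
    potential drop q*E*(z_top - z_basin2); their zero-field weights are
    damped by the corresponding Boltzmann factor, so the axial fraction
    rises monotonically with the applied field.
    """
    pA, pB, pC = base
    pU = max(0.0, 1.0 - pA - pB - pC)
    drop = (params.charge * params.field
            * FIELD_FORCE_KJ_PER_MOL_NM_PER_E_V_NM
            * (geometry.z_top - geometry.z_basin2))
    beta = 1.0 / params.kT
    w = np.array([
        pA,
        pB * math.exp(-0.5 * beta * max(drop, 0.0)),
        pC * math.exp(-1.0 * beta * max(drop, 0.0)),
        pU * math.exp(-1.0 * beta * max(drop, 0.0)),
    ])
    return w / w.sum()


def _bounded_noise(rng, n, scale, lo, hi):
    return np.clip(rng.normal(0.0, scale, n), lo, hi)


def generate_permeation_ensemble(
    geometry: ChannelGeometry,
    params: SimulationParams,
    pathway_fractions: tuple[float, float, float] | None = (0.53, 0.25, 0.17),
    n_ions: int = 100,
    n_frames: int = 400,
) -> list[IonTrajectory]:
    """Pore-passing ion trajectories with ground-truth exit labels.

    Each ion starts below the luminal landmark, traverses the pore, and
    exits by an assigned mode: axially through the central pore (A), via a
    protomer cleft then axially (B), or laterally out of a cleft (C); the
    remaining probability mass produces ambiguous recrossing trajectories
    that end inside a cleft.  The assigned label is stored in
    ``traj.meta['true_pathway']``.

    When ``pathway_fractions`` is ``None`` the mode mixture is derived from
    the applied field via Boltzmann damping of the non-axial modes (axial
    fraction grows with field strength); the zero-field base mixture is
    (0.53, 0.25, 0.17).
    """
    if pathway_fractions is not None:
        if sum(pathway_fractions) > 1 + 1e-12:
            raise ValueError("pathway fractions must sum to at most 1")
        if min(pathway_fractions) < 0:
            raise ValueError("pathway fractions must be non-negative")
        pA, pB, pC = pathway_fractions
        probs = np.array([pA, pB, pC, max(0.0, 1 - pA - pB - pC)])
    else:
        probs = _pathway_probabilities((0.53, 0.25, 0.17), geometry, params)

    rng = np.random.default_rng(params.seed)
    g = geometry
    Lz = params.box_length if params.box_length else (g.z_top - g.z_lumen) * 3.0
    box = np.array([2.5 * g.r_lateral, 2.5 * g.r_lateral, Lz])
    band = g.z_top - g.z_basin2
    times = np.arange(1, n_frames + 1) * params.time_step

    trajs: list[IonTrajectory] = []
    for ion in range(n_ions):
        label = ("A", "B", "C", "unclassified")[rng.choice(4, p=probs)]
        z0 = g.z_lumen - 0.5 * band - rng.uniform(0, 0.5 * band)
        t = np.linspace(0.0, 1.0, n_frames)
        noise_z = _bounded_noise(rng, n_frames, 0.03 * band,
                                 -0.08 * band, 0.08 * band)
        r = np.empty(n_frames)
        cleft_mid = 0.5 * (g.r_cleft + g.r_lateral)

        if label == "A":
            z = z0 + (g.z_top + 0.8 * band - z0) * t + noise_z
            z[-1] = max(z[-1], g.z_top + 0.3 * band)
            r[:] = np.abs(_bounded_noise(rng, n_frames, 0.3 * g.r_cleft,
                                         -0.8 * g.r_cleft, 0.8 * g.r_cleft))
        elif label == "B":
            # rise to mid-band, dwell in a cleft, return, exit axially
            z_path = np.concatenate([
                np.linspace(z0, g.z_basin2 + 0.5 * band, n_frames // 2),
                np.full(n_frames // 4, g.z_basin2 + 0.5 * band),
                np.linspace(g.z_basin2 + 0.5 * band, g.z_top + 0.8 * band,
                            n_frames - n_frames // 2 - n_frames // 4),
            ])
            z = z_path + noise_z
            z[-1] = max(z[-1], g.z_top + 0.3 * band)
            r[:] = np.abs(_bounded_noise(rng, n_frames, 0.3 * g.r_cleft,
                                         -0.8 * g.r_cleft, 0.8 * g.r_cleft))
            lo, hi = n_frames // 2, n_frames // 2 + n_frames // 4
            r[lo:hi] = cleft_mid + _bounded_noise(
                rng, hi - lo, 0.1 * (g.r_lateral - g.r_cleft),
                g.r_cleft * 1.05 - cleft_mid, g.r_lateral * 0.95 - cleft_mid)
            # clamp z during the cleft dwell safely inside the band
            z[lo:hi] = np.clip(z[lo:hi], g.z_basin2 + 0.15 * band,
                               g.z_top - 0.15 * band)
        elif label == "C":
            half = n_frames // 2
            z_path = np.concatenate([
                np.linspace(z0, g.z_basin2 + 0.5 * band, half),
                np.full(n_frames - half, g.z_basin2 + 0.5 * band),
            ])
            z = z_path + noise_z
            z[half:] = np.clip(z[half:], g.z_basin2 + 0.15 * band,
                               g.z_top - 0.15 * band)
            r[:half] = np.abs(_bounded_noise(rng, half, 0.3 * g.r_cleft,
                                             -0.8 * g.r_cleft, 0.8 * g.r_cleft))
            r_exit = g.r_lateral + 0.5 * g.r_cleft + \
                (g.r_lateral - g.r_cleft) * t[: n_frames - half] * 2
            r[half:] = np.maximum.accumulate(
                np.linspace(r[half - 1], r_exit[-1], n_frames - half))
            r[-1] = max(r[-1], g.r_lateral * 1.1)
        else:  # ambiguous: recross the cleft boundary, end inside the cleft
            half = n_frames // 2
            z_path = np.concatenate([
                np.linspace(z0, g.z_basin2 + 0.5 * band, half),
                np.full(n_frames - half, g.z_basin2 + 0.5 * band),
            ])
            z = z_path + noise_z
            z[half:] = np.clip(z[half:], g.z_basin2 + 0.15 * band,
                               g.z_top - 0.15 * band)
            r[:half] = np.abs(_bounded_noise(rng, half, 0.3 * g.r_cleft,
                                             -0.8 * g.r_cleft, 0.8 * g.r_cleft))
            osc = 0.5 + 0.45 * np.sin(np.linspace(0, 6 * math.pi,
                                                  n_frames - half))
            r[half:] = g.r_cleft * (0.5 + osc)  # oscillates across r_cleft
            r[-1] = cleft_mid                    # ends inside the cleft
        # keep the pre-band approach strictly below the lumen at frame 0
        z[0] = min(z[0], g.z_lumen - 0.05 * band)

        theta = rng.uniform(0, 2 * math.pi) + _bounded_noise(
            rng, n_frames, 0.05, -0.15, 0.15).cumsum()
        pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        trajs.append(IonTrajectory(
            ion_id=ion,
            charge=params.charge if params.charge else 1.0,
            times=times.copy(),
            positions=pos,
            box=box.copy(),
            wrapped=False,
            meta={"true_pathway": label},
        ))
    return trajs


def generate_field_ensemble(
    potential: Potential1D,
    params: SimulationParams,
    n_ions: int,
    record_stride: int = 10,
) -> list[IonTrajectory]:
    """Independent ions drifting in an axial field under periodic boundaries.

    The synthetic stand-in for an applied-voltage permeation run: ``n_ions``
    non-interacting ions evolve in ``potential`` plus the constant field
    force q*E, wrapped into the axial box, and are recorded every
    ``record_stride`` steps as wrapped :class:`IonTrajectory` objects
    (x = y = 0; only the axial coordinate matters to crossing counts).
    """
    if params.box_length is None:
        raise ValueError("field ensembles require a periodic box_length")
    if n_ions <= 0:
        raise ValueError("n_ions must be positive")
    rng = np.random.default_rng(params.seed)
    L = params.box_length
    starts = rng.uniform(0.0, L, size=n_ions)
    series = simulate_langevin_batch(potential, params, starts, rng=rng)
    idx = np.arange(record_stride - 1, params.n_steps, record_stride)
    times = (idx + 1) * params.time_step
    box = np.array([L, L, L])
    out = []
    for i in range(n_ions):
        z = series[idx, i]
        pos = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        out.append(IonTrajectory(
            ion_id=i, charge=params.charge, times=times.copy(),
            positions=pos, box=box.copy(), wrapped=True,
            meta={"field_V_per_nm": params.field},
        ))
    return out


# ---------------------------------------------------------------------------
# solvent point clouds
# ---------------------------------------------------------------------------

def generate_solvent_cloud(
    density: float,
    box: tuple[float, float, float],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Homogeneous Poisson point cloud of solvent sites in a box.

    Parameters
    ----------
    density : number density in nm^-3 (bulk water oxygen: ~33.4 nm^-3)
    box : box edge lengths (Lx, Ly, Lz) in nm

    Returns
    -------
    (N, 3) array with N ~ Poisson(density * volume).
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    box = np.asarray(box, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = rng.poisson(density * float(np.prod(box)))
    return rng.uniform(0.0, 1.0, size=(n, 3)) * box
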