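"""Currents and conductance from periodic-boundary crossing counts.

Under an applied axial field, the ionic current is obtained by counting the
net number of ions that cross the periodic boundary parallel to the
membrane: each passage of an ion's unwrapped axial coordinate through a
periodic image of the boundary plane is one signed crossing event.  The
applied voltage is the product of field and axial box length, V = E * Lz.
Currents at several voltages are combined by a first-order polynomial fit
I = g V + I0 whose slope is the conductance in pS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .units import PICOAMP_PER_E_PER_NS

__all__ = [
    "IonTrajectory",
    "CrossingEvents",
    "Current",
    "IVPoint",
    "IVFit",
    "voltage_from_field",
    "field_from_voltage",
    "detect_crossings",
    "current_from_events",
    "ensemble_current",
    "fit_iv",
]


@dataclass
class IonTrajectory:
    """3-D position time series of one ion.

    ``wrapped`` declares whether positions were folded into the box (in
    which case the crossing detector unwraps z by minimum image) or are
    already continuous.
    """

    ion_id: int | str
    charge: float                    # elementary charges
    times: np.ndarray                # ns, strictly increasing
    positions: np.ndarray            # (N, 3) nm
    box: np.ndarray                  # (Lx, Ly, Lz) nm
    wrapped: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if self.wrapped:
            z = self.positions[:, 2]
            if z.min() < -1e-9 or z.max() > self.box[2] + 1e-9:
                raise ValueError("wrapped trajectory has z outside the box")

    @property
    def z(self) -> np.ndarray:
        return self.positions[:, 2]

    def unwrapped_z(self) -> np.ndarray:
        """Continuous axial coordinate (minimum-image unwrap if wrapped)."""
        z = self.z
        Lz = float(self.box[2])
        dz = np.diff(z)
        if self.wrapped:
            dz = dz - Lz * np.round(dz / Lz)
        elif np.any(np.abs(dz) >= 0.5 * Lz):
            raise ValueError(
                f"ion {self.ion_id}: frame-to-frame |dz| >= Lz/2 on an "
                "unwrapped trajectory — frame spacing too coarse to count "
                "crossings unambiguously"
            )
        return np.concatenate([[z[0]], z[0] + np.cumsum(dz)])


@dataclass(frozen=True)
class CrossingEvents:
    """Signed periodic-boundary crossing events of one ion."""

    times: np.ndarray            # ns, event times
    signs: np.ndarray            # +1 forward (increasing z), -1 backward
    charge: float                # e
    boundary_z: float            # nm

    @property
    def net(self) -> int:
        return int(self.signs.sum())

    @property
    def n_forward(self) -> int:
        return int(np.sum(self.signs > 0))

    @property
    def n_backward(self) -> int:
        return int(np.sum(self.signs < 0))


@dataclass(frozen=True)
class Current:
    value: float                 # pA
    error: float                 # pA (sqrt(Nf + Nb) counting estimate)
    net_crossings: float         # summed signed events weighted by charge
    window: tuple[float, float]  # ns


@dataclass(frozen=True)
class IVPoint:
    voltage: float               # V
    current: float               # pA
    current_error: float = 0.0   # pA
    analysis_window: tuple[float, float] | None = None

    def __post_init__(self):
        if self.analysis_window is not None:
            t0, t1 = self.analysis_window
            if not t1 > t0:
                raise ValueError("analysis window must have t_end > t_start")


@dataclass(frozen=True)
class IVFit:
    conductance: float           # pS
    conductance_error: float     # pS
    intercept: float             # pA
    r_squared: float
    n_points: int


def voltage_from_field(field_v_per_nm: float, box_length_z: float) -> float:
    """Transmembrane voltage V = E * Lz for a constant axial field."""
    if box_length_z <= 0:
        raise ValueError("box length must be positive")
    return field_v_per_nm * box_length_z


def field_from_voltage(voltage: float, box_length_z: float) -> float:
    """Inverse helper: field E = V / Lz in V/nm."""
    if box_length_z <= 0:
        raise ValueError("box length must be positive")
    return voltage / box_length_z


def detect_crossings(
    traj: IonTrajectory,
    boundary_z: float = 0.0,
    discard: float = 10.0,
) -> CrossingEvents:
    """Signed crossings of the periodic boundary plane by one ion.

    The axial coordinate is unwrapped by minimum image per frame pair; a
    crossing event is recorded whenever the unwrapped z passes any periodic
    image ``boundary_z + m * Lz``.  Events earlier than ``discard`` ns after
    the first frame are dropped (equilibration of the field response).
    """
    Lz = float(traj.box[2])
    zu = traj.unwrapped_z()
    k = np.floor((zu - boundary_z) / Lz)
    dk = np.diff(k).astype(int)
    idx = np.nonzero(dk != 0)[0]
    times, signs = [], []
    for i in idx:
        step = dk[i]
        for _ in range(abs(step)):           # |dz| < Lz/2 makes |step| <= 1
            times.append(traj.times[i + 1])
            signs.append(int(np.sign(step)))
    times = np.asarray(times, dtype=float)
    signs = np.asarray(signs, dtype=int)
    keep = times >= traj.times[0] + discard
    return CrossingEvents(times=times[keep], signs=signs[keep],
                          charge=traj.charge, boundary_z=boundary_z)


def current_from_events(
    events: Sequence[CrossingEvents],
    analysis_window: tuple[float, float],
) -> Current:
    """Current from pooled crossing events inside an analysis window.

    I = (sum of signed crossings, weighted by each ion's charge) * e / T,
    reported in pA; the counting error treats forward and backward events
    as independent, err = sqrt(Nf + Nb) * |q| * e / T.
    """
    t0, t1 = analysis_window
    if not t1 > t0:
        raise ValueError("analysis window must have t_end > t_start")
    net_q = 0.0
    n_tot = 0
    q_abs = [abs(ev.charge) for ev in events] or [1.0]
    for ev in events:
        sel = (ev.times >= t0) & (ev.times <= t1)
        net_q += ev.charge * float(ev.signs[sel].sum())
        n_tot += int(sel.sum())
    duration = t1 - t0
    value = net_q * PICOAMP_PER_E_PER_NS / duration
    error = math.sqrt(n_tot) * max(q_abs) * PICOAMP_PER_E_PER_NS / duration
    return Current(value=value, error=error, net_crossings=net_q,
                   window=(t0, t1))


def ensemble_current(
    trajectories: Sequence[IonTrajectory],
    boundary_z: float = 0.0,
    discard: float = 10.0,
    analysis_window: tuple[float, float] | None = None,
) -> dict[float, Current]:
    """Per-species currents (one entry per distinct charge) for an ensemble.

    The total current is the sum over entries; by construction it equals
    the total transported charge divided by the window duration.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    if analysis_window is None:
        t0 = max(t.times[0] for t in trajectories) + discard
        t1 = min(t.times[-1] for t in trajectories)
        analysis_window = (t0, t1)
    by_charge: dict[float, list[CrossingEvents]] = {}
    for tr in trajectories:
        ev = detect_crossings(tr, boundary_z=boundary_z, discard=discard)
        by_charge.setdefault(float(tr.charge), []).append(ev)
    return {q: current_from_events(evs, analysis_window)
            for q, evs in by_charge.items()}


def fit_iv(
    points: Sequence[IVPoint],
    proportional: bool = False,
    weighted: bool | None = None,
) -> IVFit:
    """First-order polynomial fit I = g V + I0 of an IV relation.

    The slope g is the conductance in pS (pA/V).  The slope standard error
    comes from the fit residuals; with ``weighted=True`` (default when all
    points carry errors) points are weighted by 1/sigma^2.  With
    ``proportional=True`` the intercept is fixed at zero.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 IV points")
    V = np.array([p.voltage for p in points], dtype=float)
    I = np.array([p.current for p in points], dtype=float)
    sig = np.array([p.current_error for p in points], dtype=float)
    if np.ptp(V) == 0:
        raise ValueError("all voltages identical — slope undefined")
    if weighted is None:
        weighted = bool(np.all(sig > 0))
    w = 1.0 / sig**2 if weighted else np.ones_like(V)

    if proportional:
        g = float(np.sum(w * V * I) / np.sum(w * V * V))
        resid = I - g * V
        dof = len(points) - 1
        s2 = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
        g_err = math.sqrt(s2 / float(np.sum(w * V * V)))
        intercept = 0.0
    else:
        W = np.sum(w)
        Vm = np.sum(w * V) / W
        Im = np.sum(w * I) / W
        Svv = np.sum(w * (V - Vm) ** 2)
        g = float(np.sum(w * (V - Vm) * (I - Im)) / Svv)
        intercept = float(Im - g * Vm)
        resid = I - (g * V + intercept)
        dof = len(points) - 2
        s2 = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
        g_err = math.sqrt(s2 / Svv)
    ss_tot = float(np.sum((I - I.mean()) ** 2))
    ss_res = float(np.sum((I - (g * V + intercept)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return IVFit(conductance=g, conductance_error=g_err,
                 intercept=intercept, r_squared=r2, n_points=len(points))
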