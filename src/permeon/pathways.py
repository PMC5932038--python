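"""Exit-pathway classification of pore-passing ion trajectories.

Each permeating trajectory is reduced to cylindrical coordinates about the
pore axis and classified by the sequence of regions it visits between the
second-basin level ``z_basin2`` and the cytoplasmic exit plane ``z_top``:

* **A** — central axial exit: the ion never leaves the central pore
  (r < r_cleft) inside that z band and ends beyond z_top;
* **B** — cleft detour: the ion enters a protomer cleft (r > r_cleft in the
  band) but still exits axially past z_top, with r < r_lateral at its last
  upward z_top crossing;
* **C** — lateral exit: the ion leaves a cleft sideways, r > r_lateral
  inside the band, before ever crossing z_top;
* **unclassified** — the visit sequence matches none or more than one rule
  (recrossings, or the trajectory ends inside a cleft).

Only the final committed exit counts: an excursion is committed when the
ion does not subsequently return to the central pore below z_top.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .permeation import IonTrajectory
from .synthetic import ChannelGeometry  # noqa: F401  (re-export convenience)

__all__ = [
    "PathwayLabel",
    "PathwayReport",
    "NotPorePassingError",
    "to_cylindrical",
    "classify_exit",
    "classify_ensemble",
    "pathway_report",
]

LABELS = ("A", "B", "C", "unclassified")


class NotPorePassingError(ValueError):
    """Trajectory never traverses the pore; excluded from fractions."""


@dataclass(frozen=True)
class PathwayLabel:
    label: str                          # one of LABELS
    decision_trace: tuple[str, ...]     # compressed region-visit sequence

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not self.decision_trace:
            raise ValueError("decision trace must be non-empty")


@dataclass(frozen=True)
class PathwayReport:
    counts: dict
    fractions: dict
    confidence_intervals: dict          # 95% exact (Clopper-Pearson)
    total: int

    def __post_init__(self):
        if sum(self.counts.values()) != self.total:
            raise ValueError("counts must sum to total")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")


def to_cylindrical(
    traj: IonTrajectory | np.ndarray,
    axis_point: Sequence[float] = (0.0, 0.0, 0.0),
    axis_direction: Sequence[float] = (0.0, 0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Axial coordinate z and distance r to the pore axis, per frame.

    The axis is the line through ``axis_point`` along ``axis_direction``
    (default: the z axis).  Positions must be unwrapped in z.
    """
    pos = traj.positions if isinstance(traj, IonTrajectory) else np.asarray(
        traj, dtype=float)
    p0 = np.asarray(axis_point, dtype=float)
    u = np.asarray(axis_direction, dtype=float)
    u = u / np.linalg.norm(u)
    rel = pos - p0
    z = rel @ u
    perp = rel - np.outer(z, u)
    r = np.linalg.norm(perp, axis=1)
    return z, r


def _region(z: float, r: float, g: ChannelGeometry) -> str:
    if z <= g.z_lumen:
        return "below_lumen"
    if z > g.z_top:
        return "above_top"
    if z > g.z_basin2:
        if r > g.r_lateral:
            return "lateral"
        if r > g.r_cleft:
            return "cleft"
        return "band_axial"
    return "pore"


def classify_exit(
    z: np.ndarray,
    r: np.ndarray,
    geometry: ChannelGeometry,
) -> PathwayLabel:
    """Classify one pore-passing trajectory given in cylindrical form.

    Raises
    ------
    NotPorePassingError
        If the trajectory never visits z < z_lumen and subsequently
        reaches z > z_basin2.
    """
    z = np.asarray(z, dtype=float)
    r = np.asarray(r, dtype=float)
    g = geometry

    below = np.nonzero(z < g.z_lumen)[0]
    if below.size == 0:
        raise NotPorePassingError("trajectory never enters below z_lumen")
    after = below[0]
    entered = np.nonzero(z[after:] > g.z_basin2)[0]
    if entered.size == 0:
        raise NotPorePassingError(
            "trajectory never reaches z > z_basin2 after the luminal side")
    i0 = after + entered[0]

    regions = [_region(float(zi), float(ri), g) for zi, ri in zip(z, r)]
    trace = tuple(k for k, _ in itertools.groupby(regions))
    zz, rr = z[i0:], r[i0:]

    in_band = (zz > g.z_basin2) & (zz <= g.z_top)
    up_cross = np.nonzero((zz[:-1] <= g.z_top) & (zz[1:] > g.z_top))[0] + 1
    first_top = up_cross[0] if up_cross.size else None
    last_top = up_cross[-1] if up_cross.size else None

    cleft_visit = bool(np.any(in_band & (rr > g.r_cleft)))
    lateral_mask = in_band & (rr > g.r_lateral)
    if first_top is None:
        lateral_before_top = bool(np.any(lateral_mask))
    else:
        lateral_before_top = bool(np.any(lateral_mask[:first_top]))

    final_z, final_r = float(zz[-1]), float(rr[-1])
    ends_in_cleft = (g.z_basin2 < final_z <= g.z_top) and final_r > g.r_cleft

    matched = set()
    if final_z > g.z_top:
        if not cleft_visit:
            matched.add("A")
        elif last_top is not None and rr[last_top] < g.r_lateral:
            matched.add("B")
    if lateral_before_top and final_r > g.r_cleft:
        matched.add("C")

    if len(matched) == 1 and not (ends_in_cleft and "C" not in matched):
        label = matched.pop()
    else:
        label = "unclassified"
    return PathwayLabel(label=label, decision_trace=trace)


def classify_ensemble(
    trajectories: Sequence[IonTrajectory],
    geometry: ChannelGeometry,
    axis_point: Sequence[float] = (0.0, 0.0, 0.0),
    axis_direction: Sequence[float] = (0.0, 0.0, 1.0),
) -> tuple[list[PathwayLabel], list[tuple[IonTrajectory, str]]]:
    """Classify every trajectory; returns (labels, rejected-with-reason)."""
    labels: list[PathwayLabel] = []
    rejected: list[tuple[IonTrajectory, str]] = []
    for tr in trajectories:
        zc, rc = to_cylindrical(tr, axis_point, axis_direction)
        try:
            labels.append(classify_exit(zc, rc, geometry))
        except NotPorePassingError as err:
            rejected.append((tr, str(err)))
    return labels, rejected


def pathway_report(labels: Sequence[PathwayLabel | str],
                   confidence: float = 0.95) -> PathwayReport:
    """Counts, fractions and exact binomial confidence intervals per label."""
    if len(labels) == 0:
        raise ValueError("cannot report fractions of an empty label list")
    names = [lab.label if isinstance(lab, PathwayLabel) else lab
             for lab in labels]
    bad = set(names) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    n = len(names)
    counts = {lab: 0 for lab in LABELS}
    counts.update(Counter(names))
    fractions = {lab: counts[lab] / n for lab in LABELS}
    cis = {}
    for lab in LABELS:
        res = stats.binomtest(counts[lab], n)
        ci = res.proportion_ci(confidence_level=confidence, method="exact")
        cis[lab] = (float(ci.low), float(ci.high))
    return PathwayReport(counts=counts, fractions=fractions,
                         confidence_intervals=cis, total=n)
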