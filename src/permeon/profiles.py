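"""Static profiles along the pore axis: hydration numbers and pore radius.

Hydration numbers count solvent sites inside nested radial cutoffs (first
and second hydration shell) around an ion, binned by the ion's axial
position.  The pore-radius profile is a simplified inscribed-sphere
estimate: at each grid plane z, the radius is the smallest
(distance from the on-axis point (0, 0, z) to any nearby atom) minus that
atom's radius, i.e. the largest sphere centred on the axis that touches no
atom.  Unlike the full published channel-profiling method there is no
off-axis centre optimisation, so the estimate is a lower bound in
non-axisymmetric pores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ShellDefinition",
    "HydrationProfile",
    "RadiusProfile",
    "DEFAULT_SHELLS",
    "hydration_numbers",
    "retained_fraction",
    "pore_radius_profile",
]


@dataclass(frozen=True)
class ShellDefinition:
    """Nested radial cutoffs of the first and second hydration shell."""

    species: str
    first_shell_radius: float     # nm
    second_shell_radius: float    # nm

    def __post_init__(self):
        if not 0 < self.first_shell_radius < self.second_shell_radius:
            raise ValueError("need 0 < first_shell_radius < second_shell_radius")


#: Default shell cutoffs (nm) at the first/second ion-oxygen RDF minima.
DEFAULT_SHELLS: dict[str, ShellDefinition] = {
    s.species: s
    for s in (
        ShellDefinition("Mg2+", 0.28, 0.50),
        ShellDefinition("Ca2+", 0.32, 0.55),
        ShellDefinition("Ba2+", 0.35, 0.58),
        ShellDefinition("Na+", 0.32, 0.56),
        ShellDefinition("K+", 0.36, 0.60),
        ShellDefinition("Cl-", 0.39, 0.62),
    )
}


def shell_for(species: str) -> ShellDefinition:
    try:
        return DEFAULT_SHELLS[species]
    except KeyError:
        raise KeyError(
            f"no hydration-shell definition for species {species!r}; "
            f"known: {sorted(DEFAULT_SHELLS)}"
        ) from None


@dataclass
class HydrationProfile:
    bin_centers: np.ndarray       # nm (ion z)
    n_first: np.ndarray           # mean waters within the first shell
    n_second: np.ndarray          # mean waters in (first, second]
    frames_per_bin: np.ndarray

    def __post_init__(self):
        if not (len(self.bin_centers) == len(self.n_first)
                == len(self.n_second) == len(self.frames_per_bin)):
            raise ValueError("profile arrays must align")


@dataclass
class RadiusProfile:
    z: np.ndarray                 # nm, strictly increasing grid
    radius: np.ndarray            # nm; NaN where a slab held no atoms
    standard_error: np.ndarray    # nm; 0 for a single frame

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if len(self.z) > 1 and not np.all(np.diff(self.z) > 0):
            raise ValueError("z grid must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.radius < 0):
                raise ValueError("radii must be non-negative")


def _min_image(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


def hydration_numbers(
    ion_positions: np.ndarray,
    waters_per_frame: Sequence[np.ndarray],
    shells: ShellDefinition,
    bin_edges: np.ndarray | None = None,
    box: Sequence[float] | None = None,
) -> HydrationProfile:
    """First- and second-shell water counts, binned by the ion's z.

    Parameters
    ----------
    ion_positions : (F, 3) ion position per frame, nm
    waters_per_frame : length-F sequence of (Nw, 3) water-site positions
    shells : radial cutoffs for the species
    bin_edges : z bin edges (default: 0.1 nm bins spanning the ion's range)
    box : optional periodic box lengths for minimum-image distances
    """
    ion_positions = np.asarray(ion_positions, dtype=float)
    if ion_positions.ndim != 2 or ion_positions.shape[1] != 3:
        raise ValueError("ion_positions must have shape (F, 3)")
    if len(waters_per_frame) != len(ion_positions):
        raise ValueError("one water point set is required per frame")
    box_arr = None if box is None else np.asarray(box, dtype=float)

    z_ion = ion_positions[:, 2]
    if bin_edges is None:
        lo, hi = float(z_ion.min()), float(z_ion.max())
        hi = hi + 1e-9 if hi == lo else hi
        bin_edges = np.arange(lo, hi + 0.1, 0.1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    nb = len(bin_edges) - 1

    n1_frame = np.empty(len(ion_positions))
    n2_frame = np.empty(len(ion_positions))
    r1, r2 = shells.first_shell_radius, shells.second_shell_radius
    for f, waters in enumerate(waters_per_frame):
        waters = np.asarray(waters, dtype=float).reshape(-1, 3)
        if waters.size == 0:
            n1_frame[f] = n2_frame[f] = 0
            continue
        d = _min_image(waters - ion_positions[f], box_arr)
        dist = np.linalg.norm(d, axis=1)
        n1_frame[f] = np.count_nonzero(dist <= r1)
        n2_frame[f] = np.count_nonzero((dist > r1) & (dist <= r2))

    which = np.clip(np.digitize(z_ion, bin_edges) - 1, 0, nb - 1)
    counts = np.bincount(which, minlength=nb).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        n1 = np.bincount(which, weights=n1_frame, minlength=nb) / counts
        n2 = np.bincount(which, weights=n2_frame, minlength=nb) / counts
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return HydrationProfile(bin_centers=centers, n_first=n1, n_second=n2,
                            frames_per_bin=counts)


def retained_fraction(
    z: np.ndarray,
    n_profile: np.ndarray,
    bulk_range: tuple[float, float],
) -> np.ndarray:
    """Hydration profile normalised by its mean over the bulk z range.

    A value of 1 means the ion keeps its full bulk shell at that position;
    e.g. fractions above 0.85 everywhere mean the ion keeps more than 85%
    of the shell across the pore.
    """
    z = np.asarray(z, dtype=float)
    n_profile = np.asarray(n_profile, dtype=float)
    lo, hi = bulk_range
    m = (z >= lo) & (z <= hi) & np.isfinite(n_profile)
    if not m.any():
        raise ValueError(f"no profile bins inside the bulk range ({lo}, {hi})")
    bulk = float(np.mean(n_profile[m]))
    if bulk == 0:
        raise ValueError("bulk hydration number is zero — fraction undefined")
    return n_profile / bulk


def pore_radius_profile(
    frames: Sequence[np.ndarray] | np.ndarray,
    atom_radii: np.ndarray,
    z_grid: np.ndarray,
    axis_point: Sequence[float] = (0.0, 0.0, 0.0),
    axis_direction: Sequence[float] = (0.0, 0.0, 1.0),
    slab_half_width: float = 0.1,
) -> RadiusProfile:
    """Largest on-axis inscribed-sphere radius at each grid plane.

    For every grid value z, atoms whose axial coordinate lies within
    ``slab_half_width`` of z are considered; the profile value is

        R(z) = min_i ( |x_i - (axis point at z)| - radius_i ),  clipped at 0.

    Planes whose slab contains no atoms yield NaN (missing, not zero).
    With multiple frames the mean and standard error across frames are
    returned.
    """
    if isinstance(frames, np.ndarray) and frames.ndim == 2:
        frames = [frames]
    atom_radii = np.asarray(atom_radii, dtype=float)
    z_grid = np.asarray(z_grid, dtype=float)
    p0 = np.asarray(axis_point, dtype=float)
    u = np.asarray(axis_direction, dtype=float)
    u = u / np.linalg.norm(u)

    per_frame = np.full((len(frames), len(z_grid)), np.nan)
    for f, coords in enumerate(frames):
        coords = np.asarray(coords, dtype=float)
        if len(coords) != len(atom_radii):
            raise ValueError("one radius is required per atom")
        rel = coords - p0
        z_at = rel @ u
        for j, zj in enumerate(z_grid):
            sel = np.abs(z_at - zj) <= slab_half_width
            if not sel.any():
                continue
            centre = p0 + zj * u
            dist = np.linalg.norm(coords[sel] - centre, axis=1)
            per_frame[f, j] = max(0.0, float(np.min(dist - atom_radii[sel])))

    n_ok = np.sum(np.isfinite(per_frame), axis=0)
    sums = np.nansum(per_frame, axis=0)
    sumsq = np.nansum(per_frame**2, axis=0)
    mean = np.where(n_ok > 0, sums / np.maximum(n_ok, 1), np.nan)
    with np.errstate(invalid="ignore"):
        var = (sumsq - np.maximum(n_ok, 1) * mean**2) / np.maximum(n_ok - 1, 1)
        var = np.clip(var, 0.0, None)
        sem = np.where(n_ok > 1, np.sqrt(var / np.maximum(n_ok, 1)), 0.0)
    sem = np.where(n_ok > 0, sem, np.nan)
    return RadiusProfile(z=z_grid, radius=mean, standard_error=sem)
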