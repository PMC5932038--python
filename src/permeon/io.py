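"""File formats, run manifests and the end-to-end pipeline.

Formats
-------
* XVG pull-coordinate tables (GROMACS dialect: ``#`` and ``@`` lines are
  comments/preamble, data rows are whitespace-separated floats) for
  umbrella windows and PMF output.
* Whitespace-separated trajectory tables with columns
  ``time ion_id x y z`` for permeation runs.
* GRO coordinate snapshots (fixed-column dialect) for pore profiling.
* A YAML run manifest listing datasets with their metadata plus global
  settings; :func:`run_pipeline` executes every stage the manifest enables
  in the order PMF -> binding, permeation -> currents -> IV -> pathways,
  snapshots -> radius profile.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .binding import BindingConfig, standard_binding_free_energy
from .permeation import (IVPoint, IonTrajectory, ensemble_current, fit_iv,
                         voltage_from_field)
from .pathways import classify_ensemble, pathway_report
from .profiles import pore_radius_profile
from .synthetic import ChannelGeometry
from .wham import UmbrellaWindow, bootstrap_pmf, pmf_extremum, solve_wham

logger = logging.getLogger("permeon")

__all__ = [
    "XVGTable",
    "RunManifest",
    "PipelineError",
    "read_xvg",
    "write_xvg",
    "read_trajectory_table",
    "write_trajectory_table",
    "read_gro",
    "write_umbrella_window_xvg",
    "read_umbrella_window_xvg",
    "load_manifest",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# XVG
# ---------------------------------------------------------------------------

@dataclass
class XVGTable:
    """Rectangular numeric table with its XVG preamble preserved."""

    data: np.ndarray                  # (rows, cols) floats
    labels: list[str] = field(default_factory=list)
    comments: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("XVG data must be 2-D")


def read_xvg(path: str | Path) -> XVGTable:
    """Parse an XVG file; ``#``/``@`` lines are never treated as data."""
    path = Path(path)
    comments: list[str] = []
    labels: list[str] = []
    rows: list[list[float]] = []
    ncol: int | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(("#", "@")):
                comments.append(s)
                if s.startswith("@") and "legend" in s and '"' in s:
                    labels.append(s.split('"')[1])
                continue
            try:
                vals = [float(tok) for tok in s.split()]
            except ValueError as err:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric data row: {s!r}") from err
            if ncol is None:
                ncol = len(vals)
            elif len(vals) != ncol:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(vals)} columns, "
                    f"expected {ncol})")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows (only comments/preamble)")
    return XVGTable(data=np.array(rows, dtype=float), labels=labels,
                    comments=comments)


def write_xvg(path: str | Path, data: np.ndarray,
              labels: Sequence[str] = (), comments: Sequence[str] = ()) -> None:
    """Write a numeric table in XVG form with full float precision."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    path = Path(path)
    with path.open("w") as fh:
        for c in comments:
            c = c if c.startswith(("#", "@")) else f"# {c}"
            fh.write(c + "\n")
        for i, lab in enumerate(labels):
            fh.write(f'@ s{i} legend "{lab}"\n')
        for row in data:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# umbrella windows
# ---------------------------------------------------------------------------

def write_umbrella_window_xvg(path: str | Path, window: UmbrellaWindow,
                              time_step: float = 1.0) -> None:
    """One window as an XVG pull-coordinate file: time, z [, x1, x2]."""
    n = len(window.samples)
    t = np.arange(n) * time_step
    cols = [t, window.samples]
    if window.perp_samples is not None:
        cols += [window.perp_samples[:, 0], window.perp_samples[:, 1]]
    comments = [
        f"# permeon {_pkg_version} umbrella window",
        f"# center_nm {window.center:.17g}",
        f"# spring_constant_kj_mol_nm2 {window.spring_constant:.17g}",
        f"# discard_fraction {window.discard_fraction:.17g}",
        '@ xaxis label "time (ns)"',
        '@ yaxis label "position (nm)"',
    ]
    write_xvg(path, np.column_stack(cols), comments=comments)


def read_umbrella_window_xvg(path: str | Path,
                             center: float | None = None,
                             spring_constant: float | None = None,
                             discard_fraction: float | None = None
                             ) -> UmbrellaWindow:
    """Read a window file; metadata falls back to the file's own header."""
    table = read_xvg(path)
    meta: dict[str, float] = {}
    for c in table.comments:
        parts = c.lstrip("#@ ").split()
        if len(parts) == 2:
            try:
                meta[parts[0]] = float(parts[1])
            except ValueError:
                pass
    if center is None:
        center = meta.get("center_nm")
    if spring_constant is None:
        spring_constant = meta.get("spring_constant_kj_mol_nm2")
    if discard_fraction is None:
        discard_fraction = meta.get("discard_fraction", 1.0 / 6.0)
    if center is None or spring_constant is None:
        raise ValueError(
            f"{path}: window center/spring constant neither given nor "
            "present in the file header")
    perp = table.data[:, 2:4] if table.data.shape[1] >= 4 else None
    return UmbrellaWindow(center=center, spring_constant=spring_constant,
                          samples=table.data[:, 1], perp_samples=perp,
                          discard_fraction=discard_fraction)


# ---------------------------------------------------------------------------
# trajectory tables
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = ["time", "ion_id", "x", "y", "z"]


def write_trajectory_table(path: str | Path,
                           trajectories: Sequence[IonTrajectory]) -> None:
    frames = []
    for tr in trajectories:
        frames.append(pd.DataFrame({
            "time": tr.times,
            "ion_id": tr.ion_id,
            "x": tr.positions[:, 0],
            "y": tr.positions[:, 1],
            "z": tr.positions[:, 2],
        }))
    df = pd.concat(frames, ignore_index=True)
    with Path(path).open("w") as fh:
        fh.write("# permeon trajectory table: time ion_id x y z\n")
        df.to_csv(fh, sep="\t", index=False, header=False,
                  float_format="%.17g")


def read_trajectory_table(
    path: str | Path,
    box: Sequence[float],
    charge: float = 1.0,
    wrapped: bool = False,
) -> list[IonTrajectory]:
    """Read ``time ion_id x y z`` rows into one trajectory per ion."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=_TRAJ_COLUMNS)
    if df.empty:
        raise ValueError(f"{path}: no trajectory rows")
    out = []
    for ion_id, grp in df.groupby("ion_id", sort=True):
        grp = grp.sort_values("time")
        out.append(IonTrajectory(
            ion_id=ion_id,
            charge=charge,
            times=grp["time"].to_numpy(),
            positions=grp[["x", "y", "z"]].to_numpy(),
            box=np.asarray(box, dtype=float),
            wrapped=wrapped,
        ))
    return out


# ---------------------------------------------------------------------------
# GRO snapshots
# ---------------------------------------------------------------------------

#: Fallback van der Waals radii by element, nm.
_ELEMENT_RADII_NM = {"H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
                     "S": 0.180, "P": 0.180}


def read_gro(path: str | Path,
             radii: dict[str, float] | None = None
             ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Atom coordinates (nm), per-atom radii (nm) and names from a GRO file.

    Radii are looked up by atom name, then by its leading element letter in
    a small van der Waals table (override with ``radii``).
    """
    import MDAnalysis as mda  # heavyweight; imported only when needed

    u = mda.Universe(str(path))
    coords = u.atoms.positions / 10.0          # A -> nm
    names = [str(n) for n in u.atoms.names]
    table = dict(_ELEMENT_RADII_NM)
    if radii:
        table.update(radii)
    out_r = np.empty(len(names))
    for i, name in enumerate(names):
        key = name if name in table else name[:1].upper()
        out_r[i] = table.get(key, 0.17)
    return coords.astype(float), out_r, names


# ---------------------------------------------------------------------------
# manifest + pipeline
# ---------------------------------------------------------------------------

_KIND_REQUIRED = {
    "umbrella_window": {"center", "spring_constant"},
    "permeation_run": {"box", "charge"},
    "snapshot": set(),
}


@dataclass
class RunManifest:
    """Validated list of dataset entries plus global settings."""

    datasets: list[dict]
    settings: dict
    geometry: ChannelGeometry | None = None
    base_dir: Path = Path(".")

    def entries(self, kind: str) -> list[dict]:
        return [d for d in self.datasets if d["kind"] == kind]


def load_manifest(path: str | Path) -> RunManifest:
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: manifest must be a mapping")
    settings = dict(raw.get("settings", {}))
    datasets = list(raw.get("datasets", []))
    base = path.parent
    for i, d in enumerate(datasets):
        kind = d.get("kind")
        if kind not in _KIND_REQUIRED:
            raise ValueError(f"{path}: dataset {i}: unknown kind {kind!r}")
        missing = _KIND_REQUIRED[kind] - set(d)
        if kind == "permeation_run" and not ({"voltage", "field"} & set(d)):
            missing.add("voltage|field")
        if missing:
            raise ValueError(
                f"{path}: dataset {i} ({kind}): missing metadata "
                f"{sorted(missing)}")
        p = base / d["path"]
        if not p.exists():
            raise FileNotFoundError(f"{path}: dataset {i}: no such file {p}")
    geometry = None
    if "geometry" in raw:
        geometry = ChannelGeometry(**{
            k: v for k, v in raw["geometry"].items()
            if k in {"z_lumen", "z_basin2", "z_top", "r_cleft", "r_lateral",
                     "n_clefts"}})
    return RunManifest(datasets=datasets, settings=settings,
                       geometry=geometry, base_dir=base)


def _provenance(manifest: RunManifest, stage: str, seed) -> list[str]:
    inputs = ", ".join(str(d["path"]) for d in manifest.datasets)
    return [
        f"# permeon {_pkg_version} stage={stage} seed={seed}",
        f"# inputs: {inputs}",
        f"# settings: {manifest.settings}",
    ]


def _write_csv(path: Path, df: pd.DataFrame, header_lines: list[str]) -> None:
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def run_pipeline(manifest: RunManifest | str | Path,
                 out_dir: str | Path | None = None) -> dict[str, Any]:
    """Run every stage the manifest enables; returns the result bundle.

    Stages with no matching datasets are reported as skipped, not failed.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    if not isinstance(manifest, RunManifest):
        manifest = load_manifest(manifest)
    s = manifest.settings
    seed = s.get("seed")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {"skipped": []}

    temperature = float(s.get("temperature", 300.0))
    periodic_length = s.get("periodic_length")

    # ---- PMF + binding ---------------------------------------------------
    win_entries = manifest.entries("umbrella_window")
    if win_entries:
        try:
            windows = [
                read_umbrella_window_xvg(
                    manifest.base_dir / d["path"],
                    center=d.get("center"),
                    spring_constant=d.get("spring_constant"),
                    discard_fraction=d.get("discard_fraction"),
                ) for d in win_entries
            ]
            bulk = s.get("bulk_interval")
            kwargs = dict(
                n_bins=int(s.get("n_bins", 200)),
                temperature=temperature,
                periodic_length=periodic_length,
                tol=float(s.get("tol", 1e-6)),
            )
            if bulk is not None:
                profile = solve_wham(windows, reference="bulk_zero",
                                     bulk_interval=tuple(bulk), **kwargs)
            else:
                profile = solve_wham(windows, **kwargs)
            n_boot = int(s.get("n_boot", 200))
            if n_boot >= 2:
                profile.errors = bootstrap_pmf(
                    windows, n_boot=n_boot, seed=seed,
                    reference=profile.reference,
                    bulk_interval=profile.bulk_interval, **kwargs)
            bundle["pmf"] = profile
            if bulk is not None:
                bound = tuple(s.get("bound_interval", (-6.0, 7.5)))
                cfg = BindingConfig(bound_interval=bound,
                                    temperature=temperature)
                perp = [w.retained_perp_samples for w in windows
                        if w.retained_perp_samples is not None
                        and not (bound[0] <= w.center <= bound[1])]
                if perp:
                    binding = standard_binding_free_energy(
                        profile, cfg, perp_samples=np.vstack(perp), seed=seed)
                elif s.get("area") is not None:
                    binding = standard_binding_free_energy(
                        profile, cfg, area=float(s["area"]), seed=seed)
                else:
                    binding = None
                    bundle["skipped"].append(
                        "binding (no bulk-window in-plane samples and no "
                        "area setting)")
                if binding is not None:
                    bundle["binding"] = binding
                bundle["pmf_extremum"] = pmf_extremum(profile)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage 'wham/binding' failed: {err}") from err
        if out is not None:
            prov = _provenance(manifest, "wham", seed)
            _write_csv(out / "pmf.csv", pd.DataFrame({
                "z_nm": profile.bin_centers,
                "pmf_kj_mol": profile.values,
                "error_kj_mol": profile.errors,
            }), prov)
            write_xvg(out / "pmf.xvg",
                      np.column_stack([profile.bin_centers, profile.values,
                                       profile.errors]),
                      labels=["PMF (kJ/mol)", "error (kJ/mol)"],
                      comments=prov)
            if bundle.get("binding") is not None:
                b = bundle["binding"]
                _write_csv(out / "binding.csv", pd.DataFrame([
                    dataclasses.asdict(b)]), prov)
    else:
        bundle["skipped"].append("wham/binding (no umbrella windows)")

    # ---- permeation: currents, IV, pathways ------------------------------
    run_entries = manifest.entries("permeation_run")
    all_trajs: list[IonTrajectory] = []
    if run_entries:
        try:
            discard = float(s.get("discard", 10.0))
            boundary_z = float(s.get("boundary_z", 0.0))
            iv_points, current_rows = [], []
            for d in run_entries:
                box = [float(v) for v in d["box"]]
                trajs = read_trajectory_table(
                    manifest.base_dir / d["path"], box=box,
                    charge=float(d["charge"]),
                    wrapped=bool(d.get("wrapped", False)))
                # runs may feed the IV fit, the pathway classifier, or both
                use = d.get("analysis", "both")
                if use in ("pathways", "both"):
                    all_trajs.extend(trajs)
                if use not in ("current", "both"):
                    continue
                V = (float(d["voltage"]) if "voltage" in d
                     else voltage_from_field(float(d["field"]), box[2]))
                currents = ensemble_current(trajs, boundary_z=boundary_z,
                                            discard=discard)
                total = sum(c.value for c in currents.values())
                err = float(np.hypot.reduce(
                    [c.error for c in currents.values()]))
                window = next(iter(currents.values())).window
                iv_points.append(IVPoint(voltage=V, current=total,
                                         current_error=err,
                                         analysis_window=window))
                current_rows.append({"path": d["path"], "voltage_V": V,
                                     "current_pA": total,
                                     "current_error_pA": err})
            bundle["currents"] = pd.DataFrame(current_rows)
            if len({p.voltage for p in iv_points}) >= 2:
                bundle["iv_fit"] = fit_iv(iv_points)
            else:
                bundle["skipped"].append("iv fit (fewer than 2 voltages)")
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage 'permeation' failed: {err}") from err
        if out is not None:
            prov = _provenance(manifest, "permeation", seed)
            _write_csv(out / "currents.csv", bundle["currents"], prov)
            if "iv_fit" in bundle:
                _write_csv(out / "iv.csv", pd.DataFrame(
                    [dataclasses.asdict(bundle["iv_fit"])]), prov)
    else:
        bundle["skipped"].append("permeation (no permeation runs)")

    if all_trajs and manifest.geometry is not None:
        try:
            labels, rejected = classify_ensemble(all_trajs, manifest.geometry)
            bundle["pathway_labels"] = labels
            bundle["pathway_rejected"] = rejected
            if labels:
                bundle["pathway_report"] = pathway_report(labels)
            else:
                bundle["skipped"].append(
                    "pathway report (no pore-passing trajectories)")
        except Exception as err:
            raise PipelineError(f"stage 'pathways' failed: {err}") from err
        if out is not None and "pathway_report" in bundle:
            rep = bundle["pathway_report"]
            _write_csv(out / "pathways.csv", pd.DataFrame({
                "label": list(rep.counts),
                "count": list(rep.counts.values()),
                "fraction": [rep.fractions[k] for k in rep.counts],
                "ci_low": [rep.confidence_intervals[k][0] for k in rep.counts],
                "ci_high": [rep.confidence_intervals[k][1] for k in rep.counts],
            }), _provenance(manifest, "pathways", seed))
    elif all_trajs:
        bundle["skipped"].append("pathways (no geometry in manifest)")

    # ---- snapshots: pore radius ------------------------------------------
    snap_entries = manifest.entries("snapshot")
    if snap_entries:
        try:
            grid = s.get("radius_grid", [-7.0, 7.0, 0.1])
            z_grid = np.arange(grid[0], grid[1] + 1e-9, grid[2])
            frames, radii = [], None
            for d in snap_entries:
                c, r, _names = read_gro(manifest.base_dir / d["path"],
                                        radii=s.get("atom_radii"))
                frames.append(c)
                radii = r
            bundle["radius_profile"] = pore_radius_profile(
                frames, radii, z_grid,
                slab_half_width=float(s.get("slab_half_width", 0.1)))
        except Exception as err:
            raise PipelineError(f"stage 'profiles' failed: {err}") from err
        if out is not None:
            rp = bundle["radius_profile"]
            _write_csv(out / "radius.csv", pd.DataFrame({
                "z_nm": rp.z, "radius_nm": rp.radius,
                "standard_error_nm": rp.standard_error,
            }), _provenance(manifest, "profiles", seed))
    else:
        bundle["skipped"].append("profiles (no snapshots)")

    for msg in bundle["skipped"]:
        logger.info("skipped stage: %s", msg)
    return bundle
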