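# permeon

Ion-permeation analysis for wide channel pores, built around the
single-file-of-truth quantities an applied-voltage / umbrella-sampling
study produces:

* **Cyclic WHAM potentials of mean force** W(z) from harmonically biased
  umbrella windows, with window-level bootstrap error bars;
* **Standard binding free energies** from a 1-D PMF via the
  no-orthogonal-restraint standard-state correction
  dG⁰ = −kT ln(C⁰ · A · ∫_bound e^(−βW(z)) dz), where the effectively
  sampled in-plane area A = 2πξ₁ξ₂ comes from the eigenvalues of the
  bulk-window covariance matrix;
* **Ionic currents and conductance** from net periodic-boundary crossing
  counts under an applied field (V = E·L_z), with a first-order IV fit
  whose slope is the conductance in pS;
* **Exit-pathway classification** of pore-passing ions into central-axial
  (A), cleft-then-axial (B), lateral (C) or unclassified modes, with exact
  binomial confidence intervals on the mode fractions;
* **Static pore profiles**: first/second hydration-shell counts along the
  axis and a simplified inscribed-sphere pore-radius profile.

Because real channel trajectories are rarely shareable, the package ships a
first-class synthetic-data module: overdamped-Langevin (Brownian) dynamics
in prescribed 1-D potentials, umbrella-biased window generation,
applied-field permeation ensembles in a branching channel geometry with
ground-truth exit labels, step-potential compartment restraints, and
Poisson solvent clouds. Every analysis stage is validated against the
generator's known ground truth or an analytic closed form. The intended
users are simulation groups analysing ion permeation through large pores
(ryanodine-receptor-like geometries being the motivating scale) who want
the analysis layer decoupled from any MD engine: the readers accept
GROMACS-style XVG pull files and plain tabular trajectories.

## Worked example

Known ground truth in, free energy of binding out:

```python
import numpy as np
import permeon as pm

# 1. synthetic umbrella campaign on a known periodic potential
L = 8.0
pot = pm.Potential1D.gaussian_well(depth=8.0, center=4.0, width=0.4,
                                   periodic_length=L)
params = pm.SimulationParams(diffusion_coefficient=1.0, time_step=2.5e-4,
                             n_steps=100_000, seed=21, box_length=L)
windows = pm.generate_umbrella_dataset(pot, n_windows=40, spacing=0.2,
                                       k=100.0, params=params,
                                       perp_spread=(1.2, 0.9))

# 2. cyclic WHAM with bootstrap errors, zero fixed on the bulk region
profile = pm.solve_wham(windows, n_bins=160, periodic_length=L,
                        reference="bulk_zero", bulk_interval=(0.0, 1.5))
profile.errors = pm.bootstrap_pmf(windows, n_boot=50, seed=21,
                                  n_bins=160, periodic_length=L,
                                  reference="bulk_zero",
                                  bulk_interval=(0.0, 1.5))
ext = pm.pmf_extremum(profile)
print(f"PMF converged in {profile.n_iterations} iterations; "
      f"deepest {ext.kind} {ext.value:.2f} kJ/mol at z = {ext.position:.2f} nm")

# 3. standard binding free energy with the covariance-eigenvalue area
bulk = [w.retained_perp_samples for w in windows
        if not 2.0 <= w.center <= 6.0]
result = pm.standard_binding_free_energy(
    profile, pm.BindingConfig(bound_interval=(2.0, 6.0)),
    perp_samples=np.vstack(bulk), seed=21)
print(f"A = {result.effective_area:.2f} nm^2, "
      f"dG0 = {result.delta_g0:.2f} +- {result.delta_g0_error:.2f} kJ/mol")
```

Output:

```
PMF converged in 743 iterations; deepest well -8.26 kJ/mol at z = 3.98 nm
A = 6.79 nm^2, dG0 = -11.09 +- 0.12 kJ/mol
```

The recovered well depth matches the 8 kJ/mol ground-truth potential
(the extremum sits slightly above −8.26 because the bulk reference absorbs
the well's tails), the area matches 2π·1.2·0.9 ≈ 6.79 nm², and dG⁰ agrees
with direct quadrature of the true potential to well under the bootstrap
error bar. The same stages run from the shell:

```sh
permeon simulate umbrella --seed 3 --out-dir camp --n-windows 40 --spacing 0.2
permeon wham --manifest camp/manifest.yaml --n-boot 200 --out pmf.xvg
permeon bind --pmf pmf.xvg --bound 2.0:6.0 --bulk 0.0:1.5 --area 6.79
permeon current --traj run.tsv --box 10 10 10 --voltage 0.3 --discard 10
permeon classify --traj perm.tsv --box 7.5 7.5 18 --geometry geom.yaml
permeon pipeline --manifest manifest.yaml --out-dir results/
```

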