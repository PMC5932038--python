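# Methods

`permeon` analyses single-ion permeation through a wide, tetrameric channel
pore along its symmetry axis z (luminal side negative, cytoplasmic
positive). It implements five analysis stages — cyclic WHAM free-energy
profiles, standard binding free energies, crossing-count currents and
conductance, exit-pathway classification, and static pore profiles — and a
Brownian-dynamics generator that produces every input class with known
ground truth. Units are fixed package-wide: nm, ns, kJ/mol, elementary
charges, volts; kT at 300 K is 2.494 kJ/mol.

## Synthetic data: overdamped Langevin dynamics

The generator integrates the overdamped (Brownian) Langevin equation with
the Euler–Maruyama scheme,

    z(t+dt) = z(t) + beta D F(z) dt + sqrt(2 D dt) eta,  eta ~ N(0,1),

whose stationary density is exp(-beta U(z)) up to O(dt) bias. This is the
cheapest process with the correct equilibrium statistics, and equilibrium
statistics of z(t) are all the downstream analyses consume. All-atom MD is
far richer (inertia, solvent structure, ion–ion correlation); none of that
is emulated, so green tests demonstrate the correctness of the *analyses*,
not fidelity to any particular channel.

Forces compose additively: the prescribed potential, an optional harmonic
umbrella bias −k(z−c) (minimum-image displacement when periodic), a
constant field force qE·96.485 kJ/mol/nm per V/nm, and an optional
step-shaped compartment restraint. The integrator warns when the drift
length beta·F_max·D·dt exceeds 0.1 nm and aborts if a single step exceeds
half the periodic box (unwrap ambiguity). Discretisation bias matters
quantitatively: a harmonic bias sampled at drift fraction
theta = beta·D·k·dt has stationary variance inflated by ~theta/2, so the
default window datasets keep theta ≤ 0.05.

The step restraint is a constant repulsive force inside a narrow transition
region (half-width 0.1 nm by default) around the periodic boundary,
pointing away from the boundary into the ion's current compartment. With
the default 10000 kJ/mol/nm magnitude the implied step height is
~1000 kJ/mol — effectively impenetrable at 300 K (the tests count zero
boundary crossings in 10^6 steps). The transition width and the
constant-force functional form are this package's choices; only the
magnitude and the step shape are fixed by the use case.

Umbrella windows carry, besides the biased z series, independent Gaussian
in-plane samples with prescribed spreads (xi1, xi2). They are generated
independently rather than from a 3-D potential because their only consumer
is the covariance-eigenvalue area estimate, which is exact for Gaussians.
The leading 1/6 of every series is flagged as equilibration and excluded
from all histograms (the usual 0.1 ns discard of a 0.6 ns window).

Permeation ensembles for the pathway classifier are constructed stochastic
paths, not 3-D Langevin runs: each ion draws an exit mode (axial A, cleft
detour B, lateral C, or ambiguous) and follows a noisy parametric path that
realises that mode by construction, with bounded noise so the ground-truth
label is certain. Ambiguous paths recross the cleft boundary several times
and end inside a cleft, exercising the classifier's unclassified branch.
When no mode mixture is given it is derived from the applied field: the
non-axial modes forgo part of the axial potential drop q·E·(z_top −
z_basin2) and their zero-field weights (0.53/0.25/0.17/0.05) are damped by
the corresponding Boltzmann factors, so the axial fraction rises
monotonically with field strength.

## Cyclic WHAM

`solve_wham` iterates the standard self-consistency equations on binned
histograms,

    p(b) = sum_i n_i(b) / sum_i N_i exp(beta(f_i − w_i(b))),
    exp(−beta f_i) = sum_b p(b) exp(−beta w_i(b)),

with bias w_i(b) = k_i/2 · d(z_b, z_i)^2 and d the minimum-image distance
for cyclic profiles. Convergence is declared when the largest change of any
window free energy f_i between iterations falls below 1e−6 kJ/mol
(max_iter 10^5); the iteration count and final residual are stored on the
profile. Defaults: 200 bins over the period (≈ window resolution at the
209 × 0.07 nm layout). Neighbouring windows whose histograms share no
occupied bin raise an error naming the gap. The tests cross-check the
fixed point against an independent route — direct convex minimisation of
the binned WHAM log-likelihood — with agreement at the 1e−5 kJ/mol level.

Two zero conventions are supported and recorded on the profile: `min_zero`
for display, and `bulk_zero(interval)` — mean of W over the declared
unbound region set to zero — required by the binding analysis.

**Bootstrap errors.** `bootstrap_pmf` resamples *complete windows* with
replacement (default 200 replicas), re-solves, aligns each replica to the
common reference, and reports the per-bin standard deviation. Windows are
the resampling unit because within-window samples are autocorrelated;
resampling raw samples would underestimate errors by roughly the
correlation-time factor. Replicas that fail to converge are retried once
with a fresh resampling; more than 10% persistent failures abort.
Calibration (20 independent replicate datasets) shows the mean bootstrap
error tracks the true across-replicate scatter of W within a factor of 2
per bin, with a mild (~20%) overestimate at the median.

`pmf_extremum` reports the signed extremal free energy of a bulk-referenced
profile: the deepest well (negative) when any bin dips below zero, else the
highest barrier (positive); exact ties resolve to the smallest |z|.

## Standard binding free energy

The binding stage uses the one-dimensional-PMF standard-state correction
without orthogonal restraints:

    dG0 = −kT ln( C0 · A · ∫_bound exp(−beta W(z)) dz ),

with C0 one molecule per 1.6606 nm^3 (1 mol/L) and W bulk-referenced. The
integral is trapezoidal on the PMF grid with interpolated endpoints; cyclic
profiles are unrolled so any interval up to one period is integrable. The
effectively sampled area is A = 2·pi·xi1·xi2 with xi1^2, xi2^2 the
eigenvalues of the 2×2 covariance of in-plane positions pooled over all
bulk-phase windows — eigenvalues, not marginal variances, so A is invariant
under rotation of the in-plane axes. Per-species presets (areas
3.09–9.09 nm^2, bound interval (−6.0, 7.5) nm) ship as overridable config
values for the RyR1-scale use case. Pooling across bulk windows is the
default; a per-window mean is a trivial variation the caller can compute.
When the PMF carries bootstrap errors, dG0's error is propagated by per-bin
Gaussian resampling of W (200 draws, seeded).

Useful identities the implementation satisfies exactly: dG0 = 0 when
A·(bound length) equals the standard-state volume at W ≡ 0, and
dG0(2A) − dG0(A) = −kT ln 2.

## Currents and conductance

An ion's axial coordinate is unwrapped by minimum image per frame pair
(frames must satisfy |dz| < Lz/2); a signed crossing event is recorded each
time the unwrapped z passes any periodic image of the boundary plane
(default z = 0). In a single-membrane periodic box, net boundary crossings
equal net transmembrane permeation. Events before the discard time
(default 10 ns) are dropped. The current is

    I = (net signed crossings · q · e) / T,   in pA,

with a counting error sqrt(N_forward + N_backward)·q·e/T — an
independent-event approximation; block averaging would be the alternative
for strongly correlated recrossings. Applied voltage is V = E·Lz. The IV
relation is fitted by first-order least squares with a free intercept
(weighted by 1/sigma^2 when errors are present); a proportional-fit switch
exists. The slope in pA/V is the conductance in pS. On flat-potential
Brownian ensembles the fit reproduces the drift–diffusion closed form
g = N q^2 D / (kT Lz^2) within statistical error.

## Exit-pathway classification

Trajectories are projected to cylindrical coordinates (z, r) about the pore
axis. A trajectory is pore-passing if it visits z < z_lumen and later
reaches z > z_basin2. Between z_basin2 and z_top, r > r_cleft means "in a
protomer cleft" and r > r_lateral means "left the channel sideways". The
rules, applied to the portion after pore entry:

* **A** — never in a cleft within the band, final z > z_top;
* **B** — visited a cleft, final z > z_top, and r < r_lateral at the last
  upward z_top crossing;
* **C** — exceeded r_lateral inside the band before any z_top crossing and
  did not return to the central pore;
* **unclassified** — no rule or more than one rule matched, or the
  trajectory ends inside a cleft.

Only the final committed excursion decides the label: an excursion is
committed when the ion does not subsequently return below z_top at
r < r_cleft. These concrete rules are this package's formalisation of a
region-sequence heuristic; all thresholds are configuration values of the
geometry, never hard-coded channel dimensions. z_basin2 is placed at the
level of the second free-energy basin, where the cleft pathways branch
off. Raising r_cleft can only move labels toward A (monotonicity, tested).
Reports include exact (Clopper–Pearson) binomial confidence intervals per
label.

## Static profiles

Hydration numbers count solvent sites within nested radial cutoffs of the
ion (first shell ≤ r1, second shell in (r1, r2]), minimum-image in periodic
boxes, binned by ion z (0.1 nm bins). Default cutoffs per species
(Mg 0.28/0.50 … Cl 0.39/0.62 nm) sit at typical ion–oxygen RDF minima and
are overridable — counting sites, not whole molecules. `retained_fraction`
normalises a profile by its mean over a declared bulk range.

The pore-radius profile is a simplified inscribed-sphere estimate: at each
grid plane, R(z) = min over slab atoms (|x_i − (0,0,z)| − radius_i),
clipped at zero, slab half-width 0.1 nm. There is no off-axis centre
optimisation as in full channel-surface methods, so R is a lower bound in
non-axisymmetric pores; for the synthetic test geometries (rings,
cylinders) it is exact. Empty slabs yield missing values, never zero.
Multiple frames give mean and standard error.

## Problem sizes and numerical choices

The test-suite and acceptance-script study conditions, chosen so each
statistical tolerance is met with headroom at desk scale:

| study | conditions |
|---|---|
| double-well recovery | L = 5.1 nm, barrier 10 kJ/mol, 51 windows × 0.1 nm, k = 500, D = 0.5 nm²/ns, dt = 5e−4 ns, 48000 retained samples/window, 200 bins |
| flat null | as above but k = 100, D = 1, dt = 2.5e−4, 144000 retained samples/window, 150 bins |
| bootstrap calibration | 20 datasets, 25 windows × 0.2 nm on a 5 kJ/mol sine² profile, 100 bootstrap replicas each |
| end-to-end binding | 8 kJ/mol Gaussian well on L = 8 nm, 40 windows, k = 100 |
| conductance | 32 ions, Lz = 10 nm, 5 voltages in ±0.4 V, 50 ns per run |
| pathways | 400-ion labelled ensembles (1600 in the acceptance script's fraction estimate) |

Other numerical choices: WHAM tolerance 1e−6 kJ/mol on window free
energies; gauge fixed to the first window; exp(−beta w) underflow to zero
is harmless and left to the FPU; degenerate (single-bin) windows yield a
zero-error profile rather than failing; the IV intercept is left free
because an offset-free line is an assumption, not a given; Poisson counts
in the solvent generator come from the generator's own seeded RNG so every
dataset is bit-reproducible from its seed.

## Known limitations

* Single-ion physics only: no ion–ion interaction, no multi-ion PMFs, no
  saturation effects; the Ca-saturation comparison workflow is documented
  but its absolute currents require all-atom simulation.
* Euler–Maruyama has O(dt) equilibrium bias; the defaults keep it below the
  statistical noise, but user-supplied dt is only warned about, not
  corrected.
* The pathway generator guarantees its labels by construction; it validates
  the classifier's rule logic, not the physical realism of any particular
  exit-route geometry.
* The on-axis pore-radius estimate underestimates radii in
  non-axisymmetric pores.
* Absolute experimental-scale results (specific free energies of binding,
  a specific channel's conductance) are out of reach of the synthetic
  generator by design; the package's claims are correctness claims about
  the analyses.
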