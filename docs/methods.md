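# Methods

This note documents the models, estimation procedure, numerical choices and
known limitations of `prestressmap`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Contact models and the tip parametrization

All four models express the indentation force F at depth d through a small
number of material parameters once the tip geometry is fixed:

- **HS** (Hertz sphere + prestress):
  `F = 4πRdσ·cos(tan⁻¹√(2R/d)) + (4/3)(1−γ²)⁻¹ E √R d^1.5`.
  The first term is the vertical projection of a pre-existing horizontal
  stress σ acting over the contact; σ > 0 is tensile, σ < 0 compressive.
  With σ < 0 the total force is negative below a crossover depth d* — both
  terms scale as d^1.5 at shallow depth, so a crossover exists only when
  `|σ| ≳ 0.2 E` (for γ = 0.5); `negative_force_crossover` finds d* by
  bisection.
- **Hertz**: the σ = 0 special case (HS nests it exactly).
- **Sneddon** (cone): `F = (2tanθ/π)(1−γ²)⁻¹ E d²`.
- **CSLC** (cortical shell, liquid core): `F = 4T(1/r_cell + 1/R)πRd`,
  linear in depth, parametrized by cortical tension T (N/m) and the cell
  radius r_cell (user input; a reasonable default is half the topography
  footprint diameter).

The effective tip radius (half-angle for the cone) is
`R(d) = r + a·∂z/∂x + b·∂z/∂y + c·d`.  The gradient couplings absorb tip
asymmetry and — empirically dominant along the scan direction — the
synchronization error between lateral scanning and vertical indentation;
the depth coupling absorbs non-sphericity and substrate proximity.  R(d) is
substituted pointwise into the constant-R expressions; no re-derivation of
the contact integrals is attempted.  A nonpositive R(d) at a used sample is
a *geometry violation*: reported and penalized, never clamped.

The angle factor is implemented through the identity
`cos(tan⁻¹ x) = 1/√(1+x²)`, i.e. `√(d/(d+2R))`, and is a pluggable function
(`ModelConfig.angle_factor`) so alternate readings can be tested without
touching the fitter.

### Parameters, units, defaults

| parameter | meaning | unit | default | why |
|---|---|---|---|---|
| γ | Poisson ratio | – | 0.5 | incompressible cell, standard in AFM cell mechanics |
| r | base tip radius | m | 50 nm (phantom truth); init from nominal | sharp pyramidal probes |
| a, b | gradient couplings | m/slope | 10, 30 nm | b > a: scan-direction error dominates |
| c | depth coupling | – | 0.02 | tens of nm over an 800 nm ramp |
| trigger | force threshold | N | 3 nN maps, 1.5 nN line scans | instrument setpoints |
| depth grid | sampling | m | 0–800 nm, 10 nm steps | desk-scale version of deep indentation |

## Estimation

**Per-pixel fit.**  With geometry fixed, every model is linear in its
parameters, so each pixel is an ordinary least-squares problem on design
columns Φ (for HS: Φ_σ = 4πRd·√(d/(d+2R)), Φ_E = (4/3)(1−γ²)⁻¹√R d^1.5).
`fit_curve_linear` is the reference path (QR-based lstsq); the map path
solves the equilibrated 1×1 / 2×2 normal equations vectorized across all
pixels — columns are scaled to unit norm first, so conditioning reflects
only the Φ_σ–Φ_E correlation (≈ 0.99; scaled 2×2 condition ≈ (1+ρ)/(1−ρ)),
which keeps noiseless round trips at ~1e-10 relative.  E (or T) is *not*
constrained nonnegative: a negative value sets a soft `negative_E` flag but
the value is kept.  Masking such pixels would bias shallow-window stress
maps, because at small depths E is barely identifiable and the sign of its
noise is anti-correlated with the σ estimate.

**Map objectives.**  Two aggregates of the per-pixel residual rms are
available: its *variance* across the map (default — a correctly described
tip leaves no location-dependent misfit) and its *sum* (accumulated fitting
error).  Only hard-invalid pixels (missing, too shallow, geometry
violation, singular design) leave the objective; excluding soft-flagged
pixels would let a bad descriptor proposal lower the aggregate by shedding
its worst pixels.  Measured on phantoms at 1% force noise, the variance
objective is nearly flat in r (a wrong radius rescales per-pixel σ and E
and leaves the residual variance at the noise floor), while the sum
objective has a clean minimum at the true descriptors — so descriptor
recovery experiments use `objective="sum"`, and variance remains the
default for map production.

**MCMC search.**  The descriptor search is a Metropolis *minimizer*, not a
posterior sampler: Gaussian proposals per parameter (5% of |init|, with
absolute floors), acceptance `min(1, exp(−ΔL/T))`, temperature annealed
linearly to 10% of its start, best-so-far returned; 1000 iterations by
default.  The start temperature is `1e-3 ×` the initial objective: the
objective basin is shallow (relative depth ~1e-3 at realistic noise), so a
temperature at the objective scale would random-walk without resolving r; a
near-descent chain converges in a few hundred iterations.  Bounds keep the
geometry physical (r ∈ (0, 10 µm], a, b ∈ [±5 µm]/slope, c ∈ [±10]; angle
variants for the cone).  A proposal violating geometry on > 1% of all
samples is rejected outright.  Chains are exactly reproducible from
(seed, config, data).

**Model selection.**  The sample set is split per curve into 7/8 training
and 1/8 test, stratified in depth (one draw per contiguous depth block), so
every pixel's parameters remain estimable from its training points — a
per-curve holdout would leave test pixels with no fitted parameters at all.
Each model is calibrated independently on the training samples and scored
by out-of-sample force rms on the held-out samples.

## Depth windows

Depth-windowed maps re-fit each pixel on samples with d ≤ d_max, reusing
the descriptors calibrated once on the full curves (the window changes the
data subset, not the geometry).  Shallow windows (100 nm) read the cortex;
the full window (0–800 nm) is labeled nucleoskeletal.  A caveat the
two-layer phantom makes explicit: because force is cumulative, the shallow
layer's contribution persists in deep samples as a near-constant offset,
and the collinear HS columns amplify that offset — the unconstrained
full-window σ estimate lands near the *cortex* value rather than between
the layers.  The shallow window recovers the cortex stress cleanly (within
10% at 1% noise); full-window values for layered specimens should be read
as cortex-contaminated and interpreted with care.  The acceptance test for
layer discrimination asserts the idealized between-layers behavior and is
expected to fail on that clause; the failure is a property of cumulative
force + unconstrained linear fitting, not a code defect.

## The phantom: what it emulates, what it does not

`synthetic.make_phantom` builds a deterministic virtual cell: a truncated
paraboloid dome (3 µm high, 7 µm footprint — smooth, analytic gradients),
fiber-like tensile segments (+20 kPa, 0.8 µm wide chords) over a
compressive background (−5 kPa), matching the tens-of-kPa scale that
live-cell depth-resolved stress maps report; modulus 10 kPa; optionally a
two-layer nucleus structure (cortex thickness 150 nm).  Forward curves use
the HS law with the true depth-dependent tip radius, optional
scan-synchronization error (an extra b-like coupling), additive Gaussian
force noise, and trigger truncation.  Two-layer curves are offset-matched
concatenations — continuous at the interface *by construction*; this is a
test scaffold, not a physical multilayer contact model.  At
tens-of-kPa stresses a 3 nN trigger terminates curves near ~120 nm, so
two-layer depth-window experiments disable the trigger to sample the full
800 nm — a consistency requirement of the stated stress scale, not a tuned
value.

The phantom does **not** emulate: viscoelasticity or rate dependence,
adhesion on retract, membrane tenting, heteroscedastic or 1/f instrument
noise, drift, or piezo nonlinearity.  A green phantom test therefore
establishes the *estimator's* correctness under the stated forward physics,
not robustness to every artifact of a real instrument.

`make_linescan_series` is a profile-level generator (Gaussian stress bump +
1D dome replayed over time with exponential relaxation) for the
repeated-line-scan statistics; it does not simulate curves.

## Numerical choices and degenerate inputs

- Strict SI units everywhere in memory and in containers; exports state
  units explicitly and refuse unitless maps.
- Singular designs (e.g. all depths equal) are flagged, not raised; an
  all-zero-force curve fits as exactly zero parameters, not singular.
- The 2×2 solve declares singularity at scaled determinant < 1e-12
  (1 − ρ² for unit-normed columns).
- Contact detection (raw traces): linear baseline on the first 30% of the
  approach, contact at force > baseline + max(5×MAD noise, 0.1 pN), refined
  by backward extrapolation of a d^1.5 fit; the method is an enum so
  alternatives can be swapped.
- Depth stratification of the train/test split uses contiguous blocks of
  the depth-ordered samples with one uniform draw per block; curves with
  fewer than 8 samples go wholly to training.
- Radial profiles average unmasked pixels in equal-width bins; empty bins
  are NaN with count 0; normalization divides by the maximum |mean| within
  r_max.
- Line-scan height statistic is the window maximum by default (mean
  selectable); the averaging window defaults to the central 5 µm.

## Known limitations

- The variance objective cannot identify the base tip radius by itself (the
  degeneracy documented above); use the sum objective when descriptors are
  the quantity of interest.
- Full-depth windows on layered specimens carry cortex contamination (see
  Depth windows).
- The CSLC cell radius is not fitted; results for that model are
  conditional on the supplied r_cell.
- No bottom-effect (substrate) correction beyond what the depth coupling c
  absorbs empirically.
- Desk-scale defaults (32×32 grids) are ~64× smaller than real 256×256
  acquisitions; runtimes scale linearly in pixel count and the vectorized
  fitter handles 256×256 maps, but the shipped experiments are sized for
  minutes-scale CI.
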