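# Methods

This note documents the models, estimators and numerical choices behind
`incluflux`, and what the synthetic-data generator does and does not
emulate.

## Synthetic-data generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream stage is validated.

**Trajectories.** 2D particle positions advance by independent per-axis
Gaussian increments of variance 2·D·Δt (free diffusion).  The *directed*
kind adds a drift step of length v·Δt whose direction re-orients at
exponentially distributed waiting times with mean `drift_persistence_s`;
tuning (v, persistence) spans fitted exponents α between 1 (no drift) and
2 (ballistic limit).  No drift speed or persistence is known for real
inclusion bodies, so values used in examples were chosen empirically to
span α ≈ 1.2–1.4 on the lag range probed and are not measurements.  The
*stationary* and *ballistic* kinds (D = 0, and constant-direction drift,
respectively) exist as analytic limiting cases.  Trajectories are
unbounded by default; an optional reflective boundary keeps walks inside a
rendering field.  Defaults: D = 5.9 × 10⁻² μm²/s (the measured
small-aggregate diffusion coefficient), 32 or 10 frames/s (the two
acquisition regimes for GFP- and mEos2-tagged material).

**Rendering.** Particles render as sampled 2D Gaussians of
σ = 0.12 μm on a uniform background; the default geometry is a 64×64 px
field at 0.1 μm/px, the scale of a 100×/1.45 NA objective on a typical
sCMOS camera.  The camera model is Poisson(signal) followed by additive
Gaussian read noise, in that order.  Photobleaching multiplies amplitude
by `retention^frame`.  Z-stacks render ovoid inclusions as filled
ellipsoids at a chosen multiple of the cytoplasmic mean, blurred in-plane
by the PSF, with an optional darker vacuolar sphere; a per-slice label
image is returned as ground truth.

**FRAP.** The compartment is the equatorial disk of a sphere, uniform at
relative concentration 1 before the bleach and (1 − bleach_depth) after.
Recovered material R(t) = bleach_depth·(1 − e^(−k·t)) enters by one of
three regimes: distributed uniformly (*interior_mixing* — the observed
behaviour of gel-like inclusions), deposited only in a boundary shell
(*surface_accretion* — the rejected accretion alternative), or not at all
(*no_exchange*).  Frames are compartment-scale concentration maps on the
cytoplasmic background; optical blur is deliberately omitted so the
spatial pattern of recovery is directly measurable.  Shot noise is scaled
by a photon budget of 200 photons per concentration unit, a moderate
confocal regime.

**Pulse-chase.** A two-pool (cytoplasm C, inclusion I), two-colour linear
kinetic model:

    C' = −k_in·C + k_out·I − k_deg·C  (+ synthesis, green only)
    I' =  k_in·C − k_out·I

Red is created once at t = 0 by converting a fraction of all green;
no red is ever synthesised.  Integration is fixed-step explicit Euler at
step ≤ min(0.1/max rate, sampling/10); the model is linear and stiff-free
at these rates, and the scheme conserves C + I exactly when k_deg = 0.
At each division time the cytoplasmic pool is divided by
(1 + daughter_fraction); the inclusion stays with the mother (daughters do
not usually inherit inclusion bodies), and the amount handed to daughters
is retained in a ledger so mass balance is checkable.  Imaging bleach
physically depletes both pools of a colour by the channel retention after
every observation; because the red dynamics are linear and source-free
this commutes with the dynamics, making the division-free bleach
correction exact — while for green, continued synthesis makes exact
correction impossible, which is why the green channel is reported as an
uncorrected/corrected bracketing pair.

Default rates (k_in = 0.02, k_out = 0.012, k_deg = 0.008 min⁻¹, initial
pools 100/60 A.U., conversion fraction 0.5) were chosen once so the red
inclusion trace reproduces the qualitative experimental shape — a rise to
a maximum near one hour followed by a ~35–40% decline over the remaining
3.5 h — since the underlying rates are not measured quantities.
Measurement noise is multiplicative Gaussian on the reported values only
(2% in the recovery fixtures).

**What the generator does not emulate:** budding-cell geometry and the
cell cycle, 3D PSF optics beyond the Gaussian approximation, vesicle or
autophagosome dynamics, detector fixed-pattern noise, stage drift and
focus loss, and the crowding/heterogeneity of real cytoplasm.  Passing
tests therefore establish that the *estimators* are correct and calibrated
under the stated statistical model, not that real-cell images would yield
the same numbers.

## Detection

The spot-enhancing filter is a negative Laplacian-of-Gaussian, built as an
explicitly sampled kernel on a ⌈4σ⌉ support, made exactly zero-sum (so
constants and offsets are annihilated to machine precision despite
truncation) and scaled by σ² (scale-normalised blob-detection convention);
borders use reflective padding.  The exact response normalisation of the
original interactive plugin is unpublished; this documented kernel defines
the reference behaviour, and the test suite verifies it against a direct
spatial-convolution oracle to 10⁻⁶.  Candidates are 8-connected
supra-threshold response regions of at least `min_size_px` pixels
(2 for small particles, 4 for inclusion bodies), positioned at the
response-weighted centroid.  The default threshold, mean + 3·SD of the
filtered frame, is a standard choice where the plugin default is
undocumented; it is configurable.  An optional Gaussian pre-smooth stands
in for camera-noise denoising ahead of enhancement.

## Tracking

One particle per movie (movies are cropped around a single particle);
multi-target assignment is out of scope.  The path maximises

    Σ_frames [ w_int·ŝ + w_var·(1 − |Δŝ|) − w_mov·(step/step_max) − w_ctr·(d_centre/r_field) ]

over candidate nodes, where ŝ is the per-movie min-max-normalised filter
response, subject to step ≤ step_max = 10 px, solved exactly by per-frame
dynamic programming.  Defaults: w_int = 0.80, w_var = 0.20, w_mov = 0.40,
w_ctr = 0 (implemented but inert).  The exact functional form by which the
original plugin combines its percentage weights is unpublished; this
documented score defines the reference objective, and optimality is
verified against exhaustive path enumeration.  Ties break by higher raw
response then lower candidate index, making output deterministic.  Gaps
are not closed: an empty frame or an infeasible step ends the track, which
is returned as the longest feasible leading segment with a diagnostic,
because MSD analysis requires contiguous frames.

## Motion analysis

MSD uses all overlapping start frames per lag ("each possible time
interval"), lags 1–16 frames by default, truncated with a warning for
shorter tracks; Δt per lag comes from timestamps.  α is the OLS slope of
log₁₀ MSD on log₁₀ Δt (zero-MSD lags excluded with a warning; at least 3
positive lags required).  D is the zero-intercept least-squares slope of
MSD against Δt over all used lags, divided by 4 — not the lag-1 point
alone — because the relation MSD = 4DΔt does not privilege a lag; a
single-lag curve reduces to the direct arithmetic inversion.  Motion class
uses a ±0.05 dead-band around α = 1 (measurement SEMs for these data are
≈ 0.03–0.06, so a knife-edge boundary would be noise-driven).  Group
comparison is Welch's unpaired two-tailed t with Satterthwaite degrees of
freedom, also available from summary statistics (mean, SEM, n).

Finite tracks bias the overlapping-MSD log-log slope slightly downward at
high lags; the calibration tests therefore use 300-frame tracks for
ensemble means (where the residual bias is ≈ 1–3%, well inside the
ensemble SEM) and 600-frame tracks when asserting that every per-track
fit reaches r² ≥ 0.98.

## Morphometry

Segmentation thresholds at k × mean cytoplasmic intensity (k = 1.2 for
morphometry, 1.4 for FRAP, 1.5 for pulse-chase, matching the three
experimental protocols), after background subtraction on both sides.
In-plane connectivity is 8-connected; slices are linked into 3D objects by
centroid overlap; measurements are taken on the z-slice with maximal
integrated object intensity (for a convex body, its widest bright
section).  The mask perimeter uses the multi-directional Crofton estimate:
naive pixel-edge counting overestimates perimeter and depresses CR, while
the Crofton estimator reproduces CR = 1 within 5% for a 0.5 μm disk at
0.1 μm pixels.  Aspect ratio comes from the eigenvalues of the
intensity-weighted central second moments (the best-fit ellipse); at least
5 pixels are required and collinear regions are not estimable.  Apparent
volume sums supra-threshold voxels × pixel² × z-spacing.

Classification: supra-threshold objects of ≥ 0.01 μm² are IBs; smaller
supra-threshold objects, and sub-threshold bodies visible in more than one
focal plane, are small particles.  Cluster-like inclusions are described
only qualitatively in the source material, so a concrete rule was
required: a supra-threshold object is a CLI if it separates into ≥ 3
watershed lobes, or has CR < 0.8 with ≥ 5 accompanying peripheral
supra-threshold objects; both cutoffs are configurable.

The chance-overlap probability between an inclusion (diameter d_ib) and a
second body (diameter d_ap) is π·((d_ib + 2·d_ap)/2)² divided by the
available cytoplasmic cross-sectional area, saturating at 1 with a
warning.

## Flux analysis

Bleach calibration fits I(c) = retention^c to a rapid-cycle series
normalised to cycle 0 (zero-intercept fit on the log scale); correction
divides measured intensities by retention^cycles.  Cycles default to one
per timepoint (whole-stack acquisition); explicit per-timepoint counts
support counting z-planes instead, since which of the two drives bleaching
in a given protocol is acquisition-dependent.  Background subtraction
precedes thresholding and integration throughout.  FRAP reports the
equivalent-circle diameter 2·√(area/π) (a single scalar "diameter" per
timepoint; axis-based measures are available through the morphometry
ellipse fit).  The shell/core statistic — mean background-subtracted
intensity in the outer 20% of the compartment radius over the core mean —
discriminates interior mixing (≈ 1) from surface accretion (≫ 1); with
shot noise it is evaluated on mid-recovery frames (averaged over
2–5 min), where recovered signal is measurable, rather than immediately
post-bleach where the ratio is noise-dominated.

The dilution prediction returns 1/dilution_factor (3.7-fold → 27%).  The
forward derivation of a dilution factor from cycle counts is not unique —
naively compounding (1 + daughter_fraction)^n_cycles with 0.7 and 2.2
gives ≈ 3.2, not 3.7 — so the factor is accepted as an input and the
compounded value is reported only as a flagged alternative derivation.

The two-pool kinetic fit uses the closed-form solution of the linear red
ODE (matrix exponential) in a least-squares fit over log-parameterised
rates, on bleach-corrected amounts (cytoplasm mean × volume, inclusion
integrated intensity).  On division-free simulated series with 2%
measurement noise it recovers k_in, k_out, k_deg within ~15% per
replicate and ~3–4% in the 20-replicate mean.

## Problem sizes and reproducibility

All stochastic entry points take an explicit integer seed; ensembles
derive per-track seeds via seed-sequence spawning, and identical seeds
give bit-identical outputs including rendered images.  The standard
analysis ensembles are 23 tracks × 300 frames (32 fps) and 8 tracks ×
300 frames (10 fps); fit-quality checks use 600-frame tracks; replicate
counts for the FRAP-discrimination and rate-recovery properties are 20.

## Known limitations

* The tracker links exactly one particle per movie; crossing particles or
  multi-target scenes are out of scope.
* No confinement-model fitting, velocity autocorrelation, or Bayesian
  motion-model selection; α alone summarises directedness.
* FRAP is modelled at compartment scale (well-mixed or shell-deposited),
  not as a reaction–diffusion PDE; no absolute molecule counts.
* The green pulse-chase channel cannot be exactly bleach-corrected in the
  presence of synthesis; only the bracketing pair is meaningful.
* Whole-cell segmentation from bright-field images is not provided; the
  cytoplasmic reference ROI is supplied by the caller (or a calibrated
  mean is used).
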