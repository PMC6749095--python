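# incluflux

Quantitative fluorescence-microscopy analysis of mobile, exchanging protein
inclusion bodies — the kind formed by polyglutamine-expanded huntingtin
exon 1 in budding yeast — built for researchers who need the full numeric
pipeline behind such a characterisation: single-particle tracking,
anomalous-diffusion analysis, inclusion morphometry, FRAP quantitation, and
photoconversion pulse-chase flux analysis.  Every stage is exercised
against a bundled, seeded synthetic-microscopy generator with ground
truth, so the whole pipeline is testable without any acquired data.

## What it computes

**Motion analysis.** For a tracked particle with positions r(t), the mean
squared displacement over lag time Δt follows

    MSD(Δt) ∝ Δt^α,        MSD(Δt) = 4·D·Δt for 2D free diffusion,

where the anomalous-diffusion exponent α is fitted as the slope of
log₁₀ MSD versus log₁₀ Δt over frame lags 1–16 (all overlapping
intervals), and the diffusion coefficient D from a zero-intercept fit of
MSD against Δt.  α ≈ 1 indicates free diffusion, α > 1 superdiffusion
(active transport), α = 2 the ballistic limit.  Small cytoplasmic
aggregates in this system diffuse with D ≈ 5.9 × 10⁻² μm²/s and α ≈ 1;
inclusion bodies move super-diffusively (α ≈ 1.2–1.4).

**Detection and tracking.** Particles are enhanced with a scale-normalised
negative Laplacian-of-Gaussian filter and linked frame-to-frame by exact
dynamic programming maximising a weighted score (intensity 80%, intensity
variation 20%, movement penalty 40%, centre penalty 0%) under a 10-px
maximum displacement.

**Morphometry.** Inclusions are segmented at 1.2× the mean cytoplasmic
intensity on the brightest z-slice; shape is summarised by the circularity
ratio CR = 4π·area/perimeter² and the best-fit-ellipse aspect ratio;
objects are classified as inclusion bodies (IBs), small particles
(supra-threshold area < 0.01 μm², or multi-plane sub-threshold bodies) or
cluster-like inclusions.

**Flux analysis.** FRAP recovery (1.4× threshold, integrated intensity =
area × mean, equivalent-circle diameter ratio, shell/core statistic
separating interior mixing from surface accretion), exponential
photobleaching calibration and correction, photoconversion pulse-chase
quantitation (1.5× union masks, per-channel normalisation), the
cell-division dilution prediction, and a two-pool kinetic fit recovering
incorporation/release/degradation rates.

## Worked example

Simulate an ensemble of 23 freely diffusing particles at 32 frames/s with
D = 0.059 μm²/s, then run the motion analysis:

```python
import numpy as np
from incluflux import (MotionModel, simulate_ensemble, compute_msd,
                       fit_alpha, classify_motion)

model = MotionModel(kind="brownian", diffusion_um2_s=0.059)
tracks = simulate_ensemble(model, n_tracks=23, n_frames=300,
                           frame_interval_s=1 / 32, seed=1)
ests = [fit_alpha(compute_msd(t, max_lag=16)) for t in tracks]
alphas = [e.alpha for e in ests]
print(f"mean alpha = {np.mean(alphas):.3f} +/- "
      f"{np.std(alphas, ddof=1)/np.sqrt(len(alphas)):.3f} (SEM)")
print(f"mean D     = {np.mean([e.D_um2_s for e in ests]):.4f} um^2/s")
print(f"worst fit  r^2 = {min(e.r_squared for e in ests):.3f}")
print(f"class of track 0: {classify_motion(ests[0]).value}")
```

prints

```
mean alpha = 0.988 +/- 0.016 (SEM)
mean D     = 0.0578 um^2/s
worst fit  r^2 = 0.994
class of track 0: diffusive
```

— the fitted exponent is statistically indistinguishable from 1 (free
diffusion), the recovered D is within a few percent of the generator's
0.059 μm²/s, and every per-track log-log fit is tight (r² > 0.98).

The same chain is available from the shell:

```sh
incluflux simulate --seed 1 --out out/   # trajectories -> tracks CSV
incluflux msd --out out/                 # per-track alpha, D, r2, class
incluflux run --seed 1 --out out/ --stages simulate,render,detect,track,msd
```

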