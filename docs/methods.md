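# Methods

## Model and estimators

A pixel of a repeatedly raster-scanned field reports photon counts F(t),
t = 0 … T−1, one sample per frame.  The generative picture is a Poisson
number of diffusing complexes occupying the effective observation volume
during each dwell, each complex carrying k labeled fluorophores that emit
ε₀·k expected counts per dwell, plus uniform Poisson background B.  The
per-pixel statistics are

    F   = ⟨F(t)⟩
    ε   = ⟨δF(t)²⟩ / F − 1
    n   = F² / (⟨δF(t)²⟩ − F)

and satisfy n·ε = F algebraically wherever n is defined.  For a single
species with stoichiometry s and labeling probability p (k ~ Binomial(s, p)),
the closed forms are

    ⟨F⟩    = B + n̄·s·p·ε₀
    Var(F) = ⟨F⟩ + ε₀²·n̄·E[k²],   E[k²] = s·p(1−p) + (s·p)²

so with no background the apparent brightness (Var−Mean)/Mean equals
ε₀·(1 + (s−1)p): ε₀ for monomers, 2ε₀ for fully labeled dimers.  Background
is handled by masking, not subtraction, so apparent brightness at dim or
background-contaminated pixels is diluted toward zero; this is a known bias
source and the reason analysis is restricted to thresholded cell pixels.

### Estimator conventions

- **Variance divisor.** The default is the unbiased sample variance
  (divisor T−1).  With the population divisor T the brightness estimator
  acquires a −(1+ε)/T bias — at T = 100 about −0.011 counts/dwell, i.e. a
  quarter of a monomer brightness — large enough to shift every
  stoichiometry low.  The population convention remains available
  (`ddof=0`) as a sensitivity switch.
- **ROI summaries.** ROI-level brightness is the pooled-moment ratio
  Σvariance/Σmean − 1 (and number analogously from pooled moments).
  Averaging per-pixel ratios instead would inherit a small-denominator bias
  at dim pixels; pooling the moments first removes it.  Per-pixel maps keep
  the classic pixelwise formulas — they are for maps and histograms, not
  for point estimation.
- **Peak statistics and smoothing.** The per-pixel brightness noise has
  SD ≈ √(2/T)·(1+ε) — about 0.15 counts/dwell at T = 100, independent of
  how bright the pixel is — and positive skew ≈ 0.5 (χ²-type variance noise
  plus Poisson kurtosis).  A Gaussian fit of the raw histogram therefore
  tracks the *mode*, which sits ~0.015 below the mean; a fitted "dimer"
  peak lands near 0.08 rather than 0.096.  When a peak (rather than mean)
  statistic is wanted, the brightness map is boxcar-averaged first
  (`smooth_box`, default 3×3 in the pipeline): averaging k² pixels shrinks
  both SD and skew by k and makes the fitted peak track the centre.  Pixel
  pooling is what makes per-pixel sN&B robust; the smoothing radius trades
  spatial resolution against peak bias.
- **Gaussian fit.** Nonlinear least squares of A·exp(−(x−μ)²/2σ²) over the
  full histogram, initialized at the modal bin with a robust width
  (IQR/1.349).  Non-convergence falls back to the modal bin centre with a
  warning flag.

### Quality control

Photobleaching is measured as the relative first-to-last decline of a
least-squares line through the frame means; stacks above 10% are rejected
(bleaching deflates the late-stack mean and inflates apparent variance).
The simulator's bleaching model is a deterministic linear ramp on the
expected signal — sufficient to exercise the rule; per-fluorophore
stochastic bleaching is out of scope.  An optional global linear detrend
exists but defaults off: bleached stacks are rejected, not repaired.

## Stoichiometry and mixtures

Subunits per complex is peak brightness / ε₀ with the free-dye calibration
(ε₀ = 0.048 ± 0.001 counts/40 μs/molecule; V_eff = 0.355 fL).  Expression is
median(F)/ε₀ in subunits per V_eff, with regimes low (< 90), physiological
[90, 600), high (≥ 600); window edges are closed-left, open-right.

Accumulated histograms pool all valid pixel brightness values from cells in
an expression window and are normalized to unit area.  The mixture model is
a sum of log-normal components parameterized by mode m and log-space SD σ
(density ∝ exp(−(ln x − ln m − σ²)²/2σ²)/x), because the anchoring is on
*peak positions*: the dimer mode is fixed at 2× and the tetramer at 4× the
monomer anchor (a log-normal fit of a monomeric dye histogram, or ε₀
directly), the larger-oligomer mode is free above the tetramer, shapes are
free in [0.05, 1.5], areas non-negative.  Fractions are component areas over
the total area (areas are analytic in this parameterization).  Fits are
unweighted least squares on the binned density (bin width ε₀/12 by default);
the fitted domain is zero-padded beyond the observed support so a component
cannot park itself outside the data at no cost.  Negative brightness values
are excluded from mixture fitting (log-normal support) but retained in maps,
per-cell histograms, and Gaussian peak fits.  If the larger-oligomer area
degenerates to zero the result is flagged as a two-component fallback.  An
optional monomer component (mode fixed at the anchor) can be enabled for
low-expression regimes.

## The synthetic-data generator

The fast tier draws, per pixel-frame, complexes N ~ Poisson(n̄) per species,
labeled subunits Binomial(N·s, p), and counts Poisson(ε₀·ΣK·ramp(t) + B).
Frames are independent — the correct limit when the frame interval (tens of
ms) far exceeds the residence time of a membrane complex in the focal volume
(ms) — and the defaults mirror the acquisition this analysis is designed
for: 40 μs dwell, 156 nm pixels, 100 frames, ε₀ = 0.048, labeling
efficiency 1.0 (SNAP-tag labeling is near-quantitative).

The diffusion tier places explicit 2-D Brownian particles on a periodic
plane, advances them once per scan row, and integrates a squared-Gaussian
two-photon profile exp(−4r²/w²) at each pixel.  Its apparent brightness
carries the Gaussian-profile shape factor (ε → ε₀/2 at matched peak rate),
which cancels in the monomer-normalized ratios the analysis reports; the
tier exists to validate the independent-frame assumption (dimers show 2×
brightness, half the particles), not for routine testing.  Diffusion-tier
validation runs use a brighter test fluorophore (ε₀ = 0.5) because the
ratios under test are brightness-invariant while their Monte-Carlo error at
desk-scale stack sizes is not.  A step-per-row larger than half the beam
waist triggers a temporal-aliasing warning.

What the simulator does **not** emulate: 3-D diffusion and axial structure,
triplet/blinking photophysics, detector afterpulsing or dead time, scanner
distortion, spatially varying background, and real cell morphology (masks
stand in for it).  Passing synthetic recovery therefore demonstrates the
estimators and fits, not robustness to these instrumental effects.

## Problem sizes for validation runs

Per-cell statistics are validated at the acquisition scale (T = 100 frames,
64×64 pixels).  Mixture-decomposition studies use cohorts of 32×32-pixel
cells with T = 8192 frames at ~120 subunits/V_eff: resolving components
spaced 2ε₀ apart requires the per-pixel brightness SE √(2/T)(1+ε) to sit
well below the spacing (at T = 100 it is ~0.16, twice the spacing, so
pixel-level decomposition is not identifiable there; at T = 8192 component
log-widths fall to ~0.18 where log-normal area allocation is unbiased).
Dimer-doubling checks pool 12 replicate stacks per condition so the
Monte-Carlo SE of the peak ratio (~0.04 after pooling) is small against the
effect.  The brightness-oracle grid spans s ∈ {1,2,4}, p ∈ {0.5,1},
n̄ ∈ {1,10} with block-resampled standard errors.

## Design choices on genuinely open points

- Component widths in the mixture are free per component (shared or
  noise-law-tied widths were evaluated and not needed once components are
  resolvable).
- The Gaussian peak is fitted over the full histogram; restricted windows
  were evaluated and track the mode no better while being less stable.
- Expression matching in the cluster comparison uses intensity deciles of
  the analysis mask; "inside" means components of at least `min_size = 4`
  pixels at 8-connectivity, and selected-but-unclustered pixels count as
  outside, which is what makes an expression-matched outside population
  exist at all when the selection is exactly the top decile.
- TR-FRET shading correction divides by a rolling-ball background estimate
  and rescales to preserve the image mean; the ball radius (default 50 px)
  couples spatial and intensity scales, so smaller radii follow smoother
  shading more closely.  Bleedthrough is a per-setup scalar (6% default),
  never estimated from the data being corrected.

## Known limitations

- Background is masked, not subtracted: brightness near the threshold is
  biased low; choose thresholds generously.
- The Gaussian-peak statistic without smoothing is mode-tracking and biased
  low by ~0.3 subunits at T = 100; use `smooth_box ≥ 3` (default) or the
  pooled ROI brightness for unbiased point estimates.
- The per-pixel number map is extremely noisy whenever the variance excess
  is small compared to its own sampling noise; only pooled ROI numbers are
  quantitative.
- Mixture decomposition assumes species segregate between cells/pixels; a
  pixel containing a true mixture of species reports one intermediate
  brightness, which the fit will attribute to the nearest components.
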