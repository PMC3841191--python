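# Methods

This note records the models, conventions and numerical choices behind
`biofilmscape`, and what the synthetic experiments can and cannot show.

## Texture quantification (SGLDM)

A spatial gray level dependence matrix for offset *(d, θ)* counts ordered
gray-level pairs *(i, j)* of pixels separated by *d* columns (θ = 0°) or by
*(−d, +d)* in (row, column) (θ = 45°, the up-right diagonal).  Conventions:

* Full 8-bit depth: 256 × 256 matrices, no gray-level quantization.  This is
  required for the *(f₆/2) − 1 = mean gray* identity to hold exactly.
* Only pairs entirely inside the image count; no padding.  Each unordered
  pair is counted in both directions, so *p = pᵀ* and Σp = 1.
* On the diagonal the per-axis offset is *d* pixels (physical separation
  *d·s·√2* at pixel size *s*), but the distance *label* uses the per-axis
  pixel count: label = round-to-nearest-10(d · s).  At s = 2.92 µm the
  default menu d ∈ {10, 20, …, 100, 200, 250, 300, 350, 400} labels as
  30–1170 µm.
* Descriptor formulas use 1-based gray indices (value + 1), natural
  logarithms, and 0·log 0 ≡ 0.

The 15-descriptor registry defaults to Haralick f₁–f₁₄ plus the maximal
probability, and is swappable (any mapping name → function of the matrix).
Two conventions worth noting: sum variance (f₇) is computed about the sum
average f₆ (the common reading of the original formula, whose printed
self-reference to f₈ is a known erratum), and the maximal correlation
coefficient (f₁₄) is the second-largest singular value of
*p(i,j)/√(pₓ(i)pₓ(j))* restricted to occupied gray levels — numerically
stabler than the eigendecomposition of the non-symmetric Q matrix.
Degenerate matrices (one occupied gray level) leave f₃, f₁₂–f₁₄ undefined;
they carry NaN plus a flag and are excluded per key when averaging over
locations, and dropped (with a log message) before PCA if unusable in every
sample.  Feature keys are ordered illumination (transmitted, oblique) ×
angle (0°, 45°) × distance (menu order) × descriptor (f₁…f₁₅): 900 entries
under the defaults.

## Fingerprint processing

Alignment maps scan positions onto the ladder's size coordinate by a
piecewise-linear monotone interpolant through the detected standard peaks
(end segments extrapolate linearly).  Resampling onto the common grid goes
through the cumulative integral — per-grid-bin mass is the difference of
the interpolated cumulative at bin edges — so total signal mass is
conserved exactly up to edge interpolation, rather than approximately as
with naive point interpolation.  Normalization subtracts a rolling-minimum
baseline (window 101 grid points ≈ 45 size units by default), clips
negatives, and scales to unit sum.

−log Simpson diversity is computed on the aligned, *unbinned* profile,
treating every grid point as an abundance unit: λ = Σᵢ pᵢ², D = −ln λ.  A
peak-based variant (λ over relative peak areas) is available and is the
form that matches species-level closed forms through the renderer; the
grid-point form additionally reflects peak width and is the default for
time series.

Peak calling: local maxima above `min_height_frac` × profile maximum
(default 0.05) separated by `min_separation` (default 6 size units);
areas integrate trapezoidally between flanking minima and are reported
relative to the per-sample total.  Binning is single-linkage clustering of
peak positions cut at `tolerance` (default 3 size units): positions chain —
100, 100.4, 100.8 at tolerance 0.5 form one bin.  This automates the
"semi-automated" curation step; bin assignments are exportable for manual
review.

## Raup–Crick null model

For samples with presence sets A, B from a pool of every bin ever observed,
the statistic ranks the observed shared-bin count SS against `n_reps`
(default 9 999) random pairs that preserve each sample's richness and draw
bins with probability proportional to occupancy (uniform optional):

    rc = 2·[(#{SSnull > SSobs} + ½·#{SSnull = SSobs}) / n_reps] − 1

Ties count half — this makes two full-pool communities score exactly 0 —
and rc < −0.95 / > 0.95 mark significant similarity / dissimilarity.  Null
draws use the Gumbel top-k construction (add Gumbel noise to log-weights,
take the k largest), which is exactly successive weighted sampling without
replacement and vectorizes over replicates.

## Ordination

PCA standardizes columns (mean 0, unit variance, ddof = 1) and
eigendecomposes via SVD; variance fractions are eigenvalues over the number
of retained variables (the correlation-matrix total).  Constant or
NaN-containing columns are dropped and logged, not jittered.  PCoA applies
Gower double-centering −½·J·D²·J and keeps positive-eigenvalue axes;
variance fractions are relative to the positive spectrum, negative
eigenvalue mass is reported, and no Cailliez/Lingoes correction is applied.
The community distance is the quantitative Jaccard (Ružička) form
D = 2B/(1+B) on Bray–Curtis B; all-zero sample pairs get D = 0 with a
warning.  Because ordination signs are arbitrary, `orient_axis` pins them:
by default the transmitted-illumination entropy loading is made negative on
PC1 (complex morphology = negative PC1, an inverted axis when plotted) and
the highest-diversity sample positive on PCoA1.  Tables from replicate
experiments can be concatenated with a run label and ordinated jointly so
scores are comparable across runs.

## Time-series layer

Sampling is irregular (72 h weekend gaps), so everything works in real
days.  Morphology–community regressions match PC1 and PCoA1 by exact day
equality (both derive from the same coupon) and restrict to the treatment
window; OLS with the two-sided slope p-value.  Recovery metrics take the
last pre-pulse sample as reference: drop = reference − first post-pulse
value; recovery time = first sampling time back within ε of the reference
on the departed side, flagged incomplete if the next pulse arrives first.
ε is a user parameter (the pipeline default is 0.2 × the series range) —
recovery is not quantified more finely than that by design.  The dominant
period linearly interpolates to a uniform grid (median sampling interval),
detrends, and takes the strongest periodogram ordinate; Fisher's exact
g-test (closed-form null for the maximum periodogram share of white noise)
must reject at α = 0.05 before a period is reported, otherwise the series
is flagged "no dominant period".  Interpolation-to-grid is an approximation
for gapped series; with ≤ 2-day gaps and weekly signals the period error
stays below one sampling step.

## Synthetic experiments

The generator emulates the statistical structure the analysis assumes:

* **Images**: biomass field = base film (0.15) + round(c·n_max) Gaussian
  bumps (amplitudes 0.25–0.7, widths 8–40 px, n_max = 40) + smoothed noise
  (sd 0.02); transmitted = 255·(1 − biomass), oblique = 0.85·255·biomass,
  both clipped to 8 bits.  All bump parameters are drawn before truncating
  to the first round(c·n_max), so at fixed seed the transmitted mean gray
  decreases strictly with complexity c.
* **Profiles**: a fixed pool of S = 20 species at geometric abundances
  aᵢ ∝ k^(i−1) with ratio k = 0.85 (peak-rich, fairly even — the complex
  end of the community spectrum), rendered as Gaussian peaks (width 3 size
  units) on a 3000-point scan axis with a per-sample migration shift
  (sd 20 scan units) and a mildly nonlinear size→scan map, plus a 10-step
  synthetic ladder channel; constant-plus-slow-wave baseline and white
  noise (0.4 % of peak height).  The ladder makes alignment a real,
  testable operation rather than a pass-through.
* **Disturbance series**: at a pulse the dominant member's share jumps to
  ρ = 0.6 (the rest rescale), and latent morphological complexity drops by
  the factor 0.7; both relax exponentially with τ = 2 d toward the
  undisturbed state.  The presence set never changes — disturbance shifts
  abundances only (a composition-churn mode exists but is off by default).
  Morphology and community share one relaxation clock so their correlation
  is plantable; rendering noise is the only decoupling.  ρ and τ are
  testability choices, labelled synthetic: no field values exist for them.

With ρ = 0.6 a pulse leaves most members above the 5 % detection threshold
(richness drops from ~20 to ~6–8, recovering over days), so consecutive
samples share mid-sized presence sets from a much larger pool — the regime
in which Raup–Crick similarity becomes significant.  Weekly pulses with
τ = 2 d recover within the interval (resilient oscillation at 7 d); daily
pulses hold the system at its disturbed state (monotone non-increasing
diversity envelope, no resolvable period at the sampling frequency).

What passing tests do **not** show about real data: the image renderer has
no optics (no illumination calibration, shading, protist motion, or depth
effects), the profile renderer has no PCR/electrophoresis artifacts beyond
a rigid migration shift, and real communities change composition as well as
abundance.  Headline variance percentages from the original experiments are
not reproducible from synthetic data; the pipeline's configuration
exactness (900 variables, distance labels, field-of-view arithmetic) and
its statistical machinery (oracle-checked SGLDM/descriptors, enumerated
Raup–Crick, closed-form diversity, PCoA reconstruction) are.

## Problem sizes and defaults

Simulated pipeline runs use 512 × 384 px images, 2 locations per sample and
a 15-distance menu capped at 350 px (the full-frame 15-distance menu to
400 px applies to ≥ 512 × 512 images; an offset must fit inside the image
in both axes at 45°).  Averaging is location-count-agnostic — the 14
locations of the full acquisition protocol are exercised with synthetic
vectors in tests.  Time series default to daily sampling over 56 days with
treatment from day 21 (5 weekly or 15 daily pulses).  A single master seed
drives every stochastic stage through per-stage derived seeds (CRC32 of the
stage name XOR the master, < 2³¹), so runs are bit-reproducible.
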