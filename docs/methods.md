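# Methods

This note documents the models, estimators and numerical choices behind
each stage of the pipeline, and what the synthetic-data tests do and do
not establish about real data.

## Densitometry

A band's content is its *signal mass*: the summed intensity inside a
rectangle enclosing the band minus the mean of a nearby background
rectangle times the band-rectangle area. Backgrounds are plain arithmetic
means — no rolling-ball or morphological estimate — because the
quantity of interest is a local pedestal under the band, and the mean is
unbiased for it. Negative masses are reported and flagged, never clamped:
silent clamping at zero would bias group means of weakly expressed
proteins upward.

The normalization factor for loading is computed on the source gel: the
mean total-protein signal over a large lane rectangle above its own
background, optionally excluding the molecular-weight interval of the
proteins under study (the exclusion improves sensitivity slightly because
a regulated protein would otherwise contribute to its own denominator).
Contents are band mass ÷ lane factor, in arbitrary units; 8/12/16-bit
scans are processed on their native scales. Whether the blot background
is taken per lane or globally is a free choice; the implementation is
per-lane (each band carries its own background rectangle), with nothing
preventing a shared rectangle.

Exact properties enforced by tests: additivity over ROI splits, invariance
to a constant offset of the whole image, loading invariance of normalized
contents (≤ 2%), and linearity of content vs amount (r > 0.999 on
noiseless ladders).

## Stack restoration

**Order.** Background subtraction → spectral unmixing → deconvolution.
Provenance flags on the stack enforce the order; running steps out of
order raises.

**Background** is a per-channel scalar, estimated as the mode of the
intensity histogram (most voxels in an immunostained fiber stack are
background). A low percentile would be biased low by one-to-two counts
under Poisson noise. Subtraction clips negatives by default; the
bleed-through estimator should be fed unclipped residuals
(`clip_negatives=False`), since clipping biases a slope through the
origin upward.

**Unmixing** inverts the two-channel linear model exactly; the forward
model applied to the (pre-clipping) solution reproduces the input to
machine precision. Negatives produced under noise are clipped and the
clipped fraction reported; above 5% a warning marks the coefficients as
suspect. Coefficients can be estimated from single-marker acquisitions as
the origin-constrained slope of the absent channel against the present
one over the brightest 5% of voxels.

**Deconvolution** is Richardson–Lucy with the non-negativity constraint,
run on the full 3-D stack; a Van Cittert iteration with clipping is
available behind a flag. Defaults: 50 iterations, early stop when the
relative change per iteration falls below 1e-4. The PSF is either
measured (any non-negative kernel) or a separable Gaussian surrogate
parameterized by (σx, σy, σz) in nm; ~0.25 µm and ~0.1 µm lateral
resolutions correspond to σxy ≈ 106 and 42 nm.

Boundary handling matters for flux accounting. Two models are provided:
`reflect` (default) mirrors the field by one PSF support and crops back;
`wrap` performs true circular convolution via FFT. Richardson–Lucy
conserves integrated intensity exactly on its computational domain, so
conservation of the *cropped* result holds to ≲ 0.01% for compact
structures away from edges (reflect) and exactly for periodic fields
holding whole sarcomere repeats (wrap). Structure blurred across the crop
border under `reflect` can shift a few percent of flux into or out of the
field — a property of any windowed deconvolution, documented rather than
hidden. The restoration tests verify re-resolution of a 240 nm
terminal-cisternae doublet from a 110 nm-σ blur (the blurred input has no
central dip; the restored doublet is bimodal with > 2:1 peak-to-saddle
contrast and the correct 240 nm spacing).

## Apo-form derivation and profiles

F_GPb = F_GP − (B/C)·F′_GPa, computed pixel-wise with negatives clipped
and the clipped fraction reported. B and C (the two antibodies'
proportionality constants) are not separately identifiable; only their
ratio is used.

"Removing the shoulder" is operationalized as: the largest B/C on a
0.01-step grid over (0, 1.5] for which at most q = 1% of the evaluation
samples of F_GP − (B/C)·F′_GPa are negative, evaluated where the phospho
image carries appreciable signal (above its median positive value). By
default the criterion is applied to **y-averaged profiles**, where the
shoulder is actually judged and where photon noise is averaged out;
pixel-level evaluation (available via `use_profiles=False`) is noisier
and biases the estimate low by up to ~30% at realistic photon counts,
versus ≤ 10% error for the profile criterion. An alternative estimator —
minimize the absolute correlation between the derived image and the
phospho image over the shoulder support — is selectable (`mincorr`).
B/C is treated per-image; estimates outside the plausible 0.2–0.8 range
are flagged, not rejected. The scale is identifiable only where the
phospho form has signal free of apo-form overlap; with strongly
overlapping distributions the non-negativity criterion carries an
irreducible positive bias equal to the minimum apo/phospho intensity
ratio on the support, which is why the recovery fixtures contain a clean
shoulder.

Profiles are means over (masked) y at each x with fibers aligned to x;
masked-out columns are interpolated and reported. The striation period is
detected from the first autocorrelation peak with parabolic sub-pixel
refinement. FWHM is measured per peak at half of (peak − baseline) with
linear interpolation between samples, baseline = 1st percentile of the
profile, then averaged over sarcomere repeats (mean ± SEM). Because the
baseline is taken from the profile itself, overlapping tails of
neighbouring repeats raise the floor and narrow the measurable width;
band motifs in the generator are therefore calibrated numerically
(bisection on σ) so the rendered periodic profile *measures* the
requested FWHM. Wide bands (e.g. 1.26 µm) are exercised at a 3.0 µm
sarcomere period — moderately stretched fibers — where the periodic
overlap is small and the two band widths (1.26 vs 0.85 µm) remain
morphologically distinct.

## Colocalization

Objects are connected components above an Otsu threshold (parameter-free
default; a percentile threshold is the fallback), size-filtered at
4 voxels. Centers are intensity-weighted centroids converted to nm with
the anisotropic voxel sizes (dxy, dxy, dz), so a one-z-plane offset reads
as 120 nm, not "1 pixel". Nearest-center distances are computed with a
KD-tree in both directions (a→b and b→a; the measure is not symmetric and
the direction used in any published summary is a reporting choice).
Pearson and Manders M1/M2 coefficients and a sub-pixel cross-correlation
shift (parabolic interpolation of the CCF peak; half-period ambiguity of
periodic profiles is detected and flagged) complement the object-based
measure. No randomization-based significance test is provided.

## Cohort statistics

Test selection follows the gate: Shapiro–Wilk on both groups AND a
median-centered (Brown–Forsythe-type) Levene test, each at α = 0.05 →
two-sample t-test with pooled variance; otherwise Mann–Whitney u. All
p-values are two-tailed and reported raw (an optional Benjamini–Hochberg
adjustment is a column, not a replacement). Under normal 13/12 null data
the procedure's type-I error stays within [0.035, 0.065], and its power
at a 1-SD shift matches the closed-form t-test power.

Correlation significance uses t = r√(n−2)/√(1−r²) with n−2 df. The
printed form of this statistic is typographically ambiguous (√n vs
√(n−2)); the n−2 convention is the one consistent with the stated degrees
of freedom and reproduces the published p = 0.002 at r = 0.58, n = 25,
so it is the default, with the literal √n variant behind
`df_convention="n"`. The Fisher alternative v = √(n−3)·artanh(r) is
standard-normal under the null. The two agree within a factor of 1.5
wherever p ≳ 1e-3; deep in the tails the *ratio* of any two tail
approximations diverges even as both vanish, so no factor bound holds
there.

Variance decomposition of the nested replicate design (lanes within
patients, repeated evaluations within lanes) is a simple ANOVA in
fractional units: technical = pooled within-lane mean square ÷ squared
patient mean; the lane component is MS(lane means) − technical/n_reps
(unbiased); total = lane + technical. The irreducible part (total −
technical) yields the SD of a single determination, the 2-SD threshold
(in %) below which individual differences are not interpretable, and the
probable error of an n-patient mean (threshold/√n, n = 13 by default).

Multivariate regression is OLS (listwise deletion, exact-collinear
predictors dropped with a warning), reporting the multivariate r = √R²,
the overall F and its p, and per-coefficient SE/t/p. "Direct" mode (one
independent variable, many responses) is a list of simple fits; "inverse"
mode is the joint fit.

MC/MN subgroups: patients ranked by the sum of within-cohort ranks of
microsomal phosphorylase-kinase and phosphorylase content; MC = top k
among MHS, MN = bottom k overall with non-MHN members flagged; ties break
by patient id. Under the default generator conditions the bottom-6 group
is pure MHN in roughly three quarters of simulated cohorts — strong
enrichment over the ~1% expected by chance, but not a deterministic
outcome at n = 25.

## Synthetic data

The generators emulate the study's three input classes at its stated
conditions and expose full ground truth.

**Fiber stacks.** A periodic 1-D sarcomere motif along the fiber axis —
Z-line spike, I-band band, terminal-cisternae doublet (default 200 nm
intra-doublet separation, a modeling choice: resolvable at the ~100 nm
target resolution), scattered 3-D clusters — extruded across the fiber,
convolved with the Gaussian PSF surrogate, channel-mixed with the
bleed-through coefficients, offset by a photon background and corrupted
with Poisson plus Gaussian read noise. Default acquisition geometry: 20
planes at 120 nm z spacing and 36 nm pixels (40 nm in some fixtures so
whole sarcomere repeats tile the field exactly, making the periodic
boundary model exact). Defaults of 2.0 µm resting sarcomere length,
photons-per-voxel amplitudes of tens of counts and a background of 10
counts are typical of averaged confocal immunofluorescence.

**Gels and blots.** Bands are separable (Gaussian along the
molecular-weight axis × flat-top lane profile), normalized so the
integrated blur-free band signal equals amplitude × loading factor. The
gel carries a fixed many-band total-protein pattern scaled by loading;
the blot carries the single target band. Additive background (optional
gradient), Gaussian blur and read noise complete the forward model.

**Cohorts.** Contents are log-normal — strictly positive and
right-skewed, as the group mean/median gaps in the study's summary table
imply — with group-specific medians taken from that table and dispersions
derived from the group SEMs at n = 13/12. Correlations are imposed by a
Gaussian copula whose target Pearson matrix is mapped analytically to
latent-normal correlations (exact bivariate log-normal moment formulas).
The published pairwise correlation matrix is **not positive
semi-definite** (smallest eigenvalue ≈ −0.15), as matrices assembled from
pairwise estimates with varying n often are; the latent matrix is
repaired by eigenvalue clipping and `effective_correlation_targets()`
returns the matrix the generated data actually converge to. Latent draws
are whitened and re-colored (as in MASS `mvrnorm(empirical=TRUE)`) so the
imposed latent correlation is exact at finite n; without this, Pearson
sampling noise of heavy-tailed log-normal marginals alone exceeds the
recovery tolerance used in testing. Phosphorylation ratios are derived
columns (GPa/GP); fasting blood sugar is linear in the whole-muscle ratio
(intercept 4.2 mM, slope 2.5 mM per unit ratio, noise SD 0.7 mM); age and
BMI are clipped normals.

**Replicate tables.** value = patient mean × (1 + lane_cv·ε) ×
(1 + tech_cv·η) with standard-normal ε per lane and η per evaluation;
defaults lane_cv = 0.165, tech_cv = 0.051, 4 patients × 3 lanes ×
5 evaluations, matching the measured variance regime (total ≈ 0.030,
technical ≈ 0.0026).

**What passing tests do not show.** The fiber generator has no spherical
aberration, depth-dependent PSF, fixation artifacts or staining
heterogeneity, and its motifs are y/z-uniform, so restoration results on
real, structurally disordered tissue will be noisier than the fixtures
suggest. The cohort generator reproduces marginals and pairwise
correlations, not the unknown joint distribution; subgroup and regression
results transfer only to the extent the log-normal/copula family is
adequate. Gel fixtures have rectangular lanes and Gaussian bands; real
scans have smile, streaks and saturation that the densitometry does not
model.

## Problem sizes in routine runs

Tests and the acceptance script use stacks of ≈ 24×24×(150–250) voxels,
50–60 deconvolution iterations, 2000-replicate null simulations for the
type-I rate, 100–200 simulated cohorts for subgroup/regression
frequencies, and n = 10⁴ single-group cohorts for correlation-matrix
recovery — sizes at which every estimator is well into its asymptotic
regime while the full suite runs in well under a minute.
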