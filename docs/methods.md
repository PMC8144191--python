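# Methods

`azquant` quantifies fluorescence-microscopy readouts of protein
liquid–liquid phase separation and presynaptic active-zone composition:
condensate segmentation and fusion/fission dynamics, FRAP recovery, STED
side-view synapse line profiles, confocal synaptic ROI intensities, and the
statistical comparisons applied to all of them. Because the corresponding
raw imaging data are not public, the package pairs every analysis stage
with a synthetic generator whose ground truth is recorded exactly; the test
suite and the reproducibility script close the loop generator → analysis →
truth.

## Synthetic forward model

All generators share one forward model (`azquant.synth.scene`): ideal
geometry is rasterised at pixel centres (0-based indices; physical position
= index × pixel size), convolved with an isotropic Gaussian PSF, summed
with a constant background, and noise is applied last — Poisson on the
expected counts or additive Gaussian. Defaults: 90 nm PSF sigma for
confocal-like scenes, 30 nm for STED-like scenes sampled at 22.5 nm/px.
Neither the PSF width nor the background levels of the original experiments
are published; these are declared defaults, not inferred values. Identical
spec + seed gives bit-identical output.

What the generators deliberately do not model: 3-D structure, coalescence
hydrodynamics (the post-fusion shape is a constant-area ellipse whose
aspect ratio follows the exponential law exactly), camera gain/offset,
chromatic misregistration, and spatial heterogeneity of the cytosol.
Passing closed-loop tests therefore demonstrates that the measurement
chain is correct and unbiased under the stated image-formation model, not
that it is robust to every artefact of real microscopy.

### Droplet movies

Droplets are uniform disks (radius, intensity, birth/death frame, optional
linear drift). A fusion event consumes two parents at frame *f*: the
product conserves area (π(r₁² + r₂²)), starts with aspect ratio
AR₀ = (r₁ + r₂)/max(r₁, r₂) — the bounding geometry of the touching
parents — and relaxes as

    AR(t) = AR∞ + (AR₀ − AR∞) · exp(−t/τ),

with the long axis along the pre-fusion axis and the centre at the
area-weighted parent centroid. `child_death_frame` plants products that
dissolve early (used to probe the stability rule). Fissions are planted by
ending a parent and starting two offspring on the next frame. Ground truth
records analytic centroid/area/AR per frame; droplets that would not fit
inside the image after the blur margin are rejected, and unintended
overlaps of non-fusing droplets are recorded as warnings.

### FRAP traces

A trace is a flat baseline, then per bleach a drop to
`bleach_floor_fraction` × the pre-bleach level followed by
F(t) = floor + A·(1 − exp(−k·t)). After the first bleach only the mobile
fraction of the lost signal recovers (A = mobile_fraction × (pre − floor));
after a second bleach the remaining pool is fully mobile and recovers
toward the pre-second-bleach level. The default rate is k = ln 2 / 16.1 s⁻¹
(the measured condensate recovery half-time) with a 40% mobile pool and two
baseline frames, matching the double-bleach protocol the analysis targets.

### Side-view synapses

Three channels along a profile axis **u** (positive pointing away from the
vesicle cloud): a broad isotropic Gaussian vesicle cloud (FWHM > 300 nm,
default 400 nm) whose centre lies one half-width behind the marker; an
anisotropic Gaussian marker bar (default 500 × 100 nm FWHM) at the image
centre, elongated perpendicular to **u**; and an isotropic protein peak at
a signed offset along **u**, plus optional decoy peaks. The analytic
profile generator (`simulate_sideview_profile`) produces the same 1-D
signal in closed form for fast randomized checks.

### Confocal punctum fields

Channel 0 holds uniform-intensity marker disks (the ROI definition
channel), channel 1 the protein disks with per-punctum means on an optional
background field (constant or a callable evaluated on the pixel grid).
Puncta are placed uniformly without overlap with bounded retries. The
cohort helper plants per-group intensity ratios across cultures with
optional per-culture scaling and per-punctum variability.

## Analysis stages

### Condensate segmentation and dynamics

"Automatic thresholding" is Otsu's method by default (IsoData and fixed
thresholds are config options — the original Fiji analysis does not state
its method, so the choice is exposed and echoed into outputs). Components
use 8-connectivity; the minimum-diameter filter (default 1 µm) uses the
equivalent diameter from area, 2√(A/π), which matches particle-analysis
size semantics; a constant frame yields an empty result rather than an
error. Droplet-positive classification additionally requires sphericity,
AR ≤ 1.5 by default (the original count was manual; the cutoff is
configurable and reported). AR is the fitted-ellipse major/minor axis
ratio, ≥ 1 by construction; a one-pixel object gets AR = 1 and a
zero-minor-axis object AR = ∞.

Tracking is greedy nearest-centroid linking under a maximum link distance
(default 500 nm/frame; the original study tracked by eye). Equal-distance
ties break toward the lower object id. Two tracks converging on one object
end there, the product starts a new track, and a candidate fusion is
recorded; a track that both continues and spawns an extra nearby object is
ended symmetrically as a candidate fission. Note the link radius must
cover the jump from parent centroid to product centroid (≈ one parent
radius), so fusion-bearing movies need a radius of roughly the droplet
radius plus half the pre-fusion gap — the drivers use 900–1200 nm.

A candidate fusion is confirmed when the product persists ≥ 30 s (the
stability criterion of the original definition) and is at least as large
as each parent; fission is the mirror image. Event frames are the first
product frame.

The relaxation fit is unweighted least squares of
AR(t) = AR∞ + (AR₀ − AR∞)·exp(−t/τ) with t = 0 at the first sample,
initialised at AR₀ = first value, AR∞ = last value, τ = span/3, and τ
bounded positive. AR∞ is deliberately unconstrained — the published
empirical fit itself has AR∞ = 0.93 < 1 — but a sub-unity asymptote is
flagged. Fewer than 4 points is an error; a constant series returns a
degenerate-flagged result; non-convergence returns rss = ∞.

### FRAP

Traces are normalised to the mean of one or two pre-bleach frames.
Segments run from each bleach frame to the next bleach (or trace end);
bleaches are declared or auto-detected as the largest single-frame drops
exceeding 3× a robust (MAD-based) estimate of frame-to-frame variation.
Per segment: floor = first post-bleach value; amplitude = max − floor
(optional 3-frame smoothing, off by default); t½ = first time the trace
reaches floor + amplitude/2, linearly interpolated between frames (the
protocol is silent on interpolation, so the frame-resolution value is
reported alongside); the recovered fraction uses the baseline as reference
for the first segment and the last pre-bleach sample for later segments,
which makes a fully mobile remainder recover to fraction 1 after a second
bleach. The mobile fraction is amplitude/(reference − floor). Whether the
published ~40% plateau was read at the last frame or as the maximum is
unstated: both are reported (`max_recovered_fraction`, `final_fraction`).
A single-exponential fit (floor + A(1 − e^(−kt))) cross-checks the
nonparametric t½ via ln 2/k. No acquisition-photobleaching correction is
applied (none was applied originally).

Because the measured maximum of a finite segment sits below the asymptotic
plateau, t½ read from the segment maximum is biased slightly early; the
bias is < 1 frame once k·T ≳ 6, which sets the trace lengths used in the
validation studies.

### STED side-view profiles

Qualification of a candidate side view requires (a) vesicle-cloud FWHM
along the profile > 300 nm, (b) marker elongation ≥ 2 with the major axis
perpendicular to the profile within 30°, and (c) the marker centroid at
the cloud edge, 25–100% of the cloud half-width from the cloud centre.
The original selection was by eye; these thresholds are explicit
configuration.

Profiles are 1 µm long × 250 nm wide by default, sampled at pixel pitch
with bilinear interpolation and width-averaged. Smoothing is a centred
5-pixel moving average with shrinking edge windows (verified exactly
against a brute-force oracle). The marker peak is the argmax of the
smoothed marker profile (flat-top ties break toward the vesicle cloud);
the protein peak is the maximum of the smoothed protein profile within
±100 nm of the marker peak, ties breaking toward the marker. Whether the
window applies to smoothed or raw protein profiles is unstated; smoothed
is the default and the raw value at the chosen position is also reported.
No sub-pixel refinement is performed (peaks are reported at the 22.5-nm
pixel level, as in the original measurement). Density segmentation
thresholds, labels, and retains objects of 0.04–0.4 µm² without shape or
orientation criteria. PMA responses are expressed as percent of the
per-culture −PMA mean.

### Confocal synaptic intensities

Local background is a circular mean filter of diameter 1.4 µm subtracted
and clipped at zero — the named plugin says "rolling average", read here
as a mean filter; a morphological rolling-ball alternative sits behind a
flag. The mean filter includes an object's own pixels in its window, so a
punctum loses a fraction of its intensity roughly equal to its area share
of the footprint; this bias is multiplicative and cancels in
control-normalised ratios, which is what the pipeline reports. ROIs come
from the vesicle-marker channel (threshold → 8-connected components →
area filter, default 0.1–3 µm², configurable and logged; touching puncta
merge — no watershed, as the original is silent). Per-image values are
means over ROI means, normalised to the per-culture control mean.
Colocalization is plain Pearson correlation over a stated mask (Costes
thresholding is out of scope and the result is labelled accordingly);
zero variance yields NaN with a warning.

### Statistics

Normality (Shapiro–Wilk, per group) and variance homogeneity (Levene,
median-centred Brown–Forsythe variant) gate the test choice at α = 0.05
(the gating alpha is not stated in the original methods; 0.05 is assumed
and configurable): parametric (t-test / one-way ANOVA) when all pass,
otherwise Mann–Whitney U / Kruskal–Wallis. Groups with n < 3 or zero
variance force the nonparametric branch, flagged. All tests are two-sided.
Post hoc: Tukey–Kramer (parametric) or pairwise Mann–Whitney with Holm
step-down correction (nonparametric); adjustment always spans all pairs,
and a reference group only filters which rows are marked reported. Holm
is implemented as sort → scale by (m − rank) → running max → cap → unsort
and is verified exactly against both a brute-force oracle and
statsmodels. A chi-square goodness-of-fit against an expected ratio
covers survival-ratio checks.

## Validation studies and problem sizes

`azquant.validation` packages the closed-loop studies used by
`tests/test_acceptance.py` and `scripts/acceptance.py`:

- Relaxation: 15 noiseless fits over τ ∈ {3…15} s, AR∞ ∈ {0.93, 1.0, 1.1},
  amplitude 1.48 (the published-fit regime), plus 50 noisy fits (sd 0.05).
- FRAP: k ∈ {0.02…0.2} s⁻¹ × mobile fraction ∈ {0.2…1.0}, trace lengths
  scaled so k·T ≥ 6 per segment.
- STED: 100 rendered synapses with offsets uniform in ±90 nm; 1000
  analytic profiles with brighter out-of-window decoys.
- Segmentation: 250 condensate scenes + 250 density scenes, noiseless,
  object sizes ≥ 2 px clear of the cutoffs (exact-count regime).
- Events: 100 movies (stable fusion / sub-threshold fusion / fission).
- Oracle equivalence: 1000 random cases each for smoothing, Holm, and
  ROI counting.
- Cohort: 3 cultures × 2 groups × 5 images with a 0.65× planted ratio,
  and a 2000-rep Gaussian null (n = 15/group) for the pipeline's type-I
  error.

These sizes were chosen as the smallest that make the exactness claims
meaningful; each study runs in seconds on one CPU.

## Known limitations

- Segmentation exactness holds in the noiseless, well-separated regime;
  with blur and noise, counts near the size cutoffs depend on the
  threshold method, which is therefore always echoed into outputs.
- The tracker is greedy and single-hypothesis; it is adequate for sparse,
  slowly moving condensates but not for dense or fast scenes.
- The FRAP model is a single exponential (molecular exchange limited);
  no reaction–diffusion modelling or spatial recovery profiles.
- Peak positions are pixel-quantised; sub-pixel localization error on a
  single synapse can reach half a pixel by construction.
- The mean-filter background subtraction attenuates objects by their
  footprint share (see above); absolute intensities are biased low even
  though normalised ratios are not.
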