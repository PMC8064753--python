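# Methods

`granulekit` quantifies the condensation state of RNP-granule components in
single-plane confocal images of neuronal cell bodies, together with the
measurements that surround that readout in a typical granule-remodeling
study: granule counts per field, object-based RNA–granule colocalization,
GCaMP ΔF/F traces and dose–response endpoints, nascent-translation foci
time courses, replicate-aware statistics, and a co-IP interactor filter.
Because such studies rarely deposit raw microscopy, the package ships a
synthetic-field generator with complete ground truth; every quantitative
claim the test suite makes is a property of the pipeline measured against
that ground truth.

## The synthetic scene

A field is a 2D grid (default 256×256 px at 0.043 µm/px, the Airyscan-class
pixel size of the emulated acquisitions) composed of:

- **Somata**: disks of cytoplasm (default level 200) with dark nuclear
  voids (background level, default 40), so each cell's cytoplasm appears
  as a bright ring around its nucleus. The default scene packs six
  overlapping somata so that **cytoplasm is the majority phase** of the
  field. This is not cosmetic: the cytoplasm-mask procedure below
  thresholds a σ=8-blurred image at its global mean, and the mask boundary
  falls on the cytoplasm side of every intensity edge only when the
  cytoplasm covers more than half the field. Packed somata match the
  crowded cell-body fields this analysis is designed for and make the
  cytoplasm estimate unbiased; sparse scenes (a single thin ring on empty
  background) bias the cytoplasm mean low and the coefficients high.
- **Granules**: isotropic 2D Gaussians (σ default 1.5 raw px, matching
  100–200 nm near-diffraction-limited puncta; no optics are modeled)
  added on top of the cytoplasm. A granule of amplitude A has true
  partition coefficient (cytoplasm + A)/cytoplasm. Default amplitudes are
  drawn uniformly from 150–450, spanning coefficients 1.75–3.25 — the
  magnitude somatic granules span. Centers are integer pixels ≥ 6 px
  apart.
- **Noise**: optional additive Gaussian noise and Poisson shot noise (via
  a gain factor); both off by default so unit tests are exact. Values are
  clipped (not wrapped) at the declared bit depth, matching camera
  saturation.

Absolute intensity levels are free parameters chosen for detector
testability: only ratios of them are ever reported, and the emulated
acquisitions publish no raw-intensity statistics.

Time-lapses share one cell geometry; after a stimulus frame every
granule's amplitude follows ρ(t) = ρ_f + (ρ_0 − ρ_f)·exp(−k·(t − t_stim)),
the exponential decondensation law, exactly in the noise-free ground
truth (all granules share the trajectory; per-granule amplitudes would
make the per-frame mean an average of different laws). An optional
`conserve_total` mode redistributes the intensity lost by dimming
granules uniformly over the cytoplasm, so whole-frame intensity is
conserved while each granule still satisfies ρ(t) against the adjusted
cytoplasm level — the regime in which protein-level controls should read
1.0.

smFISH channel pairs place exactly round(n·f) spots at granule centers
(at most one per granule, so the object-based pipeline can resolve them)
and the remainder in granule-free cytoplasm, ≥ 3 granule-σ away from
every granule center and ≥ 6 px from each other. Calcium traces are a
baseline, a linear rise from stimulus to peak, and an exponential return
to a plateau.

## Detection

The detection chain mirrors the standard ImageJ recipe for puncta
quantification: Gaussian smoothing (default 0.5 raw px ≙ 1 px on the
detection grid; the original workflow states no σ), ×2 bilinear pyramid
upsampling, and linear min–max conversion to the 16-bit range (a
deterministic, parameter-free stand-in for ImageJ's unspecified
display-range conversion; a constant field degenerates to zeros with a
warning).

Particles are then extracted from a **scale-normalized
Laplacian-of-Gaussian band-pass response** (σ = 3 detection px for
granule channels, 2 for RNA spots, matched to the punctum radius), with
**curvature-based edge rejection**: pixels where the smoothed-intensity
Hessian fails the ratio test trace²/det ≤ (r+1)²/r (r = 10) — one
dominant principal curvature — are edges, not puncta, and their response
is zeroed. Without this step, soma boundaries are the brightest band-pass
structures at low thresholds and particle counts are not monotone in the
threshold. Foreground is `response > relative_threshold × (response
range)`, so the threshold is a unitless value in (0, 1); the shipped
defaults keep the published interface values (0.6234 for protein-granule
channels, 0.3434 for smFISH channels). This detector is fully specified
here and is *not* the SPaDe algorithm those published thresholds were
tuned for; on any new dataset the threshold should be re-calibrated (see
below). 8-connected components of area ≥ 4 detection px become
particles; antibody-stained granule channels additionally exclude
particles smaller than 13 detection px. Both size thresholds are
interpreted on the ×2-resized grid, where detection runs, and are
configurable.

Coordinates map between grids with the area-centered convention: a
feature at raw pixel r sits at detection coordinate 2r + 0.5, so
centroids map back as (d + 0.5)/f − 0.5 while footprints map by floor
division (detection pixels 2r and 2r + 1 both cover raw pixel r).
Noise-free localization error is ≤ 1 detection px.

**Threshold calibration** follows the F1 procedure: annotations (point
coordinates of true granules) are matched to detected particles — an
annotation is a true positive when it falls inside a particle's raw-grid
footprint, each particle absorbs at most one annotation, greedily by
centroid distance — and the threshold maximizing mean F1 over the
annotated fields is selected, ties broken toward the larger (more
conservative) threshold. On the default synthetic scenes the calibrated
threshold lands near 0.3 with F1 = 1.0.

## Partition coefficients

The coefficient of granule i is max(raw intensity over its footprint) /
mean(raw intensity over the cytoplasm mask). Maxima are measured on the
original raw image; the detection grid only delineates footprints. The
cytoplasm mask reproduces the ImageJ procedure literally: granule
footprints are blanked (set to 0 — a normalized-convolution variant that
ignores blanked pixels is available behind a flag), the image is blurred
with σ = 8 px, and pixels whose blurred value lies in [global mean,
65000] — minus the granule footprints — form the mask. Means are then
measured on the raw image under the mask.

Field summaries are unweighted arithmetic means over granules (each
granule is one data point; replicate-level aggregation happens in the
statistics layer). Time-lapse analysis detects and measures each frame
independently (no tracking), pools granules across crop regions by
default (region-mean averaging is a switch), and records frames with
zero detected granules as an explicit missing mean — substituting zero
would bias time courses. The decondensation rate is recovered by
least-squares fitting a + b·exp(−k t) to the post-stimulus means
(non-negative bounds, initialized from the data).

Accuracy on the default scenes: noise-free coefficients are within 2% of
truth (bias comes only from preprocessing blur and mask edges); with
Gaussian noise at 5% of the cytoplasm level, the mean coefficient over
100 granules is recovered within ~0.5% and the fitted k within a few
percent of 0.1/frame.

## Colocalization

Object-based, as in the JACoP object method: RNA spots are reduced to
their band-pass-weighted centers of mass; a spot is granule-associated
iff its center, rounded to the nearest raw pixel, lies inside a granule
footprint. The center-vs-particle tolerance radius of the original
plugin is not published; strict pixel membership is the default and a
dilation tolerance is exposed as a parameter. Fractions are normalized
to the mean of a control condition. Pearson/Manders pixel correlation is
deliberately out of scope.

## Traces

ΔF/F uses F0 = mean of the first four frames (the pre-stimulus frames of
a 30-s-interval acquisition where treatment is added after four frames);
the baseline ΔF/F mean is exactly zero. Dose–response endpoints set each
t0 to 1 and report both the normalized endpoint f_t30/f_t0 and the
difference on that scale (and the raw difference, since the source
convention is ambiguous between raw and normalized scales). Foci time
courses are normalized per movie to that movie's maximum (all-zero
movies are excluded with a warning); across-movie error bars are SEM
with the n − 1 denominator. Reporter intensities are ROI means on
maximum-intensity projections. Foci counting itself is expected to be
manual (with cells carrying a pre-stimulus ScFv-GFP cluster excluded via
an exclusion list); automated counting can be assembled from
`detect_spots` but is an extension, not the measured procedure.

## Statistics

Long-format tables (condition, replicate, field, value). Normalization
to a control condition defaults to per-replicate scope (each value is
divided by its own replicate's control mean — figures pool replicates
after normalization); global scope is available since the source
convention is not stated. SuperPlot summaries report both the mean of
replicate means and the pooled mean so pseudoreplication stays visible.

Test designs: Welch two-sample t (Student's optional), Mann–Whitney U,
Kruskal–Wallis with Dunn's rank z post-tests versus a control
(Bonferroni-adjusted by default; the adjustment is configurable because
the upstream convention is a black box), and one-way ANOVA with
Dunnett's test (scipy), which is family-wise by construction. Either
individual points or replicate means can be the test unit. Under the
null, all four designs reject between 3% and 7% of 1000 simulated tables
at α = 0.05 (verified in the test suite).

The co-IP interactor filter retains a protein iff, in every required
replicate, bait peptides ≥ 10 and bait ≥ 2× control (control 0 passes
when the minimum holds); missing replicates fail. Thresholds are
parameters; the filter is monotone in both.

## Numerical choices and problem sizes

- Threshold sweeps use 41 points (0.10–0.90, step 0.02).
- The suite's end-to-end checks run on 256×256 fields with 10–30
  granules (20 fields for detection fidelity, 4×25 granules for noisy
  recovery), 60-frame time-lapses with 20 granules, a 220-granule scene
  with 200 spots for colocalization, and 1000 simulated tables per test
  design — sizes at which every ground-truth property is resolvable
  while the whole suite runs in about two minutes.
- Seeds are explicit arguments of every stochastic operation; there is
  no global random state.

## What passing tests do and do not show

The generator reproduces the statistical structure the analysis assumes
— ring-shaped cytoplasm, near-diffraction-limited puncta over a diffuse
pool, Poisson–Gaussian noise, exponential decondensation, binomially
placed RNA spots — but not optics (no PSF, no Airyscan processing), not
3D, not granule motion, fusion, fission, or photobleaching, and not the
spatial heterogeneity of real neuropil. Passing tests therefore
demonstrate that the *pipeline* is correct and unbiased under its own
model assumptions; they do not validate the published thresholds for any
particular microscope, which is exactly why the F1 calibration step is a
first-class operation.

## Known limitations

- The detector shares SPaDe's interface (relative threshold in (0, 1),
  4-px minimum size) but not its internals; published threshold values
  transfer as defaults, not as guarantees.
- The cytoplasm mask inherits the literal blank-and-blur procedure's
  geometry sensitivity; on fields whose cytoplasm is a minority phase the
  coefficients are biased high (use the normalized-convolution option
  and inspect the mask).
- Per-frame partition means are computed without tracking; they measure
  the population, not individual granule kinetics.
- `fraction_in_granules` is undefined (error) with zero spots, by
  design.
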