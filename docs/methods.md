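# Methods

This note documents the models, parameter choices and numerical decisions
behind gvbquant: what the synthetic generator emulates, how each
measurement is defined, and where the design was genuinely open.

## The measurement problem

A tau-seeding experiment asks four quantitative questions. Which neurons
carry tau pathology, which carry GVBs, and how do the two statuses co-occur
per cell? How large are GVB cores? How much tau-pathology and GVB signal
does each well of a plate carry, across seed doses? And do reporters
(proteolysis probes, overexpressed cargo) accumulate inside GVBs relative
to cytosol? gvbquant implements these measurements; the synthetic generator
provides images whose true answers are known, so every stage can be scored.

## Synthetic image model

A scene is a set of non-overlapping somata (random convex blobs, radial
profile 1 + low-order Fourier wobble clipped to ±25%) with elliptical
nuclei, thin dendrite strokes, and per-cell structures:

* **GVB structures** — one or more disk cores inside a 2-px membrane
  annulus. The morphology class is drawn from (single, multiple, filling)
  with probabilities (0.59, 0.12, 0.29), the super-resolution tally of GVB
  morphologies. Single cores occupy 20–45% of the vacuole interior,
  filling cores 85–95%, multiple-core structures hold 2–3 smaller cores in
  a wider vacuole.
* **Plain lysosomes** — membrane rings without a GVB-marker core
  (Poisson-distributed, mean 4 per cell), so that GVB-marker-negative
  control structures exist for ratio comparisons.
* **Tau signal** — a diffuse somatic fill (8 AU for tau+ cells, 1 AU
  otherwise) plus 1 + Poisson(2) bright aggregate patches of 2–6 µm² in
  tau+ cells.
* **Reporter (DQ-BSA-type) signal** — cytosolic base 40 AU; each
  structure's lumen is elevated to base × its true ratio. True ratios are
  log-normal(µ = 0.645, σ = 0.481), the unique log-normal with
  P(ratio > 1) = 0.91 and P(ratio > 2) = 0.46 — the measured exceedance
  fractions this class of experiment reports. `reporter_target="core"`
  switches the elevation to the dense core instead of the lumen, the
  appropriate forward model for a cytosolic cargo such as a GFP-tagged
  core protein.

Per-cell statuses are drawn independently from the joint model
tau+ ~ Bernoulli(p_tau), GVB+|tau± ~ Bernoulli(p_gvb_given_tau /
p_gvb_given_no_tau). Defaults (0.5, 0.35, 0.0875) are the unique choice at
p_tau = 0.5 reproducing both P(GVB+|tau+) = 0.35 and P(tau+|GVB+) = 0.80.
Core areas are Normal(0.45, 0.15) µm², floored at 0.05 µm²; somata average
160 µm² (mouse hippocampal scale).

Cores are rasterized as complete lattice-distance shells whose cumulative
pixel count is closest to the requested area. This makes the rendered area
an exactly countable quantity (a 0.50 µm² request at 0.1 µm/px yields the
49 lattice points within radius 4, i.e. 0.49 µm²) and lets segmentation be
tested against a lattice-point oracle with zero tolerance.

Rendering adds, in order: a tilted-plane background gradient (offset 2 AU,
amplitude 3 AU by default), Gaussian PSF blur (σ = 0.1 µm confocal,
0.3 µm high-content), optional Poisson scaling, and Gaussian read noise
(SD 1 AU). Blur conserves each interior object's flux within 1%. Z-stacks
are rendered as focus-weighted slices (default a single in-focus plane,
since most quantifications analyze single focal planes). All intensities
are arbitrary units on this documented scale; acquisition gain and offset
are not modelled beyond the additive background.

Three optics presets cover the regimes: `confocal_optics` (0.1 µm/px, for
sizing and structure-level ratios), `survey_optics` (0.25 µm/px, 1536 px
fields, for population classification) and `hcs_optics` (0.325 µm/px,
640 px wells, for plate loads). Somata are placed by rejection sampling
(500 retries, then an explicit capacity error); the standard survey field
holds 160 cells, about 60% of the jamming density, where placement never
failed across 50 seeds.

### What the generator does not emulate

Real PSFs are not Gaussian and vary with depth; staining intensity varies
between cells far more than the fixed per-status levels here; neurites form
dense meshes rather than isolated strokes; somata overlap in dense
cultures; and real backgrounds contain structured debris, not a smooth
plane. Passing tests therefore demonstrate that the measurements are
correct and unbiased under a controlled forward model — not that their
absolute accuracy transfers to any particular microscope.

## Measurement definitions and numerical choices

**Core segmentation.** Threshold at mean + k·SD (k = 3) of the GVB channel
— computed within the thresholded soma mask when a soma channel is present,
because cytosol, not the whole frame, is the relevant reference — then
watershed on the Euclidean distance transform with h-maxima seeding
(h = 1 px), border-object exclusion, and a minimum area of 0.15 µm²
(smaller than any real core at these pixel sizes; rejects single-pixel
noise). Each object must peak at least 8 SDs above the statistics-region
mean: cores are tens of SDs above cytosol, noise clumps are not. Accepted
objects are re-sized at background + half their peak (FWHM criterion), so a
sharp disk's area is lattice-exact and a blurred disk's area stays within a
few percent (measured mean absolute relative error ≈ 2–4% at 0.1 µm/px
under default blur and noise).

**Cell classification.** Nuclei: Otsu threshold, hole filling, watershed
split of touching nuclei, minimum area 8 µm². Somata: watershed of the
soma-marker intensity seeded at nuclei within the thresholded
somatodendritic mask. Tau status: background-corrected somatic mean
(nucleus excluded) above a cutoff — either an absolute AU value or
mean + 2·SD of control-condition somata (`tau_threshold_from_controls`).
GVB status: at least `min_puncta` (default 1) segmented cores with centroid
inside the cell territory.

**Ratios.** DQ-BSA background: four square ROIs (side = median structure
diameter) sampled with a fixed seed from cytosol excluding dilated
structure masks — a reproducible surrogate for manually placed ROIs.
GVB/cytosol ratios refine the marker ROI at half-peak so the ROI covers the
bright structure rather than its blur skirt. Ratios are scale-invariant by
construction; an additive offset c moves a ratio s/b to (s+c)/(b+c), which
is tested explicitly. Under default blur the measured GVB/cytosol ratio of
a core-localized reporter attenuates to roughly 0.8× its generating value
(e.g. a true 6.3 measures ≈ 5.0); the exceedance fractions of lumen-filling
reporters are less affected.

**High-content loads.** Background removal: grey opening with a flat
square element of half-side 1.5 µm — larger than any punctum, small enough
to avoid soma-edge artifacts — estimated on a lightly smoothed (σ = 1 px)
copy and re-centred at the residual median, because opening a raw noisy
raster tracks the lower noise envelope and would bias the residual by
about +2 noise SDs. Puncta detection smooths the residual at the punctum
scale (0.2 µm) for thresholding only, then re-masks each punctum on the raw
residual; acceptance criteria are intensity ≥ 5 AU (≈ 5 noise SDs), area
0.1–2.0 µm², circularity 4πA/P² ≥ 0.6 (clipped at 1 for few-pixel regions
whose discrete perimeter underestimates a circle). Clustering is
single-linkage at 8 µm, the soma radius of the generator's neurons; this
both merges a cell's multiple cores into one object and keeps neighboring
cells separate (verified equal to a brute-force union-find oracle on
random point sets). With these defaults, 16 rendered buffer wells
yield zero detected GVB objects in every well.

**Normalization schemes.** Background subtraction removes the mean raw
control-well load (control mean becomes exactly 0; corrected values are not
clipped at zero by default, preserving unbiased averaging).
"Top-two = 100" is implemented as mean-of-the-two-largest = 100, which is
well defined when the two differ and preserves ranks. Min–max rescaling is
computed within each experiment group and is invariant to positive affine
transforms. Load ratios (GVB/tau per well) exclude wells with non-positive
corrected tau load (count reported) and are scaled so the reference-region
mean is exactly 1. Histogram bins are left-closed/right-open with the edge
grid extended one bin past the maximum, so percentages always sum to 100.

**Statistics.** The normality gate applies Shapiro–Wilk per group at
α = 0.05; any single failure routes the whole comparison to the
non-parametric branch (the strictest aggregation rule). Student's t is the
classical equal-variance form. Tukey HSD comes from scipy; Dunn's test is
implemented directly (pooled mid-ranks, tie-corrected variance, two-sided
normal p, Bonferroni adjustment) since no pre-packaged implementation is
available in the environment. The whole adaptive procedure's type-I error
on two Normal(0,1) groups of 20 measures ≈ 0.04–0.05 over 2000 replicates.

**Dose–response conditions.** The well-load generator draws per-well true
tau load proportional to dose (0/40/80/160 nM), GVB load proportional to
the realized tau load, and independent multiplicative log-normal noise of
CV 0.15 on both read-outs plus an additive dose-independent background.
Measured loads on this ladder correlate at r ≈ 0.98 (median over 50
replicates); an image-based ladder (smaller, rendered wells) exercises the
same path end-to-end in the pipeline tests.

## Problem sizes

Test and acceptance runs use: five populations of ~2080 cells (13 survey
fields of 160 cells) for co-occurrence recovery; ~150 cores at 0.1 µm/px
for sizing; 50 replicates of the 24-well dose ladder; 16 buffer wells for
specificity; 12 two-cell confocal scenes for structure-level ratios and
morphology; 2000 replicates for the type-I error. These sizes put binomial
and Monte-Carlo standard errors well inside the tolerances being checked.

## Known limitations

Areas are biased low by ~1 shell for cores whose requested area falls
between lattice shells; the FWHM refinement under-sizes heavily blurred
small objects (relevant below ~0.2 µm² at 0.25 µm/px). Morphology recovery
misreads a minority of multiple-core structures as single when their cores
merge under blur. The reporter-ratio attenuation noted above means
measured accumulation contrasts are conservative. `classify_cells` assumes
one nucleus per cell; oversegmented nuclei create duplicate cell records
(< 3% at the default density). Placement is rejection-based and will
raise, not degrade, when a field is overfilled.
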