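# Methods

This note documents the models, estimators, numerical choices and
limitations behind `gliaspat`, in the order the pipeline runs them.

## Conventions

All coordinates are in μm with the origin at the top-left of the window
bounding box and y increasing downward (image convention); pixel coverage
is by pixel centre. Areas are μm² internally; densities are reported in
cells/mm². The default physical scale is 1.24 μm/px, a typical 20×
confocal mosaic resolution. A single integer seed expands through
`numpy.random.SeedSequence` into independent substreams for geometry,
marks and pixel noise, so every simulated object is bit-reproducible.

## Synthetic data

The generator produces the two kinds of inputs the pipeline accepts.

**Point patterns.** The null model is the homogeneous Poisson process
(complete spatial randomness, CSR) at a requested intensity (points/mm²)
inside an arbitrary polygonal window, sampled by bounding-box rejection.
The dispersal model — a stand-in for territorial microglia, not a
biological claim — is a Matérn type-II hard-core process: a Poisson
proposal set with i.i.d. birth times, keeping a point only if it holds
the earliest birth time within the hard-core radius R among all
proposals. Matérn II was chosen over rejection samplers because its
hard-core radius is exact (every surviving pair is ≥ R apart, which the
tests assert over all pairs) and the construction cannot fail; the cost
is that realized intensity is below the request and saturates at
1/(πR²), for which a warning is emitted when the shortfall exceeds half.

**Marks.** Binary activity marks are attached by (i) independent
Bernoulli(p_high) thinning ("random labelling", the null of the
segregation test), or (ii) a sequential contagion: points are visited in
random order and marked 'high' with probability min(1, p_high·boost)
when an already-'high' point lies within the attraction radius. Defaults
p_high = 0.35, boost = 3, attraction radius ≈ 2× the mean NND make the
contagion strong enough to be an unambiguous positive control.

**Images.** Each point is rendered as a bright ellipse (pixel-centre
coverage; for a circle of radius 10 px this covers 317 px against
πr² ≈ 314) with per-soma intensity, plus optional thin polylines that
mimic process fragments and Gaussian pixel noise, clipped to 8 bits. The
ground-truth table (centroid, pixel area, roundness = b/a) is returned
alongside. Fragments are placed clear of somata (bounded resampling) so
the ground truth remains valid for every rendered object. The renderer
makes no attempt at realistic process arborization, z-stacks, shading or
stitching artefacts; consequently the recovery tests certify the
measurement chain on well-posed inputs, not robustness to real staining
variability.

## Segmentation

The pipeline order is fixed: attribute opening → morphological opening →
maximum-entropy threshold → particle extraction → NND gate.

* **Attribute opening** (grey-scale area opening, default area 25 px,
  8-connectivity) flattens every bright grain smaller than the area
  minimum at every grey level; implemented via scikit-image's max-tree
  `area_opening` and property-tested against a brute-force
  threshold-decomposition oracle.
* **Morphological opening** uses a radius-1 octagonal element,
  implemented as the full 3×3 footprint (cross with corners); it removes
  1-px-wide processes while preserving soma bodies. Both filters are
  anti-extensive and idempotent, asserted pixelwise.
* **Maximum-entropy threshold** follows the Kapur–Sahoo–Wong criterion on
  the 256-bin histogram: choose t maximizing the summed Shannon entropies
  of the normalized sub-histograms [0..t] and [t+1..255]; ties break
  toward the lower t; a constant image is an error. scikit-image does not
  ship this criterion (its `threshold_yen` is a different entropy), so it
  is implemented directly and tested against exhaustive search.
* **Particles** are 8-connected components with at least the particle
  area minimum (default 10 px) in pixels; area converts via pixel_size²,
  the centroid is the component centre of mass, and M is the major axis
  of the normalized-second-central-moment ellipse fit (the convention
  behind ImageJ's "fit ellipse"). Roundness 4A/(πM²) is 1 for a circle
  and b/a for an ellipse with semi-axes a ≥ b. Discretization limits the
  accuracy of this fit: at semi-major axes of 4–7 px the roundness error
  can reach ~0.1, shrinking below 0.05 only at ≥ ~10 px. The recovery
  fixtures therefore render somata at 12–18 px semi-major with the
  particle gate scaled accordingly (30 px), and the reported <0.05
  roundness accuracy applies in that regime.
* **NND gate.** The published recipe retains particles with NND < 14 px.
  Read literally this keeps only tightly packed particles, which runs
  counter to its stated purpose of excluding isolated process fragments;
  we implement the printed rule as the default and expose a direction
  flag. The end-to-end recovery suites run with the flag inverted (keep
  NND ≥ gate), since their sparse territorial fixtures would otherwise be
  discarded wholesale.
* **Tissue area/boundary**: pixels in the low-intensity interval
  (default 0–5) are background and tissue is the complement (invertible
  by flag); area is the pixel count × pixel_size²/10⁶ and the boundary is
  the longest outer contour of the largest tissue component, simplified
  with a 1-px tolerance to remove the staircase artefact from the
  perimeter.

## Population descriptors

NND uses exact nearest-neighbour search (k-d tree); the regularity index
is the mean NND over its standard deviation, with the sample (n−1)
denominator by default (configurable) since the source material does not
specify it. A zero spread (degenerate lattice) flags RI as undefined
rather than raising. For a Poisson process the expected RI is the
Clark–Evans value (1/2)√(4π/(4−π)) ≈ 1.913; the oracle test pools NNDs
from interior points only (≥100 μm from the boundary, neighbours from the
full window), because edge-censored NNDs inflate the spread and bias the
pooled RI low by ~3% at the simulated scales. Retina-level summaries are
computed per retina, matching per-retina error bars, not pooled across
retinas. Eccentricity profiles bin the distance-to-ONH at 50 μm and
normalize by the retina's total cell count. The Bland–Altman routine
works on the percentage scale, 100·(a−b)/mean(a,b), with limits of
agreement at bias ± 1.96·sd.

## Phenotype clustering

Soma area and roundness are pooled across all retinas and groups before
normalization (the alternative — winsorizing per group — would remove
group differences in scale, which are the signal). Each feature is
90%-winsorized: values outside the 5th–95th percentiles are clipped to
those quantiles, computed with linear interpolation (R type 7). Note that
winsorizing with interpolated quantiles is not exactly idempotent at
small n (the clipped sample's own 5th percentile moves inward); at
realistic population sizes a second pass moves values by <1% of a
standard deviation, which the tests assert. "Normalization" is z-scoring
by default (min-max available).

k-means with two centres follows the Hartigan–Wong protocol: Lloyd
passes to a stable partition, then single-point transfers accepted when
the size-corrected cost n₁/(n₁−1)·d₁² exceeds n₂/(n₂+1)·d₂², iterated to
a local minimum of the within-cluster sum of squares; 10 seeded random
starts (configurable), best objective kept. scikit-learn implements only
Lloyd/Elkan, so Hartigan–Wong is implemented here and cross-checked
against `sklearn.cluster.KMeans` in the tests (our objective must never
be worse). The cluster whose cells have the larger mean soma area is
labelled 'high' activity — matching the morphology of reactive microglia
(enlarged, less round somata) — so label semantics never depend on
cluster indices or initialization.

## Ripley territory analysis

K̂(r) sums pair indicators 1[dᵢⱼ ≤ r] with edge-correction weights,
normalized by n(n−1)/|W|² (the nearly unbiased choice); L = √(K/π) and
H = L − r are exact transforms of K̂ at every grid point. The default
grid is 0–150 μm at 1 μm steps, bracketing territory radii in the tens
of μm with margin.

* **Translation correction** (default) weights each pair by
  |W|/γ_W(xⱼ−xᵢ), where γ_W(v) = |W ∩ (W+v)| is the window's set
  covariance. For axis-aligned rectangles γ is the closed form
  (a−|dx|)(b−|dy|); for general polygons γ is evaluated by FFT
  autocorrelation of a rasterized window mask (~1024 cells across the
  diagonal, bilinearly interpolated, normalized so γ(0) = |W| exactly),
  accurate to ~1–2% against exact polygon intersections and orders of
  magnitude faster than per-pair shapely operations.
* **Border (minus-sampling) correction**: only points at least r from
  the boundary contribute at radius r, with λ̂ = (n−1)/|W|.
* **Uncorrected** estimates are retained as a negative control; they are
  biased low near the boundary, which the tests demonstrate.

Cross-K between labels i and j counts j-neighbours of i-points with the
same translation weights, normalized by nᵢnⱼ/|W|²; the estimator is
symmetric in the two labels by construction.

**Domain radius.** H(r) is smoothed by a centred 5-step moving average
(reflection-padded) and its local minima located. Minima at or below the
artefact floor — default 14 px × 1.24 μm ≈ 17.4 μm, the scale of the
segmentation NND gate — are discarded and the first surviving minimum is
returned. Because CSR patterns produce shallow noise wiggles (±~2 μm) in
H, a candidate minimum must additionally be negative-valued with
prominence ≥ 5 μm (configurable); hard-core minima are tens of μm deep,
so the default separates cleanly and CSR inputs raise "no domain
structure detected" as intended. The source material describes the
radius both as the second minimum of H and of its derivative; we follow
the H reading (the floor plays the role of excluding the first,
artefactual minimum) and expose a derivative mode. On Matérn II patterns
at half-saturation intensity, the estimate sits ~2 μm below the true
hard-core radius (smoothing and the asymmetric shape of H around its
minimum), well within the ±10% recovery tolerance of the parameter
recovery suite at radii 30–60 μm.

CSR envelopes simulate Poisson patterns matched to the observed
intensity and window and return pointwise rank envelopes of H.

## Dixon segregation test

Each point contributes its (own type → nearest-neighbour type) pair to a
2×2 contingency table; duplicates are rejected and exact ties are broken
toward the smaller point index with a warning. Under random labelling
the moments of N_ii depend only on the label counts and two NN-graph
constants: R (number of points in mutual NN pairs) and
Q = Σ indeg·(indeg−1). With falling-factorial label probabilities
p₍k₎ = Nᵢ…(Nᵢ−k+1)/(N…(N−k+1)):

    E[N_ii]  = N·p₍₂₎
    Var N_ii = (N+R)p₍₂₎ + (2N−2R+Q)p₍₃₎ + (N²−3N−Q+R)p₍₄₎ − E²
    Cov(N_ii, N_jj) = (N²−3N−Q+R)·p_iijj − E_ii·E_jj

These formulas (and the R/Q conventions) were validated against exact
enumeration of all label assignments at n = 10 and a 10⁴-permutation
Monte-Carlo oracle before being frozen into the tests. z_ii and z_jj are
the standardized self-neighbour counts; C is the quadratic form of
(N_ii−E, N_jj−E) with the inverse 2×2 covariance, asymptotically χ²(2).
Aggregation across a treatment group sums statistics and degrees of
freedom: ΣC on 2 df per retina, Σz² on 1 df per retina; retinas failing
preconditions (a label with <2 points, degenerate variance) are dropped
with a logged reason rather than silently imputed. p-values below 10⁻⁶
are reported exactly and floored for display. Calibration (type-I error
at α = 0.05 within [0.03, 0.07] under random labelling) and power
(≥0.8 against the contagion marks at n ≥ 500) are asserted by
simulation.

## Workbench

The canonical point table is a CSV with columns retina_id, group, x_um,
y_um, area_um2, roundness and optional activity_label; boundaries are
ordered x_um,y_um vertex lists; images are single-channel 8-bit TIFFs
whose pixel size is carried in resolution tags, with a warned fallback
to 1.24 μm/px. `run_pipeline` drives all stages from a JSON config,
pools cells across retinas for clustering and splits them back (cell
counts preserved exactly), writes per-retina and per-group tables
(including a Dixon summary mirroring the per-group C/z layout), and
emits a manifest of every file produced. All randomness flows from
config seeds; reruns are byte-identical, which the tests assert.

## Problem sizes in the validation suites

The simulation suites use windows of 1.2–4 mm side and intensities of
150–400 cells/mm² (n ≈ 200–2500 per pattern), 100 CSR replicates for K
calibration, 1000 label permutations for test calibration, 10 seeds per
hard-core radius, and 4000 cells for cluster recovery; the full test
suite and the acceptance script each run in well under a minute on one
CPU.

## Known limitations

* The hard-core generator is a test stand-in; real microglia dispersion
  is not claimed to be Matérn II, and realized intensity is below the
  requested one by construction.
* Segmentation accuracy claims hold at the fixture scale (somata ≥ ~10 px
  semi-major); at the 4–6 px somata of typical 20× material, roundness
  carries ~0.1 discretization error, an imaging-resolution limit rather
  than an algorithmic one.
* The printed NND-gate direction is preserved as default despite reading
  counter to its stated purpose; users should choose the direction
  consciously per dataset.
* No inhomogeneous-intensity K variants, no pair-correlation function,
  no >2-label Dixon generalization, no z-stack handling, and no group
  inferential statistics (ANOVA etc.) — these are outside the package's
  scope.
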