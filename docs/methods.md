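# Methods

`maizemap` re-implements, as a tested and reusable pipeline, a zone-specific
framework for mapping maize cropland at 10 m from Sentinel-2-style pixel time
series: pre-processing of per-pixel reflectance sequences, a discriminatively
trained recurrent classifier for the sample-rich zone plus per-zone random
forests, post-classification cleaning, and accuracy/area validation.  Real
Level-1C imagery and field campaigns are out of scope; a synthetic generator
reproduces the statistical structure the pipeline needs, so every stage is
exercised end-to-end, offline and deterministically.

## Synthetic data model

Each of the three classes (maize, non-maize crop, non-cropland) follows a
double-logistic green-fraction curve — the standard land-surface-phenology
form — over the April–October season (DOY 90–300):

    g(t) = A [ σ(k_g (t − t_peak + W)) − σ(k_s (t − t_peak − W)) ]

with amplitude `A`, growth/senescence rates `k_g`, `k_s` (per day) and a
fixed half-season width `W = 45` days.  Band reflectance mixes a green
vegetation endmember with a spectrally flat background at `base_level`:

    ρ_b(t) = base + g(t) (veg_b − base)

so `A = 0` produces a flat series at `base_level` in every band.  The
aerosols band is generated nearly collinear with blue (slope 0.95, jitter
0.002) so that the r > 0.98 redundancy screen drops one of the pair, leaving
the eight channels the classifiers consume.  Defaults are the study
conditions: maize peaking at DOY 200 with amplitude 0.65, an
earlier-season non-maize crop (peak 150, amplitude 0.55), sparsely
vegetated non-cropland (amplitude 0.08, brighter base 0.16), additive
reflectance noise with σ = 0.02, a 15 % per-acquisition cloud probability
and one acquisition every 10 days.  Cloudy acquisitions replace the
spectrum with bright draws (visible bands U[0.4, 0.9], NIR/SWIR
U[0.3, 0.8]) and keep a truth flag so detection can be scored.

What the generator deliberately does *not* emulate: spatial autocorrelation
of samples within a zone (samples are independent draws), orbital/tiling
geometry, atmospheric radiative transfer, mixed pixels at parcel edges, and
real inter-annual phenology shifts (a "year" is a fresh seed, not a new
climate).  Passing tests therefore demonstrate that the pipeline machinery
is correct and recovers planted separability — not that the published
real-data accuracies would be reproduced.  Zone difficulty is a
configuration knob (`separability` scales the between-class peak-day and
amplitude gaps), not a geographic simulation: what the pipeline exercises
is zone *routing*, and tests assert separability on noise-free NDVI
trajectories where the ordering is exact.

A patchy label raster is generated as nearest-seed (Voronoi) regions of
roughly `patch_size_px` cells with seed classes allocated by largest
remainder; single-cell components are merged away so that injected
speckles (isolated one-cell flips at interior cells with uniform 3×3
neighbourhoods, spaced ≥ 3 cells apart) are the only one-cell patches.

## Pre-processing

Cloud score: the published framework uses an adjusted cloud-score algorithm
whose exact constants are not public, so this package defines its own with
the same structure — a brightness term (blue and aerosols rescaled over
0.1–0.5, red and green over 0.15–0.7, averaged) plus moisture (NDMI) and
snow (NDSI) terms rescaled over 0–0.5, combined with weights (1.0, 0.25,
0.25) and clamped to [0, 1].  The index terms only contribute when positive
— bright *and* spectrally balanced is cloud-like, while dark soils and
vegetation sit at or below zero — which keeps flat dark spectra well below
the default masking threshold of 0.2.  The brightness weight is 1 so a
saturated pixel reaches score 1; the score is monotone non-decreasing in
each brightness band.  Undefined indices (zero denominators) contribute
nothing, and a zero denominator in any index function yields NaN rather
than an exception.  On the generator's cloud model the default threshold
achieves recall 1.0 at a false-positive rate of a few percent.

Compositing uses seven half-open 30-day windows starting at DOY 90, the
last window closed at 300; each band's monthly value is the median of
unmasked acquisitions in the window, and empty windows are gaps.  Gaps are
filled channel-wise by linear interpolation between the nearest clear
months; the published rule ("preceding and succeeding months") is undefined
at the sequence ends, where nearest-value extension is used.  NDVI and EVI
are computed *after* compositing, on the monthly medians — the alternative
(per acquisition, then composite) is not stated in the source framework;
computing after keeps the classifier input at exactly 7 × 10 and makes the
index channels consistent with their reflectance channels.

Band selection is a single greedy pass in wavelength order: a band is
removed when its |Pearson r| with an already-retained band exceeds 0.98
over the pooled clear acquisitions of maize samples.  Keeping the
earlier band of a correlated pair is a deterministic tie-break (the
source states only the threshold); zero-variance bands have undefined
correlation and are retained with a warning.

## Classifiers

Zone routing: North China (zone a, sample-rich) uses the recurrent
network; zones b–e use per-zone random forests; southern China has too few
samples of its own and borrows a forest trained on the pooled adjacent
zones b and c.

The recurrent classifier is a two-layer GRU (hidden size 64 by default)
over the 7 × 10 monthly sequence, followed by two dense layers.  The
output layer applies per-class sigmoids whose scores are row-renormalized
into probabilities: the source describes a sigmoid output for three
mutually exclusive classes, and renormalization honours that wording while
keeping the cross-entropy well defined (a softmax head would be the
conventional alternative; the choice is isolated in the decision head).
The loss is `L = w1·L_ce + w2·L_center` with `w1 = 1.0`, `w2 = 0.001`:
batch-mean cross-entropy plus the center loss
`½ Σ_i ||f(x_i) − c_{y_i}||²` summed (not averaged) over the batch, where
`f(x_i)` is the first dense layer's ReLU output.  Class centers start at
zero and move toward each batch's class-feature mean by an exponential
rate of 0.5 after every optimizer step; absent classes keep their center.
Optimization is Adam (lr 0.001, batch 50, up to 100 epochs); after each
epoch the validation overall accuracy is computed and the parameters of
the best epoch (earliest on ties) are kept.  The GRU update equations are
documented in `maizemap/_gru.py` (the update gate multiplies the *new*
candidate; equivalent to the common convention with z ↦ 1 − z) and the
backward pass is verified against numerical differentiation in the tests.

Samples are split 70:10:20 (train:validation:test), stratified per class;
per stratum the validation and test counts are half-up-rounded fractions
and training takes the remainder, so every partition is within one record
of its exact share (30 per class → 21/3/6).

The random forests have exactly 200 trees on the flattened, month-major
70-dimensional sequence; all other parameters are scikit-learn's defaults
and are recorded verbatim in the fitted model's metadata.

## Post-processing

The majority filter is a single pass with a circular kernel: at 10-m cells
and a 10-m radius the neighbourhood is the 5-cell cross (the four edge
neighbours plus the cell itself — a 10-m radius with 10-m cells only makes
sense if the 4-neighbours participate).  Nodata never votes and is never
relabeled; modal ties keep the original label, so the filter cannot invent
a class absent from a neighbourhood.  An isolated speckle loses its 4-to-1
vote and is removed.

Patch removal resets 4-connected maize components with area *strictly*
below the threshold to the modal surrounding class (ties prefer non-maize
crop).  At 10-m cells a single cell is exactly 100 m², so the default
100 m² threshold removes nothing on its own: the "< 100 m²" clause of the
source describes the speckle-removal effect of the majority filter, and
this operation exists for stricter configured thresholds.

The coarse-product mask drops maize cells whose centre lies beyond a
1000-m buffer of every positive coarse cell's *footprint* (axis-aligned
square, exact point-to-rectangle distance — buffering footprints rather
than centroids reads the "outward buffer of the product" literally).
Removed maize becomes non-maize crop.  Enlarging the buffer can only grow
the surviving maize set.

## Validation

Accuracy uses the confusion matrix in fixed class order (maize, non-maize
crop, non-cropland): UA = column-wise, PA = row-wise correctness for the
target class (maize, the mapped target — the per-zone summary in the
source prints a single UA/PA without naming the class; per-class values
are available in verbose output), OA = trace/total, and kappa
(OA − p_e)/(1 − p_e) with p_e from the marginals; degenerate denominators
yield NaN, never an exception.  Area validation counts maize cells on a
grid flagged equal-area (a missing flag warns and proceeds) and compares
against yearbook records with R² = 1 − SS_res/SS_tot about the yearbook
mean — "coefficient of determination" names this form; the squared Pearson
correlation is available as an option.  Report tables round half-up to two
decimals.

Three reference tables ship as CSV: the campaign sample inventory
(79 255 labels across zones a–e, 2017–2021, methods I–IV), the cross-year
transfer accuracies in zone a (six ordered year pairs, mean 0.85), and the
18-province mapped-vs-yearbook area comparison.  The fixture R² values
(e.g. 0.87 for 2020) are properties of this 18-province subset and are
pinned by an independent computation, not by the nationwide figures the
campaign reported, which used all provinces.

## Problem sizes and numerical choices

The reference recovery condition is 300 samples per class per zone with
the default noise and cloud rates; both model families reach test OA
≥ 0.95 there, and a model trained on one synthetic year transfers to a
matched second year within 0.03 OA.  The center-loss comparison uses 150
samples per class, 50 epochs and three fixed seeds, comparing the median
test-set intra-class feature dispersion with `w2` = 0.001 versus 0.  The
demonstration pipeline runs three zones at 120 samples per class on 32×32
rasters.  Tolerances: loss and metric oracles agree with brute force to
1e-10/1e-12; affine gap-fill recovery is exact to 1e-12; probability rows
sum to 1 within 1e-6.

## Known limitations

* Separability under the default phenologies is high; the synthetic OA
  near 1.0 says the machinery is sound, not that real smallholder scenes
  are this easy.  The `separability` and `noise_sd` knobs exist to study
  degradation.
* The cloud-score constants are this package's own calibration against its
  own cloud model; they are not the unpublished constants of the source
  framework.
* GeoTIFF support covers the tags this pipeline writes and reads
  (pixel scale, tiepoint, an EPSG geokey, JSON description); it is not a
  general GeoTIFF/CRS implementation, and no re-projection is performed —
  area estimation assumes the supplied grid is equal-area.
* The exhaustive metric verification enumerates all 3×3 count matrices
  with entries in {0..5} through the vectorized metrics core; the scalar
  API is spot-checked against per-matrix brute force on top of that.
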