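# Methods

## Problem setting

Raised bogs under peat extraction, agriculture and forestry emit CO₂ rather
than sequestering it. Quantifying this requires (i) a land-use map at a
resolution fine enough to separate extraction classes, (ii) an honest,
design-based estimate of each class's area (a map's pixel count is biased by
classification error), and (iii) emission accounting that propagates the
uncertainty of per-class emission factors. `bogmap` implements this chain
and, because wall-to-wall reference imagery cannot ship with a package, a
synthetic-scene generator that serves as its test bed.

## Synthetic scenes

**Class map.** Seed points are scattered uniformly (one per `patch_scale`²
pixels, default 20² = 400 px), apportioned to the seven classes by largest
remainder on the requested proportions, and each pixel takes the class of
its nearest seed. Nearest-seed labelling is uniform-speed region growing, so
patches are contiguous Voronoi cells with mean area `patch_scale`²; because
seed *counts* are deterministic, realised class shares concentrate tightly
around the request (within ±2 pp at 500×500 in practice; the generator
contract guarantees ±5 pp at ≥200×200). Default proportions
(0.10, 0.11, 0.43, 0.21, 0.13, 0.01, 0.01) mirror a realistic
grassland-dominated raised-bog landscape. Pixel area defaults to 0.01 ha
(a 10 m pixel).

**Spectra.** The signature catalogue is a fixed constant table chosen to
satisfy the qualitative orderings of real bog spectra — built-up brightest
in the visible, water darkest in the NIR, grassland and cutaway high-NIR,
cutover vs remnant peatland the closest pair (Euclidean distance 0.035),
SWIR inter-class spread below every visible/NIR band — and explicitly *not*
digitised from any published curve. `default_signatures()` accepts a seed
for interface uniformity but ignores it: jittering the table could silently
break the ordering contracts the tests rely on. Default per-band noise SD
is 0.005 (reflectance units), which keeps every class pair separated by
>3 SD in at least one visible/NIR band; the end-to-end tests run at the
harsher 0.01.

**Clouds.** Per scene, a target fraction is drawn uniformly from the
configured range, and a Gaussian-smoothed white-noise field (σ = 8 px) is
thresholded at exactly that quantile: spatially correlated blob clouds with
an exact realised fraction (per-pixel Bernoulli clouds would be an
unrealistically easy case for a median compositor). Flagged pixels carry the
opaque-cloud bit (10) or, for a random 20 %, the cirrus bit (11) — the QA60
bit layout. When ≥5 scenes are generated with an upper cloud bound ≤0.5, the
series is *repaired* so every pixel is clear somewhere: each always-cloudy
pixel has its QA bits cleared in the currently cloudiest scene. Repair is
used instead of rejection sampling because the acceptance probability of a
fully clear rejection draw vanishes on large grids; the guarantee and the
exact QA-fraction bookkeeping are unaffected.

**Training polygons.** Square `polygon_size`×`polygon_size` blocks (default
3×3) drawn without overlap from the pure-class positions of the truth map,
inset by ¼ pixel so neighbouring blocks never touch. Polygon size is a
parameter rather than a fitted distribution: real training campaigns have
strongly uneven polygon sizes, and nothing downstream depends on the shape.

## Compositing

Scenes at or above the cloud-fraction threshold (default 10 %, strict `<`)
are dropped; QA-flagged pixels become nodata; the composite is the per-pixel
per-band median of clear observations (even counts: mean of the central
pair). Indices are computed *after* the median, from the composited bands.
Nodata is NaN plus an explicit mask property — never a sentinel reflectance.
The median gives the compositor its key robustness property (one gross
outlier among ≥5 clear observations leaves the composite unchanged) and
reduces effective noise by roughly 1.25/√k for k clear looks, which is why
the classifier comfortably exceeds the raw per-scene Bayes accuracy.
Degenerate index denominators (band sum 0) yield nodata, not exceptions.
A nearest-neighbour `resample_nearest` helper covers 20 m → 10 m band
ingest, duplicating values exactly.

## Classification

scikit-learn's `RandomForestClassifier` is the trainer (n_estimators = 20,
`max_features` = ⌊√12⌋ = 3, Gini, bootstrap of size n, unlimited depth,
minimum leaf 1 — the common defaults of this model family where not
otherwise specified). At training time every tree is exported to flat
arrays (children, split feature, threshold, leaf class), and *prediction
always runs on these arrays*: each tree votes, and the plurality class wins
with ties broken deterministically toward the lowest class code. This keeps
the documented JSON serialisation (`bogmap-forest-v1`) and the in-memory
model on one code path — a model loaded from disk predicts bit-identically.
Training rows with any nodata feature are dropped, not imputed; pixels are
assigned to polygons by pixel-centre containment, which is unambiguous at
zero-width boundaries. Variable importances are the impurity-based (MDI)
scores normalised to sum to 1; on synthetic data their ordering is
data-dependent and only the constructed contracts (an informative feature
ranks first, a pure-noise feature last) are asserted.

## Validation and unbiased areas

Sample allocation is proportional to mapped area with a per-stratum floor
(default 50 points — rare classes would otherwise get a handful of points),
pinned classes cascading and largest-remainder rounding making counts sum
exactly to the total. Points are uniform without replacement within each
stratum. Reference labels come from the truth map (optionally flipped at a
seeded error rate to emulate photo-interpretation error).

From the confusion matrix (rows = map, columns = reference):

* count accuracies: OA = Σnⱼⱼ/n, UAᵢ = nᵢᵢ/nᵢ., PAⱼ = nⱼⱼ/n.ⱼ, stored at
  full precision with a display helper that truncates to integer percent
  (the convention of printed accuracy tables);
* area-based error matrix: p̂ᵢⱼ = Wᵢ·nᵢⱼ/nᵢ. with Wᵢ the mapped-area share;
* unbiased areas: Âⱼ = A_total·Σᵢp̂ᵢⱼ, with
  SE(p̂.ⱼ) = √( Σᵢ Wᵢ²·qᵢⱼ(1−qᵢⱼ)/(nᵢ.−1) ), qᵢⱼ = nᵢⱼ/nᵢ., and 95 % CIs at
  z = 1.96 (normal approximation; the finite-population correction is
  omitted, making the CIs slightly conservative for small strata).

Count OA and area-based OA (trace of p̂) are distinct under floor
allocations and are reported separately; the area-based version is the
consistent estimator of map-wide pixel agreement. A class present only in
the reference labels (never mapped) forms a legitimate zero-weight,
zero-sample stratum; a *mapped* stratum with no samples or no area is an
error. When the matrix is diagonal the estimator collapses to pixel
counting with zero SE.

Monte-Carlo check (500 replicates on a fixed 200×200 truth map with 10 % of
pixels flipped): per-class bias is statistically zero and CI coverage sits
at 93–96 %. Note the per-class "within 2 MC standard errors" bias check is
itself a statistical test: across 7 classes a correct estimator trips it in
roughly a quarter of reseedings, so the suite fixes its seeds and the
acceptance script reports the t-statistics without asserting.

## Emissions

Emission = area × EF per (class, tier), ranges = area × EF bounds; rounding
to integer tonnes and 2-dp megatonnes happens only at display. The packaged
factor table carries IPCC Tier 1 wetland defaults and Irish literature
Tier 2 values for cutover, cutaway, forestry and grassland; remnant
peatland, water and built-up have no factors and are reported as excluded,
never as zeros. Two documented quirks: (1) in the source compilation the
printed per-class Tier 2 totals for the two extraction classes match the
cutover/cutaway factors *swapped*; the package keeps the factors as
labelled and attaches a note to any report containing both. (2) Tier totals
sum per-class bounds, which assumes perfect dependence between classes and
overstates the combined interval; the output labels this a "naive range"
(a properly propagated interval would need the error covariance of the
factors, which the sources do not publish). The EF table is external,
documented CSV, so refined national factors can be swapped in.

## Problem sizes and determinism

Default test-bed sizes were chosen as the smallest grids at which the
statistical contracts are comfortably non-marginal: 150×150 for unit
fixtures, 200×200 / 500 replicates for the Monte-Carlo calibration,
300×300 / 10 scenes for end-to-end recovery (≈3 s). Every random draw flows
from an explicit integer seed through `numpy.random.default_rng`; identical
configs reproduce byte-identical artefacts, and the CLI records config
hashes and file checksums in per-stage manifests.

## Limitations

The generator emulates class geometry, spectral separability, noise and
cloud occlusion — not radiative transfer, mixed boundary pixels, seasonal
phenology, topographic or adjacency effects. Passing tests therefore
demonstrate the correctness of the *pipeline machinery and estimators*, not
the accuracy attainable on real imagery; real-data overall accuracy is
bounded by label quality and class mixing that the synthetic bed does not
contain. The classifier is intentionally the stock random-forest family
(no hyperparameter search beyond the fixed 20-tree, √-features design);
probabilistic outputs, CH₄/N₂O accounting and fluvial carbon exports are
out of scope.
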