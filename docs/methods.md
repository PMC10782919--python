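# Methods

This note documents the models, parameter choices and numerical decisions in
`ihcmil`, and what the synthetic experiments do and do not demonstrate.

## Preprocessing

Slides carry a physical pixel size (µm/px). Annotated regions of interest
(QuPath-dialect GeoJSON polygons) are rasterized; pixels outside the ROI
union are set to pure white before the bounding-box crop, so excluded
regions also fail the downstream edge QC. Slides are resampled bilinearly to
256/224 ≈ 1.1429 µm/px, making one 224-px tile cover 256 µm of tissue, and
tessellated on a regular 224-px grid (partial boundary tiles dropped; counts
are `floor(H/224) · floor(W/224)`). Coordinates are (row, col), 0-based,
origin top-left, half-open tile extents `[r, r+224)` — fixed once here
because heatmap/tile alignment depends on it.

Tile QC computes the Canny edge fraction on ITU-R 601 luminance scaled to
[0, 1] (Gaussian σ = 1.0, hysteresis thresholds 0.10/0.20). The thresholds
are **absolute** on that scale, not relative to the per-tile gradient
maximum: per-tile-relative thresholds would make the detector
contrast-invariant, so a blank tile containing only faint sensor noise would
report edges and defeat the blank-tile rejection that the filter exists for.
Tiles with edge fraction < 0.02 are discarded (reason `low_edge`). The 2%
criterion is interpreted as a *pixel* fraction — the fraction of tile pixels
the detector marks as edges. QC runs after resampling, i.e. on the tiles as
the encoder sees them.

## Tile encoders

Encoders are pure functions `tile → vector` behind a registry, with a fixed
output dimension (default 2048, matching the shape convention of large
pretrained extractors; desk-scale runs use 48–64). The MIL stage never
backpropagates into the encoder, so bags are precomputed once per slide.

The default `stain_stats` encoder converts the tile to optical densities
`OD_c = −log10((I_c + 1)/256)` (the +1 pseudo-count avoids log 0; a white
pixel has OD exactly 0, a black pixel saturates at −log10(1/256) ≈ 2.408)
and unmixes them into hematoxylin and DAB concentrations by least squares
against the Ruifrok–Johnston stain vectors (rows unit-normalized). The
39 base features are: 16-bin histograms of each unmixed channel over
[0, 2.5], mean/SD/positive-fraction per channel (positive = concentration
> 0.15), and a gradient-energy term; the base vector is tiled cyclically to
the requested dimension. Swapping the two stains in a tile swaps the two
feature blocks, which is tested. Features are not L2-normalized; the MIL
trainer standardizes them instead (below). A frozen random-filter
convolutional encoder (`conv_small`) is registered for texture-generic
tests.

## Attention-MIL classifier

Standard (non-gated) tanh attention with hidden size L = 128, a single
linear + sigmoid classification head, trained with binary cross-entropy one
bag per step using Adam at lr 10⁻⁴, at most 100 epochs. Gradients are
hand-derived and verified against numerical differentiation; everything is
numpy, deterministic given the seed.

Two training details matter at small cohort sizes and were chosen after the
naive variants demonstrably failed:

* **Feature standardization.** Each fold standardizes every feature
  dimension (mean/SD over the training bags' instances); the affine
  transform is stored with the fold's weights and applied identically at
  prediction and dense-heatmap time. Raw stain statistics are O(0.01) in
  scale, and with lr 10⁻⁴ the unstandardized logits stay at 10⁻⁵ after a
  full training budget — ranking can still be perfect while every score sits
  at 0.5 and the fixed 0.5 ensemble threshold degenerates.
* **Zero-initialized head.** `W_c = 0` at initialization, so the first head
  gradients follow the between-class difference of the pooled embeddings.
  With a random head and few bags relative to the feature dimension
  (n_bags < ~2·D), per-bag updates can memorize the cohort through the noise
  dimensions — training AUC 1.0, held-out AUC at or below chance — and the
  planted signal is never learned.

Early stopping monitors the validation split (20% of each fold's non-test
bags, stratified) with patience 10. The checkpoint criterion is
lexicographic: validation AUC first, validation loss as tiebreak. On small
cohorts the AUC saturates within a few epochs; restoring the first AUC peak
freezes the attention weights before they concentrate on discriminative
tiles (bags classify correctly while attention still points at stroma).
Tracking the still-falling validation loss lets the checkpoint mature, and
genuine overfitting still triggers the patience stop.

Cross-validation is stratified 5-fold (test folds partition the cohort,
class proportions preserved); slides of the same patient never straddle the
test boundary. Deployment scores are the arithmetic mean of the five fold
models; binary status calls use a fixed 0.5 threshold (configurable). For
explainability the fold model with the best training AUC is selected (ties:
lowest fold index). AUC is computed by the midrank Mann–Whitney formula,
which equals brute-force pairwise concordance with ties counted half. No
class reweighting is applied by default.

## Attention heatmaps

The "32 × 32 kernel" of the fully-convolutional formulation is implemented
as its mathematical equivalent: an explicit 224-px window evaluated every 32
px, storing the raw attention logit `e = wᵀ tanh(V h)` per window. At
stride = window the grid coincides with the tessellation and the dense map
must equal the per-tile logits of the bag-prediction path to 10⁻⁵ — the
module's primary correctness test. Windows lie fully inside the slide (no
padding). Display normalization is per-slide min–max on the logits; an
all-equal map normalizes to the constant 0 (softmax over ~10⁵ windows would
be numerically uninformative for display). Overlays upsample the grid
(nearest or bilinear, recorded) and alpha-blend under a matplotlib colormap.

Attention localization to tumor regions is an *emergent, empirical* property
— it requires roughly 15 training bags and a full (~100-epoch) training
budget with the stain-stats encoder, and it degrades when immune aggregates
carry independent DAB staining (the CPS confound) at very small cohort
sizes. The localization test therefore uses a 30-slide confound-free cohort;
the bag-level benchmark (below) checks the same mechanism instance-wise.

## Survival statistics

Implemented from the defining formulas; `lifelines` serves only as an
independent oracle in the tests.

* **Kaplan–Meier**: product-limit estimator; median = smallest event time
  with S ≤ 0.5, IQR reported as the 0.75/0.25 crossing times; unreached
  crossings are NaN ("not reached"). Confidence bands use the log-log
  (exponential Greenwood) transform; the median's 95% CI is read off the
  band crossings of 0.5. Events precede censorings at tied times.
* **Log-rank**: observed-minus-expected chi-square with hypergeometric
  variance at each distinct event time, 1 df. The statistic equals the Cox
  score test (Breslow) on tie-free data, which is asserted.
* **Cox PH**: single-covariate partial likelihood maximized by
  Newton–Raphson with step-halving; Efron tie correction by default
  (Breslow available) — PFS in months is heavily tied, where the choice
  matters. Wald CI/p. Non-convergence raises; monotone likelihood (complete
  separation) raises "infinite HR" rather than returning a divergent
  estimate.

A DeLong variance utility for a single AUC is provided for AUC confidence
intervals; survival curves themselves are compared with the log-rank test
(DeLong applies to AUCs, not KM curves).

## Synthetic data

`generate_slide` renders what the pipeline actually measures, not
photorealistic histology: tumor cells are 4–8 px discs with 2-px membrane
rings (DAB brown ≈ RGB(140, 90, 40) ± 10% jitter on a positive fraction
`true_tps`, drawn i.i.d. Bernoulli so the realized TPS is a binomial
statistic), immune aggregates are dense 2–3 px hematoxylin dots
(≈ RGB(60, 60, 140)) with an independent DAB-positive fraction (the CPS
confound), stroma is pale-pink fibrous texture, background is near-white,
and a chosen fraction of tissue blocks is Gaussian-blurred (σ = 6) to
emulate focus artifacts that fail edge QC. Slides are composed from
tile-sized blocks assigned to compartments in the requested proportions.
Ground-truth masks and cell counts are returned alongside.

`generate_cohort` links slides to a clinical table (patient/slide ids, tumor
type, TPS/CPS, PFS, event, best response, baseline flag). Labels are exactly
balanced by construction. PFS is exponential — median 2.7 months in the low
group, matching the scale of reported ICI cohorts — with the low-group
hazard `hazard_ratio` times the high-group hazard, so medians scale in
closed form (enabling derived checks). Censoring is exponential with the
rate set per group so the censoring probability equals `censor_rate` exactly
while remaining independent of the event time (default 0.2). Multi-biopsy
patients are supported via `n_patients < n_slides` with one baseline slide
per patient. `generate_feature_bags` is the imaging-free benchmark: N(0, I)
instances, signal instances shifted by `separation` along axis 0, positive
bags containing at least one signal instance.

The bundled 60-slide demo cohort (1,344 px slides, planted HR 2.0) is a
fixed artifact: `demo_config()` pins the cohort seed while training follows
the run seed, so demo reruns retrain the same data. At n = 60 the log-rank
test has only ~0.68 power against HR 2.0, so a freshly drawn cohort would
turn the demo's significance check into a coin flip that measures sampling
noise rather than the pipeline.

What passing these tests shows — and does not. The synthetic slides share
with real IHC only the properties the pipeline exploits: stain colors,
blank/blurry regions, tile-level composition, and a label defined by the 1%
TPS cutoff. They contain no scanner noise, stain batch variation, tissue
deformation, necrosis, melanin or other pigments, and the class-conditional
TPS gap (≤ 0.5% vs ≥ 5%) is wider than the near-cutoff cases that dominate
real false negatives. Recovery of planted labels, attention enrichment,
hazard ratios and response-rate arithmetic validates the *machinery*; it
does not certify clinical performance on real cohorts, which additionally
depends on a pretrained feature extractor and real staining variability.

## Problem sizes and defaults

| Parameter | Default | Why |
|---|---|---|
| target resolution | 256/224 µm/px | 224-px tile = 256 µm edge |
| tile size | 224 px | standard encoder input |
| edge threshold | 0.02 | blank/blurry discard rule |
| encoder dim (desk scale) | 48–64 | 39 base stain features, cyclic tiling |
| attention hidden L | 128 | standard tanh-attention size |
| lr / epochs / patience | 1e-4 / 100 / 10 | fixed for reproducibility |
| k folds | 5 | stratified, patient-grouped |
| ensemble threshold | 0.5 | status calls; configurable |
| heatmap stride | 32 px | dense-map output grid |
| demo cohort | 60 slides, 1344 px | exercises every stage in minutes on one CPU |
| MIL benchmark | 200 bags × 50 × 64-d, sep 6, 10% positive | planted-signal recovery target |

Monte-Carlo test sizes (100 Cox recoveries at n = 1,000; 500 null log-rank
simulations; 50 KM/empirical comparisons) were chosen so each check is
statistically decisive while the whole suite runs in about two minutes.

## Known limitations

* Single-covariate Cox only (the analysis needs a binary group or a
  continuous score); no multivariable adjustment or competing risks.
* No pyramidal WSI decoding (SVS/NDPI); inputs are plain raster images with
  a known µm/px.
* The pretrained-extractor contract is exercised by deterministic
  stand-ins; no attempt is made to reproduce pretrained-feature behavior.
* Attention localization is demonstrated on confound-free synthetic cohorts;
  with strong immune staining and very few slides the attention can settle
  on non-tumor tissue while bag-level discrimination stays perfect.
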