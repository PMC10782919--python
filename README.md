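# ihcmil

Weakly supervised prediction of PD-L1 status from immunohistochemistry (IHC)
whole-slide images, with attention-based explainability and survival
stratification of the predicted status.

## The problem

PD-L1 expression, scored by pathologists as the tumor proportion score (TPS:
the percentage of tumor cells with membranous DAB staining), guides immune
checkpoint inhibitor (ICI) therapy. Manual TPS scoring is laborious and shows
inter-observer variability, and classical image-analysis pipelines need cell
detection and tumor annotations. `ihcmil` implements the alternative: a
*weakly supervised* classifier that learns slide-level PD-L1 status
(TPS ≥ 1% vs < 1%) directly from the slide with no cell-level annotations,
explains its predictions through attention heatmaps, and tests whether the
predicted status stratifies progression-free survival (PFS) under ICI
therapy.

The package is aimed at computational-pathology researchers who want a
transparent, CPU-sized, fully testable implementation of this analysis. A
synthetic-slide module generates IHC-like images with known ground truth
(TPS, CPS, tumor/immune masks, planted survival effects) so every stage runs
and is verifiable without access to clinical slide archives.

## The model

A slide is tessellated into non-overlapping 224 × 224 px tiles at
256/224 µm/px (one tile spans 256 µm of tissue); blank and blurry tiles —
those with a Canny edge fraction below 2% — are discarded. Each kept tile is
encoded into a feature vector *h<sub>k</sub>* by a pluggable encoder (the
default summarizes Ruifrok–Johnston stain-deconvolved hematoxylin/DAB
optical densities). The slide is then a *bag* of instances with one weak
label, classified by attention-based multiple-instance learning:

```
e_k = wᵀ tanh(V h_k)          attention logit per tile
a   = softmax(e)              convex tile weighting
z   = Σ_k a_k h_k             attention-weighted bag embedding
p   = σ(W_cᵀ z + b)           slide-level P(PD-L1 high)
```

Training minimizes binary cross-entropy one bag at a time (Adam, lr 10⁻⁴)
with stratified 5-fold cross-validation; deployment averages the five fold
models' scores. The attention weights double as the explainability signal:
`ihcmil.heatmaps` slides the attention scorer densely across the slide
(224-px window, 32-px stride — the output grid of the fully-convolutional
equivalent) to render high-resolution attention heatmaps. Predicted status
groups are compared with Kaplan–Meier curves, the log-rank test and a Cox
proportional-hazards model, all implemented from their defining formulas in
`ihcmil.survival`.

## Worked example

The bundled demo simulates a 60-slide cohort (1,344 × 1,344 px slides, half
PD-L1 high, planted hazard ratio 2.0 for low vs high status), preprocesses
and encodes every slide, trains the 5-fold MIL classifier, renders a
heatmap, and stratifies PFS by the predicted status — in a few minutes on
one CPU:

```python
from ihcmil.pipeline import demo_config, run
out = run(demo_config("runs/demo", seed=7))
print((out / "report.md").read_text())
```

```
# ihcmil run report

## Cross-validated PD-L1 status classification
- per-fold test AUC: [0.889, 1.0, 1.0, 1.0, 1.0]
- mean ± sd: 0.978 ± 0.044
- overall accuracy at threshold: 0.967

## Survival stratification (predicted status)
- median PFS high vs low: 5.948948993769997 vs 3.403869985640702 months
- log-rank p = 0.007469
- Cox HR (low vs high) = 2.12 (95% CI 1.21–3.72)
```

Reading: the classifier recovers the planted slide labels almost perfectly
from pixels alone (mean test AUC 0.978); patients predicted PD-L1 high live
progression-free markedly longer (median 5.9 vs 3.4 months), and the Cox
hazard ratio of 2.12 for low-vs-high status brackets the planted value of
2.0. The run directory also contains `predictions.csv`, the KM plot
(`km.png`), an attention heatmap/overlay pair, per-tumor-type confusion
metrics and a provenance manifest.

The same stages are available as a CLI (`ihcmil run | simulate | preprocess
| extract | train | predict | heatmap | evaluate | survival`); see
`ihcmil --help`.

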