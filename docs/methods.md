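# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of `cytoscreen`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Taxonomy and class merging

The annotation vocabulary has 24 classes (C1–C24), each mapped to one or
more TBS 2014 diagnoses and a lesion category. At detection time,
morphologically similar classes merge (C1+C2 atypical glandular; C4+C5
low-N/C squamous; C6–C10 high-N/C squamous and carcinoma) and pure
background classes (MC, RC, GEC, Neutrophils, Mucus, Debris) are excluded;
the stated merge rules enumerate to **12 detection classes**. Because
grouping conventions differ between deployments, the whole table ships as
CSV package data rather than code: swapping the CSV swaps the taxonomy,
and `n_detection_classes` is derived, never hard-coded. TBS codes are
canonical upper-case; `NIL` is accepted on read as an alias of `NILM`.
The merged `AGC` code is a prediction-level pooling of AGC_NOS/AGC_FN/
AIS/ADC (too few glandular cases exist to subtype them reliably, and
their management is the same); it never appears as a Table target.

## Geometry conventions

Pixel coordinates are 0-based with half-open boxes `[x, x+w) × [y, y+h)`,
which makes tiling arithmetic exact. Annotation ROIs larger than 608 px on
a side are decomposed by a deterministic near-equal grid
(`ceil(side/608)` strips per axis); human annotators split along lesion
morphology, which a machine cannot reproduce, so the grid is the
reproducible stand-in — the contract (disjoint tiles, exact cover,
max side ≤ 608) is what downstream code relies on. Context windows are
1216 × 1216 centered on the target and shifted inward at slide borders
rather than padded, preserving true pixel statistics; only a slide
smaller than 1216 px yields a smaller window. The fine-classifier input
normalization (299 × 299 bilinear) is provided as a utility. Overlapping
detections can be deduplicated on ingestion by greedy same-class IoU
suppression (threshold configurable, default 0.5) since upstream
suppression settings are deployment-specific.

## Nucleus morphometry

Crops are converted to gray with ITU-R BT.601 weights (0.299, 0.587,
0.114) — the convention is stated explicitly for bit-reproducibility. The
nucleus statistic is the arithmetic mean gray under the mask (median and
integrated optical density are plausible alternatives; mean is the
implemented choice), with pixel area and physical area at the assumed
scan resolution of 0.25 μm/pixel (1 px = 0.0625 μm², exact). Multiple
connected components are summarized jointly with their count recorded.
An empty mask raises, signalling failed upstream segmentation.

## The 121-feature schema

The deployed feature list of the original screening system is not public,
so the shipped default is this package's own construction covering every
evidence source, declared in YAML-serializable form:

| block | features |
|---|---|
| per detection class (12): count, max, mean probability | 36 |
| per included refined class (18): count, max probability | 36 |
| per refined squamous class (8): counts above 0.5 / 0.9, top-5 mean | 24 |
| per patch label (4): mean probability | 4 |
| nucleus gray/area quantiles q∈{0.1,0.5,0.9} for SC, ASC_L_S, ASC_H_S | 18 |
| global: total targets, squamous targets, overall max probability | 3 |

Empty-set statistics are encoded as 0 **with a missing flag** and fed to
the boosted models as NaN, which routes them down learned default
branches; counts are never missing. Aggregation sorts records internally
(probability, then coordinates) before any floating-point reduction, so
the vector is bit-identical under input permutation. Split-count feature
importance divides each feature's split count by the total; an all-zero
count vector yields all-zero importances by convention.

## Decision engine

**Stage 1 (positive/negative squamous).** Stratified k-fold (default
k=10, seeded) over the labelled corpus; one gradient-boosted classifier
per fold, trained on the other k−1 folds. Hyperparameters are
conservative defaults (60 trees, depth 3, learning rate 0.3, exact
histogram method, single thread) — the decision layer's behavior comes
from the ensemble rule, not from model tuning. The slide is positive iff
**any** member's score reaches its threshold.

**Threshold tuning.** `tune_sensitivity` targets ensemble sensitivity 1.0
on the tuning set while keeping specificity as high as the union rule
allows. Exact maximization is a set-cover problem, so a deterministic
greedy is used: each member starts at the lowest threshold admitting no
tuning-set negative (covering the positives it separates cleanly); each
remaining uncovered positive is then assigned to the member whose
threshold drop admits the fewest new negatives, hardest positives first.
On a separable tuning set this admits no negative at all; in general the
tests bracket it between the naive per-member-minimum baseline and an
exhaustive grid search. Lowering any threshold can only add positive
calls (monotone contract). Per-member thresholds are stored; a member may
be parked above the score range (sentinel 2.0), meaning it never fires.

**Stage 2 (subtype).** A multiclass boosted model over positive slides
assigns ASCUS/LSIL/ASCH/HSIL/SCC; exact probability ties break toward the
**less severe** subtype, because false escalation has communication cost
while within-group confusion does not change management.

**Logic tree.** TRI, CAN, HSV, ACTINO, CC, EMC and merged AGC each fire
independently on a rule `count(class, refined_prob ≥ p) ≥ n`. Defaults
(p=0.6 throughout; n=3 for TRI/CAN/ACTINO/CC, n=2 for HSV/EMC/AGC, the
rarer or lower-burden findings) were calibrated once against the shipped
synthetic corpus and are fully overrideable — deployed thresholds would
be re-derived on real data by the same shallow-tree + expert procedure
they stand in for.

**Final report.** When several branches fire, the single reported lesion
follows treatment priority
`SCC > HSIL > ASCH > AGC > LSIL > ASCUS > EMC > HSV > TRI > ACTINO > CAN > CC > NILM`
(an explicit ordering by treatment urgency of the TBS 2014 categories;
the principle — report the lesion demanding the most urgent care — is
standard, the exact order is this package's choice). The report retains
the full evidence trail: member scores and votes, subtype probabilities,
per-branch firings, and a priority-applied flag.

Models persist as a directory of portable boosted-model JSON files plus
schema YAML, thresholds and seed.

## Quality control

Tiling is a truncating grid (nominal 6000 × 6000 px; edge tiles flagged,
never padded). Focus is the variance of the 4-neighbour 3 × 3 Laplacian
response — the common variance-of-Laplacian measure; defocus suppresses
second derivatives, and the monotone decrease under Gaussian blur is
property-tested. Color uses the classic HSI model (I = (R+G+B)/3,
S = 1 − min/I, geometric hue; achromatic pixels bin at hue 0) with
histograms of 16–32 bins per channel normalized to sum 1. Cellularity is
the dark-class area fraction under the Otsu threshold — Papanicolaou
staining is dark on a bright-field background; polarity is a flag.
A constant tile has no bimodality and returns 0 by convention; note Otsu
on a *noisy but empty* tile splits the noise near its median, so the
ratio alone does not measure cellularity on degenerate inputs — the gate
combines it with focus and histogram features. Slide-level features are
tile quantiles (0.1/0.5/0.9) and means of log-focus and cellularity plus
mean per-channel histograms, scored by a boosted gate thresholded at 0.5.

## Synthetic generators

The record generator emulates the statistical shape of screening
corpora. Class mix defaults to a screening-like composition: 50% NILM,
40% squamous lesions (ASCUS 8%, LSIL 10%, ASCH 6%, HSIL 10%, SCC 6%),
3% AGC, 2% EMC, 5% infectious — glandular and endometrial findings
deliberately rare so rare-class handling is exercised. Lesion slides
plant Poisson counts of their characteristic classes (e.g. LSIL: mean 8
koilocytes plus low-N/C atypicals; SCC: mean 11 carcinoma cells) with
Beta(8,2) refined probabilities (mean 0.8); ASCUS and ASCH use milder
distributions (Beta(5,3), Beta(6,2.5)) reflecting their equivocal
morphology. Every slide carries Poisson(15) normal-cell background, and
Poisson(1.5) low-probability (Beta(1.5,8)) false-positive detections.
Detection probability is the refined probability plus N(0, 0.08) noise,
clipped. Patch evidence (True_\*/False_\* with Beta(8,2) confidence)
attaches to squamous classes only; nucleus gray is Normal per class
(SC 120±12, ASC_L_S 100±12, ASC_H_S 70±12 — lesion nuclei darker and
larger). Allocation of n slides to the mix uses largest remainder;
slide i draws from `SeedSequence([seed, i])`, so corpora regenerate
byte-identically and piecewise.

The tile generator renders disk cells (dark nucleus, pale cytoplasm;
EA-36-like pink or EA-50-like cyan palettes) on a bright background,
painting until a planted coverage fraction is reached, then applies
stain-contrast scaling, Gaussian defocus blur, and sensor noise. The
four quality presets perturb exactly one factor: defocus (σ=6),
low-cellularity (coverage ≤ 3%), poor-stain (contrast 0.22). Default
tile side is 192 px — the metrics are resolution-local, so desk-scale
tiles exercise the same code paths as the nominal 6000 px tiles.

**What passing tests do and do not show.** The generators produce
well-separated evidence by design; recovering the planted truth shows
the decision layer is correct and calibrated end-to-end, not that it
would match clinical performance — real smears have correlated errors,
preparation artifacts, and class overlap the simulation does not model.
No photorealistic cytology rendering or scanner-optics emulation is
attempted.

## Study conditions and problem sizes

The standard experiment trains on 600 synthetic slides and evaluates on
300 held-out slides (seeded); the QC gate trains on 240 tiles and
evaluates on 200 spanning the four presets. These sizes give stable
estimates (binomial SE < 0.02 at the observed rates) while keeping the
whole pipeline in seconds on one CPU. Biopsy-cohort arithmetic uses
exact `Fraction` division before float formatting, reported to 9 decimal
places.

## Known limitations

- The 121-feature schema and logic-tree thresholds are package defaults,
  not the (unpublished) deployed ones; both are configuration.
- Stage-1/stage-2 hyperparameters are deliberately conservative; no
  search is performed.
- The greedy threshold tuner is not guaranteed optimal on non-separable
  tuning sets (set-cover hardness); it is bracketed by tests.
- ASAP I/O covers rectangle and polygon annotations via bounding boxes;
  no multi-polygon lesion topology.
- No whole-slide pyramid decoding: inputs are pre-extracted tiles/crops.
- Otsu cellularity is meaningless on unimodal tiles (see above).
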