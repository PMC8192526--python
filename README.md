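# cytoscreen

Slide-level Bethesda-system (TBS) diagnosis for cervical liquid-based
cytology, built for the decision layer that sits *between* per-cell deep
models and the signed-out report.

## The problem

Screening a cervical smear means finding a handful of abnormal cells among
tens of thousands, then translating that evidence into one of the TBS 2014
reporting categories — negative (NILM), squamous lesions (ASCUS, LSIL,
ASCH, HSIL, SCC), glandular lesions (the AGC family), endometrial cells
(EMC), and infectious findings (Trichomonas, Candida, HSV, Actinomyces,
clue cells). Upstream detectors and classifiers produce *per-target*
evidence; the clinically hard part is the slide-level call. `cytoscreen`
implements that decision layer:

- a **24-class annotation taxonomy** (C1–C24) with its TBS correspondences,
  detection-time class merging, and clinical reporting groups;
- **per-target evidence records** fusing detector class/probability,
  refined 24-class probability, patch-level true/false review, and nucleus
  morphometry, with ASAP-XML annotation and JSON-lines record I/O plus the
  ROI geometry rules (608-px decomposition, 1216-px context crops);
- **slide-feature aggregation** into a named 121-feature vector (counts,
  probability statistics, nucleus gray/area quantiles) with explicit
  missing-value flags;
- a **two-stage boosted decision engine**: a k-fold (default k=10)
  gradient-boosted ensemble calls squamous-lesion positivity with an
  *any-positive* union rule — the screening-oriented trade of specificity
  for sensitivity — followed by a subtype model; per-member thresholds can
  be tuned to drive training sensitivity to 1.0;
- a **logic tree** of `count(class, prob ≥ p) ≥ n` rules for infectious,
  glandular (merged AGC = AGC_NOS/AGC_FN/AIS/ADC) and endometrial calls,
  and a **clinical-priority** rule that reports a single lesion;
- a **digital image quality-control gate** (variance-of-Laplacian focus,
  HSI histograms, Otsu cellularity, boosted classifier) that rejects
  unscorable scans;
- **synthetic generators** for record corpora with controllable TBS truth
  and for smear tile images with controllable focus/stain/cellularity, so
  every stage is trainable and testable without clinical data.

The union rule is the statistical heart: with member calls
$v_1,\dots,v_k$, the slide is positive iff $\bigvee_j v_j$, so ensemble
sensitivity is at least any member's and ensemble specificity at most any
member's — the correct direction for a screening test.

## Worked example

Train on a 400-slide synthetic corpus, evaluate on 200 held-out slides
(`python examples/03_train_and_diagnose.py`):

```
training corpus: 400 slides; held out: 200

held-out intraepithelial sensitivity: 1.000 (n=86)
held-out other-lesion sensitivity:    0.714 (n=14)
held-out specificity:                 0.990 (n=100)
exact squamous subtype accuracy:      0.963

example report: truth LSIL -> LSIL (10/10 members voted positive)
```

Sensitivity is computed under clinical-group equivalence: an HSIL slide
called ASCH still reaches colposcopy, so within-group subtype confusion is
not an error; the exact-subtype rate (0.963 here) is the stricter number.
Biopsy-cohort arithmetic (`python examples/05_biopsy_sensitivity.py`)
computes sensitivity = (positives − missed)/positives with exact rational
arithmetic, e.g. 837 positives with 44 missed → `0.947431302`.

The other examples cover the taxonomy and ASAP annotation round-trip
(`01`), feature aggregation (`02`), and the quality-control gate (`04`).
A thin CLI (`cytoscreen simulate|train|diagnose|qc|evaluate|report`) wraps
the same functions for shell use.

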