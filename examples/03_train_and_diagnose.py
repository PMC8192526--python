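"""Train the two-stage decision engine and diagnose held-out slides.

Stage 1 is a ten-member cross-validation ensemble with an any-positive
rule, threshold-tuned to training sensitivity 1.0; stage 2 subtypes the
positives; a logic tree catches infectious / glandular / endometrial
lesions; clinical priority picks the single reported lesion.
"""

import numpy as np

import cytoscreen as cs

schema = cs.default_schema()
train = cs.make_corpus(400, seed=42)
test = cs.make_corpus(200, seed=43, prefix="T")
print(f"training corpus: {len(train)} slides; held out: {len(test)}")

X, _, ids = cs.aggregate_corpus(train.records_by_slide(), schema)
truth = {s: t for s, t, _ in train.slides}
engine = cs.DiagnosticEngine(schema=schema, k=10, seed=42)
engine.fit(X, [truth[i] for i in ids])

sids, truths, preds = [], [], []
for sid, t, recs in test.slides:
    report = engine.diagnose(recs, slide_id=sid)
    sids.append(sid), truths.append(t), preds.append(report.final_tbs)

table = cs.build_evaluation_table(sids, truths, preds)
gm = cs.group_metrics(table)
print(f"\nheld-out intraepithelial sensitivity: "
      f"{gm['intraepithelial_sensitivity']:.3f} (n={gm['n_intraepithelial']})")
print(f"held-out other-lesion sensitivity:    "
      f"{gm['other_lesion_sensitivity']:.3f} (n={gm['n_other_lesion']})")
print(f"held-out specificity:                 "
      f"{gm['specificity']:.3f} (n={gm['n_negative']})")
print(f"exact squamous subtype accuracy:      "
      f"{cs.subtype_accuracy(table):.3f}")
# Group-level sensitivity forgives within-group subtype confusion (an
# HSIL called ASCH still reaches colposcopy); the exact-subtype rate is
# necessarily lower.

one = next((sid, t, r) for sid, t, r in test.slides if t == "LSIL")
rep = engine.diagnose(one[2], slide_id=one[0])
votes = sum(rep.squamous_branch["member_calls"])
print(f"\nexample report: truth {one[1]} -> {rep.final_tbs} "
      f"({votes}/10 members voted positive)")
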