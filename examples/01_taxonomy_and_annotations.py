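"""Taxonomy lookups and ASAP annotation round-tripping.

The 24 annotation classes (C1-C24) used by upstream detectors map onto
Bethesda-system (TBS) diagnoses; morphologically similar classes merge
into shared detection classes, and pure background classes are excluded
from detection entirely.
"""

import tempfile

import cytoscreen as cs

tax = cs.default_taxonomy()

print("annotation class -> TBS targets / detection class")
for idx in (4, 9, 11, 14, 16, 1):
    cls = tax[idx]
    print(f"  C{idx:<2} {cls.code:<12} -> {sorted(cls.tbs_targets)}"
          f"  (detector class: {cls.detection_class})")
print(f"\n{len(tax)} annotation classes merge to "
      f"{tax.n_detection_classes} detection classes")
print("clinical group of SCC:", cs.clinical_group_of("SCC"))
print("clinical group of CAN:", cs.clinical_group_of("CAN"))

# Expert annotations travel as ASAP XML; a rectangle labelled "KC" is a
# single koilocyte (class C4).
targets = [cs.AnnotationTarget("demo_slide", cs.BoundingBox(1200, 3400, 180, 150), 4)]
with tempfile.NamedTemporaryFile(suffix=".xml", mode="w", delete=False) as fh:
    path = fh.name
cs.write_asap_annotations(targets, path)
(back,) = cs.read_asap_annotations(path)
print(f"\nASAP round trip: class C{back.class_index} "
      f"({tax[back.class_index].code}) at {back.box}")
# The round trip is exact: coordinates and class are preserved, so
# annotation files can be regenerated without information loss.
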