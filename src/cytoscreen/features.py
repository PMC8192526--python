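"""Slide-level feature aggregation over per-target evidence records.

The decision engine never sees individual detections: a slide's record
stream is reduced to a fixed-length, named feature vector.  The schema is
declarative (:class:`FeatureSchema`, serializable to YAML) so the feature
set is configuration, not code.  The shipped default has 121 features
spanning every evidence source:

* per detection class (12 merged classes): record count, max and mean
  detection probability — 36 features;
* per refined (24-class) included class (18 classes): record count and
  max refined probability — 36 features;
* per refined squamous lesion class (C3–C10, 8 classes): counts above
  probability 0.5 and 0.9, and the mean of the top-5 refined
  probabilities — 24 features;
* per patch label (True/False HSIL/LSIL): mean patch probability — 4;
* nucleus morphometry for SC, ASC_L_S, ASC_H_S: gray-value and area
  quantiles at q in {0.1, 0.5, 0.9} — 18;
* global: total record count, squamous-lesion record count, overall max
  refined probability — 3.

Empty-set statistics (max over no records, quantile of no nuclei) are
encoded as value 0 with an explicit missing flag rather than NaN, so the
boosted model can route missing values down a learned default branch.
Counts are never missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import PATCH_LABELS, TargetRecord
from .taxonomy import Taxonomy, default_taxonomy

__all__ = [
    "FeatureDescriptor",
    "FeatureSchema",
    "SlideFeatureVector",
    "FeatureImportance",
    "default_schema",
    "aggregate_slide",
    "aggregate_corpus",
    "importance_from_splits",
    "importance_from_model",
]

logger = logging.getLogger(__name__)

_SOURCES = ("detection", "refined", "patch", "nucleus", "global")
_STATISTICS = (
    "count", "count-above-threshold", "max-prob", "mean-prob",
    "top-k-mean-prob", "quantile", "nucleus-gray-quantile",
    "nucleus-area-quantile",
)

#: Refined classes carrying squamous lesion evidence (C3..C10).
SQUAMOUS_REFINED = tuple(range(3, 11))
#: Refined classes with nucleus morphometry (ASC_L_S, ASC_H_S, SC).
NUCLEUS_REFINED = (3, 8, 12)


@dataclass(frozen=True)
class FeatureDescriptor:
    """One named slide-level statistic.

    ``class_scope`` selects records: a detection-class id for source
    ``detection``, a refined class index for ``refined``/``nucleus``, a
    patch label for ``patch``, or ``None`` for ``global``.
    """

    name: str
    source: str
    statistic: str
    class_scope: int | str | None = None
    threshold: float | None = None
    k: int | None = None
    q: float | None = None

    def __post_init__(self):
        if self.source not in _SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.statistic not in _STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")


class FeatureSchema:
    """Ordered, uniquely named list of :class:`FeatureDescriptor`."""

    def __init__(self, descriptors: Sequence[FeatureDescriptor]):
        names = [d.name for d in descriptors]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        self.descriptors = tuple(descriptors)
        self.names = tuple(names)

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __eq__(self, other) -> bool:
        return (isinstance(other, FeatureSchema)
                and self.descriptors == other.descriptors)

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        import yaml

        rows = []
        for d in self.descriptors:
            row = {"name": d.name, "source": d.source, "statistic": d.statistic}
            if d.class_scope is not None:
                row["class_scope"] = d.class_scope
            for key in ("threshold", "k", "q"):
                val = getattr(d, key)
                if val is not None:
                    row[key] = val
            rows.append(row)
        with open(path, "w") as fh:
            yaml.safe_dump({"features": rows}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls([FeatureDescriptor(**row) for row in doc["features"]])


@dataclass
class SlideFeatureVector:
    """Feature values for one slide, with per-feature missing flags."""

    slide_id: str
    values: np.ndarray
    missing: np.ndarray
    schema: FeatureSchema

    def to_array(self, missing_as_nan: bool = True) -> np.ndarray:
        """Dense float vector; missing entries as NaN (model input) or 0."""
        out = self.values.astype(float).copy()
        if missing_as_nan:
            out[self.missing] = np.nan
        return out

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.schema.names, self.values))


def default_schema(taxonomy: Taxonomy | None = None) -> FeatureSchema:
    """Build the shipped 121-feature schema from the taxonomy."""
    tax = taxonomy or default_taxonomy()
    desc: list[FeatureDescriptor] = []

    for g in tax.detection_classes:
        desc.append(FeatureDescriptor(f"det{g}_count", "detection", "count", g))
        desc.append(FeatureDescriptor(f"det{g}_maxp", "detection", "max-prob", g))
        desc.append(FeatureDescriptor(f"det{g}_meanp", "detection", "mean-prob", g))

    for idx in tax.included_indices():
        code = tax[idx].code
        desc.append(FeatureDescriptor(f"ref_{code}_count", "refined", "count", idx))
        desc.append(FeatureDescriptor(f"ref_{code}_maxp", "refined", "max-prob", idx))

    for idx in SQUAMOUS_REFINED:
        code = tax[idx].code
        desc.append(FeatureDescriptor(f"ref_{code}_n_ge05", "refined",
                                      "count-above-threshold", idx, threshold=0.5))
        desc.append(FeatureDescriptor(f"ref_{code}_n_ge09", "refined",
                                      "count-above-threshold", idx, threshold=0.9))
        desc.append(FeatureDescriptor(f"ref_{code}_top5_meanp", "refined",
                                      "top-k-mean-prob", idx, k=5))

    for lbl in PATCH_LABELS:
        desc.append(FeatureDescriptor(f"patch_{lbl}_meanp", "patch",
                                      "mean-prob", lbl))

    for idx in NUCLEUS_REFINED:
        code = tax[idx].code
        for q in (0.1, 0.5, 0.9):
            desc.append(FeatureDescriptor(
                f"nuc_{code}_gray_q{int(q * 100):02d}", "nucleus",
                "nucleus-gray-quantile", idx, q=q))
            desc.append(FeatureDescriptor(
                f"nuc_{code}_area_q{int(q * 100):02d}", "nucleus",
                "nucleus-area-quantile", idx, q=q))

    desc.append(FeatureDescriptor("total_targets", "global", "count"))
    desc.append(FeatureDescriptor("squamous_targets", "global",
                                  "count-above-threshold", threshold=0.0))
    desc.append(FeatureDescriptor("ref_maxp_all", "global", "max-prob"))
    return FeatureSchema(desc)


def _scope_records(records: Sequence[TargetRecord], d: FeatureDescriptor
                   ) -> list[TargetRecord]:
    if d.source == "detection":
        return [r for r in records if r.det_class == d.class_scope]
    if d.source in ("refined", "nucleus"):
        sel = [r for r in records if r.refined_class == d.class_scope]
        if d.source == "nucleus":
            sel = [r for r in sel if r.nucleus is not None]
        return sel
    if d.source == "patch":
        return [r for r in records if r.patch_label == d.class_scope
                and r.patch_prob is not None]
    # global scopes
    if d.statistic == "count-above-threshold":  # squamous lesion total
        return [r for r in records if r.refined_class in SQUAMOUS_REFINED]
    return list(records)


def _probs(sel: Sequence[TargetRecord], d: FeatureDescriptor) -> np.ndarray:
    if d.source == "detection":
        return np.array([r.det_prob for r in sel])
    if d.source == "patch":
        return np.array([r.patch_prob for r in sel])
    return np.array([r.refined_prob for r in sel])


def _evaluate(d: FeatureDescriptor, sel: Sequence[TargetRecord]
              ) -> tuple[float, bool]:
    """(value, missing) for one descriptor over its scoped records."""
    if d.statistic == "count":
        return float(len(sel)), False
    if d.statistic == "count-above-threshold":
        if d.source == "global":  # scoping already applied the class filter
            return float(len(sel)), False
        p = _probs(sel, d)
        return float(int((p >= d.threshold).sum())), False
    if not sel:
        return 0.0, True
    if d.statistic == "max-prob":
        return float(_probs(sel, d).max()), False
    if d.statistic == "mean-prob":
        return float(_probs(sel, d).mean()), False
    if d.statistic == "top-k-mean-prob":
        p = np.sort(_probs(sel, d))[::-1][: d.k]
        return float(p.mean()), False
    if d.statistic == "nucleus-gray-quantile":
        vals = np.array([r.nucleus.mean_gray for r in sel])
        return float(np.quantile(vals, d.q)), False
    if d.statistic == "nucleus-area-quantile":
        vals = np.array([r.nucleus.area_um2 for r in sel])
        return float(np.quantile(vals, d.q)), False
    if d.statistic == "quantile":
        return float(np.quantile(_probs(sel, d), d.q)), False
    raise AssertionError(d.statistic)


def aggregate_slide(records: Sequence[TargetRecord], schema: FeatureSchema,
                    slide_id: str | None = None) -> SlideFeatureVector:
    """Reduce one slide's record stream to a :class:`SlideFeatureVector`.

    Order-invariant to the bit: records are sorted internally (by
    probability, then coordinates) before any floating-point reduction, so
    shuffled input yields an identical vector.  Records whose refined
    class lies outside 1..24 (possible when ingesting foreign streams)
    are ignored with a warning, never an exception.
    """
    clean = []
    for r in records:
        if not (1 <= r.refined_class <= 24):
            logger.warning("ignoring record with out-of-taxonomy class %r",
                           r.refined_class)
            continue
        clean.append(r)
    clean.sort(key=lambda r: (r.refined_prob, r.det_prob, r.box.x, r.box.y,
                              r.box.width, r.box.height, r.refined_class))
    if slide_id is None:
        slide_id = clean[0].slide_id if clean else ""
    values = np.zeros(len(schema))
    missing = np.zeros(len(schema), dtype=bool)
    for i, d in enumerate(schema):
        sel = _scope_records(clean, d)
        values[i], missing[i] = _evaluate(d, sel)
    return SlideFeatureVector(slide_id, values, missing, schema)


def aggregate_corpus(slides: Mapping[str, Sequence[TargetRecord]],
                     schema: FeatureSchema):
    """Feature matrix over many slides.

    Returns ``(X, missing, slide_ids)``: a float matrix with NaN at
    missing entries (boosted-model input convention), the boolean missing
    mask, and the row order.
    """
    ids = list(slides)
    X = np.empty((len(ids), len(schema)))
    miss = np.zeros((len(ids), len(schema)), dtype=bool)
    for i, sid in enumerate(ids):
        fv = aggregate_slide(slides[sid], schema, slide_id=sid)
        X[i] = fv.to_array(missing_as_nan=True)
        miss[i] = fv.missing
    return X, miss, ids


def features_to_dataframe(X: np.ndarray, schema: FeatureSchema,
                          slide_ids: Sequence[str]):
    """CSV-ready pandas frame, header row = feature names."""
    import pandas as pd

    return pd.DataFrame(X, columns=list(schema.names), index=list(slide_ids))


@dataclass
class FeatureImportance:
    """Split counts per feature and their normalized share."""

    names: tuple[str, ...]
    split_counts: np.ndarray
    normalized: np.ndarray

    def top(self, n: int = 10) -> list[tuple[str, float]]:
        order = np.argsort(self.split_counts)[::-1][:n]
        return [(self.names[i], float(self.normalized[i])) for i in order]


def importance_from_splits(split_counts, names: Sequence[str] | None = None
                           ) -> FeatureImportance:
    """Normalize per-feature split counts into an importance distribution.

    All-zero counts yield all-zero importances (no division); otherwise the
    normalized values sum to 1 and preserve the raw-count ordering.
    """
    counts = np.asarray(split_counts, dtype=float)
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("split counts must be non-negative integers")
    total = counts.sum()
    norm = counts / total if total > 0 else np.zeros_like(counts)
    if names is None:
        names = tuple(f"f{i}" for i in range(len(counts)))
    return FeatureImportance(tuple(names), counts.astype(int), norm)


def importance_from_model(booster, schema: FeatureSchema) -> FeatureImportance:
    """Split-count importance of a trained gradient-boosted model.

    Counts how often each schema feature is used as a split across all
    trees, then normalizes (the same computation as
    :func:`importance_from_splits`, sourced from the model dump).
    """
    if hasattr(booster, "get_booster"):  # sklearn wrapper
        booster = booster.get_booster()
    score = booster.get_score(importance_type="weight")
    counts = np.zeros(len(schema))
    for i, name in enumerate(schema.names):
        counts[i] = score.get(name, score.get(f"f{i}", 0))
    return importance_from_splits(counts, schema.names)
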