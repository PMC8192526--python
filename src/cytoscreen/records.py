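"""Per-target evidence records, ROI geometry, and annotation-file I/O.

A whole-slide scan at 0.25 um/pixel is screened by pluggable front-ends
(object detector, fine-grained classifier, patch true/false classifier,
nucleus segmenter).  Their fused per-target output is a
:class:`TargetRecord`; streams of records are the interchange format
between detection and the slide-level decision engine, serialized as
JSON-lines (one record per line).

Expert annotations travel as ASAP-dialect XML (the Automated Slide
Analysis Platform rectangle/polygon format) and are mapped to
:class:`AnnotationTarget` via the taxonomy codes.

Geometry conventions: pixel coordinates are 0-based, boxes are half-open
``[x, x+width) x [y, y+height)``, so tiling arithmetic is exact.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator, Sequence

import numpy as np

from .taxonomy import Taxonomy, TaxonomyError, default_taxonomy

__all__ = [
    "BoundingBox",
    "AnnotationTarget",
    "NucleusStats",
    "TargetRecord",
    "PATCH_LABELS",
    "sigmoid",
    "split_roi",
    "context_crop",
    "resize_bilinear",
    "iou",
    "deduplicate",
    "read_asap_annotations",
    "write_asap_annotations",
    "read_records_jsonl",
    "write_records_jsonl",
    "records_to_dataframe",
]

#: Patch-model label space for squamous targets.
PATCH_LABELS = ("True_HSIL", "False_HSIL", "True_LSIL", "False_LSIL")

#: Annotation ROIs larger than this (either side) are decomposed.
MAX_ROI_SIDE = 608

#: Context window side used around a detection for patch-level review.
CONTEXT_SIDE = 1216


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle, 0-based top-left corner, half-open extents."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"degenerate box: {self}")

    @property
    def x2(self) -> int:
        return self.x + self.width

    @property
    def y2(self) -> int:
        return self.y + self.height

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)


@dataclass(frozen=True)
class AnnotationTarget:
    """One expert- or detector-labelled region on a slide."""

    slide_id: str
    box: BoundingBox
    class_index: int


@dataclass(frozen=True)
class NucleusStats:
    """Nucleus morphometry summary attached to selected squamous targets."""

    mean_gray: float
    area_px: int
    area_um2: float
    n_components: int = 1


@dataclass
class TargetRecord:
    """Fused evidence for one detected target.

    ``det_*`` fields come from the detector (merged class space),
    ``refined_*`` from the fine-grained 24-class classifier, ``patch_*``
    from the true/false patch reviewer (squamous classes only), and
    ``nucleus`` from segmentation-based morphometry (SC / ASC_L_S /
    ASC_H_S only).  ``raw_score`` optionally retains the pre-sigmoid
    classifier score.
    """

    slide_id: str
    box: BoundingBox
    det_class: int
    det_prob: float
    refined_class: int
    refined_prob: float
    patch_label: str | None = None
    patch_prob: float | None = None
    nucleus: NucleusStats | None = None
    raw_score: float | None = None

    def __post_init__(self):
        for name, p in (("det_prob", self.det_prob),
                        ("refined_prob", self.refined_prob),
                        ("patch_prob", self.patch_prob)):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.patch_label is not None and self.patch_label not in PATCH_LABELS:
            raise ValueError(f"unknown patch label {self.patch_label!r}")
        if not (1 <= self.refined_class <= 24):
            raise ValueError(f"refined_class {self.refined_class} outside 1..24")


def sigmoid(raw_score: float) -> float:
    """Logistic map of a raw classifier score to a probability in (0, 1).

    sigma(z) = 1 / (1 + exp(-z)); non-finite input raises ``ValueError``.
    """
    z = float(raw_score)
    if not math.isfinite(z):
        raise ValueError(f"non-finite raw score: {raw_score!r}")
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)  # avoid overflow for very negative z
    return ez / (1.0 + ez)


def _split_lengths(total: int, max_len: int) -> list[int]:
    """Partition ``total`` into ceil(total/max_len) near-equal pieces."""
    n = -(-total // max_len)
    base, extra = divmod(total, n)
    return [base + 1] * extra + [base] * (n - extra)


def split_roi(box: BoundingBox, max_side: int = MAX_ROI_SIDE) -> list[BoundingBox]:
    """Decompose an ROI into a grid of boxes with sides <= ``max_side``.

    The pieces are disjoint and exactly tile the input.  Cytologists split
    oversized lesion annotations along morphology; machine splitting uses a
    deterministic near-equal grid instead.
    """
    widths = _split_lengths(box.width, max_side)
    heights = _split_lengths(box.height, max_side)
    out = []
    y = box.y
    for h in heights:
        x = box.x
        for w in widths:
            out.append(BoundingBox(x, y, w, h))
            x += w
        y += h
    return out


def context_crop(box: BoundingBox, slide_dims: tuple[int, int],
                 side: int = CONTEXT_SIDE) -> BoundingBox:
    """Square context window centered on ``box``, clamped inside the slide.

    ``slide_dims`` is (width, height).  When the slide is large enough the
    window keeps its full ``side`` and is shifted inward at borders; a
    slide smaller than ``side`` in a dimension yields the full slide extent
    in that dimension (padding, if any, is the consumer's concern — true
    pixel statistics are preserved here).
    """
    sw, sh = slide_dims
    cx, cy = box.center

    def _axis(c: float, size: int) -> tuple[int, int]:
        if size <= side:
            return 0, size
        start = int(round(c - side / 2.0))
        start = min(max(start, 0), size - side)
        return start, side

    x, w = _axis(cx, sw)
    y, h = _axis(cy, sh)
    return BoundingBox(x, y, w, h)


def resize_bilinear(image: np.ndarray, shape: tuple[int, int] = (299, 299)) -> np.ndarray:
    """Bilinear resize of an 8-bit image crop (fine-classifier input norm)."""
    from skimage.transform import resize

    out = resize(image.astype(np.float64), shape, order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes (0 when disjoint)."""
    ix = max(0, min(a.x2, b.x2) - max(a.x, b.x))
    iy = max(0, min(a.y2, b.y2) - max(a.y, b.y))
    inter = ix * iy
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


def deduplicate(records: Sequence[TargetRecord], iou_threshold: float = 0.5
                ) -> list[TargetRecord]:
    """Greedy overlap suppression on ingestion (same detection class only).

    Records are ranked by detection probability (ties by coordinates for
    determinism); a record overlapping an already-kept record of the same
    detection class above ``iou_threshold`` is dropped.
    """
    ranked = sorted(records, key=lambda r: (-r.det_prob, r.box.x, r.box.y,
                                            r.box.width, r.box.height))
    kept: list[TargetRecord] = []
    for rec in ranked:
        if any(k.det_class == rec.det_class and iou(k.box, rec.box) >= iou_threshold
               for k in kept):
            continue
        kept.append(rec)
    return kept


# --------------------------------------------------------------------------
# ASAP XML annotation dialect


def read_asap_annotations(path, taxonomy: Taxonomy | None = None,
                          slide_id: str | None = None) -> list[AnnotationTarget]:
    """Parse an ASAP XML annotation file into :class:`AnnotationTarget` list.

    Rectangle (and polygon, via bounding box) annotations are supported;
    the ``PartOfGroup``/``Name`` label must be a taxonomy class code such
    as ``KC``.  Malformed XML raises ``ValueError`` with parse context;
    unknown labels raise :class:`~cytoscreen.taxonomy.TaxonomyError`.
    """
    taxonomy = taxonomy or default_taxonomy()
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"malformed ASAP XML in {path}: {exc}") from exc
    root = tree.getroot()
    sid = slide_id if slide_id is not None else root.get("SlideID", "")
    targets = []
    for ann in root.iter("Annotation"):
        label = ann.get("PartOfGroup") or ann.get("Name") or ""
        label = label.strip()
        try:
            cls = taxonomy[label]
        except TaxonomyError:
            raise TaxonomyError(
                f"annotation label {label!r} is not a taxonomy class code")
        xs, ys = [], []
        for coord in ann.iter("Coordinate"):
            xs.append(float(coord.get("X")))
            ys.append(float(coord.get("Y")))
        if not xs:
            continue
        x, y = int(round(min(xs))), int(round(min(ys)))
        w = int(round(max(xs))) - x
        h = int(round(max(ys))) - y
        targets.append(AnnotationTarget(
            slide_id=sid, box=BoundingBox(x, y, max(w, 1), max(h, 1)),
            class_index=cls.index))
    return targets


def write_asap_annotations(targets: Sequence[AnnotationTarget], path,
                           taxonomy: Taxonomy | None = None) -> None:
    """Write targets as ASAP rectangle annotations (read round-trips exactly)."""
    taxonomy = taxonomy or default_taxonomy()
    root = ET.Element("ASAP_Annotations")
    if targets:
        root.set("SlideID", targets[0].slide_id)
    anns = ET.SubElement(root, "Annotations")
    groups = ET.SubElement(root, "AnnotationGroups")
    seen_groups: set[str] = set()
    for i, tgt in enumerate(targets):
        code = taxonomy[tgt.class_index].code
        ann = ET.SubElement(anns, "Annotation", Name=f"Annotation {i}",
                            Type="Rectangle", PartOfGroup=code, Color="#F4FA58")
        coords = ET.SubElement(ann, "Coordinates")
        b = tgt.box
        corners = [(b.x, b.y), (b.x2, b.y), (b.x2, b.y2), (b.x, b.y2)]
        for order, (cx, cy) in enumerate(corners):
            ET.SubElement(coords, "Coordinate", Order=str(order),
                          X=str(cx), Y=str(cy))
        if code not in seen_groups:
            ET.SubElement(groups, "Group", Name=code, PartOfGroup="None",
                          Color="#F4FA58")
            seen_groups.add(code)
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


# --------------------------------------------------------------------------
# JSON-lines record streams


def _record_to_dict(rec: TargetRecord) -> dict:
    d = {
        "slide_id": rec.slide_id,
        "box": [rec.box.x, rec.box.y, rec.box.width, rec.box.height],
        "det_class": rec.det_class,
        "det_prob": rec.det_prob,
        "refined_class": rec.refined_class,
        "refined_prob": rec.refined_prob,
    }
    if rec.patch_label is not None:
        d["patch_label"] = rec.patch_label
        d["patch_prob"] = rec.patch_prob
    if rec.nucleus is not None:
        d["nucleus"] = asdict(rec.nucleus)
    if rec.raw_score is not None:
        d["raw_score"] = rec.raw_score
    return d


def _record_from_dict(d: dict) -> TargetRecord:
    nuc = d.get("nucleus")
    return TargetRecord(
        slide_id=d["slide_id"],
        box=BoundingBox(*d["box"]),
        det_class=d["det_class"],
        det_prob=d["det_prob"],
        refined_class=d["refined_class"],
        refined_prob=d["refined_prob"],
        patch_label=d.get("patch_label"),
        patch_prob=d.get("patch_prob"),
        nucleus=NucleusStats(**nuc) if nuc else None,
        raw_score=d.get("raw_score"),
    )


def record_to_json(rec: TargetRecord) -> str:
    """One-line JSON form of a record (stable key order)."""
    return json.dumps(_record_to_dict(rec), sort_keys=True,
                      separators=(",", ":"))


def write_records_jsonl(records: Iterable[TargetRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(record_to_json(rec) + "\n")


def read_records_jsonl(path) -> list[TargetRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(_record_from_dict(json.loads(line)))
    return out


def records_to_dataframe(records: Sequence[TargetRecord]):
    """Flat pandas view of a record stream (CSV export)."""
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "slide_id": r.slide_id,
            "x": r.box.x, "y": r.box.y,
            "width": r.box.width, "height": r.box.height,
            "det_class": r.det_class, "det_prob": r.det_prob,
            "refined_class": r.refined_class, "refined_prob": r.refined_prob,
            "patch_label": r.patch_label, "patch_prob": r.patch_prob,
        }
        if r.nucleus is not None:
            row.update(nucleus_mean_gray=r.nucleus.mean_gray,
                       nucleus_area_px=r.nucleus.area_px,
                       nucleus_area_um2=r.nucleus.area_um2)
        rows.append(row)
    return pd.DataFrame(rows)
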