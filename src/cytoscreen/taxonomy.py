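"""The 24-class cervical cytology annotation taxonomy and its TBS mapping.

Cervical liquid-based smears are reported under The Bethesda System (TBS,
2014 revision).  Upstream detectors work on a finer 24-class annotation
vocabulary (single koilocytes, clustered atypical squamous cells, candida
hyphae, ...) whose members each correspond to one or more TBS diagnoses.
This module is the single authoritative table for:

* the 24 annotation classes (index 1-24, short code, lesion category,
  TBS targets, free-text definition);
* the TBS diagnostic codes and their clinical reporting groups;
* the detection-time class merging (morphologically similar annotation
  classes share one detector class; purely background classes such as
  mucus and debris are excluded from detection altogether).

The table ships as package data (``data/taxonomy.csv``) so the grouping is
a configuration artifact, not hard-coded logic: loading an alternative CSV
with the same header yields an alternative :class:`Taxonomy`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "AnnotationClass",
    "Taxonomy",
    "TBS_CODES",
    "CLINICAL_GROUPS",
    "AGC_MERGE_MEMBERS",
    "EXCLUDED",
    "load_default_taxonomy",
    "default_taxonomy",
    "map_annotation_to_tbs",
    "detection_class_of",
    "clinical_group_of",
    "normalize_tbs_code",
]

#: Canonical TBS diagnostic codes used throughout the system.
TBS_CODES: tuple[str, ...] = (
    "NILM", "ASCUS", "LSIL", "ASCH", "HSIL", "SCC",
    "AGC", "AGC_NOS", "AGC_FN", "AIS", "ADC",
    "EMC", "TRI", "CAN", "HSV", "ACTINO", "CC",
)

#: Glandular codes collapsed into the single merged AGC prediction class.
AGC_MERGE_MEMBERS: frozenset[str] = frozenset({"AGC_NOS", "AGC_FN", "AIS", "ADC"})

#: Clinical reporting group per TBS code.  Subtype confusion inside one
#: group does not change clinical management and is forgiven at evaluation.
CLINICAL_GROUPS: dict[str, str] = {
    "NILM": "negative",
    "ASCUS": "squamous-intraepithelial",
    "LSIL": "squamous-intraepithelial",
    "ASCH": "squamous-intraepithelial",
    "HSIL": "squamous-intraepithelial",
    "SCC": "squamous-intraepithelial",
    "AGC": "glandular-intraepithelial",
    "AGC_NOS": "glandular-intraepithelial",
    "AGC_FN": "glandular-intraepithelial",
    "AIS": "glandular-intraepithelial",
    "ADC": "glandular-intraepithelial",
    "EMC": "EMC",
    "TRI": "infectious",
    "CAN": "infectious",
    "HSV": "infectious",
    "ACTINO": "infectious",
    "CC": "infectious",
}

#: Sentinel detection class for annotation classes the detector never emits.
EXCLUDED = "excluded"

_CATEGORIES = frozenset({
    "glandular-intraepithelial",
    "squamous-intraepithelial",
    "normal",
    "infectious",
    "evidence-of-infection",
    "EMC",
})

# historical spellings tolerated on read
_TBS_ALIASES = {"NIL": "NILM"}


class TaxonomyError(ValueError):
    """Invalid annotation class index, TBS code, or malformed taxonomy table."""


def normalize_tbs_code(code: str) -> str:
    """Canonical upper-case TBS code; accepts case variants and ``NIL``.

    Raises :class:`TaxonomyError` for codes outside the closed set.
    """
    canon = code.strip().upper()
    canon = _TBS_ALIASES.get(canon, canon)
    if canon not in TBS_CODES:
        raise TaxonomyError(f"unknown TBS code: {code!r}")
    return canon


@dataclass(frozen=True)
class AnnotationClass:
    """One row of the annotation taxonomy (one of the 24 C-classes)."""

    index: int
    code: str
    category: str
    tbs_targets: frozenset[str]
    detection_class: int | str  # integer group id, or EXCLUDED
    definition: str = ""

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise TaxonomyError(f"unknown category {self.category!r} for {self.code}")
        if not self.tbs_targets:
            raise TaxonomyError(f"class {self.code} has no TBS target")


class Taxonomy:
    """Immutable lookup table over a set of :class:`AnnotationClass` rows."""

    def __init__(self, classes: Iterable[AnnotationClass]):
        rows = sorted(classes, key=lambda c: c.index)
        indices = [c.index for c in rows]
        if len(set(indices)) != len(indices):
            raise TaxonomyError("duplicate annotation class indices")
        if indices != list(range(1, len(rows) + 1)):
            raise TaxonomyError("annotation class indices must be 1..N without gaps")
        self._by_index: dict[int, AnnotationClass] = {c.index: c for c in rows}
        self._by_code: dict[str, AnnotationClass] = {c.code: c for c in rows}
        if len(self._by_code) != len(rows):
            raise TaxonomyError("duplicate annotation class codes")

    def __len__(self) -> int:
        return len(self._by_index)

    def __iter__(self):
        return iter(self._by_index.values())

    def __getitem__(self, key: int | str) -> AnnotationClass:
        table = self._by_code if isinstance(key, str) else self._by_index
        try:
            return table[key]
        except KeyError:
            raise TaxonomyError(f"unknown annotation class: {key!r}") from None

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(self._by_index)

    @property
    def n_detection_classes(self) -> int:
        """Number of distinct detector classes after merging/exclusion."""
        return len({c.detection_class for c in self if c.detection_class != EXCLUDED})

    @property
    def detection_classes(self) -> tuple[int, ...]:
        return tuple(sorted({c.detection_class for c in self
                             if c.detection_class != EXCLUDED}))

    def included_indices(self) -> tuple[int, ...]:
        """Annotation indices the detector can emit (non-excluded)."""
        return tuple(c.index for c in self if c.detection_class != EXCLUDED)

    def detection_group(self, detection_class: int) -> tuple[int, ...]:
        """Annotation indices merged into one detector class."""
        members = tuple(c.index for c in self if c.detection_class == detection_class)
        if not members:
            raise TaxonomyError(f"unknown detection class: {detection_class!r}")
        return members

    # -- the three spec operations ------------------------------------------

    def map_annotation_to_tbs(self, class_index: int) -> frozenset[str]:
        """TBS diagnoses an annotation class can support (never empty)."""
        return self[class_index].tbs_targets

    def detection_class_of(self, class_index: int) -> int | str:
        """Detector class of an annotation class, or ``'excluded'``."""
        return self[class_index].detection_class

    @staticmethod
    def clinical_group_of(tbs_code: str) -> str:
        """Clinical reporting group of a TBS code."""
        return CLINICAL_GROUPS[normalize_tbs_code(tbs_code)]

    # -- (de)serialization ---------------------------------------------------

    @classmethod
    def from_csv(cls, path_or_file) -> "Taxonomy":
        if hasattr(path_or_file, "read"):
            reader = csv.DictReader(path_or_file)
            rows = list(reader)
        else:
            with open(path_or_file, newline="") as fh:
                rows = list(csv.DictReader(fh))
        classes = []
        for row in rows:
            det: int | str = row["detection_class"].strip()
            if det != EXCLUDED:
                det = int(det)
            classes.append(AnnotationClass(
                index=int(row["index"]),
                code=row["code"].strip(),
                category=row["category"].strip(),
                tbs_targets=frozenset(
                    normalize_tbs_code(t) for t in row["tbs_targets"].split(";")
                ),
                detection_class=det,
                definition=row.get("definition", "").strip(),
            ))
        return cls(classes)


def load_default_taxonomy() -> Taxonomy:
    """Load the shipped 24-class table."""
    ref = resources.files("cytoscreen.data").joinpath("taxonomy.csv")
    with ref.open("r", newline="") as fh:
        return Taxonomy.from_csv(fh)


_DEFAULT: Taxonomy | None = None


def default_taxonomy() -> Taxonomy:
    """Shared instance of the shipped taxonomy (loaded once)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_default_taxonomy()
    return _DEFAULT


# Module-level conveniences operating on the shipped table.

def map_annotation_to_tbs(class_index: int) -> frozenset[str]:
    return default_taxonomy().map_annotation_to_tbs(class_index)


def detection_class_of(class_index: int) -> int | str:
    return default_taxonomy().detection_class_of(class_index)


def clinical_group_of(tbs_code: str) -> str:
    return Taxonomy.clinical_group_of(tbs_code)
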