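"""Screening-performance metrics and biopsy-sensitivity arithmetic.

Evaluation follows clinical-treatment equivalence: predicting one
squamous subtype as another, or one glandular subtype as another, does
not change management, so group-level sensitivity forgives within-group
confusion.  Intraepithelial-lesion sensitivity pools squamous and
glandular truths; "other lesions" pools infectious findings and
endometrial cells; specificity is computed over truth-negative slides.

Biopsy-cohort sensitivity uses exact rational arithmetic before final
formatting so printed values are reproducible to their full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

from .taxonomy import clinical_group_of, normalize_tbs_code

__all__ = [
    "BiopsyCohort", "EvaluationTable", "sensitivity", "group_metrics",
    "subtype_accuracy", "build_evaluation_table",
]

_INTRAEPITHELIAL = {"squamous-intraepithelial", "glandular-intraepithelial"}
_OTHER_LESION = {"infectious", "EMC"}


@dataclass(frozen=True)
class BiopsyCohort:
    """Histology-confirmed cohort: biopsies, positives, and system misses."""

    n_biopsies: int
    n_positive: int
    n_missed: int

    def __post_init__(self):
        if not (0 <= self.n_missed <= self.n_positive <= self.n_biopsies):
            raise ValueError(
                f"inconsistent cohort counts: {self.n_biopsies}, "
                f"{self.n_positive}, {self.n_missed}")


def sensitivity(cohort: BiopsyCohort) -> float:
    """(positives - missed) / positives, exact until the final float."""
    if cohort.n_positive == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive samples")
    frac = Fraction(cohort.n_positive - cohort.n_missed, cohort.n_positive)
    return float(frac)


@dataclass
class EvaluationTable:
    """Per-slide truth/prediction table with group annotations."""

    frame: pd.DataFrame  # columns: slide_id, truth, pred, truth_group, pred_group

    def __post_init__(self):
        required = {"slide_id", "truth", "pred", "truth_group", "pred_group"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"evaluation table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    def confusion(self, level: str = "group") -> pd.DataFrame:
        """Class- or group-level confusion counts."""
        t, p = (("truth", "pred") if level == "class"
                else ("truth_group", "pred_group"))
        return pd.crosstab(self.frame[t], self.frame[p])


def build_evaluation_table(slide_ids: Sequence[str], truths: Sequence[str],
                           preds: Sequence[str]) -> EvaluationTable:
    truths = [normalize_tbs_code(t) for t in truths]
    preds = [normalize_tbs_code(p) for p in preds]
    frame = pd.DataFrame({
        "slide_id": list(slide_ids),
        "truth": truths,
        "pred": preds,
        "truth_group": [clinical_group_of(t) for t in truths],
        "pred_group": [clinical_group_of(p) for p in preds],
    })
    return EvaluationTable(frame)


def group_metrics(table: EvaluationTable,
                  include_ascus_in_intraepithelial: bool = True) -> dict:
    """Group-level sensitivities and the overall specificity.

    A lesion slide counts as detected when the predicted group matches the
    truth group's pooled lesion category; within-group subtype confusion
    (HSIL predicted as ASCH, AIS as AGC_NOS, ...) is not an error.  With
    ``include_ascus_in_intraepithelial=False`` a second breakdown excludes
    ASCUS truths from the intraepithelial pool (they are also reported
    separately either way).
    """
    if len(table) == 0:
        raise ValueError("empty evaluation table")
    df = table.frame

    def _sens(mask) -> float | None:
        sub = df[mask]
        if len(sub) == 0:
            return None
        # detected iff predicted group is any intraepithelial group for
        # intraepithelial truths, or the exact group for other lesions
        hits = 0
        for _, row in sub.iterrows():
            if row.truth_group in _INTRAEPITHELIAL:
                hits += row.pred_group in _INTRAEPITHELIAL
            else:
                hits += row.pred_group == row.truth_group
        return hits / len(sub)

    intra_mask = df.truth_group.isin(_INTRAEPITHELIAL)
    if not include_ascus_in_intraepithelial:
        intra_mask &= df.truth != "ASCUS"
    other_mask = df.truth_group.isin(_OTHER_LESION)
    neg_mask = df.truth_group == "negative"
    if not neg_mask.any():
        raise ZeroDivisionError("specificity undefined: no negative slides")
    specificity = float((df[neg_mask].pred_group == "negative").mean())

    out = {
        "intraepithelial_sensitivity": _sens(intra_mask),
        "other_lesion_sensitivity": _sens(other_mask),
        "specificity": specificity,
        "n_intraepithelial": int(intra_mask.sum()),
        "n_other_lesion": int(other_mask.sum()),
        "n_negative": int(neg_mask.sum()),
        "ascus_sensitivity": _sens(df.truth == "ASCUS"),
        "n_ascus": int((df.truth == "ASCUS").sum()),
    }
    return out


def subtype_accuracy(table: EvaluationTable) -> float:
    """Exact-subtype match rate among squamous true positives."""
    df = table.frame
    squamous = df[(df.truth_group == "squamous-intraepithelial")
                  & (df.pred_group.isin(_INTRAEPITHELIAL))]
    if len(squamous) == 0:
        raise ZeroDivisionError(
            "subtype accuracy undefined: no squamous true positives")
    return float((squamous.truth == squamous.pred).mean())
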