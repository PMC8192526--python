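"""Slide-level TBS diagnosis: boosted ensemble, logic tree, priority report.

The decision layer mirrors how a cytopathologist signs out a slide:

1. *Stage 1* — is there a squamous intraepithelial lesion at all?  A
   k-fold cross-validation ensemble of gradient-boosted classifiers
   (default k=10) votes on the slide feature vector; the slide is called
   positive when **any** member votes positive.  This union rule trades
   specificity for sensitivity, the correct direction for a screening
   test, and member thresholds can be tuned to drive training-set
   sensitivity to 1.
2. *Stage 2* — positive slides are subtyped into ASCUS / LSIL / ASCH /
   HSIL / SCC by a second boosted model; ties break toward the less
   severe subtype.
3. *Logic tree* — infectious organisms (TRI, CAN, HSV, ACTINO, CC),
   endometrial cells (EMC), and the merged atypical-glandular class
   (AGC, pooling AGC_NOS / AGC_FN / AIS / ADC) have distinctive
   morphology, so simple per-class threshold rules of the form
   ``count(class, prob >= p) >= n`` suffice.
4. *Priority* — when several lesions fire, the report carries the single
   lesion of highest clinical-treatment priority.

Boosted models route missing feature values (NaN) down learned default
branches, so empty-set statistics need no imputation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from .features import FeatureSchema, aggregate_slide, default_schema
from .records import TargetRecord

__all__ = [
    "SUBTYPES", "PRIORITY_ORDER", "LOGIC_BRANCH_CLASSES",
    "LogicTreeConfig", "EnsembleModel", "TBSReport", "DiagnosticEngine",
    "train_stage1", "train_stage2", "ensemble_positive",
    "subtype_from_probabilities", "logic_tree_decide", "finalize_report",
    "tune_sensitivity",
]

#: Squamous subtypes in increasing severity.
SUBTYPES = ("ASCUS", "LSIL", "ASCH", "HSIL", "SCC")

#: Clinical-treatment priority for single-lesion reporting (most urgent first).
PRIORITY_ORDER = ("SCC", "HSIL", "ASCH", "AGC", "LSIL", "ASCUS",
                  "EMC", "HSV", "TRI", "ACTINO", "CAN", "CC", "NILM")

#: Refined annotation classes feeding each logic-tree branch.
LOGIC_BRANCH_CLASSES: dict[str, tuple[int, ...]] = {
    "TRI": (16,), "CAN": (17,), "HSV": (18,), "ACTINO": (19,), "CC": (20,),
    "EMC": (15,), "AGC": (1, 2),
}

_XGB_DEFAULTS = dict(
    n_estimators=60, max_depth=3, learning_rate=0.3,
    tree_method="hist", n_jobs=1, verbosity=0,
)


class TrainingError(ValueError):
    """Unusable training or tuning input (single class, no positives...)."""


@dataclass(frozen=True)
class LogicTreeConfig:
    """Per-branch ``count(class, prob >= min_prob) >= min_count`` rules.

    Defaults were calibrated once on the shipped synthetic corpus and can
    be overridden wholesale or per branch.
    """

    rules: Mapping[str, tuple[float, int]] = field(default_factory=lambda: {
        "TRI": (0.6, 3), "CAN": (0.6, 3), "HSV": (0.6, 2),
        "ACTINO": (0.6, 3), "CC": (0.6, 3), "EMC": (0.6, 2), "AGC": (0.6, 2),
    })

    def __post_init__(self):
        for branch, (p, n) in self.rules.items():
            if branch not in LOGIC_BRANCH_CLASSES:
                raise ValueError(f"unknown logic-tree branch {branch!r}")
            if not (0.0 <= p <= 1.0) or n < 1:
                raise ValueError(f"malformed rule for {branch}: p={p}, n={n}")


@dataclass
class TBSReport:
    """Final per-slide diagnosis with a recomputable evidence trail."""

    slide_id: str
    final_tbs: str
    squamous_branch: dict
    other_branch: dict
    priority_applied: bool

    def to_json(self) -> str:
        return json.dumps({
            "slide_id": self.slide_id,
            "final_tbs": self.final_tbs,
            "squamous_branch": self.squamous_branch,
            "other_branch": self.other_branch,
            "priority_applied": self.priority_applied,
        }, sort_keys=True, separators=(",", ":"))


# --------------------------------------------------------------------------
# Stage 1: positive/negative ensemble


class EnsembleModel:
    """k boosted members from k-fold cross-validation, with per-member
    decision thresholds and an any-positive union rule."""

    def __init__(self, members: Sequence[xgb.XGBClassifier],
                 schema: FeatureSchema, seed: int,
                 thresholds: Sequence[float] | None = None,
                 fold_assignments: Sequence[int] | None = None):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = list(members)
        self.schema = schema
        self.seed = seed
        self.thresholds = (list(thresholds) if thresholds is not None
                           else [0.5] * len(self.members))
        self.fold_assignments = (list(fold_assignments)
                                 if fold_assignments is not None else None)

    @property
    def k(self) -> int:
        return len(self.members)

    def member_scores(self, X: np.ndarray) -> np.ndarray:
        """(n_slides, k) positive-class scores."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([m.predict_proba(X)[:, 1] for m in self.members])

    def member_calls(self, X: np.ndarray) -> np.ndarray:
        """(n_slides, k) boolean votes at the per-member thresholds."""
        return self.member_scores(X) >= np.asarray(self.thresholds)

    def predict_positive(self, X: np.ndarray) -> np.ndarray:
        """Union-rule slide calls: positive iff any member votes positive."""
        return self.member_calls(X).any(axis=1)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        self.schema.to_yaml(os.path.join(directory, "schema.yaml"))
        for i, m in enumerate(self.members):
            m.get_booster().save_model(os.path.join(directory, f"member_{i:02d}.json"))
        meta = {"k": self.k, "seed": self.seed, "thresholds": self.thresholds,
                "fold_assignments": self.fold_assignments}
        with open(os.path.join(directory, "ensemble.json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "EnsembleModel":
        with open(os.path.join(directory, "ensemble.json")) as fh:
            meta = json.load(fh)
        schema = FeatureSchema.from_yaml(os.path.join(directory, "schema.yaml"))
        members = []
        for i in range(meta["k"]):
            m = xgb.XGBClassifier(**_XGB_DEFAULTS)
            m.load_model(os.path.join(directory, f"member_{i:02d}.json"))
            members.append(m)
        return cls(members, schema, meta["seed"], meta["thresholds"],
                   meta["fold_assignments"])


def train_stage1(X: np.ndarray, labels: Sequence[int], schema: FeatureSchema,
                 k: int = 10, seed: int = 0, **xgb_params) -> EnsembleModel:
    """Train the k-member positive/negative ensemble.

    Stratified k-fold split (reproducible from ``seed``); each member is
    trained on k-1 folds.  ``labels`` are binary (1 = squamous lesion).
    ``k=1`` degenerates to a single model trained on everything.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError("stage-1 training needs both classes present")
    params = {**_XGB_DEFAULTS, **xgb_params}
    members, assignment = [], np.zeros(len(y), dtype=int)
    if k == 1:
        m = xgb.XGBClassifier(random_state=seed, **params)
        m.fit(X, y)
        members.append(m)
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            if len(np.unique(y[train_idx])) < 2:
                raise TrainingError(f"fold {fold} lost a class; need more data")
            m = xgb.XGBClassifier(random_state=seed + fold, **params)
            m.fit(X[train_idx], y[train_idx])
            members.append(m)
            assignment[test_idx] = fold
    return EnsembleModel(members, schema, seed,
                         fold_assignments=assignment.tolist())


def ensemble_positive(member_calls: Sequence[bool]) -> bool:
    """Any-positive union rule over member votes."""
    calls = list(member_calls)
    if not calls:
        raise ValueError("ensemble_positive needs at least one member call")
    return any(bool(c) for c in calls)


#: Threshold above any attainable score: the member never fires.
NEVER_FIRE = 2.0


def tune_sensitivity(model: EnsembleModel, X: np.ndarray,
                     labels: Sequence[int]) -> list[float]:
    """Set per-member thresholds for ensemble sensitivity 1.0 on a tuning
    set while keeping specificity as high as the union rule allows.

    Greedy coverage: each member starts at the lowest threshold that
    admits no tuning-set negative (free coverage of the positives it
    cleanly separates); every still-uncovered positive is then assigned
    to the member whose threshold drop to that positive's score admits
    the fewest new negatives.  Every positive ends up at or above some
    member's threshold, so union sensitivity is 1.0; on a separable
    tuning set no negative is admitted at all.  Lowering any threshold
    can only add positive calls, never remove them (monotone contract).
    Thresholds are stored on the model and returned.
    """
    y = np.asarray(labels, dtype=int)
    if not (y == 1).any():
        raise TrainingError("tuning set has no positive slides")
    scores = model.member_scores(np.asarray(X, dtype=float))
    pos, neg = scores[y == 1], scores[y == 0]
    k = scores.shape[1]
    thresholds = np.full(k, NEVER_FIRE)
    for j in range(k):
        ceiling = neg[:, j].max() if len(neg) else 0.0
        clean = pos[pos[:, j] > ceiling, j]
        if len(clean):
            thresholds[j] = clean.min()
    covered = (pos >= thresholds).any(axis=1)
    # hardest positives first: those with the lowest best member score
    for p in np.argsort(pos.max(axis=1)):
        if covered[p]:
            continue
        costs = [((neg[:, j] >= pos[p, j]) & (neg[:, j] < thresholds[j])).sum()
                 if len(neg) else 0 for j in range(k)]
        j = int(np.argmin(costs))
        thresholds[j] = min(thresholds[j], pos[p, j])
        covered |= (pos >= thresholds).any(axis=1)
    model.thresholds = thresholds.tolist()
    return list(model.thresholds)


# --------------------------------------------------------------------------
# Stage 2: squamous subtype


def train_stage2(X: np.ndarray, subtype_labels: Sequence[str],
                 seed: int = 0, **xgb_params) -> xgb.XGBClassifier:
    """Multiclass boosted model over positive slides (labels in SUBTYPES)."""
    y = np.array([SUBTYPES.index(s) for s in subtype_labels])
    if len(np.unique(y)) < 2:
        raise TrainingError("stage-2 training needs at least two subtypes")
    params = {**_XGB_DEFAULTS, **xgb_params}
    m = xgb.XGBClassifier(random_state=seed, **params)
    m.fit(np.asarray(X, dtype=float), y)
    return m


def subtype_from_probabilities(probs: Sequence[float]) -> str:
    """Argmax subtype; exact ties resolve toward the less severe class."""
    p = np.asarray(probs, dtype=float)
    if p.shape != (len(SUBTYPES),):
        raise ValueError(f"expected {len(SUBTYPES)} probabilities, got {p.shape}")
    return SUBTYPES[int(np.argmax(p))]  # first max = least severe


def predict_stage2_subtype(features: np.ndarray, model: xgb.XGBClassifier
                           ) -> tuple[str, dict[str, float]]:
    """Subtype call plus per-class probabilities for one positive slide."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    raw = model.predict_proba(X)[0]
    present = [int(c) for c in model.classes_]
    probs = np.zeros(len(SUBTYPES))
    probs[present] = raw
    call = subtype_from_probabilities(probs)
    return call, {s: float(p) for s, p in zip(SUBTYPES, probs)}


# --------------------------------------------------------------------------
# Logic tree and final report


def logic_tree_decide(records: Sequence[TargetRecord],
                      config: LogicTreeConfig | None = None) -> set[str]:
    """Fire the infectious / EMC / merged-AGC branches independently."""
    config = config or LogicTreeConfig()
    fired = set()
    for branch, (min_prob, min_count) in config.rules.items():
        classes = LOGIC_BRANCH_CLASSES[branch]
        n = sum(1 for r in records
                if r.refined_class in classes and r.refined_prob >= min_prob)
        if n >= min_count:
            fired.add(branch)
    return fired


def finalize_report(slide_id: str, squamous_branch: dict,
                    other_calls: set[str]) -> TBSReport:
    """Collapse all branch calls into one report by clinical priority."""
    candidates = set(other_calls)
    if squamous_branch.get("ensemble_positive"):
        candidates.add(squamous_branch["subtype"])
    if not candidates:
        final, applied = "NILM", False
    else:
        final = min(candidates, key=PRIORITY_ORDER.index)
        applied = len(candidates) > 1
    other = {b: {"fired": b in other_calls} for b in LOGIC_BRANCH_CLASSES}
    return TBSReport(slide_id=slide_id, final_tbs=final,
                     squamous_branch=squamous_branch, other_branch=other,
                     priority_applied=applied)


# --------------------------------------------------------------------------
# Full engine


class DiagnosticEngine:
    """Trained end-to-end slide classifier (stages 1+2 plus logic tree)."""

    def __init__(self, schema: FeatureSchema | None = None,
                 logic_config: LogicTreeConfig | None = None,
                 k: int = 10, seed: int = 0):
        self.schema = schema or default_schema()
        self.logic_config = logic_config or LogicTreeConfig()
        self.k = k
        self.seed = seed
        self.stage1: EnsembleModel | None = None
        self.stage2: xgb.XGBClassifier | None = None

    def fit(self, X: np.ndarray, truth_tbs: Sequence[str],
            tune: bool = True) -> "DiagnosticEngine":
        """Train both stages from a labelled feature matrix.

        ``truth_tbs`` holds slide-level TBS truth codes; squamous subtypes
        become stage-1 positives and stage-2 labels.  With ``tune``, member
        thresholds are pushed to training-set sensitivity 1.0.
        """
        truth = list(truth_tbs)
        y1 = np.array([1 if t in SUBTYPES else 0 for t in truth])
        self.stage1 = train_stage1(X, y1, self.schema, k=self.k, seed=self.seed)
        if tune:
            tune_sensitivity(self.stage1, X, y1)
        pos_mask = y1 == 1
        self.stage2 = train_stage2(np.asarray(X, float)[pos_mask],
                                   [t for t in truth if t in SUBTYPES],
                                   seed=self.seed)
        return self

    def diagnose_features(self, fv_values: np.ndarray, slide_id: str,
                          records: Sequence[TargetRecord] = ()) -> TBSReport:
        if self.stage1 is None or self.stage2 is None:
            raise TrainingError("engine is not trained")
        scores = self.stage1.member_scores(fv_values)[0]
        calls = (scores >= np.asarray(self.stage1.thresholds)).tolist()
        positive = ensemble_positive(calls)
        squamous = {
            "member_scores": [round(float(s), 9) for s in scores],
            "member_calls": calls,
            "ensemble_positive": positive,
        }
        if positive:
            subtype, probs = predict_stage2_subtype(fv_values, self.stage2)
            squamous["subtype"] = subtype
            squamous["subtype_probs"] = {s: round(p, 9)
                                         for s, p in probs.items()}
        other = logic_tree_decide(records, self.logic_config)
        return finalize_report(slide_id, squamous, other)

    def diagnose(self, records: Sequence[TargetRecord],
                 slide_id: str | None = None) -> TBSReport:
        """Records in, TBSReport out."""
        fv = aggregate_slide(records, self.schema, slide_id=slide_id)
        return self.diagnose_features(fv.to_array(missing_as_nan=True),
                                      fv.slide_id, records)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        if self.stage1 is None or self.stage2 is None:
            raise TrainingError("cannot save an untrained engine")
        os.makedirs(directory, exist_ok=True)
        self.stage1.save(os.path.join(directory, "stage1"))
        self.stage2.get_booster().save_model(os.path.join(directory, "stage2.json"))
        meta = {"k": self.k, "seed": self.seed,
                "logic_rules": {b: list(r) for b, r
                                in self.logic_config.rules.items()},
                "stage2_classes": [int(c) for c in self.stage2.classes_]}
        with open(os.path.join(directory, "engine.json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "DiagnosticEngine":
        with open(os.path.join(directory, "engine.json")) as fh:
            meta = json.load(fh)
        stage1 = EnsembleModel.load(os.path.join(directory, "stage1"))
        eng = cls(schema=stage1.schema,
                  logic_config=LogicTreeConfig({
                      b: (p, n) for b, (p, n) in meta["logic_rules"].items()}),
                  k=meta["k"], seed=meta["seed"])
        eng.stage1 = stage1
        eng.stage2 = xgb.XGBClassifier(**_XGB_DEFAULTS)
        eng.stage2.load_model(os.path.join(directory, "stage2.json"))
        return eng
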