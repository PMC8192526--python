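"""Decision engine: ensemble rule, subtype model, logic tree, priority."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import cytoscreen as cs
from cytoscreen.engine import (
    LOGIC_BRANCH_CLASSES, DiagnosticEngine, LogicTreeConfig, TrainingError,
    ensemble_positive, finalize_report, logic_tree_decide,
    predict_stage2_subtype, subtype_from_probabilities, train_stage1,
    train_stage2, tune_sensitivity,
)
from cytoscreen.records import BoundingBox, TargetRecord


def _rec(cls, prob):
    det = cs.detection_class_of(cls)
    return TargetRecord("s", BoundingBox(0, 0, 10, 10),
                        det if det != "excluded" else 0, prob, cls, prob)


@pytest.fixture(scope="module")
def labelled_features(schema):
    corpus = cs.make_corpus(200, seed=21)
    X, _, ids = cs.aggregate_corpus(corpus.records_by_slide(), schema)
    truth = {s: t for s, t, _ in corpus.slides}
    y = np.array([1 if truth[i] in cs.SUBTYPES else 0 for i in ids])
    subtypes = {i: truth[i] for i in ids if truth[i] in cs.SUBTYPES}
    return corpus, X, ids, y, subtypes


class TestStage1Training:
    def test_ten_members_with_informative_heldout_auc(self, schema,
                                                      labelled_features):
        _, X, ids, y, _ = labelled_features
        model = train_stage1(X, y, schema, k=10, seed=0)
        assert model.k == 10
        folds = np.array(model.fold_assignments)
        for fold, member in enumerate(model.members):
            held = folds == fold
            scores = member.predict_proba(X[held])[:, 1]
            auc = roc_auc_score(y[held], scores)
            assert auc > 0.5  # beats a label-shuffled baseline

    def test_k_equals_one_degenerates_to_single_model(self, schema,
                                                      labelled_features):
        _, X, _, y, _ = labelled_features
        model = train_stage1(X, y, schema, k=1, seed=0)
        assert model.k == 1
        preds = model.predict_positive(X)
        assert preds.shape == (len(y),)

    def test_uninformative_features_give_chance_auc(self, schema, rng):
        """Identical feature distribution for both classes: AUC ~ 0.5."""
        X = rng.normal(size=(300, len(schema)))
        y = np.array([0, 1] * 150)
        model = train_stage1(X, y, schema, k=5, seed=1)
        folds = np.array(model.fold_assignments)
        aucs = [roc_auc_score(y[folds == f],
                              m.predict_proba(X[folds == f])[:, 1])
                for f, m in enumerate(model.members)]
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_single_class_input_raises(self, schema, rng):
        X = rng.normal(size=(40, len(schema)))
        with pytest.raises(TrainingError):
            train_stage1(X, np.ones(40), schema, k=5, seed=0)

    def test_fold_assignment_reproducible_from_seed(self, schema,
                                                    labelled_features):
        _, X, _, y, _ = labelled_features
        a = train_stage1(X, y, schema, k=5, seed=9)
        b = train_stage1(X, y, schema, k=5, seed=9)
        assert a.fold_assignments == b.fold_assignments


class TestEnsembleRule:
    def test_all_false_is_negative(self):
        assert ensemble_positive([False] * 10) is False

    def test_one_of_ten_is_positive(self):
        calls = [False] * 10
        calls[7] = True
        assert ensemble_positive(calls) is True

    def test_all_true_is_positive(self):
        assert ensemble_positive([True] * 10) is True

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_positive([])

    def test_union_monotonicity_inequality(self, schema, labelled_features):
        """Ensemble sensitivity >= any member's; specificity <= any member's."""
        _, X, _, y, _ = labelled_features
        model = train_stage1(X, y, schema, k=10, seed=3)
        calls = model.member_calls(X)
        ens = calls.any(axis=1)
        ens_sens = ens[y == 1].mean()
        ens_spec = 1 - ens[y == 0].mean()
        for j in range(model.k):
            member_sens = calls[y == 1, j].mean()
            member_spec = 1 - calls[y == 0, j].mean()
            assert ens_sens >= member_sens
            assert ens_spec <= member_spec


class TestSensitivityTuning:
    def test_separable_set_reaches_full_sensitivity(self, schema):
        """On a separable tuning set (pristine negatives vs heavy-burden
        lesions) tuning reaches sensitivity 1.0 without losing specificity."""
        cfg = cs.SlideSimConfig(fp_rate=0.0)
        corpus = cs.make_corpus(120, {"NILM": 0.5, "HSIL": 0.5}, seed=51,
                                config=cfg)
        X, _, ids = cs.aggregate_corpus(corpus.records_by_slide(), schema)
        truth = {s: t for s, t, _ in corpus.slides}
        y = np.array([truth[i] == "HSIL" for i in ids], dtype=int)
        model = train_stage1(X, y, schema, k=10, seed=0)
        pred_before = model.predict_positive(X)
        spec_before = 1 - pred_before[y == 0].mean()
        tune_sensitivity(model, X, y)
        pred = model.predict_positive(X)
        assert pred[y == 1].all()  # sensitivity 1.0
        assert 1 - pred[y == 0].mean() >= spec_before - 1e-12

    def test_bracketed_by_grid_search_oracle(self, schema, labelled_features):
        """Tuned specificity reaches sensitivity 1.0, beats the naive
        per-member-minimum baseline, and never exceeds the exhaustive
        grid-search optimum (k=2, brute force over all threshold pairs)."""
        from itertools import product

        _, X, _, y, _ = labelled_features
        model = train_stage1(X, y, schema, k=2, seed=4)
        scores = model.member_scores(X)
        pos, neg = scores[y == 1], scores[y == 0]

        def spec(thresholds):
            return 1 - (neg >= thresholds).any(axis=1).mean()

        # exhaustive search over observed-score thresholds (plus "never")
        grids = [np.append(np.unique(scores[:, j]), 2.0) for j in range(2)]
        best = -1.0
        for t in product(*grids):
            t = np.array(t)
            if (pos >= t).any(axis=1).all():  # sensitivity 1 required
                best = max(best, spec(t))

        tuned = np.array(tune_sensitivity(model, X, y))
        assert (pos >= tuned).any(axis=1).all()
        naive = pos.min(axis=0)
        assert spec(naive) <= spec(tuned) <= best + 1e-12

    def test_threshold_bounds(self, schema, labelled_features):
        _, X, _, y, _ = labelled_features
        model = train_stage1(X, y, schema, k=3, seed=0)
        model.thresholds = [0.0] * model.k
        pred = model.predict_positive(X)
        assert pred.all()  # sensitivity 1, specificity 0
        model.thresholds = [1.1] * model.k
        assert not model.predict_positive(X).any()

    def test_no_positives_raises(self, schema, rng):
        X = rng.normal(size=(30, len(schema)))
        model = train_stage1(X, np.array([0, 1] * 15), schema, k=3, seed=0)
        with pytest.raises(TrainingError):
            tune_sensitivity(model, X, np.zeros(30))


class TestStage2:
    def test_argmax(self):
        assert subtype_from_probabilities([0.1, 0.2, 0.1, 0.5, 0.1]) == "HSIL"

    def test_tie_breaks_to_less_severe(self):
        assert subtype_from_probabilities([0.3, 0.3, 0.3, 0.05, 0.05]) == "ASCUS"
        assert subtype_from_probabilities([0.2] * 5) == "ASCUS"

    def test_generator_label_recovery_for_scc(self, schema, labelled_features):
        _, X, ids, y, subtypes = labelled_features
        mask = np.array([i in subtypes for i in ids])
        model = train_stage2(X[mask], [subtypes[i] for i in ids if i in subtypes],
                             seed=0)
        hits = total = 0
        for row, sid in zip(X[mask], [i for i in ids if i in subtypes]):
            if subtypes[sid] != "SCC":
                continue
            call, probs = predict_stage2_subtype(row, model)
            total += 1
            hits += call == "SCC"
            assert abs(sum(probs.values()) - 1.0) < 1e-6
        assert total > 0 and hits / total > 0.9

    def test_single_subtype_raises(self, schema, rng):
        with pytest.raises(TrainingError):
            train_stage2(rng.normal(size=(10, 4)), ["LSIL"] * 10)


class TestLogicTree:
    def test_trichomonas_rule_fires(self):
        recs = [_rec(16, 0.95) for _ in range(5)]
        cfg = LogicTreeConfig({"TRI": (0.9, 3)})
        assert logic_tree_decide(recs, cfg) == {"TRI"}

    def test_no_records_no_calls(self):
        assert logic_tree_decide([], LogicTreeConfig()) == set()

    def test_merged_agc_counts_both_subclasses(self):
        recs = [_rec(1, 0.9), _rec(1, 0.9), _rec(2, 0.9)]
        cfg = LogicTreeConfig({"AGC": (0.5, 3)})
        assert logic_tree_decide(recs, cfg) == {"AGC"}

    def test_below_probability_records_do_not_count(self):
        recs = [_rec(16, 0.5)] * 10
        cfg = LogicTreeConfig({"TRI": (0.9, 3)})
        assert logic_tree_decide(recs, cfg) == set()

    def test_branches_fire_independently(self):
        recs = [_rec(16, 0.95)] * 3 + [_rec(17, 0.95)] * 3
        cfg = LogicTreeConfig({"TRI": (0.9, 3), "CAN": (0.9, 3)})
        assert logic_tree_decide(recs, cfg) == {"TRI", "CAN"}

    def test_malformed_rule_rejected(self):
        with pytest.raises(ValueError):
            LogicTreeConfig({"TRI": (1.5, 3)})
        with pytest.raises(ValueError):
            LogicTreeConfig({"NOT_A_BRANCH": (0.5, 1)})

    def test_branch_class_map_matches_taxonomy(self, taxonomy=None):
        tax = cs.default_taxonomy()
        for branch, classes in LOGIC_BRANCH_CLASSES.items():
            for c in classes:
                targets = tax.map_annotation_to_tbs(c)
                if branch == "AGC":
                    assert targets & {"AGC_NOS", "AGC_FN", "AIS", "ADC"}
                else:
                    assert branch in targets


class TestFinalReport:
    def test_all_negative_is_nilm(self):
        rep = finalize_report("s", {"ensemble_positive": False}, set())
        assert rep.final_tbs == "NILM"
        assert not rep.priority_applied

    def test_lsil_outranks_trichomonas(self):
        rep = finalize_report(
            "s", {"ensemble_positive": True, "subtype": "LSIL"}, {"TRI"})
        assert rep.final_tbs == "LSIL"
        assert rep.priority_applied

    def test_single_infectious_lesion(self):
        rep = finalize_report("s", {"ensemble_positive": False}, {"CAN"})
        assert rep.final_tbs == "CAN"
        assert not rep.priority_applied

    def test_scc_outranks_everything(self):
        rep = finalize_report(
            "s", {"ensemble_positive": True, "subtype": "SCC"},
            {"AGC", "TRI", "EMC"})
        assert rep.final_tbs == "SCC"

    def test_agc_outranks_lsil_priority_order(self):
        rep = finalize_report(
            "s", {"ensemble_positive": True, "subtype": "LSIL"}, {"AGC"})
        assert rep.final_tbs == "AGC"


class TestEnginePersistence:
    def test_save_load_identical_reports(self, tmp_path, schema):
        corpus = cs.make_corpus(150, seed=31)
        X, _, ids = cs.aggregate_corpus(corpus.records_by_slide(), schema)
        truth = {s: t for s, t, _ in corpus.slides}
        eng = DiagnosticEngine(schema=schema, k=5, seed=2)
        eng.fit(X, [truth[i] for i in ids])
        eng.save(tmp_path / "model")
        loaded = DiagnosticEngine.load(tmp_path / "model")
        for sid, _t, recs in corpus.slides[:20]:
            assert (loaded.diagnose(recs, slide_id=sid).to_json()
                    == eng.diagnose(recs, slide_id=sid).to_json())

    def test_untrained_engine_refuses(self, schema):
        eng = DiagnosticEngine(schema=schema)
        with pytest.raises(TrainingError):
            eng.diagnose_features(np.zeros(len(schema)), "s")
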