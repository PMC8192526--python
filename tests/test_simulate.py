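"""Synthetic generators: determinism, composition, statistical fidelity."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import cytoscreen as cs
from cytoscreen.records import record_to_json
from cytoscreen.simulate import (
    ClassBurden, SlideSimConfig, allocate_counts, make_corpus, make_qc_corpus,
    simulate_slide, simulate_tile,
)


class TestSimulateSlide:
    def test_pristine_negative_has_no_lesion_records(self):
        cfg = SlideSimConfig(fp_rate=0.0)
        for seed in range(20):
            recs, truth = simulate_slide(cfg, "NILM", seed=seed)
            assert truth == "NILM"
            assert all(r.refined_class in (12,) for r in recs)

    def test_scc_preset_plants_scc_bearing_detection_class(self, taxonomy):
        """The keratinizing-carcinoma detection group appears with high
        refined probability on essentially every simulated SCC slide."""
        scc_group = taxonomy.detection_class_of(9)
        cfg = SlideSimConfig(fp_rate=0.0)  # isolate the planted lesions
        probs = []
        for seed in range(300):
            recs, _ = simulate_slide(cfg, "SCC", seed=seed)
            hits = [r for r in recs if r.det_class == scc_group]
            assert hits  # Poisson(14) total burden: zero is ~8e-7
            probs.extend(r.refined_prob for r in hits
                         if r.refined_class in (9, 10))
        # planted Beta(8, 2): mean 0.8, se ~ 0.12/sqrt(n)
        assert abs(np.mean(probs) - 0.8) < 3 * 0.12 / np.sqrt(len(probs))

    def test_same_seed_identical_streams(self):
        a, _ = simulate_slide(SlideSimConfig(), "HSIL", seed=77)
        b, _ = simulate_slide(SlideSimConfig(), "HSIL", seed=77)
        assert [record_to_json(r) for r in a] == [record_to_json(r) for r in b]

    def test_unknown_truth_rejected(self):
        with pytest.raises(ValueError):
            simulate_slide(SlideSimConfig(), "ATROPHY", seed=0)

    def test_evidence_attached_where_pipeline_expects(self):
        recs, _ = simulate_slide(SlideSimConfig(), "HSIL", seed=3)
        for r in recs:
            if r.patch_label is not None:
                assert 3 <= r.refined_class <= 10
            if r.nucleus is not None:
                assert r.refined_class in (3, 8, 12)
                assert r.nucleus.area_um2 == r.nucleus.area_px * 0.0625


class TestBetaFidelity:
    def test_empirical_mean_within_three_se(self):
        """Planted Beta(8,2) probabilities: mean 0.8 within 3 SE at n=1000."""
        cfg = SlideSimConfig(lesion_burdens={"LSIL": (ClassBurden(4, 8.0),)},
                             background_mean=0.0, fp_rate=0.0)
        probs = []
        seed = 0
        while len(probs) < 1000:
            recs, _ = simulate_slide(cfg, "LSIL", seed=seed)
            probs.extend(r.refined_prob for r in recs)
            seed += 1
        probs = np.array(probs[:1000])
        mean, var = 0.8, (0.8 * 0.2) / 11.0  # Beta(8,2) moments
        assert abs(probs.mean() - mean) < 3 * np.sqrt(var / 1000)


class TestCorpus:
    def test_largest_remainder_allocation(self):
        counts = allocate_counts(100, {"NILM": 0.8, "HSIL": 0.2})
        assert counts == {"NILM": 80, "HSIL": 20}
        counts = allocate_counts(10, {"A": 0.55, "B": 0.25, "C": 0.2})
        assert sum(counts.values()) == 10
        assert counts["A"] == 6  # largest remainder gets the spare slide

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            allocate_counts(10, {"NILM": 0.5, "HSIL": 0.2})

    def test_mix_realized_in_labels(self):
        corpus = make_corpus(100, {"NILM": 0.8, "HSIL": 0.2}, seed=3)
        assert corpus.truths.count("NILM") == 80
        assert corpus.truths.count("HSIL") == 20

    def test_empty_corpus_valid_manifest(self):
        corpus = make_corpus(0, seed=5)
        assert len(corpus) == 0
        assert corpus.manifest["n_slides"] == 0

    def test_regeneration_is_byte_identical(self):
        a = make_corpus(40, seed=9)
        b = make_corpus(40, seed=9)
        assert a.manifest == b.manifest
        for (sa, ta, ra), (sb, tb, rb) in zip(a.slides, b.slides):
            assert (sa, ta) == (sb, tb)
            assert [record_to_json(r) for r in ra] == \
                [record_to_json(r) for r in rb]

    def test_slides_regenerable_in_isolation(self):
        corpus = make_corpus(20, seed=13)
        sid, truth, recs = corpus.slides[7]
        rng = np.random.default_rng(np.random.SeedSequence([13, 7]))
        regen, _ = simulate_slide(SlideSimConfig(), truth, rng, slide_id=sid)
        assert [record_to_json(r) for r in regen] == \
            [record_to_json(r) for r in recs]


class TestSeparationKnob:
    def test_higher_lesion_probability_raises_auc(self, schema):
        """Raising the positive-class Beta mean improves stage-1
        separability on average (3 seeded repeats per setting).  Lesion
        counts are matched to the false-positive background so the
        probability distribution is the only separating signal."""
        def mean_auc(beta):
            aucs = []
            for rep in range(3):
                # identical planted counts on both arms, on a class that
                # carries no patch/nucleus side channel (endometrial cells):
                # the class-probability distribution is the only signal
                burdens = {"NILM": (ClassBurden(15, 3.0, 1.5, 8.0),),
                           "EMC": (ClassBurden(15, 3.0, *beta),)}
                cfg = SlideSimConfig(lesion_burdens=burdens, fp_rate=0.0)
                corpus = make_corpus(80, {"NILM": 0.5, "EMC": 0.5},
                                     seed=100 + rep, config=cfg)
                X, _, ids = cs.aggregate_corpus(corpus.records_by_slide(),
                                                schema)
                truth = {s: t for s, t, _ in corpus.slides}
                y = np.array([truth[i] == "EMC" for i in ids], dtype=int)
                model = cs.train_stage1(X, y, schema, k=2, seed=rep)
                folds = np.array(model.fold_assignments)
                for f, m in enumerate(model.members):
                    held = folds == f
                    aucs.append(roc_auc_score(
                        y[held], m.predict_proba(X[held])[:, 1]))
            return np.mean(aucs)

        weak = mean_auc((1.5, 8.0))    # same mean as the fp background
        strong = mean_auc((8.0, 2.0))  # mean 0.8, well separated
        assert strong > weak


class TestSimulateTile:
    def test_zero_density_background_only(self):
        # noise off: an empty tile is pure background (Otsu has no signal)
        cfg = cs.ImageSimConfig(noise_sd=0.0)
        img = simulate_tile(cfg, "qualified", seed=4, coverage=0.0)
        gray = np.clip(np.rint(img.astype(float) @ [0.299, 0.587, 0.114]),
                       0, 255).astype(np.uint8)
        assert cs.cell_area_ratio(gray) < 0.05

    def test_defocus_lowers_focus_score(self):
        sharp = simulate_tile(None, "qualified", seed=6)
        soft = simulate_tile(None, "defocus", seed=6)
        to_gray = lambda im: im.astype(float) @ [0.299, 0.587, 0.114]
        assert cs.focus_score(to_gray(soft)) < cs.focus_score(to_gray(sharp))

    def test_planted_coverage_recovered(self):
        img = simulate_tile(None, "qualified", seed=8, coverage=0.30)
        gray = np.clip(np.rint(img.astype(float) @ [0.299, 0.587, 0.114]),
                       0, 255).astype(np.uint8)
        assert cs.cell_area_ratio(gray) == pytest.approx(0.30, abs=0.02)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            simulate_tile(None, "scratched", seed=0)

    def test_qc_corpus_balanced_and_deterministic(self):
        a = make_qc_corpus(8, seed=3)
        b = make_qc_corpus(8, seed=3)
        assert [p for _, p, _ in a] == list(cs.QUALITY_PRESETS) * 2
        for (ia, _, qa), (ib, _, qb) in zip(a, b):
            assert qa == qb
            np.testing.assert_array_equal(ia, ib)
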