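import numpy as np
import pytest

import oracles  # noqa: F401  (shared conftest path)
from adeeg import (
    ClassProbabilities,
    ClinicalModel,
    ConfusionCounts,
    PEClassifier,
    accuracy,
    confusion_counts,
    fit_stacker,
    fuse,
    generate_clinical_table,
    multiclass_accuracy,
    roc_curve,
    screen_clinical,
)
from adeeg.recording import ClinicalRecord


def _uniform_table(n, seed):
    return generate_clinical_table(n, effects={}, seed=seed)


class TestScreening:
    def test_default_effects_recovered(self):
        records = generate_clinical_table(100, seed=0)
        result = screen_clinical(records)
        assert set(result.selected) == {"age", "diabetes", "eye_movement"}

    def test_alpha_one_selects_every_feature(self):
        records = _uniform_table(60, seed=1)
        result = screen_clinical(records, alpha=1.0)
        assert len(result.selected) == 6

    def test_constant_feature_warns_and_gets_p_one(self):
        records = [
            ClinicalRecord(age=60 + i, sex="F", hypertension=0,
                           hyperlipidemia=0, diabetes=0,
                           eye_movement=50.0 + i,
                           label=["calm", "transitional", "morbidity"][i % 3])
            for i in range(30)
        ]
        with pytest.warns(UserWarning, match="constant"):
            result = screen_clinical(records)
        row = result.tests.set_index("feature").loc["diabetes"]
        assert row["p_value"] == 1.0

    def test_single_state_rejected(self):
        records = [
            ClinicalRecord(age=60, sex="F", hypertension=0, hyperlipidemia=0,
                           diabetes=0, eye_movement=50.0, label="calm")
            for _ in range(20)
        ]
        with pytest.raises(ValueError, match="two states"):
            screen_clinical(records)

    def test_null_table_selection_is_rare(self):
        """Type-I behaviour: under the null each feature is selected at
        roughly the nominal rate (coarse check over 60 seeds)."""
        count = 0
        for seed in range(60):
            count += len(screen_clinical(_uniform_table(100, seed)).selected)
        rate = count / (60 * 6)
        assert rate < 0.12

    def test_p_values_in_unit_interval(self):
        result = screen_clinical(generate_clinical_table(50, seed=4))
        p = result.tests["p_value"]
        assert ((0 <= p) & (p <= 1)).all()


class TestAccuracy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(10, 0, 10, 0), 1.0),
            (ConfusionCounts(3, 1, 4, 2), 0.7),
            (ConfusionCounts(0, 5, 0, 5), 0.0),
        ],
    )
    def test_direct_arithmetic(self, counts, expected):
        assert accuracy(counts) == pytest.approx(expected)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_confusion_matches_direct_prediction_tally(self, rng):
        y = rng.integers(0, 3, 60)
        p = rng.integers(0, 3, 60)
        for cls in range(3):
            c = confusion_counts(y, p, cls)
            assert c.total == 60
            direct = np.mean((y == cls) == (p == cls))
            assert accuracy(c) == pytest.approx(direct)
        assert multiclass_accuracy(y, p) == pytest.approx((y == p).mean())


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        _, _, auc = roc_curve(scores, y, positive_class=1)
        assert auc == 1.0

    def test_label_independent_scores_give_half(self, rng):
        y = rng.integers(0, 2, 1000)
        scores = rng.random(1000)
        _, _, auc = roc_curve(scores, y, positive_class=1)
        assert abs(auc - 0.5) < 0.05

    def test_auc_equals_pairwise_concordance(self, rng):
        for _ in range(5):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            scores = rng.random(30)
            _, _, auc = roc_curve(scores, y, positive_class=1)
            pos = scores[y == 1]
            neg = scores[y == 0]
            gt = (pos[:, None] > neg[None, :]).mean()
            ties = 0.5 * (pos[:, None] == neg[None, :]).mean()
            assert auc == pytest.approx(gt + ties, abs=1e-12)

    def test_curve_is_monotone(self, rng):
        y = rng.integers(0, 3, 200)
        scores = rng.random((200, 3))
        fpr, tpr, _ = roc_curve(scores, y, positive_class="calm")
        assert np.all(np.diff(fpr) >= 0)
        assert np.all(np.diff(tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive and negative"):
            roc_curve(np.array([0.1, 0.9]), np.array([1, 1]),
                      positive_class=1)


class TestFusion:
    def test_identical_sources_are_a_fixed_point(self):
        v = np.array([0.2, 0.3, 0.5])
        p = ClassProbabilities(pe=v, re=v, clinical=v)
        assert np.allclose(fuse(p, "mean"), v)
        assert np.allclose(fuse(p, "weighted", weights=(0.5, 0.25, 0.25)), v)

    def test_degenerate_weights_select_one_source(self):
        p = ClassProbabilities(
            pe=np.array([0.7, 0.2, 0.1]),
            re=np.array([0.1, 0.8, 0.1]),
            clinical=np.array([1 / 3, 1 / 3, 1 / 3]),
        )
        assert np.allclose(fuse(p, "weighted", weights=(1.0, 0.0, 0.0)),
                           p.pe)

    def test_unnormalized_weights_are_renormalized_with_warning(self):
        p = ClassProbabilities(pe=np.array([0.6, 0.3, 0.1]),
                               re=np.array([0.2, 0.5, 0.3]))
        with pytest.warns(UserWarning, match="renormaliz"):
            out = fuse(p, "weighted", weights=(2.0, 2.0))
        assert np.allclose(out, 0.5 * (p.pe + p.re))

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError, match="no source"):
            fuse(ClassProbabilities(), "mean")

    def test_stacked_fusion_learns_a_reliable_source(self, rng):
        """The meta-classifier keys on the informative source when the
        other is noise."""
        labels = rng.integers(0, 3, 120)
        prob_list = []
        for y in labels:
            good = np.full(3, 0.1)
            good[y] = 0.8
            noise = rng.dirichlet(np.ones(3))
            prob_list.append(ClassProbabilities(pe=noise, re=good))
        meta = fit_stacker(prob_list[:80], labels[:80], seed=0)
        preds = [fuse(p, "stacked", meta_model=meta).argmax()
                 for p in prob_list[80:]]
        assert (np.array(preds) == labels[80:]).mean() > 0.9

    def test_probability_validation(self):
        with pytest.raises(ValueError, match="probability"):
            ClassProbabilities(pe=np.array([0.5, 0.6, 0.2]))


class TestClassifierBranches:
    def test_pe_outputs_simplex_and_is_deterministic(self, rng):
        X = rng.normal(size=(90, 8))
        y = rng.integers(0, 3, 90)
        X[y == 1] += 2.0
        X[y == 2] -= 2.0
        clf = PEClassifier(seed=0).fit(X, y)
        probs = clf.predict_proba(np.vstack([X[0], X[0]]))
        assert np.array_equal(probs[0], probs[1])
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-9

    def test_pe_dimension_mismatch_rejected(self, rng):
        clf = PEClassifier(seed=0).fit(rng.normal(size=(30, 5)),
                                       rng.integers(0, 3, 30))
        with pytest.raises(ValueError, match="dimension"):
            clf.predict_proba(rng.normal(size=(2, 4)))

    def test_pe_separable_problem_beats_chance(self, rng):
        y = np.repeat([0, 1, 2], 60)
        X = rng.normal(size=(180, 4)) + 3.0 * y[:, None]
        clf = PEClassifier(seed=0).fit(X[::2], y[::2])
        acc = (clf.predict_proba(X[1::2]).argmax(1) == y[1::2]).mean()
        assert acc > 1 / 3 + 0.2

    def test_clinical_empty_screen_gives_uniform(self):
        records = generate_clinical_table(30, effects={}, seed=0)
        screened = screen_clinical(records, alpha=1e-9)
        assert screened.selected == ()
        with pytest.warns(UserWarning, match="uniform"):
            model = ClinicalModel(screened).fit(records)
        probs = model.predict_proba(records[:5])
        assert np.allclose(probs, 1 / 3)

    def test_clinical_model_beats_chance_on_injected_effects(self, rng):
        records = generate_clinical_table(300, seed=5)
        order = rng.permutation(len(records))
        records = [records[i] for i in order]
        screened = screen_clinical(records[:200])
        model = ClinicalModel(screened, seed=0).fit(records[:200])
        probs = model.predict_proba(records[200:])
        y = np.array([["calm", "transitional", "morbidity"].index(r.label)
                      for r in records[200:]])
        assert (probs.argmax(1) == y).mean() > 1 / 3
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-9
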