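import numpy as np
import pytest

from adeeg import OneVsRestCSP, csp_features, fit_csp, normalized_covariance
from adeeg.csp import read_csp, write_csp


def _trials(rng, A, n, T=256):
    """Trials with population covariance A @ A.T."""
    return [A @ rng.standard_normal((A.shape[0], T)) for _ in range(n)]


@pytest.fixture(scope="module")
def two_class_problem():
    rng = np.random.default_rng(7)
    A1 = np.diag([5.0, 1.0]) ** 0.5
    A2 = np.diag([1.0, 5.0]) ** 0.5
    return {
        "train": (_trials(rng, A1, 200), _trials(rng, A2, 200)),
        "test": (_trials(rng, A1, 200), _trials(rng, A2, 200)),
    }


class TestNormalizedCovariance:
    def test_orthogonal_unit_rows(self):
        X = np.eye(2)
        assert np.allclose(normalized_covariance(X), np.eye(2) / 2)

    def test_unit_trace(self, rng):
        R = normalized_covariance(rng.normal(size=(4, 1000)))
        assert np.trace(R) == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        X = rng.normal(size=(3, 50))
        S = X @ X.T
        assert np.abs(
            normalized_covariance(X) - S / np.trace(S)
        ).max() < 1e-12

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="trace"):
            normalized_covariance(np.zeros((3, 10)))


class TestFitCSP:
    def test_whitening_and_eigenvalue_constraints(self, two_class_problem):
        c1, c2 = two_class_problem["train"]
        model = fit_csp(c1, c2, m=1)
        M = model.n_channels
        assert np.abs(model.P @ model.Rc @ model.P.T - np.eye(M)).max() < 1e-8
        assert np.abs(model.lambda1 + model.lambda2 - 1.0).max() < 1e-8

    def test_simultaneous_diagonalization(self, two_class_problem):
        c1, c2 = two_class_problem["train"]
        model = fit_csp(c1, c2, m=1)
        S1 = model.P @ model.R1_bar @ model.P.T
        D = model.B.T @ S1 @ model.B
        assert np.abs(D - np.diag(np.diag(D))).max() < 1e-8
        S2 = model.P @ model.R2_bar @ model.P.T
        D2 = model.B.T @ S2 @ model.B
        assert np.abs(D2 - np.diag(np.diag(D2))).max() < 1e-8

    def test_identical_classes_are_degenerate(self, rng):
        trials = _trials(rng, np.eye(3), 50)
        model = fit_csp(trials, trials, m=1, regularize=False)
        assert np.abs(model.lambda1 - 0.5).max() < 1e-8

    def test_leading_filter_variance_ratio(self, rng):
        X1 = [np.diag([5.0, 1.0]) ** 0.5 @ rng.standard_normal((2, 2000))]
        X2 = [np.diag([1.0, 5.0]) ** 0.5 @ rng.standard_normal((2, 2000))]
        model = fit_csp(X1, X2, m=1)
        z1 = model.W @ X1[0]
        z2 = model.W @ X2[0]
        assert z1[0].var() / z2[0].var() > 3.0

    def test_recording_order_within_class_irrelevant(self, two_class_problem):
        c1, c2 = two_class_problem["train"]
        a = fit_csp(c1, c2, m=1)
        b = fit_csp(c1[::-1], c2[::-1], m=1)
        assert np.abs(a.W - b.W).max() < 1e-10

    def test_too_many_filters_rejected(self, two_class_problem):
        c1, c2 = two_class_problem["train"]
        with pytest.raises(ValueError, match="filters"):
            fit_csp(c1, c2, m=2)

    def test_empty_class_rejected(self, two_class_problem):
        with pytest.raises(ValueError, match="non-empty"):
            fit_csp([], two_class_problem["train"][1], m=1)

    def test_rank_deficiency_error_advises_regularization(self):
        X = [np.ones((3, 1)) @ np.ones((1, 100))]  # rank-1 recordings
        with pytest.raises(np.linalg.LinAlgError, match="regulariz"):
            fit_csp(X, X, m=1, regularize=False)


class TestFeatures:
    def test_feature_length_is_2m(self, rng):
        c1 = _trials(rng, np.diag([2.0, 1.0, 1.0, 0.5]) ** 0.5, 30)
        c2 = _trials(rng, np.diag([0.5, 1.0, 1.0, 2.0]) ** 0.5, 30)
        model = fit_csp(c1, c2, m=2)
        feats = csp_features(model, c1[0])
        assert feats.shape == (4,)

    def test_scaling_behaviour_of_selectors(self, two_class_problem):
        c1, c2 = two_class_problem["train"]
        model = fit_csp(c1, c2, m=1)
        X = c1[0]
        lv = csp_features(model, X, selector="log_variance")
        lv_scaled = csp_features(model, 3.0 * X, selector="log_variance")
        assert np.abs(lv - lv_scaled).max() < 1e-10
        pm = csp_features(model, X, selector="row_max")
        pm_scaled = csp_features(model, 3.0 * X, selector="row_max")
        assert np.allclose(pm_scaled, 3.0 * pm)

    def test_channel_mismatch_rejected(self, two_class_problem, rng):
        c1, c2 = two_class_problem["train"]
        model = fit_csp(c1, c2, m=1)
        with pytest.raises(ValueError, match="channels"):
            csp_features(model, rng.normal(size=(3, 100)))

    def test_held_out_separation_by_leading_feature(self, two_class_problem):
        c1, c2 = two_class_problem["train"]
        t1, t2 = two_class_problem["test"]
        model = fit_csp(c1, c2, m=1)
        f = lambda X: csp_features(model, X)[0]
        thr = 0.5 * (np.mean([f(X) for X in c1]) + np.mean([f(X) for X in c2]))
        sign = 1.0 if np.mean([f(X) for X in c1]) > thr else -1.0
        acc = 0.5 * (
            np.mean([sign * (f(X) - thr) > 0 for X in t1])
            + np.mean([sign * (f(X) - thr) < 0 for X in t2])
        )
        assert acc >= 0.95


class TestOneVsRestAndSerialization:
    def test_one_vs_rest_feature_length(self):
        from adeeg import generate_state_dataset
        recs = generate_state_dataset(4, n_samples=512, seed=0)
        ovr = OneVsRestCSP.fit(recs, m=2)
        assert ovr.transform(recs[0]).shape == (3 * 4,)

    def test_model_tsv_roundtrip(self, tmp_path, two_class_problem):
        c1, c2 = two_class_problem["train"]
        model = fit_csp(c1, c2, m=1)
        path = tmp_path / "csp.tsv"
        write_csp(path, model)
        back = read_csp(path)
        assert back.m == model.m
        assert np.abs(back.W - model.W).max() < 1e-12
        assert np.abs(back.lambda1 - model.lambda1).max() < 1e-12
        feats_a = csp_features(model, c1[0])
        feats_b = csp_features(back, c1[0])
        assert np.allclose(feats_a, feats_b)
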