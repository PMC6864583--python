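import math

import numpy as np
import pandas as pd
import pytest

from mtqsar.modeling import (
    GAConfig,
    LinearDiscriminantModel,
    ModelError,
    RFConfig,
    backward_eliminate,
    fit_lda,
    fit_rf,
    ga_select,
    reference_erk_model,
    y_randomization,
)


def _1d_frame(actives, inactives):
    X = pd.DataFrame({"x": list(actives) + list(inactives)})
    y = np.array([1] * len(actives) + [-1] * len(inactives))
    return X, y


def test_lda_hand_computed_1d():
    """Two classes at ±2 with within-scatter 4: λ = W/T = 4/20, D² = Δμ²/Sp."""
    X, y = _1d_frame([1, 3], [-1, -3])
    m = fit_lda(X, y)
    assert m.stats.wilks_lambda == pytest.approx(0.2, abs=1e-12)
    assert m.stats.canonical_R == pytest.approx(math.sqrt(0.8), abs=1e-12)
    assert m.stats.mahalanobis_D2 == pytest.approx(8.0, abs=1e-9)  # 4² / (4/2)
    assert m.stats.chi_square == pytest.approx(-1.5 * math.log(0.2), abs=1e-9)
    # boundary at the midpoint, actives positive
    assert m.classify(pd.DataFrame({"x": [0.5, -0.5]})).tolist() == [1, -1]


def test_lda_no_separation():
    X, y = _1d_frame([0, 1], [0, 1])
    m = fit_lda(X, y)
    assert m.stats.wilks_lambda == pytest.approx(1.0, abs=1e-9)
    assert m.stats.mahalanobis_D2 == pytest.approx(0.0, abs=1e-9)


def test_lda_requires_both_classes():
    X = pd.DataFrame({"x": [1.0, 2.0]})
    with pytest.raises(ModelError):
        fit_lda(X, np.array([1, 1]))


def test_lda_statistics_identities_random_fits():
    rng = np.random.default_rng(0)
    for _ in range(10):
        n, p = 60, int(rng.integers(1, 5))
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"d{i}" for i in range(p)])
        y = np.where(rng.random(n) < 0.5, 1, -1)
        if len(np.unique(y)) < 2:
            continue
        m = fit_lda(X, y)
        s = m.stats
        assert 0 < s.wilks_lambda <= 1
        assert s.canonical_R == pytest.approx(math.sqrt(1 - s.wilks_lambda), abs=1e-9)
        assert s.chi_square >= 0
        assert s.mahalanobis_D2 >= 0


def test_lda_classify_matches_mahalanobis_centroid_oracle():
    """Classification equals nearest class centroid under pooled-covariance
    Mahalanobis distance (brute-force oracle, ≤6 dimensions)."""
    rng = np.random.default_rng(5)
    for _ in range(8):
        p = int(rng.integers(1, 7))
        n = 80
        mu_a, mu_i = rng.normal(size=p), rng.normal(size=p)
        Xv = np.vstack(
            [rng.normal(size=(n // 2, p)) + mu_a, rng.normal(size=(n // 2, p)) + mu_i]
        )
        y = np.array([1] * (n // 2) + [-1] * (n // 2))
        X = pd.DataFrame(Xv, columns=[f"d{i}" for i in range(p)])
        m = fit_lda(X, y)
        # oracle: pooled covariance Mahalanobis distance to each centroid
        Xa, Xi = Xv[y == 1], Xv[y == -1]
        Sp = ((Xa - Xa.mean(0)).T @ (Xa - Xa.mean(0)) + (Xi - Xi.mean(0)).T @ (Xi - Xi.mean(0))) / (n - 2)
        Sp_inv = np.linalg.inv(Sp)

        def maha(v, mu):
            d = v - mu
            return d @ Sp_inv @ d

        oracle = np.array(
            [1 if maha(v, Xa.mean(0)) < maha(v, Xi.mean(0)) else -1 for v in Xv]
        )
        np.testing.assert_array_equal(m.classify(X), oracle)


def test_lda_agrees_with_sklearn_on_balanced_data():
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(9)
    n, p = 100, 3
    Xv = np.vstack([rng.normal(size=(50, p)) + 1.0, rng.normal(size=(50, p)) - 1.0])
    y = np.array([1] * 50 + [-1] * 50)
    X = pd.DataFrame(Xv, columns=list("abc"))
    ours = fit_lda(X, y).classify(X)
    theirs = LinearDiscriminantAnalysis().fit(Xv, y).predict(Xv)
    np.testing.assert_array_equal(ours, theirs)


# -- the bundled reference discriminant ---------------------------------------


def test_reference_model_score_arithmetic():
    m = reference_erk_model()
    zeros = {n: 0.0 for n in m.descriptor_names}
    assert m.score(zeros)[0] == pytest.approx(1.653)
    assert m.classify(zeros)[0] == 1
    x = dict(zeros, **{"D[Tssq11(CH)MN]_me": -0.1})
    assert m.score(x)[0] == pytest.approx(1.653 + 18.180 * (-0.1), abs=1e-9)
    assert m.classify(x)[0] == -1


def test_linear_score_sign_invariance():
    m = reference_erk_model()
    doubled = LinearDiscriminantModel(
        m.intercept * 2, {k: 2 * v for k, v in m.coefficients.items()}
    )
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(30, 7)), columns=m.descriptor_names)
    np.testing.assert_array_equal(m.classify(X), doubled.classify(X))


def test_score_missing_descriptor_errors():
    m = reference_erk_model()
    with pytest.raises(ModelError):
        m.score({"D[Tnsq5(CH)N2]_me": 0.0})


def test_model_json_round_trip(tmp_path):
    m = reference_erk_model()
    m.to_json(tmp_path / "m.json")
    back = LinearDiscriminantModel.from_json(tmp_path / "m.json")
    assert back.intercept == m.intercept
    assert back.coefficients == m.coefficients
    assert back.stats.wilks_lambda == pytest.approx(0.397)


# -- GA feature selection ------------------------------------------------------


def _planted_problem(n=500, noise_cols=50, beta=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, noise_cols + 1)),
        columns=["planted"] + [f"noise{i}" for i in range(noise_cols)],
    )
    p = 1 / (1 + np.exp(-(beta * X["planted"].values - 0.5)))
    y = np.where(rng.random(n) < p, 1, -1)
    return X, y


def test_ga_selects_planted_column():
    X, y = _planted_problem(seed=3)
    cfg = GAConfig(generations=15, equation_length=1, initial_population=30,
                   selected_per_generation=10, seed=11)
    res = ga_select(X, y, cfg, eliminate=False)
    assert res.columns == ["planted"]


def test_ga_best_fitness_monotone_and_deterministic():
    X, y = _planted_problem(n=200, noise_cols=20, seed=4)
    cfg = GAConfig(generations=10, equation_length=3, initial_population=20,
                   selected_per_generation=8, seed=2)
    res1 = ga_select(X, y, cfg, eliminate=False)
    res2 = ga_select(X, y, cfg, eliminate=False)
    assert res1.columns == res2.columns
    assert all(b <= a + 1e-12 for a, b in zip(res1.history, res1.history[1:]))


def test_ga_full_length_selects_everything():
    X, y = _planted_problem(n=100, noise_cols=3, seed=5)
    cfg = GAConfig(generations=2, equation_length=4, initial_population=5,
                   selected_per_generation=2, seed=0)
    res = ga_select(X, y, cfg, eliminate=False)
    assert sorted(res.columns) == sorted(X.columns)


def test_ga_equation_length_validated():
    X, y = _planted_problem(n=50, noise_cols=2, seed=6)
    with pytest.raises(ModelError):
        ga_select(X, y, GAConfig(equation_length=10, seed=0))


def test_backward_elimination_drops_noise():
    X, y = _planted_problem(n=400, noise_cols=5, seed=7)
    cols, dropped = backward_eliminate(X, y, list(X.columns))
    assert "planted" in cols
    assert len(cols) < X.shape[1]
    assert set(dropped) <= set(X.columns)


def test_duplicated_informative_column_removed_before_selection():
    """Pipeline ordering: pre-treatment removes a duplicated informative column
    so the selected subset contains exactly one copy."""
    from mtqsar.dataset_ops import pretreat

    X, y = _planted_problem(n=300, noise_cols=10, seed=8)
    X["planted_copy"] = X["planted"] * 1.5 + 0.3  # r² = 1
    Xp, report = pretreat(X)
    assert "planted_copy" in report["dropped_correlated"]
    cfg = GAConfig(generations=10, equation_length=2, initial_population=20,
                   selected_per_generation=8, seed=1)
    res = ga_select(Xp, y, cfg, eliminate=False)
    assert sum(c.startswith("planted") for c in res.columns) == 1


# -- random forest -------------------------------------------------------------


def test_rf_separable_training_accuracy():
    rng = np.random.default_rng(10)
    n = 400
    X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
    y = np.where(X["a"].values > 0, 1, -1)  # linearly separable
    model = fit_rf(X, y, RFConfig(seed=0))
    acc = np.mean(model.predict(X) == y)
    assert acc >= 0.99


def test_rf_deterministic_under_seed():
    rng = np.random.default_rng(12)
    X = pd.DataFrame(rng.normal(size=(200, 8)), columns=[f"d{i}" for i in range(8)])
    y = np.where(X.iloc[:, 0] + rng.normal(size=200) > 0, 1, -1)
    a = fit_rf(X, y, RFConfig(seed=4)).predict(X)
    b = fit_rf(X, y, RFConfig(seed=4)).predict(X)
    np.testing.assert_array_equal(a, b)


def test_rf_features_per_split():
    assert RFConfig().features_per_split(128) == 8  # int(log2(128) + 1)
    assert RFConfig().features_per_split(1) == 1
    assert RFConfig().features_per_split(1000) == 10


def test_rf_oob_close_to_cv():
    """Out-of-bag accuracy within 5 points of 10-fold CV accuracy."""
    from mtqsar.validation import cross_validate, rf_learner

    rng = np.random.default_rng(13)
    n = 500
    X = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"d{i}" for i in range(6)])
    logits = 2.0 * X["d0"].values - 1.5 * X["d1"].values
    y = np.where(rng.random(n) < 1 / (1 + np.exp(-logits)), 1, -1)
    model = fit_rf(X, y, RFConfig(seed=3), oob=True)
    cv = cross_validate(rf_learner(RFConfig(seed=3)), X, y, folds=10, seed=3)
    assert abs(model.oob_score * 100 - cv.accuracy) <= 5.0


# -- Y-randomisation -----------------------------------------------------------


def test_y_randomization_informative_vs_noise():
    rng = np.random.default_rng(14)
    n = 300
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
    y_info = np.where(X["a"] + 0.3 * rng.normal(size=n) > 0, 1, -1)
    res = y_randomization(X, y_info, n_rand=30, seed=0)
    assert len(res.lambdas) == 30
    assert res.lambda_rand_mean > res.lambda_original
    # pure noise: scrambling changes nothing systematic
    y_noise = np.where(rng.random(n) < 0.5, 1, -1)
    res2 = y_randomization(X, y_noise, n_rand=30, seed=0)
    assert abs(res2.lambda_rand_mean - res2.lambda_original) < 0.05
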