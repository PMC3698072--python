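"""Linear discriminant fitting, the decision rule, LOOCV and metrics."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import immunosig as im
from immunosig.discriminant import LinearDiscriminant, loocv_accuracy_diagonal
from immunosig.reference_tables import REFERENCE_ROWS


def two_gaussians(rng, n=30, p=2, delta=(1.0, 0.5)):
    X = rng.standard_normal((2 * n, p))
    y = np.repeat([0, 1], n)
    X[y == 1] += np.asarray(delta)[:p]
    return X, y


# -- decision rule -------------------------------------------------------

def test_symmetric_1d_boundary_at_zero():
    X = np.array([[-1.5], [-1.0], [-0.5], [0.5], [1.0], [1.5]])
    y = np.array([0, 0, 0, 1, 1, 1])
    m = im.fit_lda(X, y)
    assert m.decision_function([[0.0]])[0] == pytest.approx(0.0, abs=1e-12)
    assert m.predict([[0.5]])[0] == 1
    assert m.predict([[-0.5]])[0] == 0


def test_score_zero_assigned_to_group_j():
    """The strict decision rule sends a boundary score to the second group."""
    X = np.array([[-1.0], [-2.0], [1.0], [2.0]])
    m = im.fit_lda(X, np.array([0, 0, 1, 1]))
    assert m.decision_function([[0.0]])[0] == pytest.approx(0.0, abs=1e-12)
    assert m.predict([[0.0]])[0] == 1


def test_assignments_match_closed_form_bayes_oracle(rng):
    X, y = two_gaussians(rng)
    m = im.fit_lda(X, y)
    Xt = rng.standard_normal((200, 2)) * 2
    m0, m1 = X[y == 0].mean(0), X[y == 1].mean(0)
    S = ((X[y == 0] - m0).T @ (X[y == 0] - m0)
         + (X[y == 1] - m1).T @ (X[y == 1] - m1)) / (len(y) - 2)
    Si = np.linalg.inv(S)
    post1 = Xt @ Si @ m1 - 0.5 * m1 @ Si @ m1
    post0 = Xt @ Si @ m0 - 0.5 * m0 @ Si @ m0
    oracle = (post1 >= post0).astype(int)
    assert np.array_equal(m.predict(Xt), oracle)


def test_assignments_match_sklearn_lda(rng):
    X, y = two_gaussians(rng, n=40, p=4, delta=(1, 0.5, 0, 0.3))
    m = im.fit_lda(X, y)
    sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
    Xt = rng.standard_normal((150, 4)) * 2
    assert (m.predict(Xt) == sk.predict(Xt)).mean() == 1.0


def test_proportional_priors_shift_the_boundary(rng):
    X = np.vstack([rng.normal(-1, 1, (30, 1)), rng.normal(1, 1, (10, 1))])
    y = np.repeat([0, 1], [30, 10])
    eq = im.fit_lda(X, y, priors="equal")
    prop = im.fit_lda(X, y, priors="proportional")
    # the rarer positive class loses ground under proportional priors
    assert prop.intercept_ < eq.intercept_


def test_affine_feature_rescaling_leaves_assignments_unchanged(rng):
    X, y = two_gaussians(rng, p=3, delta=(1, 0.5, 0.2))
    scale = np.array([10.0, 0.01, 3.0])
    shift = np.array([5.0, -2.0, 0.0])
    m1 = im.fit_lda(X, y)
    m2 = im.fit_lda(X * scale + shift, y)
    Xt = rng.standard_normal((100, 3))
    assert np.array_equal(m1.predict(Xt), m2.predict(Xt * scale + shift))


def test_singular_covariance_errors_with_guidance(rng):
    X = rng.standard_normal((10, 2))
    X = np.hstack([X, X[:, :1]])  # exactly collinear
    y = np.repeat([0, 1], 5)
    with pytest.raises(np.linalg.LinAlgError, match="diagonal"):
        im.fit_lda(X, y)
    im.fit_lda(X, y, ridge=1e-8)       # opt-in ridge rescues the fit
    im.fit_lda(X, y, covariance_mode="diagonal")


def test_diagonal_agrees_with_pooled_when_truth_is_diagonal(rng):
    X, y = two_gaussians(rng, n=500, p=4, delta=(0.8, 0.4, 0.2, 0.0))
    Xt = rng.standard_normal((1000, 4))
    full = im.fit_lda(X, y).predict(Xt)
    diag = im.fit_lda(X, y, covariance_mode="diagonal").predict(Xt)
    assert (full == diag).mean() >= 0.99


# -- standardized canonical coefficients ---------------------------------

def test_single_feature_standardized_coefficient_is_unit(rng):
    X = np.vstack([rng.normal(0, 2, (12, 1)), rng.normal(3, 2, (12, 1))])
    y = np.repeat([0, 1], 12)
    m = im.fit_lda(X, y)
    assert im.standardized_coefficients(m)[0] == pytest.approx(1.0)
    m_neg = im.fit_lda(-X, y)
    assert m_neg.standardized_coef_[0] == pytest.approx(-1.0)


def test_standardized_coefficients_scale_invariant(rng):
    X, y = two_gaussians(rng, p=3, delta=(1, 0.6, 0.2))
    m1 = im.fit_lda(X, y)
    X2 = X.copy()
    X2[:, 0] *= 2.0
    m2 = im.fit_lda(X2, y)
    assert m2.coef_[0] == pytest.approx(m1.coef_[0] / 2.0)
    assert np.allclose(m2.standardized_coef_, m1.standardized_coef_)


def test_duplicate_information_features_share_magnitude(rng):
    base = np.vstack([rng.normal(0, 1, (20, 1)), rng.normal(2, 1, (20, 1))])
    y = np.repeat([0, 1], 20)
    X = np.hstack([base, base + rng.normal(0, 1e-6, base.shape)])
    m = im.fit_lda(X, y, covariance_mode="diagonal")
    assert abs(m.standardized_coef_[0]) == pytest.approx(
        abs(m.standardized_coef_[1]), abs=1e-4)


# -- LOOCV ---------------------------------------------------------------

def test_loocv_separated_classes_is_diagonal(rng):
    X = np.vstack([rng.normal(-5, 0.5, (5, 2)), rng.normal(5, 0.5, (5, 2))])
    y = np.repeat([0, 1], 5)
    cm = im.loocv(X, y)
    assert cm.counts.tolist() == [[5, 0], [0, 5]]


def test_loocv_matches_hand_enumerated_folds():
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    y = np.array([0, 0, 1, 1])
    expected = []
    for i in range(4):
        mask = np.ones(4, bool)
        mask[i] = False
        fold = im.fit_lda(X[mask], y[mask])
        expected.append(fold.predict(X[i:i + 1])[0])
    cm = im.loocv(X, y)
    assert expected == [0, 0, 1, 1]
    assert cm.counts.tolist() == [[2, 0], [0, 2]]


def test_loocv_separable_synthetic_accuracy_high():
    """Delta = 4 pooled SD, n = 20/20: LOOCV accuracy >= 0.95 over seeds."""
    accs = []
    for s in range(50):
        X, y = im.two_group_design(20, 3, informative=(0,), delta=4.0,
                                   correlated_with=None, seed=s)
        cm = im.loocv(X, y)
        accs.append((cm.tp + cm.tn) / cm.total)
    assert min(accs) >= 0.85 and np.mean(accs) >= 0.95


def test_loocv_permuted_labels_near_chance(rng):
    accs = []
    for _ in range(200):
        X = rng.standard_normal((30, 3))
        y = np.repeat([0, 1], 15)
        rng.shuffle(y)
        cm = im.loocv(X, y)
        accs.append((cm.tp + cm.tn) / cm.total)
    assert abs(np.mean(accs) - 0.5) <= 0.025


def test_loocv_errors_when_fold_empties_a_class(rng):
    X = rng.standard_normal((6, 2))
    y = np.array([0, 1, 1, 1, 1, 1])
    with pytest.raises(ValueError, match="class"):
        im.loocv(X, y)


def test_fast_diagonal_loocv_equals_generic(rng):
    for _ in range(10):
        n0, n1 = rng.integers(4, 20, 2)
        p = int(rng.integers(1, 6))
        X = rng.standard_normal((n0 + n1, p))
        y = np.repeat([0, 1], [n0, n1])
        X[y == 1] += rng.normal(0, 1, p)
        cm = im.loocv(X, y, LinearDiscriminant("diagonal", "equal"))
        assert loocv_accuracy_diagonal(X, y) == pytest.approx(
            (cm.tp + cm.tn) / cm.total, abs=1e-12)


# -- metrics -------------------------------------------------------------

def test_metric_arithmetic_on_published_count_rows():
    row = next(r for r in REFERENCE_ROWS if r.contrast == "mHC vs fHC at T0")
    m = im.evaluate_metrics(row.confusion_matrix()).as_dict(rounded=True)
    assert m == {"accuracy": 0.87, "sensitivity": 0.78, "specificity": 0.90,
                 "ppv": 0.78, "npv": 0.90}
    row = next(r for r in REFERENCE_ROWS
               if r.contrast == "GWI vs HC males at T0-T2")
    m = im.evaluate_metrics(row.confusion_matrix()).as_dict(rounded=True)
    assert m == {"accuracy": 0.83, "sensitivity": 0.85, "specificity": 0.81,
                 "ppv": 0.81, "npv": 0.85}


def test_perfect_classifier_metrics_all_one():
    cm = im.ConfusionMatrix([[10, 0], [0, 10]])
    assert all(v == 1.0 for v in im.evaluate_metrics(cm).as_dict().values())


def test_class_swap_exchanges_sensitivity_specificity():
    cm = im.ConfusionMatrix([[17, 4], [3, 17]])
    m = im.evaluate_metrics(cm)
    ms = im.evaluate_metrics(cm.swapped())
    assert ms.sensitivity == m.specificity
    assert ms.specificity == m.sensitivity
    assert ms.ppv == m.npv and ms.npv == m.ppv
    assert ms.accuracy == m.accuracy


def test_undefined_metrics_flagged_not_raised():
    cm = im.ConfusionMatrix([[5, 0], [0, 0]])  # no true/assigned positives
    m = im.evaluate_metrics(cm)
    assert np.isnan(m.sensitivity) and np.isnan(m.ppv)
    assert {"sensitivity", "ppv"} <= set(m.undefined)
    assert m.accuracy == 1.0


def test_rounding_is_half_up():
    assert im.round_half_up(0.8667) == 0.87
    assert im.round_half_up(0.865) == 0.87   # ties away from zero
    assert im.round_half_up(0.864999) == 0.86
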