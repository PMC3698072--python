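"""Stepwise partial-F selection and random-subset ensemble ranking."""

import itertools

import numpy as np
import pytest
from scipy import stats

import immunosig as im
from immunosig.discriminant import loocv_accuracy_diagonal


# -- partial F -----------------------------------------------------------

def test_partial_f_empty_model_equals_squared_pooled_t(rng):
    worst = 0.0
    for _ in range(1000):
        n = int(rng.integers(8, 40))
        x = rng.standard_normal(n)
        y = np.repeat([0, 1], [n // 2, n - n // 2])
        f, pf = im.partial_f(x[:, None], y, [], 0)
        t, pt = stats.ttest_ind(x[y == 1], x[y == 0], equal_var=True)
        worst = max(worst, abs(f - t ** 2), abs(pf - pt))
    assert worst < 1e-10


def test_partial_f_matches_explicit_normal_equations(rng):
    X = rng.standard_normal((25, 3))
    y = np.repeat([0, 1], [12, 13])
    X[y == 1, 0] += 1.5
    g = np.where(y == 1, 1.0, -1.0)

    def rss(cols):
        Z = np.hstack([np.ones((25, 1)), X[:, cols]]) if cols else \
            np.ones((25, 1))
        beta = np.linalg.solve(Z.T @ Z, Z.T @ g)
        r = g - Z @ beta
        return r @ r

    for selected, cand in [([], 0), ([0], 1), ([0, 1], 2)]:
        f, p = im.partial_f(X, y, selected, cand)
        dfd = 25 - len(selected) - 2
        f_oracle = (rss(selected) - rss(selected + [cand])) / \
            (rss(selected + [cand]) / dfd)
        assert f == pytest.approx(f_oracle, rel=1e-10)
        assert p == pytest.approx(stats.f.sf(f_oracle, 1, dfd), rel=1e-10)


def test_partial_f_rank_deficient_candidate_is_ineligible(rng):
    X = rng.standard_normal((20, 2))
    X = np.hstack([X, X[:, :1]])  # col 2 duplicates col 0
    y = np.repeat([0, 1], 10)
    f, p = im.partial_f(X, y, [0], 2)
    assert f == 0.0 and p == 1.0


def test_partial_f_orthogonal_candidate_near_null(rng):
    n = 40
    y = np.repeat([0, 1], 20)
    g = np.where(y == 1, 1.0, -1.0)
    x0 = g + rng.normal(0, 0.5, n)
    # candidate orthogonal to the residual of g on [1, x0]
    Z = np.hstack([np.ones((n, 1)), x0[:, None]])
    resid = g - Z @ np.linalg.lstsq(Z, g, rcond=None)[0]
    cand = rng.standard_normal(n)
    cand -= Z @ np.linalg.lstsq(Z, cand, rcond=None)[0]
    cand -= resid * (cand @ resid) / (resid @ resid)
    f, p = im.partial_f(np.column_stack([x0, cand]), y, [0], 1)
    assert f == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0, abs=1e-6)


# -- stepwise ------------------------------------------------------------

def test_stepwise_constant_features_yield_no_model():
    X = np.ones((12, 4))
    y = np.repeat([0, 1], 6)
    trace = im.stepwise(X, y)
    assert trace.no_model and trace.events == []


def test_stepwise_null_data_rarely_builds_models(rng):
    no_model = 0
    for s in range(50):
        r = np.random.default_rng(s)
        X = r.standard_normal((24, 5))
        y = np.repeat([0, 1], 12)
        no_model += im.stepwise(X, y).no_model
    # 5 null candidates at p_enter 0.05: most runs select nothing
    assert no_model >= 30


def test_stepwise_enters_planted_feature_first_and_truncates_copy():
    a_first = 0
    b_absent = 0
    for s in range(100):
        X, y = im.two_group_design(20, 3, informative=(0,), delta=3.0,
                                   correlated_with={1: 0}, seed=s)
        trace = im.stepwise(X, y)
        a_first += bool(trace.events and trace.events[0].feature == 0)
        b_absent += 1 not in trace.selected
    assert a_first >= 95
    assert b_absent >= 90  # null entry of the copy happens at ~ the 5% rate


def test_stepwise_trace_replay_reconstructs_final_set():
    X, y = im.two_group_design(20, 6, informative=(0, 2), delta=2.0, seed=7)
    trace = im.stepwise(X, y)
    assert trace.replay() == trace.selected


def test_stepwise_never_cycles_on_adversarial_correlated_design(rng):
    # strongly cross-correlated informative block
    base = rng.standard_normal((40, 1))
    X = np.hstack([base + 0.3 * rng.standard_normal((40, 1))
                   for _ in range(6)])
    y = np.repeat([0, 1], 20)
    X[y == 1] += 1.5
    sel = im.StepwiseSelector(max_steps=50).fit(X, y)
    enters = sum(e.action == "enter" for e in sel.trace_.events)
    assert enters <= 50
    assert sel.trace_.replay() == sel.selected_


def test_stepwise_threshold_ordering_enforced():
    with pytest.raises(ValueError, match="p_enter <= p_remove"):
        im.StepwiseSelector(p_enter=0.2, p_remove=0.1).fit(
            np.zeros((8, 2)), np.repeat([0, 1], 4))


# -- ensemble ------------------------------------------------------------

def test_ensemble_zero_iterations_and_unreachable_threshold():
    X, y = im.two_group_design(10, 6, informative=(0,), delta=3.0, seed=0)
    r = im.EnsembleRanker(n_iterations=0, subset_size=3).fit(X, y)
    assert r.n_passing_ == 0 and not r.counts_.any()
    with pytest.warns(UserWarning, match="no model"):
        r2 = im.EnsembleRanker(50, 3, accuracy_threshold=1.5,
                               random_state=0).fit(X, y)
    assert r2.n_passing_ == 0 and not r2.frequencies_.any()


def test_ensemble_reproducible_and_stable_across_seeds():
    X, y = im.two_group_design(20, 10, informative=(0, 1), delta=2.5, seed=3)
    r1 = im.EnsembleRanker(500, 5, random_state=11).fit(X, y)
    r2 = im.EnsembleRanker(500, 5, random_state=11).fit(X, y)
    assert r1.ranking_ == r2.ranking_
    assert np.array_equal(r1.counts_, r2.counts_)
    # across seeds the uninformative features' counts are exchangeable, so
    # rank correlation of raw counts is diluted; the stable quantities are
    # the overall count profile and the identity of the top features
    for seed in (12, 13, 14):
        r3 = im.EnsembleRanker(500, 5, random_state=seed).fit(X, y)
        assert set(r3.ranking_[:2]) == set(r1.ranking_[:2]) == {0, 1}
        assert np.corrcoef(r1.counts_, r3.counts_)[0, 1] > 0.75


def test_ensemble_exhaustive_matches_enumeration_oracle():
    X, y = im.two_group_design(20, 8, informative=(0, 1), delta=2.5, seed=5)
    counts = np.zeros(8, dtype=int)
    n_pass = 0
    for sub in itertools.combinations(range(8), 5):
        if loocv_accuracy_diagonal(X[:, list(sub)], y) >= 0.80:
            counts[list(sub)] += 1
            n_pass += 1
    r = im.EnsembleRanker(subset_size=5, mode="exhaustive").fit(X, y)
    assert np.array_equal(r.counts_, counts)
    assert r.n_passing_ == n_pass


def test_ensemble_places_planted_features_on_top():
    hits = 0
    for s in range(20):
        X, y = im.two_group_design(20, 10, informative=(0, 1), delta=2.5,
                                   seed=1000 + s)
        r = im.EnsembleRanker(500, 5, 0.80, random_state=s).fit(X, y)
        hits += set(r.ranking_[:2]) == {0, 1}
    assert hits >= 19


def test_ensemble_permuted_labels_rarely_pass(rng):
    passing_frac = []
    for _ in range(50):
        X = rng.standard_normal((30, 10))
        y = np.repeat([0, 1], 15)
        rng.shuffle(y)
        r = im.EnsembleRanker(20, 5, 0.80, random_state=1).fit(X, y)
        passing_frac.append(r.n_passing_ / 20)
    assert np.mean(passing_frac) < 0.05


# -- final model ---------------------------------------------------------

def test_build_final_model_consistency_and_guards():
    X, y = im.two_group_design(20, 6, informative=(0, 1), delta=2.5, seed=2)
    r = im.EnsembleRanker(200, 3, random_state=4).fit(X, y)
    model, idx, cm, metrics = im.build_final_model(X, y, r.ranking_, 2)
    assert idx == r.ranking_[:2]
    assert 0 <= metrics.accuracy <= 1
    # top_k = all features equals a direct diagonal fit on everything
    model_all, idx_all, _, _ = im.build_final_model(X, y, list(range(6)), 6)
    direct = im.fit_lda(X, y, covariance_mode="diagonal")
    assert np.allclose(model_all.coef_, direct.coef_)
    with pytest.raises(ValueError, match="top_k"):
        im.build_final_model(X, y, r.ranking_, 0)


def test_final_model_beats_median_random_pair():
    X, y = im.two_group_design(20, 10, informative=(0, 1), delta=2.5, seed=9)
    r = im.EnsembleRanker(500, 5, random_state=9).fit(X, y)
    _, _, cm, metrics = im.build_final_model(X, y, r.ranking_, 2)
    rng = np.random.default_rng(9)
    rand_accs = []
    for _ in range(100):
        pair = rng.choice(10, 2, replace=False)
        rand_accs.append(loocv_accuracy_diagonal(X[:, pair], y))
    assert metrics.accuracy > np.median(rand_accs)
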