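"""Marker-subset selection for discriminant models.

Two complementary strategies, mirroring the study workflow:

* **Stepwise partial-F selection** — features enter a regression of a +/-1
  group indicator one at a time when their partial-F null probability drops
  below ``p_enter`` (0.05) and leave when it rises above ``p_remove``
  (0.10).  Because the partial F conditions on the markers already in the
  model, the procedure favours minimally redundant subsets, truncating
  correlated cytokines.

* **Random-subset ensemble ranking** — the opposite relaxation: random
  draws of ``subset_size`` (5) features from all candidates (48) are each
  evaluated as a diagonal-covariance discriminant by LOOCV accuracy, over
  ``n_iterations`` (500) draws; features are ranked by how often they
  appear in models reaching ``accuracy_threshold`` (0.80).  Correlated
  markers can be selected together because the diagonal covariance
  suppresses the variance inflation they would otherwise cause.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .discriminant import (ConfusionMatrix, LinearDiscriminant,
                           evaluate_metrics, loocv, loocv_accuracy_diagonal)


def _rss(Z: np.ndarray, g: np.ndarray) -> float:
    resid = g - Z @ np.linalg.lstsq(Z, g, rcond=None)[0]
    return float(resid @ resid)


def partial_f(X, y, selected, candidate: int) -> tuple[float, float]:
    """Partial-F statistic for adding ``candidate`` to ``selected``.

    Uses the classical stepwise-discriminant equivalence: ordinary least
    squares of a +/-1 group indicator g on the selected columns, with

        F = (RSS_reduced - RSS_full) / (RSS_full / (n - s - 2)),

    where s = len(selected), and p from F(1, n - s - 2).  A candidate that
    adds no rank (or no residual reduction) reports (0, 1) and is
    ineligible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    selected = list(selected)
    if candidate in selected:
        raise ValueError("candidate already in the selected set")
    n = len(y)
    s = len(selected)
    dfd = n - s - 2
    if dfd < 1:
        raise ValueError("too few observations for the requested model size")
    g = np.where(y == np.unique(y)[1], 1.0, -1.0)
    ones = np.ones((n, 1))
    Z_red = np.hstack([ones, X[:, selected]]) if selected else ones
    Z_full = np.hstack([Z_red, X[:, [candidate]]])
    if np.linalg.matrix_rank(Z_full) <= np.linalg.matrix_rank(Z_red):
        return 0.0, 1.0
    rss_red = _rss(Z_red, g)
    rss_full = _rss(Z_full, g)
    if rss_full <= 0:
        # perfect fit: infinite evidence for the candidate
        return float("inf"), 0.0
    f = max(0.0, (rss_red - rss_full) / (rss_full / dfd))
    return f, float(stats.f.sf(f, 1, dfd))


def _removal_f(X, y, model: list[int], member: int) -> tuple[float, float]:
    """Partial F of a feature currently in the model (reduced = model \\ member)."""
    others = [j for j in model if j != member]
    return partial_f(X, y, others, member)


@dataclass
class StepEvent:
    step: int
    action: str  # "enter" | "remove"
    feature: int
    F: float
    p: float


@dataclass
class SelectionTrace:
    """Ordered record of stepwise enter/remove events and the final set."""

    events: list[StepEvent] = field(default_factory=list)
    selected: list[int] = field(default_factory=list)

    @property
    def no_model(self) -> bool:
        return not self.selected

    def replay(self) -> list[int]:
        """Re-derive the final set from the event list (consistency check)."""
        current: list[int] = []
        for ev in self.events:
            if ev.action == "enter":
                current.append(ev.feature)
            else:
                current.remove(ev.feature)
        return current


class StepwiseSelector:
    """Stepwise partial-F feature selection (scikit-learn style).

    Parameters
    ----------
    p_enter : float, default 0.05
        A candidate enters when its partial-F p value is < ``p_enter``
        (smallest p first; ties broken by larger F, then feature order).
    p_remove : float, default 0.10
        An included feature is removed when its revised partial-F p value
        is > ``p_remove`` (largest p first).  ``p_enter <= p_remove`` is
        enforced to prevent cycling.
    max_steps : int, default 100
        Hard guard on the number of enter events.

    Attributes (after :meth:`fit`)
    ------------------------------
    trace_ : SelectionTrace
    selected_ : list of column indices, in entry order
    support_ : boolean mask over columns
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10,
                 max_steps: int = 100):
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.max_steps = max_steps

    def get_params(self, deep: bool = True) -> dict:
        return {"p_enter": self.p_enter, "p_remove": self.p_remove,
                "max_steps": self.max_steps}

    def set_params(self, **params) -> "StepwiseSelector":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def clone(self) -> "StepwiseSelector":
        return StepwiseSelector(**self.get_params())

    def fit(self, X, y) -> "StepwiseSelector":
        if not (0 < self.p_enter <= self.p_remove < 1):
            raise ValueError("need 0 < p_enter <= p_remove < 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        if p < 1:
            raise ValueError("need at least one candidate feature")
        trace = SelectionTrace()
        model: list[int] = []
        step = 0
        while step < self.max_steps:
            # entry: smallest p among candidates below p_enter
            best = None
            for j in range(p):
                if j in model:
                    continue
                if n - len(model) - 2 < 1:
                    break
                f, pv = partial_f(X, y, model, j)
                if pv < self.p_enter:
                    key = (pv, -f, j)
                    if best is None or key < best[0]:
                        best = (key, j, f, pv)
            if best is None:
                break
            step += 1
            _, j, f, pv = best
            model.append(j)
            trace.events.append(StepEvent(step, "enter", j, f, pv))
            # removal sweep: largest offending p first, repeat until stable
            while len(model) > 1:
                worst = None
                for m in model:
                    f_m, p_m = _removal_f(X, y, model, m)
                    if p_m > self.p_remove:
                        key = (-p_m, f_m, m)
                        if worst is None or key < worst[0]:
                            worst = (key, m, f_m, p_m)
                if worst is None:
                    break
                _, m, f_m, p_m = worst
                model.remove(m)
                trace.events.append(StepEvent(step, "remove", m, f_m, p_m))
        trace.selected = list(model)
        self.trace_ = trace
        self.selected_ = list(model)
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[model] = True
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "selected_"):
            raise RuntimeError("selector is not fitted")
        return np.asarray(X, dtype=float)[:, self.selected_]

    def fit_transform(self, X, y) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def get_support(self) -> np.ndarray:
        return self.support_


def stepwise(X, y, p_enter: float = 0.05, p_remove: float = 0.10,
             max_steps: int = 100) -> SelectionTrace:
    """Functional wrapper over :class:`StepwiseSelector`; returns the trace."""
    return StepwiseSelector(p_enter, p_remove, max_steps).fit(X, y).trace_


class EnsembleRanker:
    """Random-subset ensemble feature ranking (scikit-learn style).

    Each iteration draws ``subset_size`` features uniformly without
    replacement (duplicate subsets across iterations allowed), fits a
    diagonal-covariance, equal-priors discriminant and scores it by LOOCV
    accuracy; members of models at or above ``accuracy_threshold`` earn a
    count.  Features are ranked by count (ties by feature order).

    With ``mode='exhaustive'`` every size-``subset_size`` subset is
    evaluated exactly once (feasible for <= 20 candidates) — the oracle
    that the randomised mode approximates.

    Attributes (after :meth:`fit`)
    ------------------------------
    counts_ : per-feature counts among passing models
    counts_all_ : per-feature counts among all evaluated models (diagnostic)
    n_passing_ : number of models reaching the threshold
    ranking_ : feature indices sorted by descending count, ties by order
    frequencies_ : counts / n_passing (zeros when nothing passed)
    """

    def __init__(self, n_iterations: int = 500, subset_size: int = 5,
                 accuracy_threshold: float = 0.80, random_state=None,
                 mode: str = "random"):
        self.n_iterations = n_iterations
        self.subset_size = subset_size
        self.accuracy_threshold = accuracy_threshold
        self.random_state = random_state
        self.mode = mode

    def get_params(self, deep: bool = True) -> dict:
        return {"n_iterations": self.n_iterations,
                "subset_size": self.subset_size,
                "accuracy_threshold": self.accuracy_threshold,
                "random_state": self.random_state, "mode": self.mode}

    def set_params(self, **params) -> "EnsembleRanker":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "EnsembleRanker":
        if not (0 < self.accuracy_threshold):
            raise ValueError("accuracy_threshold must be positive")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        if self.subset_size > p:
            raise ValueError("subset_size exceeds the number of candidates")
        counts = np.zeros(p, dtype=int)
        counts_all = np.zeros(p, dtype=int)
        n_passing = 0
        if self.mode == "exhaustive":
            if p > 20:
                raise ValueError("exhaustive mode is limited to <= 20 features")
            subsets = itertools.combinations(range(p), self.subset_size)
        elif self.mode == "random":
            rng = np.random.default_rng(self.random_state)
            subsets = (
                rng.choice(p, size=self.subset_size, replace=False)
                for _ in range(self.n_iterations)
            )
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        for subset in subsets:
            idx = np.asarray(subset, dtype=int)
            counts_all[idx] += 1
            acc = loocv_accuracy_diagonal(X[:, idx], y)
            if acc >= self.accuracy_threshold:
                counts[idx] += 1
                n_passing += 1
        if n_passing == 0 and (self.n_iterations > 0 or self.mode == "exhaustive"):
            warnings.warn("no model reached the accuracy threshold; all "
                          "selection frequencies are zero", UserWarning,
                          stacklevel=2)
        self.counts_ = counts
        self.counts_all_ = counts_all
        self.n_passing_ = n_passing
        self.ranking_ = sorted(range(p), key=lambda j: (-counts[j], j))
        self.frequencies_ = counts / n_passing if n_passing else counts.astype(float)
        self.n_features_in_ = p
        return self


def ensemble_rank(X, y, n_iterations: int = 500, subset_size: int = 5,
                  accuracy_threshold: float = 0.80, random_state=None,
                  mode: str = "random"):
    """Functional wrapper: fit an :class:`EnsembleRanker`, return
    (ranking, counts, n_passing)."""
    r = EnsembleRanker(n_iterations, subset_size, accuracy_threshold,
                       random_state, mode).fit(X, y)
    return r.ranking_, r.counts_, r.n_passing_


def build_final_model(X, y, ranking, top_k: int):
    """Diagonal-covariance discriminant on the ``top_k`` ranked features.

    Returns the fitted model, the feature indices used, the LOOCV confusion
    matrix, and the five performance metrics.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if top_k > len(ranking):
        raise ValueError("top_k exceeds the number of ranked features")
    idx = list(ranking[:top_k])
    Xs = np.asarray(X, dtype=float)[:, idx]
    model = LinearDiscriminant("diagonal", "equal").fit(Xs, y)
    cm = loocv(Xs, y, LinearDiscriminant("diagonal", "equal"))
    return model, idx, cm, evaluate_metrics(cm)
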