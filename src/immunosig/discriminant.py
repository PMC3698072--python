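"""Two-class linear discriminant models with leave-one-out evaluation.

The classifier is Fisher/Gaussian linear discriminant analysis for two
groups I and J.  With pooled within-group covariance S, class means m_I and
m_J and prior probabilities pi_I, pi_J, the discriminant score of a profile
x is

    s(x) = B0 + x . B,      B  = S^-1 (m_J - m_I),
                            B0 = -(m_I + m_J) . B / 2 + log(pi_J / pi_I).

Under this sign convention the subject is assigned to group J when
s(x) >= 0 and to group I when s(x) < 0; an exact zero goes to J, the strict
form of the published decision rule.  Group J is, by convention, the
second-listed (positive) class: female, GWI or CFS in the study contrasts.

Two covariance modes are supported: ``pooled_full`` (classical LDA) and
``diagonal``, which zeroes between-feature covariances to stabilise models
built from correlated markers.  Standardized canonical coefficients rescale
B so that the discriminant score has unit pooled within-group variance and
multiply each entry by its feature's pooled within-group standard
deviation, making coefficient magnitudes comparable across features (a
single-feature model always scores +/-1.00).

Model quality is always reported from leave-one-out cross-validation
(LOOCV): each subject is assigned by a model refitted without that
subject's profile, and the resulting confusion matrix yields accuracy,
sensitivity, specificity, PPV and NPV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero (0.005 -> 0.01)."""
    if x != x:  # NaN
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# confusion matrices and the five performance metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """2x2 cross-validation counts, rows = true group, cols = assigned group.

    Row/column 0 is group I (negative class), row/column 1 is group J (the
    positive class: female, GWI or CFS in the study contrasts).
    """

    counts: np.ndarray
    labels: tuple[str, str] = ("I", "J")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2) or np.any(self.counts < 0):
            raise ValueError("counts must be a nonnegative 2x2 matrix")

    @property
    def positive_class(self) -> str:
        return self.labels[1]

    @property
    def tn(self) -> int:
        return int(self.counts[0, 0])

    @property
    def fp(self) -> int:
        return int(self.counts[0, 1])

    @property
    def fn(self) -> int:
        return int(self.counts[1, 0])

    @property
    def tp(self) -> int:
        return int(self.counts[1, 1])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def swapped(self) -> "ConfusionMatrix":
        """The same tallies with the class roles exchanged."""
        return ConfusionMatrix(self.counts[::-1, ::-1], self.labels[::-1])


@dataclass
class PerformanceMetrics:
    """Accuracy, sensitivity, specificity, PPV and NPV of a 2x2 table.

    A metric whose denominator is zero is NaN and listed in ``undefined``.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: tuple[str, ...] = ()

    _FIELDS = ("accuracy", "sensitivity", "specificity", "ppv", "npv")

    def as_dict(self, rounded: bool = False) -> dict[str, float]:
        vals = {f: getattr(self, f) for f in self._FIELDS}
        if rounded:
            vals = {f: round_half_up(v, 2) for f, v in vals.items()}
        return vals

    def rounded(self) -> "PerformanceMetrics":
        """Metrics half-up rounded to 2 decimals, for table comparison."""
        return PerformanceMetrics(**self.as_dict(rounded=True),
                                  undefined=self.undefined)


def evaluate_metrics(cm: ConfusionMatrix) -> PerformanceMetrics:
    """The five published rates from a confusion matrix.

    accuracy    = (TP + TN) / N
    sensitivity = TP / (TP + FN)      (true positives recovered)
    specificity = TN / (TN + FP)      (true negatives recovered)
    PPV         = TP / (TP + FP)      (assigned-positive correctness)
    NPV         = TN / (TN + FN)      (assigned-negative correctness)
    """
    def ratio(num: int, den: int, name: str, undef: list) -> float:
        if den == 0:
            undef.append(name)
            return float("nan")
        return num / den

    undef: list[str] = []
    metrics = PerformanceMetrics(
        accuracy=ratio(cm.tp + cm.tn, cm.total, "accuracy", undef),
        sensitivity=ratio(cm.tp, cm.tp + cm.fn, "sensitivity", undef),
        specificity=ratio(cm.tn, cm.tn + cm.fp, "specificity", undef),
        ppv=ratio(cm.tp, cm.tp + cm.fp, "ppv", undef),
        npv=ratio(cm.tn, cm.tn + cm.fn, "npv", undef),
    )
    metrics.undefined = tuple(undef)
    return metrics


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------

class LinearDiscriminant:
    """Two-class linear discriminant classifier (scikit-learn style).

    Parameters
    ----------
    covariance_mode : {"pooled_full", "diagonal"}, default "pooled_full"
        ``pooled_full`` uses the pooled within-group covariance matrix;
        ``diagonal`` keeps only its diagonal, the stabilising correction
        used when markers are strongly co-expressed.
    priors : {"equal", "proportional"}, default "equal"
        Class prior probabilities: equal, or proportional to training
        group sizes.
    ridge : float, default 0.0
        Relative ridge added to a singular pooled covariance as
        ``ridge * trace(S)/p * I``.  With the default 0, a singular pooled
        matrix raises instead, with instructions to use diagonal mode or a
        positive ridge.

    Attributes (after :meth:`fit`)
    ------------------------------
    classes_ : (2,) array of class labels, second entry = group J
    means_ : (2, p) class means
    covariance_ : (p, p) pooled within-group covariance (diagonal zeroed
        off-diagonal in diagonal mode)
    coef_ : (p,) coefficient vector B
    intercept_ : float B0
    standardized_coef_ : (p,) standardized canonical coefficients
    """

    def __init__(self, covariance_mode: str = "pooled_full",
                 priors: str = "equal", ridge: float = 0.0):
        self.covariance_mode = covariance_mode
        self.priors = priors
        self.ridge = ridge

    # sklearn plumbing ----------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"covariance_mode": self.covariance_mode,
                "priors": self.priors, "ridge": self.ridge}

    def set_params(self, **params) -> "LinearDiscriminant":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def clone(self) -> "LinearDiscriminant":
        return LinearDiscriminant(**self.get_params())

    # ---------------------------------------------------------------------
    def fit(self, X, y) -> "LinearDiscriminant":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute first")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly 2 classes, got {classes.size}")
        n0 = int(np.sum(y == classes[0]))
        n1 = int(np.sum(y == classes[1]))
        if min(n0, n1) < 1 or n0 + n1 < 3:
            # a singleton class is tolerated (its scatter contribution is 0);
            # the pooled denominator n - 2 still needs at least one df
            raise ValueError("need both classes present and N >= 3")
        X0 = X[y == classes[0]]
        X1 = X[y == classes[1]]
        m0 = X0.mean(axis=0)
        m1 = X1.mean(axis=0)
        n, p = X.shape
        ss = (X0 - m0).T @ (X0 - m0) + (X1 - m1).T @ (X1 - m1)
        S = ss / (n - 2)
        if self.covariance_mode == "diagonal":
            S = np.diag(np.diag(S))
            if np.any(np.diag(S) <= 0):
                cols = list(np.nonzero(np.diag(S) <= 0)[0])
                raise ValueError(f"zero-variance feature column(s): {cols}")
        elif self.covariance_mode == "pooled_full":
            pass
        else:
            raise ValueError(f"unknown covariance_mode {self.covariance_mode!r}")

        if self.ridge:
            S = S + (self.ridge * np.trace(S) / p) * np.eye(p)

        diff = m1 - m0
        try:
            cond_bad = (np.linalg.cond(S) > 1 / np.finfo(float).eps)
        except np.linalg.LinAlgError:  # pragma: no cover
            cond_bad = True
        if self.covariance_mode == "pooled_full" and cond_bad:
            raise np.linalg.LinAlgError(
                "pooled covariance is singular; use covariance_mode='diagonal' "
                "or a positive ridge"
            )
        coef = np.linalg.solve(S, diff)

        if self.priors == "equal":
            log_ratio = 0.0
            prior = np.array([0.5, 0.5])
        elif self.priors == "proportional":
            prior = np.array([n0, n1]) / n
            log_ratio = float(np.log(prior[1] / prior[0]))
        else:
            raise ValueError(f"unknown priors {self.priors!r}")

        self.classes_ = classes
        self.priors_ = prior
        self.means_ = np.vstack([m0, m1])
        self.covariance_ = S
        self.coef_ = coef
        self.intercept_ = float(-0.5 * (m0 + m1) @ coef + log_ratio)
        self.n_features_in_ = p

        # standardized canonical coefficients: scale B to unit pooled
        # within-group score variance, then multiply by feature SDs
        score_var = float(coef @ S @ coef)
        canon = coef / np.sqrt(score_var) if score_var > 0 else coef
        self.standardized_coef_ = canon * np.sqrt(np.diag(S))
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def predict(self, X) -> np.ndarray:
        """Assign group J (``classes_[1]``) when the score is >= 0.

        The boundary case scores exactly 0: the strict published rule
        places it in group J.
        """
        s = self.decision_function(np.atleast_2d(np.asarray(X, dtype=float)))
        return np.where(s >= 0, self.classes_[1], self.classes_[0])

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def fit_lda(X, y, covariance_mode: str = "pooled_full",
            priors: str = "equal", ridge: float = 0.0) -> LinearDiscriminant:
    """Functional wrapper: fit a :class:`LinearDiscriminant`."""
    return LinearDiscriminant(covariance_mode, priors, ridge).fit(X, y)


def standardized_coefficients(model: LinearDiscriminant) -> np.ndarray:
    """Standardized canonical coefficients of a fitted model."""
    return model.standardized_coef_


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

def loocv(X, y, estimator: LinearDiscriminant | None = None,
          labels: tuple[str, str] = ("I", "J")) -> ConfusionMatrix:
    """Leave-one-out cross-validation of a linear discriminant.

    Every subject is assigned by a model refitted on the remaining N - 1
    profiles; assignments are tallied into a 2x2 confusion matrix with the
    second class (group J) as the positive class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 4:
        raise ValueError("LOOCV needs N >= 4")
    est = estimator if estimator is not None else LinearDiscriminant()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly 2 classes")
    counts = np.zeros((2, 2), dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        yi = y[mask]
        if np.unique(yi).size < 2:
            raise ValueError(f"fold {i} leaves a class empty")
        fold = est.clone().fit(X[mask], yi)
        pred = fold.predict(X[i:i + 1])[0]
        counts[int(np.nonzero(classes == y[i])[0][0]),
               int(np.nonzero(classes == pred)[0][0])] += 1
        mask[i] = True
    return ConfusionMatrix(counts, labels)


def loocv_accuracy_diagonal(X, y) -> float:
    """Fast LOOCV accuracy for the diagonal-covariance, equal-priors model.

    Algebraically identical to :func:`loocv` with
    ``LinearDiscriminant('diagonal', 'equal')`` but vectorised over folds
    via leave-one-out mean/variance updates, for use inside the
    random-subset ensemble where thousands of LOOCV runs are needed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    n, p = X.shape
    is1 = (y == classes[1])
    n0 = int(np.sum(~is1))
    n1 = int(np.sum(is1))
    if min(n0, n1) < 2 or n < 4:
        # a fold would leave a class empty; mirror loocv's error
        raise ValueError("each class needs n >= 2 for diagonal LOOCV")
    X0, X1 = X[~is1], X[is1]
    s0, s1 = X0.sum(axis=0), X1.sum(axis=0)
    q0, q1 = (X0 ** 2).sum(axis=0), (X1 ** 2).sum(axis=0)
    m0_full, m1_full = s0 / n0, s1 / n1
    ss0_full = q0 - n0 * m0_full ** 2
    ss1_full = q1 - n1 * m1_full ** 2

    correct = 0
    # class-0 held-out folds, vectorised
    for (held, s_c, q_c, n_c, m_o, ss_o, own_is_1) in (
        (X0, s0, q0, n0, m1_full, ss1_full, False),
        (X1, s1, q1, n1, m0_full, ss0_full, True),
    ):
        nc = n_c - 1
        m_c = (s_c[None, :] - held) / nc            # (n_c, p) updated own mean
        ss_c = (q_c[None, :] - held ** 2) - nc * m_c ** 2
        var = (ss_c + ss_o[None, :]) / (n - 3)       # pooled diag, n' - 2
        if own_is_1:
            diff = m_c - m_o[None, :]
            mid = 0.5 * (m_c + m_o[None, :])
        else:
            diff = m_o[None, :] - m_c
            mid = 0.5 * (m_c + m_o[None, :])
        coef = diff / var
        score = np.sum((held - mid) * coef, axis=1)
        assigned_1 = score >= 0
        correct += int(np.sum(assigned_1 == own_is_1))
    return correct / n
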