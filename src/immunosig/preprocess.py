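"""Preprocessing chain for cytokine concentration matrices.

The study workflow prepares concentrations for regression in three steps:
missing assay values are imputed with a small non-zero constant (0.0001
pg/mL) so every profile can be used, concentrations are log2 transformed,
and each feature is standardized to mean 0 and variance 1.

`CytokinePreprocessor` packages the chain as a scikit-learn style
transformer so it can be fitted on training folds only (leakage-free mode)
or once on the full cohort (the one-shot behaviour of the original
workflow).
"""

from __future__ import annotations

import numpy as np


def impute_missing(X, impute_value: float = 1e-4, mask=None) -> np.ndarray:
    """Replace missing cells by ``impute_value``; all other cells unchanged.

    Missing cells are NaN in ``X``, or the True cells of ``mask`` when one
    is supplied (the mask wins, so provenance masks survive earlier fills).
    """
    if impute_value <= 0:
        raise ValueError("impute_value must be > 0 (log2 follows)")
    X = np.array(X, dtype=float, copy=True)
    where = np.isnan(X) if mask is None else np.asarray(mask, dtype=bool)
    X[where] = impute_value
    return X


def log2_transform(X) -> np.ndarray:
    """Elementwise log base 2; every entry must be strictly positive."""
    X = np.asarray(X, dtype=float)
    bad = ~(X > 0)
    if np.any(bad):
        idx = tuple(int(i[0]) for i in np.nonzero(bad))
        raise ValueError(
            f"nonpositive or missing entry at cell {idx}: impute before log2"
        )
    return np.log2(X)


def zscore(X, ddof: int = 1) -> np.ndarray:
    """Standardize each column to mean 0, variance 1.

    Uses the sample (n-1) standard deviation by default; this is the
    documented convention throughout the package (``ddof=0`` gives the
    population variant).
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=ddof)
    zero = np.isclose(sd, 0.0)
    if np.any(zero):
        cols = list(np.nonzero(zero)[0])
        raise ValueError(f"zero-variance feature column(s): {cols}")
    return (X - X.mean(axis=0)) / sd


class CytokinePreprocessor:
    """Impute -> log2 -> per-feature z-score, as a fit/transform estimator.

    Parameters
    ----------
    impute_value : float, default 0.0001
        Constant replacing missing cells (pg/mL when imputing before log2).
    impute_stage : {"before_log", "after_log"}, default "before_log"
        Whether the constant replaces concentrations (then passes through
        log2) or is inserted directly into the log2 matrix.
    standardize : bool, default True
        Apply the z-score step using statistics learned in :meth:`fit`.
    ddof : int, default 1
        Degrees-of-freedom correction of the standard deviation.
    """

    def __init__(self, impute_value: float = 1e-4,
                 impute_stage: str = "before_log",
                 standardize: bool = True, ddof: int = 1):
        self.impute_value = impute_value
        self.impute_stage = impute_stage
        self.standardize = standardize
        self.ddof = ddof

    # sklearn plumbing ----------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "impute_value": self.impute_value,
            "impute_stage": self.impute_stage,
            "standardize": self.standardize,
            "ddof": self.ddof,
        }

    def set_params(self, **params) -> "CytokinePreprocessor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ---------------------------------------------------------------------
    def _logged(self, X) -> np.ndarray:
        if self.impute_stage not in ("before_log", "after_log"):
            raise ValueError(f"unknown impute_stage {self.impute_stage!r}")
        if self.impute_stage == "before_log":
            return log2_transform(impute_missing(X, self.impute_value))
        X = np.array(X, dtype=float, copy=True)
        miss = np.isnan(X)
        X[miss] = 1.0  # placeholder; overwritten below
        L = log2_transform(X)
        L[miss] = self.impute_value
        return L

    def fit(self, X, y=None) -> "CytokinePreprocessor":
        L = self._logged(X)
        self.mean_ = L.mean(axis=0)
        sd = L.std(axis=0, ddof=self.ddof)
        if self.standardize and np.any(np.isclose(sd, 0.0)):
            cols = list(np.nonzero(np.isclose(sd, 0.0))[0])
            raise ValueError(f"zero-variance feature column(s): {cols}")
        self.scale_ = sd
        self.n_features_in_ = L.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "mean_"):
            raise RuntimeError("preprocessor is not fitted")
        L = self._logged(X)
        if not self.standardize:
            return L
        return (L - self.mean_) / self.scale_

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
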