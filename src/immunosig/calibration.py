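"""Standard-curve calibration for multiplex chemiluminescent immunoassays.

Each cytokine on the plate carries its own standard curve: known standard
concentrations are assayed, and a polynomial regression of concentration on
powers of the measured signal,

    Y_p = b0 + b1*X + b2*X**2 + ... + bk*X**k,

is fitted by least squares (degree k = 2 in the study workflow).  The fitted
curve maps raw signal to predicted concentration Y_p in pg/mL.  Assay
repeatability is summarised by the coefficient of variability (CV) of
replicate measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class StandardCurve:
    """Fitted per-cytokine polynomial calibration curve.

    Attributes
    ----------
    cytokine : str
        Analyte name.
    degree : int
        Polynomial degree k (study value 2).
    coefficients : ndarray, shape (degree + 1,)
        b0..bk in ascending powers of the signal.
    fit_range : (float, float)
        Min and max signal among the standards; predictions outside are
        flagged as extrapolated.
    residuals : ndarray
        Signed residuals (observed - fitted) at the standards.
    monotone : bool
        True when the fitted derivative is positive across ``fit_range``;
        a non-monotone curve is usable but flagged at fit time.
    """

    cytokine: str
    degree: int
    coefficients: np.ndarray
    fit_range: tuple[float, float]
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    monotone: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != self.degree + 1:
            raise ValueError("need degree + 1 coefficients")

    def predict(self, signal, return_flags: bool = False):
        """Predicted concentration Y_p = sum_j b_j * signal**j.

        Negative predictions are clipped to 0; with ``return_flags`` the
        clipped cells and signals outside ``fit_range`` are reported.
        """
        s = np.asarray(signal, dtype=float)
        raw = np.polynomial.polynomial.polyval(s, self.coefficients)
        clipped = raw < 0
        out = np.where(clipped, 0.0, raw)
        if return_flags:
            lo, hi = self.fit_range
            extrapolated = (s < lo) | (s > hi)
            return out, clipped, extrapolated
        return out


def fit_standard_curve(signals, concentrations, degree: int = 2,
                       cytokine: str = "") -> StandardCurve:
    """Least-squares polynomial calibration of concentration on signal.

    Parameters
    ----------
    signals, concentrations : array-like
        Matched (signal, known concentration) standards.
    degree : int
        Polynomial degree k >= 1; requires at least ``degree + 1`` distinct
        signal values.
    """
    x = np.asarray(signals, dtype=float)
    y = np.asarray(concentrations, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("signals and concentrations must be matched 1-D arrays")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    n_distinct = len(np.unique(x))
    if n_distinct == 1:
        raise ValueError("all standard signals identical: singular design")
    if n_distinct < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct signals for degree {degree}, "
            f"got {n_distinct}"
        )
    coef = np.polynomial.polynomial.polyfit(x, y, degree)
    fitted = np.polynomial.polynomial.polyval(x, coef)
    lo, hi = float(x.min()), float(x.max())
    grid = np.linspace(lo, hi, 201)
    deriv = np.polynomial.polynomial.polyval(
        grid, np.polynomial.polynomial.polyder(coef)
    )
    monotone = bool(np.all(deriv > 0))
    if not monotone:
        warnings.warn(
            f"calibration curve {cytokine or '<unnamed>'}: fitted polynomial is "
            "not monotone increasing over the standard range",
            UserWarning,
            stacklevel=2,
        )
    return StandardCurve(
        cytokine=cytokine,
        degree=degree,
        coefficients=coef,
        fit_range=(lo, hi),
        residuals=y - fitted,
        monotone=monotone,
    )


def predict_concentration(curve: StandardCurve, signal, return_flags: bool = False):
    """Functional wrapper over :meth:`StandardCurve.predict`."""
    return curve.predict(signal, return_flags=return_flags)


def apply_detection_limits(values, lower=None, upper=None):
    """Censor concentrations outside per-cytokine detection limits.

    Values below ``lower`` or above ``upper`` become NaN (missing), to be
    handled by the imputation stage.  Limits default to none, since they are
    assay-specific configuration.
    """
    v = np.asarray(values, dtype=float).copy()
    if lower is not None:
        v[v < lower] = np.nan
    if upper is not None:
        v[v > upper] = np.nan
    return v


def assay_cv(replicate_sets) -> tuple[list[float], float]:
    """Coefficient of variability per replicate set, and their mean.

    CV = sample standard deviation (n-1 denominator) / mean.  Each set needs
    at least two values and a positive mean.

    Returns
    -------
    (per_set_cvs, mean_cv)
    """
    cvs = []
    for i, reps in enumerate(replicate_sets):
        r = np.asarray(reps, dtype=float)
        if r.size < 2:
            raise ValueError(f"replicate set {i} has fewer than 2 values")
        m = r.mean()
        if m <= 0:
            raise ValueError(f"replicate set {i} has nonpositive mean {m}")
        cvs.append(float(r.std(ddof=1) / m))
    if not cvs:
        raise ValueError("no replicate sets given")
    return cvs, float(np.mean(cvs))
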