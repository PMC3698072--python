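"""Synthetic exercise-challenge cytokine cohorts.

Real plasma cytokine panels from the sex-stratified GWI/CFS exercise study
are not publicly deposited, so every pipeline stage is exercised against
simulated cohorts with the statistical structure the analysis assumes:
six strata (2 sexes x {HC, GWI, CFS}) of realistic sizes, 48 features (16
cytokines x 3 time points), log-normal concentrations (Gaussian on the
log2 scale), stratum-specific mean shifts, within-stratum feature
correlation — including co-expressed pairs as strong as r = 0.81 — and
missing assay values.

Concentrations for one subject are drawn as

    log2(conc) ~ MVN(baseline + effect[stratum],  D R D),

where D holds per-feature log2-scale SDs and R is a positive-semidefinite
correlation matrix, then exponentiated base 2.  Missingness is completely
at random at ``missing_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import (CYTOKINES, SEXES, TIME_POINTS, CytokinePanel,
                    feature_columns)

STRATA: tuple[tuple[str, str], ...] = (
    ("male", "HC"), ("male", "GWI"), ("male", "CFS"),
    ("female", "HC"), ("female", "GWI"), ("female", "CFS"),
)

#: Study-matching stratum sizes (male HC/GWI/CFS then female HC/GWI/CFS).
STUDY_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("male", "HC"): 21, ("male", "GWI"): 20, ("male", "CFS"): 12,
    ("female", "HC"): 9, ("female", "GWI"): 10, ("female", "CFS"): 10,
}

N_FEATURES = len(CYTOKINES) * len(TIME_POINTS)


def _feature_index(feature: str) -> int:
    cols = feature_columns()
    try:
        return cols.index(feature)
    except ValueError:
        raise KeyError(f"unknown feature {feature!r}") from None


def block_correlation(r_time: float = 0.5, r_cytokine: float = 0.2,
                      pairs=None) -> np.ndarray:
    """Hand-writable 48x48 correlation recipe.

    Separable block structure: the same cytokine at two time points
    correlates at ``r_time``; two cytokines at the same time point at
    ``r_cytokine``; different cytokine and time point at their product
    (a Kronecker structure, PSD by construction).

    ``pairs`` is an optional list of ``(feature_a, feature_b, r)`` strong
    co-expression overrides (e.g. ``("IL-1b_T0", "TNFb_T0", 0.81)``).  Each
    override is applied block-consistently — the full 3x3 cross-time block
    of the two cytokines is set to ``r * R_time`` — which keeps the matrix
    PSD for moderate base correlations; the result is still verified at
    generation time.
    """
    nc, nt = len(CYTOKINES), len(TIME_POINTS)
    Rc = np.full((nc, nc), r_cytokine)
    np.fill_diagonal(Rc, 1.0)
    Rt = np.full((nt, nt), r_time)
    np.fill_diagonal(Rt, 1.0)
    R = np.kron(Rc, Rt)
    for fa, fb, r in (pairs or []):
        ia, ib = _feature_index(fa), _feature_index(fb)
        ca, cb = ia // nt, ib // nt
        if ca == cb:
            raise ValueError("pair overrides must involve two different cytokines")
        block = r * Rt
        R[ca * nt:(ca + 1) * nt, cb * nt:(cb + 1) * nt] = block
        R[cb * nt:(cb + 1) * nt, ca * nt:(ca + 1) * nt] = block.T
    return R


@dataclass
class SyntheticSpec:
    """Ground-truth recipe for one simulated cohort.

    Fields
    ------
    group_sizes : stratum -> n subjects
    baseline : (48,) log2-scale mean concentrations
    sds : (48,) log2-scale standard deviations
    effects : stratum -> (48,) additive log2 shifts (zeros when absent)
    correlation : (48, 48) within-stratum correlation matrix
    missing_rate : probability any cell is missing (MCAR)
    seed : integer random seed; generation is a pure function of the spec
    """

    group_sizes: dict = field(default_factory=lambda: dict(STUDY_GROUP_SIZES))
    baseline: np.ndarray = field(default_factory=lambda: np.full(N_FEATURES, 3.0))
    sds: np.ndarray = field(default_factory=lambda: np.ones(N_FEATURES))
    effects: dict = field(default_factory=dict)
    correlation: np.ndarray = field(default_factory=lambda: np.eye(N_FEATURES))
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        p = self.baseline.size
        if self.sds.shape != (p,) or self.correlation.shape != (p, p):
            raise ValueError("baseline, sds and correlation sizes disagree")
        if np.any(self.sds <= 0):
            raise ValueError("log2-scale SDs must be positive")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(self.correlation).min())
        if eigmin < -1e-10:
            raise ValueError(
                f"correlation matrix is not PSD (smallest eigenvalue {eigmin:.4g})"
            )
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        for stratum, n in self.group_sizes.items():
            if stratum not in STRATA:
                raise ValueError(f"unknown stratum {stratum!r}")
            if n < 0:
                raise ValueError(f"negative group size for {stratum}")
        for stratum, eff in self.effects.items():
            if stratum not in STRATA:
                raise ValueError(f"unknown effect stratum {stratum!r}")
            if np.asarray(eff, dtype=float).shape != (p,):
                raise ValueError(f"effect vector for {stratum} has wrong length")

    @property
    def n_features(self) -> int:
        return self.baseline.size

    def informative_features(self) -> dict:
        """Per-stratum indices of features with a nonzero planted shift."""
        out = {}
        for stratum, eff in self.effects.items():
            idx = list(np.nonzero(np.asarray(eff, dtype=float))[0])
            if idx:
                out[stratum] = idx
        return out


def generate(spec: SyntheticSpec) -> tuple[CytokinePanel, dict]:
    """Draw one cohort from a :class:`SyntheticSpec`.

    Returns the panel and a ground-truth record (planted effects, the
    informative-feature lists, and the seed), so parameter-recovery tests
    can score selection procedures against what was actually planted.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_features
    cols = feature_columns()[:p] if p == N_FEATURES else [
        f"F{j}_T0" for j in range(p)]
    D = np.diag(spec.sds)
    cov = D @ spec.correlation @ D
    # eigh-based factor: tolerant of exactly-semidefinite matrices
    w, V = np.linalg.eigh(cov)
    factor = V * np.sqrt(np.clip(w, 0.0, None))

    frames = []
    meta_rows = []
    for sex, dx in STRATA:
        n = spec.group_sizes.get((sex, dx), 0)
        if n == 0:
            continue
        mean = spec.baseline + np.asarray(
            spec.effects.get((sex, dx), np.zeros(p)), dtype=float)
        z = rng.standard_normal((n, p))
        log2_vals = mean + z @ factor.T
        conc = np.power(2.0, log2_vals)
        if spec.missing_rate > 0:
            miss = rng.random((n, p)) < spec.missing_rate
            conc = np.where(miss, np.nan, conc)
        ids = [f"{sex[0]}{dx}-{i + 1:03d}" for i in range(n)]
        frames.append(pd.DataFrame(conc, index=ids, columns=cols))
        meta_rows.extend({"subject_id": s, "sex": sex, "diagnosis": dx}
                         for s in ids)
    if not frames:
        raise ValueError("spec generates no subjects")
    values = pd.concat(frames)
    values.index.name = "subject_id"
    meta = pd.DataFrame(meta_rows).set_index("subject_id")
    panel = CytokinePanel(values, meta)
    truth = {
        "seed": spec.seed,
        "effects": {f"{s}:{d}": np.asarray(
            spec.effects.get((s, d), np.zeros(p)), dtype=float).tolist()
            for s, d in STRATA},
        "informative": {f"{s}:{d}": idx for (s, d), idx
                        in spec.informative_features().items()},
    }
    return panel, truth


def study_template(seed: int = 20130625) -> SyntheticSpec:
    """Default cohort spec with study-matching structure.

    Stratum sizes mirror the study cohort (82 subjects total: male
    HC/GWI/CFS = 21/20/12, female = 9/10/10).  The planted effect pattern
    is *synthetic* — a plausible sex- and illness-dependent signature
    chosen for testing, not the study's estimated effects:

    * healthy females: elevated IL-23 (all time points) and IL-12p70 at T2;
    * male GWI: raised IL-13 and lowered IL-10 at rest and recovery, with
      a mild IL-23 shift;
    * male CFS: raised IL-2 and IL-23 at peak/post exercise;
    * female GWI: raised IL-5 and lowered IL-17 at peak effort, lowered
      IL-23 at recovery;
    * female CFS: raised IL-17 at peak and lowered IL-10 at recovery.

    Shifts are about one within-stratum SD, giving signatures that are
    detectable but not trivially separable at these stratum sizes.  The
    correlation recipe couples time points within a cytokine (r = 0.5) and
    cytokines within a time point (r = 0.2), with one strongly co-expressed
    pair (IL-1b/TNFb at rest, r = 0.81).
    """
    cols = feature_columns()

    def shift(pairs: dict[str, float]) -> np.ndarray:
        eff = np.zeros(N_FEATURES)
        for feat, delta in pairs.items():
            eff[cols.index(feat)] = delta
        return eff

    female_sex_effect = {"IL-23_T0": 1.0, "IL-23_T1": 1.0, "IL-23_T2": 1.0,
                         "IL-12p70_T2": 0.8}
    effects = {
        ("female", "HC"): shift(female_sex_effect),
        ("male", "GWI"): shift({"IL-13_T0": 1.0, "IL-10_T0": -1.0,
                                "IL-13_T2": 0.9, "IL-10_T2": -0.9,
                                "IL-23_T0": 0.5}),
        ("male", "CFS"): shift({"IL-2_T1": 1.1, "IL-2_T2": 1.0,
                                "IL-23_T0": 0.9, "IL-23_T2": 0.9}),
        ("female", "GWI"): shift({**female_sex_effect,
                                  "IL-5_T1": 1.1, "IL-17_T1": -1.0,
                                  "IL-23_T2": -1.0}),
        ("female", "CFS"): shift({**female_sex_effect,
                                  "IL-17_T1": 1.0, "IL-10_T2": -1.0}),
    }
    # plausible resting plasma levels, log2 pg/mL (~2-30 pg/mL)
    baseline = np.tile(np.linspace(1.0, 5.0, len(CYTOKINES)),
                       (len(TIME_POINTS), 1)).T.ravel()
    return SyntheticSpec(
        group_sizes=dict(STUDY_GROUP_SIZES),
        baseline=baseline,
        sds=np.ones(N_FEATURES),
        effects=effects,
        correlation=block_correlation(0.5, 0.2,
                                      pairs=[("IL-1b_T0", "TNFb_T0", 0.81)]),
        missing_rate=0.02,
        seed=seed,
    )


def two_group_design(n_per_group: int = 20, n_features: int = 10,
                     informative=(0, 1), delta: float = 2.5,
                     correlated_with=None, noise_sd: float = 0.72,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Planted two-group design for selection-recovery experiments.

    Standard-normal features for two balanced groups; each index in
    ``informative`` is shifted by ``delta`` (in units of the within-group
    SD) in group 1.  ``correlated_with`` may map a feature index to the
    informative index it copies (plus Gaussian noise of ``noise_sd``),
    producing the redundant-marker structure that stepwise selection is
    meant to truncate.  The default ``noise_sd`` of 0.72 makes the copy
    correlate with its source at r ~ 0.81, the strongest co-expression the
    study pipeline contends with.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    X = rng.standard_normal((n, n_features))
    y = np.repeat([0, 1], n_per_group)
    for j in informative:
        X[y == 1, j] += delta
    for j, src in (correlated_with or {}).items():
        X[:, j] = X[:, src] + noise_sd * rng.standard_normal(n)
    return X, y
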