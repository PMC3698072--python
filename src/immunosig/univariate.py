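"""Per-feature two-group comparisons for cytokine panels.

Group differences in single markers are tested two ways, as in the study
workflow: a two-sample t test on log2-transformed concentrations (the
parametric primary test) and a Wilcoxon rank-sum test on the untransformed
values (a distribution-free confirmation).  A one-way ANOVA is provided for
cohort descriptors compared across more than two groups.  No multiplicity
adjustment is applied in the replication tables; a Benjamini-Hochberg
column is available for reuse.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .panel import CytokinePanel


def t_test_log2(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t test on log2-transformed values.

    Pooled-variance (Student) by default, with the two-tailed p from the t
    distribution on ``n_a + n_b - 2`` degrees of freedom; ``equal_var=False``
    gives the Welch variant.  All values must be positive.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("values must be > 0 before the log2 transform")
    la, lb = np.log2(a), np.log2(b)
    if equal_var:
        pooled = ((a.size - 1) * la.var(ddof=1) + (b.size - 1) * lb.var(ddof=1))
        if pooled == 0 and la.mean() == lb.mean():
            return 0.0, 1.0
        if pooled == 0:
            raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(la, lb, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_ranksum(a, b) -> tuple[float, float]:
    """Wilcoxon rank-sum test on untransformed values.

    Returns the rank-sum statistic W of the first sample and the two-tailed
    p value: exact when the pooled size is <= 20 with no ties, otherwise the
    normal approximation with midrank tie correction and continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each sample needs n >= 1")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U1 -> rank sum
    return w, float(res.pvalue)


def one_way_anova(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA F test for a group effect.

    F = between-group mean square / within-group mean square on
    (g - 1, N - g) degrees of freedom.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in arrs):
        raise ValueError("each group needs n >= 2")
    allv = np.concatenate(arrs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    if ss_within == 0 and all(g.mean() == arrs[0].mean() for g in arrs):
        raise ValueError("all observations identical: F undefined")
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (step-up FDR)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float))


def compare_table(
    panel: CytokinePanel,
    diagnoses: tuple[str, str] | None = None,
    sex: str | None = None,
    sex_contrast_diagnosis: str | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Univariate comparison table, one row per (cytokine, time point).

    Two mutually exclusive group definitions are supported: a diagnosis
    pair within an optional sex stratum (``diagnoses=('HC', 'GWI')``,
    ``sex='male'``) or a male-vs-female contrast within one diagnosis
    (``sex_contrast_diagnosis='HC'``).

    Each row carries the raw-scale mean and standard error per group, the
    t-test p on log2 values (complete observations only), the rank-sum p on
    raw values, and a flag for p <= ``alpha``.  A Benjamini-Hochberg column
    (on the t-test p values) is included for reuse but is not part of the
    replication workflow.
    """
    if (diagnoses is None) == (sex_contrast_diagnosis is None):
        raise ValueError("give exactly one of diagnoses or sex_contrast_diagnosis")
    if diagnoses is not None:
        X, y, keys = panel.select_cohort(diagnoses, sex=sex)
        names = diagnoses
    else:
        X, y, keys = panel.select_sex_cohort(sex_contrast_diagnosis)
        names = ("male", "female")

    rows = []
    for j, key in enumerate(keys):
        col = X[:, j]
        a = col[y == 0]
        b = col[y == 1]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        row = {
            "cytokine": key.cytokine,
            "time_point": key.time_point,
            "feature": str(key),
            f"mean_{names[0]}": a.mean() if a.size else np.nan,
            f"se_{names[0]}": a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else np.nan,
            f"mean_{names[1]}": b.mean() if b.size else np.nan,
            f"se_{names[1]}": b.std(ddof=1) / np.sqrt(b.size) if b.size > 1 else np.nan,
        }
        try:
            _, row["p_t"] = t_test_log2(a, b, equal_var=equal_var)
        except ValueError:
            row["p_t"] = np.nan
        try:
            _, row["p_w"] = wilcoxon_ranksum(a, b)
        except ValueError:
            row["p_w"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out["significant"] = (out["p_t"] <= alpha) | (out["p_w"] <= alpha)
    out.loc[out["p_t"].isna() & out["p_w"].isna(), "significant"] = False
    ok = out["p_t"].notna()
    out["p_t_bh"] = np.nan
    if ok.any():
        out.loc[ok, "p_t_bh"] = bh_adjust(out.loc[ok, "p_t"].to_numpy())
    return out
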