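"""Configuration-driven orchestration of the full analysis workflow.

``run_study`` takes a :class:`RunConfig` — an input panel (file path or
synthetic spec), a list of group contrasts, and preprocessing / selection /
classifier settings — and, for each contrast, produces the univariate
comparison table, the stepwise-selected discriminant model (or an explicit
"no model" record), its standardized canonical coefficients, the LOOCV
confusion matrix and the five performance rates rounded to 2 decimals.
Results are emitted both as delimited tables shaped like the study's
classification tables and as a machine-readable JSON mirror (the tested
surface).  Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discriminant import (LinearDiscriminant, evaluate_metrics, loocv,
                           round_half_up)
from .panel import TIME_POINTS, CytokinePanel, read_panel
from .preprocess import CytokinePreprocessor
from .selection import EnsembleRanker, StepwiseSelector
from .synthetic import generate, study_template
from .univariate import compare_table

log = logging.getLogger("immunosig")

TABLE_COLUMNS = ["Model", "Stand. coeff.", "Assigned {a}", "Assigned {b}",
                 "Total", "", "Accuracy", "NPV", "PPV", "Specificity",
                 "Sensitivity"]


@dataclass
class Comparison:
    """One group contrast: a diagnosis pair within a sex stratum, or a
    male-vs-female contrast within one diagnosis."""

    name: str
    time_points: tuple[str, ...] = TIME_POINTS
    diagnoses: tuple[str, str] | None = None
    sex: str | None = None
    sex_contrast_diagnosis: str | None = None

    def labels(self) -> tuple[str, str]:
        if self.sex_contrast_diagnosis:
            d = self.sex_contrast_diagnosis
            return (f"male {d}", f"female {d}")
        a, b = self.diagnoses
        s = f"{self.sex} " if self.sex else ""
        return (f"{s}{a}", f"{s}{b}")


@dataclass
class RunConfig:
    panel_path: str | None = None
    synthetic: bool = False
    seed: int = 0
    comparisons: list[Comparison] = field(default_factory=list)
    impute_value: float = 1e-4
    impute_stage: str = "before_log"
    leakage_free: bool = False      # refit preprocessing inside each fold
    reselect_in_folds: bool = False  # rerun stepwise inside each fold
    p_enter: float = 0.05
    p_remove: float = 0.10
    covariance_mode: str = "pooled_full"
    priors: str = "equal"
    ensemble: bool = False
    ensemble_iterations: int = 500
    ensemble_subset_size: int = 5
    ensemble_threshold: float = 0.80
    ensemble_top_k: int = 2
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        comps = [Comparison(
            name=c["name"],
            time_points=tuple(c.get("time_points", TIME_POINTS)),
            diagnoses=tuple(c["diagnoses"]) if "diagnoses" in c else None,
            sex=c.get("sex"),
            sex_contrast_diagnosis=c.get("sex_contrast_diagnosis"),
        ) for c in raw.pop("comparisons", [])]
        return cls(comparisons=comps, **raw)


def default_comparisons() -> list[Comparison]:
    """The study's contrast grid: sex within group, illness vs HC per sex."""
    out = [Comparison(f"male vs female {d}", sex_contrast_diagnosis=d)
           for d in ("HC", "GWI", "CFS")]
    for sex in ("male", "female"):
        for dx in ("GWI", "CFS"):
            out.append(Comparison(f"{dx} vs HC {sex}s", diagnoses=("HC", dx),
                                  sex=sex))
    return out


def _select(panel: CytokinePanel, comp: Comparison):
    if comp.sex_contrast_diagnosis:
        return panel.select_sex_cohort(comp.sex_contrast_diagnosis,
                                       time_points=comp.time_points)
    return panel.select_cohort(comp.diagnoses, sex=comp.sex,
                               time_points=comp.time_points)


def _loocv_with_preprocess(Xraw, y, selected, cfg: RunConfig):
    """LOOCV on selected features, optionally leakage-free.

    In the default one-shot mode the preprocessing statistics come from the
    full cohort (the original workflow's behaviour); in leakage-free mode
    the preprocessor is refitted on each training fold.  Coefficients are
    always refitted per fold on the fixed selected set; with
    ``reselect_in_folds`` the stepwise search itself is rerun per fold.
    """
    pre = CytokinePreprocessor(cfg.impute_value, cfg.impute_stage)
    est = LinearDiscriminant(cfg.covariance_mode, cfg.priors)
    n = len(y)
    classes = np.unique(y)
    counts = np.zeros((2, 2), dtype=int)
    Z_full = pre.fit_transform(Xraw)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        if cfg.leakage_free:
            fold_pre = CytokinePreprocessor(cfg.impute_value, cfg.impute_stage)
            Z_tr = fold_pre.fit_transform(Xraw[mask])
            Z_te = fold_pre.transform(Xraw[i:i + 1])
        else:
            Z_tr, Z_te = Z_full[mask], Z_full[i:i + 1]
        feats = selected
        if cfg.reselect_in_folds:
            sel = StepwiseSelector(cfg.p_enter, cfg.p_remove).fit(Z_tr, y[mask])
            feats = sel.selected_ or selected
        fold = est.clone().fit(Z_tr[:, feats], y[mask])
        pred = fold.predict(Z_te[:, feats])[0]
        counts[int(np.nonzero(classes == y[i])[0][0]),
               int(np.nonzero(classes == pred)[0][0])] += 1
        mask[i] = True
    return counts


def run_comparison(panel: CytokinePanel, comp: Comparison, cfg: RunConfig) -> dict:
    """Full workflow for one contrast; returns the JSON-ready record."""
    labels = comp.labels()
    X, y, keys = _select(panel, comp)
    pre = CytokinePreprocessor(cfg.impute_value, cfg.impute_stage)
    Z = pre.fit_transform(X)
    sel = StepwiseSelector(cfg.p_enter, cfg.p_remove).fit(Z, y)
    record: dict = {
        "comparison": comp.name,
        "labels": list(labels),
        "n_subjects": int(len(y)),
        "time_points": list(comp.time_points),
        "stepwise_trace": [
            {"step": e.step, "action": e.action, "feature": str(keys[e.feature]),
             "F": round(e.F, 6), "p": round(e.p, 6)}
            for e in sel.trace_.events
        ],
    }
    if sel.trace_.no_model:
        record["model"] = None
        record["metrics"] = None
        log.info("%s: no model (stepwise selected nothing)", comp.name)
        return record
    feats = sel.selected_
    model = LinearDiscriminant(cfg.covariance_mode, cfg.priors).fit(Z[:, feats], y)
    counts = _loocv_with_preprocess(X, y, feats, cfg)
    from .discriminant import ConfusionMatrix
    cm = ConfusionMatrix(counts, labels)
    metrics = evaluate_metrics(cm)
    record["model"] = {
        "features": [str(keys[j]) for j in feats],
        "intercept": model.intercept_,
        "coefficients": model.coef_.tolist(),
        "standardized_coefficients": model.standardized_coef_.tolist(),
        "covariance_mode": cfg.covariance_mode,
        "priors": cfg.priors,
    }
    record["confusion_matrix"] = counts.tolist()
    record["metrics"] = metrics.as_dict()
    record["metrics_2dp"] = metrics.as_dict(rounded=True)
    return record


def run_study(cfg: RunConfig, panel: CytokinePanel | None = None) -> dict:
    """Run every configured comparison; errors abort only their comparison."""
    if panel is None:
        if cfg.synthetic or not cfg.panel_path:
            spec = study_template(seed=cfg.seed or 20130625)
            panel, _ = generate(spec)
        else:
            panel = read_panel(cfg.panel_path)
    comparisons = cfg.comparisons or default_comparisons()
    digest = hashlib.sha256(panel.to_json().encode()).hexdigest()[:16]
    log.info("input panel: %d subjects, %d features, sha256 %s",
             panel.n_subjects, len(panel.features), digest)
    report = {"seed": cfg.seed, "input_sha256": digest, "comparisons": []}
    for comp in comparisons:
        try:
            record = run_comparison(panel, comp, cfg)
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            log.error("%s failed: %s", comp.name, exc)
            record = {"comparison": comp.name, "error": str(exc)}
        report["comparisons"].append(record)

    if cfg.ensemble:
        ens_records = []
        for comp in comparisons:
            try:
                X, y, keys = _select(panel, comp)
                Z = CytokinePreprocessor(cfg.impute_value,
                                         cfg.impute_stage).fit_transform(X)
                ranker = EnsembleRanker(cfg.ensemble_iterations,
                                        cfg.ensemble_subset_size,
                                        cfg.ensemble_threshold,
                                        random_state=cfg.seed).fit(Z, y)
                ens_records.append({
                    "comparison": comp.name,
                    "n_passing": int(ranker.n_passing_),
                    "ranking": [str(keys[j]) for j in ranker.ranking_[:10]],
                    "counts": {str(keys[j]): int(ranker.counts_[j])
                               for j in ranker.ranking_ if ranker.counts_[j]},
                })
            except Exception as exc:  # noqa: BLE001
                log.error("ensemble %s failed: %s", comp.name, exc)
                ens_records.append({"comparison": comp.name, "error": str(exc)})
        report["ensemble"] = ens_records

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, allow_nan=False,
                       default=_json_nan))
        render_table(report).to_csv(out / "classification_table.csv",
                                    index=False)
    return report


def _json_nan(x):
    if isinstance(x, float) and x != x:
        return None
    raise TypeError(f"not JSON serialisable: {x!r}")


def _fmt(v) -> str:
    return "NA" if v is None or v != v else f"{round_half_up(v, 2):.2f}"


def render_table(report: dict) -> pd.DataFrame:
    """Classification-table layout: one block per contrast.

    Columns follow the published table shape — Model, Stand. coeff., the
    two Assigned counts, Total, the truth label, then Accuracy, NPV, PPV,
    Specificity, Sensitivity (half-up 2 decimals).  Multi-feature models
    span several rows; a contrast with no model is a single "NA" row.
    """
    rows = []
    for rec in report["comparisons"]:
        name = rec.get("comparison", "?")
        if rec.get("error"):
            rows.append({"Contrast": name, "Model": "ERROR",
                         "Stand. coeff.": rec["error"]})
            continue
        la, lb = rec.get("labels", ("I", "J"))
        if rec["model"] is None:
            rows.append({"Contrast": name, "Model": "NA",
                         "Stand. coeff.": "NA", f"Assigned {la}": "NA",
                         f"Assigned {lb}": "NA", "Total": "NA", "Truth": "",
                         "Accuracy": "NA", "NPV": "NA", "PPV": "NA",
                         "Specificity": "NA", "Sensitivity": "NA"})
            continue
        feats = rec["model"]["features"]
        coeffs = rec["model"]["standardized_coefficients"]
        counts = rec["confusion_matrix"]
        m = rec["metrics"]
        for i, (f, c) in enumerate(zip(feats, coeffs)):
            row = {"Contrast": name if i == 0 else "", "Model": f,
                   "Stand. coeff.": f"{round_half_up(c, 2):.2f}"}
            if i < 2:
                row[f"Assigned {la}"] = counts[i][0]
                row[f"Assigned {lb}"] = counts[i][1]
                row["Total"] = counts[i][0] + counts[i][1]
                row["Truth"] = f"True {la}" if i == 0 else f"True {lb}"
            if i == 0:
                row.update({"Accuracy": _fmt(m["accuracy"]),
                            "NPV": _fmt(m["npv"]), "PPV": _fmt(m["ppv"]),
                            "Specificity": _fmt(m["specificity"]),
                            "Sensitivity": _fmt(m["sensitivity"])})
            rows.append(row)
        if len(feats) == 1:  # second confusion-matrix row still needed
            rows.append({"Contrast": "", "Model": "",
                         f"Assigned {la}": counts[1][0],
                         f"Assigned {lb}": counts[1][1],
                         "Total": counts[1][0] + counts[1][1],
                         "Truth": f"True {lb}"})
    return pd.DataFrame(rows).fillna("")
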