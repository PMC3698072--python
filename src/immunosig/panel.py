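"""Data model and I/O for plasma cytokine panels from exercise-challenge studies.

A panel holds one concentration (pg/mL) per subject for each (cytokine,
time point) pair, together with subject metadata (sex, diagnosis group).
The study layout is 16 cytokines measured at three blood draws — at rest
(T0), at peak effort (T1) and 4 hours post exercise (T2) — giving 48
candidate features per subject.  Missing assay values are carried as an
explicit mask (NaN in the value table) until the imputation stage; they are
never encoded as sentinel numbers here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Canonical 16-plex cytokine screen, in reporting order.
CYTOKINES: tuple[str, ...] = (
    "IL-1a", "IL-1b", "IL-2", "IL-4", "IL-5", "IL-6", "IL-8", "IL-10",
    "IL-12p70", "IL-13", "IL-15", "IL-17", "IL-23", "IFNg", "TNFa", "TNFb",
)

#: Blood-draw time points: rest, peak effort (VO2 max), 4 h post exercise.
TIME_POINTS: tuple[str, ...] = ("T0", "T1", "T2")

SEXES: tuple[str, ...] = ("male", "female")
DIAGNOSES: tuple[str, ...] = ("HC", "GWI", "CFS")

META_COLUMNS: tuple[str, ...] = ("subject_id", "sex", "diagnosis")


class FeatureKey(NamedTuple):
    """One (cytokine, time point) feature, rendered as e.g. ``IL-17_T1``."""

    cytokine: str
    time_point: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.cytokine}_{self.time_point}"

    @classmethod
    def parse(cls, name: str) -> "FeatureKey":
        """Parse a ``NAME_Tk`` column label.

        The time-point suffix must be one of T0/T1/T2; the cytokine name may
        itself contain underscores or hyphens.
        """
        cytokine, sep, tp = name.rpartition("_")
        if not sep or tp not in TIME_POINTS:
            raise ValueError(
                f"feature column {name!r} has no recognised time-point suffix "
                f"(expected one of {TIME_POINTS})"
            )
        return cls(cytokine, tp)


def feature_keys(
    cytokines: Sequence[str] = CYTOKINES,
    time_points: Sequence[str] = TIME_POINTS,
) -> list[FeatureKey]:
    """All feature keys in canonical order: cytokine-major, T0 < T1 < T2."""
    return [FeatureKey(c, t) for c in cytokines for t in time_points]


def feature_columns(
    cytokines: Sequence[str] = CYTOKINES,
    time_points: Sequence[str] = TIME_POINTS,
) -> list[str]:
    return [str(k) for k in feature_keys(cytokines, time_points)]


@dataclass
class CytokinePanel:
    """Subjects x (cytokine, time point) concentration matrix with metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Concentrations in pg/mL, indexed by subject id with one column per
        feature (``NAME_Tk``).  Missing cells are NaN.
    meta : pandas.DataFrame
        Indexed like ``values``; columns ``sex`` and ``diagnosis``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate subject_id: {list(dupes)}")
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the same subject index")
        missing_meta = [c for c in ("sex", "diagnosis") if c not in self.meta]
        if missing_meta:
            raise ValueError(f"meta lacks required columns: {missing_meta}")
        bad_sex = set(self.meta["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
        bad_dx = set(self.meta["diagnosis"]) - set(DIAGNOSES)
        if bad_dx:
            raise ValueError(f"unknown diagnosis labels: {sorted(bad_dx)}")
        for col in self.values.columns:
            FeatureKey.parse(col)  # raises on malformed names
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            rows, cols = np.nonzero(np.nan_to_num(vals, nan=0.0) < 0)
            cell = (self.values.index[rows[0]], self.values.columns[cols[0]])
            raise ValueError(f"negative concentration at {cell}")

    # -- basic views ------------------------------------------------------

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def features(self) -> list[FeatureKey]:
        return [FeatureKey.parse(c) for c in self.values.columns]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where the assay value is missing."""
        return self.values.isna()

    def assert_study_layout(self) -> None:
        """Require the full 16-cytokine x 3-time-point (48-column) layout."""
        expected = feature_columns()
        if list(self.values.columns) != expected:
            raise ValueError(
                "panel does not have the canonical 16x3 study layout "
                f"({len(self.values.columns)} columns present, 48 expected)"
            )

    # -- cohort selection -------------------------------------------------

    def select_cohort(
        self,
        diagnoses: tuple[str, str],
        sex: str | None = None,
        time_points: Iterable[str] | None = None,
        cytokines: Iterable[str] | None = None,
    ) -> tuple[np.ndarray, np.ndarray, list[FeatureKey]]:
        """Extract a two-group feature matrix for classification.

        The label convention is fixed: the *second*-listed diagnosis (group
        J, e.g. GWI or CFS against HC) is coded 1 and treated downstream as
        the positive class.

        Returns
        -------
        X : (n_subjects, n_features) float array with NaN for missing cells
        y : (n_subjects,) int array of 0/1 labels
        keys : feature keys for the columns of X, in canonical order
        """
        group_a, group_b = diagnoses
        meta = self.meta
        keep = meta["diagnosis"].isin([group_a, group_b])
        if sex is not None:
            if sex not in SEXES:
                raise ValueError(f"unknown sex filter {sex!r}")
            keep &= meta["sex"] == sex
        sub = meta[keep]
        for group in (group_a, group_b):
            if not (sub["diagnosis"] == group).any():
                stratum = f"{sex} {group}" if sex else group
                raise ValueError(f"empty stratum after filtering: {stratum}")

        tps = list(time_points) if time_points is not None else list(TIME_POINTS)
        present = {k.cytokine for k in self.features}
        cyts = [c for c in (cytokines or CYTOKINES) if c in present]
        if cytokines is None and not set(CYTOKINES) & present:
            cyts = sorted(present)  # non-canonical panel: keep what is there
        keys = [
            k for k in feature_keys(cyts, [t for t in TIME_POINTS if t in tps])
            if str(k) in self.values.columns
        ]
        if not keys:
            raise ValueError("no feature columns match the requested selection")

        # order rows so group A comes first, preserving file order within group
        order = sub.index[(sub["diagnosis"] == group_a)].append(
            sub.index[(sub["diagnosis"] == group_b)]
        )
        X = self.values.loc[order, [str(k) for k in keys]].to_numpy(dtype=float)
        y = (sub.loc[order, "diagnosis"] == group_b).to_numpy(dtype=int)
        return X, y, keys

    def select_sex_cohort(
        self,
        diagnosis: str,
        time_points: Iterable[str] | None = None,
        cytokines: Iterable[str] | None = None,
    ) -> tuple[np.ndarray, np.ndarray, list[FeatureKey]]:
        """Male-vs-female contrast within one diagnosis group.

        Females are the second-listed (positive) class, matching the
        male-vs-female reporting convention of the study workflow.
        """
        meta = self.meta
        sub = meta[meta["diagnosis"] == diagnosis]
        for sex in SEXES:
            if not (sub["sex"] == sex).any():
                raise ValueError(f"empty stratum after filtering: {sex} {diagnosis}")
        tps = list(time_points) if time_points is not None else list(TIME_POINTS)
        present = {k.cytokine for k in self.features}
        cyts = [c for c in (cytokines or CYTOKINES) if c in present] or sorted(present)
        keys = [
            k for k in feature_keys(cyts, [t for t in TIME_POINTS if t in tps])
            if str(k) in self.values.columns
        ]
        order = sub.index[sub["sex"] == "male"].append(sub.index[sub["sex"] == "female"])
        X = self.values.loc[order, [str(k) for k in keys]].to_numpy(dtype=float)
        y = (sub.loc[order, "sex"] == "female").to_numpy(dtype=int)
        return X, y, keys

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        out = self.meta.copy()
        out.insert(0, "subject_id", out.index)
        return pd.concat([out, self.values], axis=1)

    def to_json(self) -> str:
        """JSON export (used for text fixtures); NaN encoded as null."""
        payload = {
            "subjects": list(map(str, self.subject_ids)),
            "sex": self.meta["sex"].tolist(),
            "diagnosis": self.meta["diagnosis"].tolist(),
            "features": list(self.values.columns),
            "values": [
                [None if np.isnan(v) else v for v in row]
                for row in self.values.to_numpy(dtype=float)
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "CytokinePanel":
        payload = json.loads(text)
        idx = pd.Index(payload["subjects"], name="subject_id")
        values = pd.DataFrame(
            [[np.nan if v is None else v for v in row] for row in payload["values"]],
            index=idx,
            columns=payload["features"],
            dtype=float,
        )
        meta = pd.DataFrame(
            {"sex": payload["sex"], "diagnosis": payload["diagnosis"]}, index=idx
        )
        return cls(values, meta)


def read_panel(path, sep: str | None = None) -> CytokinePanel:
    """Read a wide-format delimited panel file.

    The header must name ``subject_id``, ``sex``, ``diagnosis`` and one
    column per ``CYTOKINE_TIMEPOINT`` feature.  Empty cells denote missing
    values; anything else must parse as a nonnegative number.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    missing_cols = [c for c in META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"panel file lacks required columns: {missing_cols}")
    feature_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not feature_cols:
        raise ValueError("panel file has no feature columns")

    idx = pd.Index(df["subject_id"], name="subject_id")
    raw = df[feature_cols]
    parsed = {}
    for col in feature_cols:
        FeatureKey.parse(col)
        cells = raw[col].str.strip()
        out = np.empty(len(cells), dtype=float)
        for i, v in enumerate(cells):
            if v == "":
                out[i] = np.nan
                continue
            try:
                out[i] = float(v)  # exact round-trip parse
            except ValueError:
                raise ValueError(
                    f"unparseable value {v!r} in column {col}, "
                    f"subject {idx[i]!r}"
                ) from None
        parsed[col] = out
    values = pd.DataFrame(parsed, index=idx, columns=feature_cols, dtype=float)
    meta = pd.DataFrame(
        {"sex": df["sex"].to_numpy(), "diagnosis": df["diagnosis"].to_numpy()},
        index=idx,
    )
    return CytokinePanel(values, meta)


def write_panel(panel: CytokinePanel, path, sep: str = ",") -> None:
    """Write a panel as delimited text; missing cells become empty fields.

    Values are written with full ``repr`` precision so a read/write round
    trip is bit-exact.
    """
    panel.to_frame().to_csv(path, sep=sep, index=False, na_rep="")


def select_cohort(panel: CytokinePanel, diagnoses, sex=None, time_points=None,
                  cytokines=None):
    """Functional wrapper over :meth:`CytokinePanel.select_cohort`."""
    return panel.select_cohort(diagnoses, sex=sex, time_points=time_points,
                               cytokines=cytokines)
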