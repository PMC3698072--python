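"""Published cross-validation tables of the GWI/CFS exercise-challenge study.

The study this pipeline replicates reported, for every group contrast, the
leave-one-out 2x2 assignment counts alongside five rounded performance
rates (accuracy, NPV, PPV, specificity, sensitivity).  The raw subject
data are not deposited, but the printed tables themselves are a complete
verification surface for the metric arithmetic: each row's rates must be
recomputable from that row's own counts under the second-listed-group-
positive convention (female, GWI or CFS positive; HC or male negative).

``REFERENCE_ROWS`` transcribes every row that prints a confusion matrix;
``NA_ROWS`` lists the contrasts reported as "NA" because stepwise selection
returned no model.  Counts are (true group) x (assigned group) with the
negative class first; metrics are as printed, rounded to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discriminant import ConfusionMatrix


@dataclass(frozen=True)
class ReferenceRow:
    contrast: str
    features: tuple[str, ...]
    counts: tuple[tuple[int, int], tuple[int, int]]
    labels: tuple[str, str]  # (negative group, positive group)
    accuracy: float
    npv: float
    ppv: float
    specificity: float
    sensitivity: float

    def confusion_matrix(self) -> ConfusionMatrix:
        return ConfusionMatrix(np.asarray(self.counts), self.labels)

    def printed_metrics(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "npv": self.npv, "ppv": self.ppv,
                "specificity": self.specificity,
                "sensitivity": self.sensitivity}


REFERENCE_ROWS: tuple[ReferenceRow, ...] = (
    # -- male vs female within diagnosis group (female positive) ---------
    ReferenceRow("mHC vs fHC at T0", ("IL-2_T0", "IL-23_T0"),
                 ((19, 2), (2, 7)), ("male HC", "female HC"),
                 0.87, 0.90, 0.78, 0.90, 0.78),
    ReferenceRow("mHC vs fHC at T0-T2", ("IL-2_T1", "IL-5_T1", "IL-23_T0"),
                 ((19, 2), (1, 8)), ("male HC", "female HC"),
                 0.90, 0.95, 0.80, 0.90, 0.89),
    ReferenceRow("mCFS vs fCFS at T0", ("IL-8_T0",),
                 ((7, 5), (2, 8)), ("male CFS", "female CFS"),
                 0.68, 0.78, 0.62, 0.58, 0.80),
    ReferenceRow("mCFS vs fCFS at T0-T2", ("TNFb_T2", "IL-6_T1", "IL-8_T0"),
                 ((8, 4), (1, 9)), ("male CFS", "female CFS"),
                 0.77, 0.89, 0.69, 0.67, 0.90),
    ReferenceRow("mGWI vs fGWI at T0-T2",
                 ("IL-2_T2", "IL-1a_T0", "IL-1a_T1", "IL-6_T1", "IL-10_T1"),
                 ((19, 1), (3, 7)), ("male GWI", "female GWI"),
                 0.87, 0.86, 0.88, 0.95, 0.70),
    # -- male illness vs male HC (illness positive) -----------------------
    ReferenceRow("GWI vs HC males at T0", ("IL-10_T0", "IL-13_T0", "IL-23_T0"),
                 ((16, 5), (6, 14)), ("male HC", "male GWI"),
                 0.73, 0.73, 0.74, 0.76, 0.70),
    ReferenceRow("GWI vs HC males at T2",
                 ("IL-1b_T2", "IL-10_T2", "IL-13_T2", "IL-23_T2"),
                 ((14, 7), (4, 16)), ("male HC", "male GWI"),
                 0.73, 0.78, 0.70, 0.67, 0.80),
    ReferenceRow("GWI vs HC males at T0-T2",
                 ("IL-15_T2", "IL-10_T0", "IL-13_T0", "IL-23_T0", "IFNg_T1"),
                 ((17, 4), (3, 17)), ("male HC", "male GWI"),
                 0.83, 0.85, 0.81, 0.81, 0.85),
    ReferenceRow("CFS vs HC males at T0", ("IL-23_T0",),
                 ((16, 5), (3, 9)), ("male HC", "male CFS"),
                 0.76, 0.84, 0.64, 0.76, 0.75),
    ReferenceRow("CFS vs HC males at T1",
                 ("IL-2_T1", "IL-6_T1", "IL-10_T1", "IL-15_T1"),
                 ((16, 5), (1, 11)), ("male HC", "male CFS"),
                 0.82, 0.94, 0.69, 0.76, 0.92),
    ReferenceRow("CFS vs HC males at T2", ("IL-23_T2",),
                 ((16, 5), (4, 8)), ("male HC", "male CFS"),
                 0.73, 0.80, 0.62, 0.76, 0.67),
    ReferenceRow("CFS vs HC males at T0-T2",
                 ("IL-2_T2", "IL-10_T2", "IL-23_T2", "IL-10_T1",
                  "IL-12p70_T1"),
                 ((18, 3), (2, 10)), ("male HC", "male CFS"),
                 0.85, 0.90, 0.77, 0.86, 0.83),
    # -- female illness vs female HC (illness positive) -------------------
    ReferenceRow("GWI vs HC females at T1", ("IL-5_T1", "IL-17_T1"),
                 ((8, 1), (2, 8)), ("female HC", "female GWI"),
                 0.84, 0.80, 0.89, 0.89, 0.80),
    ReferenceRow("GWI vs HC females at T2", ("IL-23_T2",),
                 ((8, 1), (3, 7)), ("female HC", "female GWI"),
                 0.79, 0.73, 0.88, 0.89, 0.70),
    ReferenceRow("GWI vs HC females at T0-T2", ("IL-23_T2", "IL-5_T1"),
                 ((8, 1), (2, 8)), ("female HC", "female GWI"),
                 0.84, 0.80, 0.89, 0.89, 0.80),
    ReferenceRow("CFS vs HC females at T0", ("IL-4_T0", "IL-17_T0"),
                 ((5, 4), (1, 9)), ("female HC", "female CFS"),
                 0.74, 0.83, 0.69, 0.56, 0.90),
    ReferenceRow("CFS vs HC females at T1", ("IL-2_T1",),
                 ((4, 5), (2, 8)), ("female HC", "female CFS"),
                 0.63, 0.67, 0.62, 0.44, 0.80),
    ReferenceRow("CFS vs HC females at T2", ("IL-2_T2",),
                 ((3, 6), (0, 10)), ("female HC", "female CFS"),
                 0.68, 1.00, 0.63, 0.33, 1.00),
    ReferenceRow("CFS vs HC females at T0-T2", ("IL-2_T1",),
                 ((4, 5), (1, 9)), ("female HC", "female CFS"),
                 0.68, 0.80, 0.64, 0.44, 0.90),
    ReferenceRow("CFS vs HC females at T0-T2 (all-possible-subsets)",
                 ("IL-17_T1", "IL-10_T2"),
                 ((8, 1), (3, 7)), ("female HC", "female CFS"),
                 0.79, 0.73, 0.88, 0.89, 0.70),
)

#: Contrasts printed as "NA": stepwise selection returned no model.
NA_ROWS: tuple[str, ...] = (
    "mGWI vs fGWI at T0",
    "GWI vs HC males at T1",
    "GWI vs HC females at T0",
)
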