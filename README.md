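# immunosig

Sex-stratified cytokine-signature classification for exercise-challenge
immune profiling.

## The problem

Gulf War Illness (GWI) and Chronic Fatigue Syndrome / myalgic
encephalomyelitis (CFS/ME) are multi-symptom conditions with overlapping
clinical presentation and suspected immune involvement. One study design
for separating them measures a 16-plex plasma cytokine panel (IL-1a, IL-1b,
IL-2, IL-4, IL-5, IL-6, IL-8, IL-10, IL-12p70, IL-13, IL-15, IL-17, IL-23,
IFNγ, TNFα, TNFβ) at three points of a graded exercise test — rest (T0),
peak effort / VO₂ max (T1), 4 h post exercise (T2) — giving 48 candidate
markers per subject, and asks which small marker subsets classify subjects
by sex and by diagnosis group (HC / GWI / CFS). `immunosig` implements that
analysis as a tested, reusable pipeline for anyone running this kind of
stratified biomarker-panel study: assay calibration, preprocessing,
univariate comparisons, discriminant modelling with two marker-selection
strategies, and cross-validated performance reporting — driven by user
panels (CSV/TSV) or by a bundled synthetic-cohort generator.

## The model

A subject's profile x is assigned between groups I and J by a two-class
linear discriminant: with pooled within-group covariance **S**, class means
m_I, m_J and priors π,

    B  = S⁻¹ (m_J − m_I),
    B₀ = −½ (m_I + m_J)·B + log(π_J / π_I),

and x goes to group J (the second-listed, "positive" group: female, GWI or
CFS) exactly when B₀ + x·B ≥ 0 — a score of exactly zero goes to J, the
strict form of the published rule. Two complementary selection strategies
choose the markers:

* **stepwise partial-F selection** — candidates enter an OLS regression of
  a ±1 group indicator while p(partial F) < 0.05 and leave when their
  revised p > 0.10, truncating correlated markers toward a minimally
  redundant subset;
* **random-subset ensemble ranking** — 500 random draws of 5 markers from
  all 48 are each fitted as a *diagonal*-covariance discriminant (the
  correction that tolerates co-expressed markers) and scored by
  leave-one-out accuracy; markers are ranked by how often they appear in
  models reaching 80% accuracy.

Every model is reported through leave-one-out cross-validation (LOOCV):
accuracy, sensitivity, specificity, PPV and NPV from the 2×2 table of true
vs assigned group, plus standardized canonical coefficients (B rescaled to
unit within-group score variance times each feature's pooled SD) so marker
contributions are comparable.

## Worked example

Simulate a study-shaped cohort (82 subjects: male HC/GWI/CFS = 21/20/12,
female = 9/10/10; 48 features; planted sex- and illness-specific log2
shifts; one co-expressed pair at r = 0.81; 2% missing cells), then run the
stepwise workflow for male CFS vs healthy controls:

```sh
$ immunosig simulate --seed 11 --out panel.csv
wrote 82 subjects to panel.csv (seed 11)

$ immunosig stepwise panel.csv --groups HC,CFS --sex male
step 1: enter IL-2_T2 (F=8.396, p=0.0068)
step 2: enter IL-10_T0 (F=15.381, p=0.0005)
step 3: enter IL-23_T0 (F=4.622, p=0.0400)
step 4: enter IL-4_T1 (F=4.323, p=0.0469)
step 5: enter IL-17_T0 (F=11.197, p=0.0024)
step 6: enter IL-6_T1 (F=5.074, p=0.0329)
selected: IL-2_T2, IL-10_T0, IL-23_T0, IL-4_T1, IL-17_T0, IL-6_T1
```

Each step reports the partial-F statistic and its null probability at the
moment of entry; the generator's planted CFS markers (IL-2 at T1/T2, IL-23
at T0/T2) are among those recruited, alongside chance entries that a
48-candidate search at p < 0.05 is expected to admit. The full workflow
over all seven study contrasts:

```sh
$ immunosig run --seed 20130625 --out results/
7 comparisons: 6 modelled, 1 NA
report written to results/report.json
```

A contrast where no marker reaches the entry threshold is reported as
"NA — no model", exactly as the original tables print it. In
`report.json`, for example, the "GWI vs HC females" contrast selected
IL-23_T2 and IL-12p70_T0 with LOOCV accuracy 0.84, sensitivity 0.90,
specificity 0.78 — the 2×2 assignment counts, raw and standardized
coefficients, and all five rates (full precision and 2-dp) accompany every
contrast, and `classification_table.csv` renders the published table
layout (Model / Stand. coeff. / Assigned counts / Accuracy / NPV / PPV /
Specificity / Sensitivity).

Library use mirrors scikit-learn:

```python
import immunosig as im

panel = im.read_panel("panel.csv")
X, y, keys = panel.select_cohort(("HC", "CFS"), sex="male")
Z = im.CytokinePreprocessor().fit_transform(X)      # impute, log2, z-score
sel = im.StepwiseSelector().fit(Z, y)
cm = im.loocv(Z[:, sel.selected_], y)
print(im.evaluate_metrics(cm).as_dict(rounded=True))
```

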