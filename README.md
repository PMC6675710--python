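# romma

A scoring and triage engine for ER-positive breast cancer built on the
**Rochester Modified Magee algorithm (RoMMa)**, with the validation
analytics that surround it: concordance with the Oncotype DX® recurrence
score (ODXRS), 2×2 diagnostic accuracy, recurrence-outcome statistics,
cost-avoidance modeling, and a synthetic-cohort generator so the entire
pipeline is testable without patient data.

## Who it is for

Pathology and oncology groups (and methods researchers) who want to ask:
*which ER+ cases can skip send-out multigene testing because routine
clinicopathologic data already pin down the answer?* The package takes
per-case CSV records — Nottingham score (NS), modified ER/PR H-scores,
HER-2 IHC/FISH, Ki-67, tumor size, optional ODXRS and outcomes — and
produces risk calls, send-for-testing recommendations, and the summary
statistics used to validate them.

## The model

The three **modified Magee equations** are published linear surrogates of
the ODXRS:

```
score_k = b0_k + Σ_j b_kj · x_j
```

with predictors drawn from {NS, ER H-score, PR H-score, HER-2 term, tumor
size, Ki-67}. Each equation uses a different predictor subset, so a case
missing Ki-67 or size is still scored by the equations that do not need it.
The **average modified Magee score (amMs)** is the mean of the computable
equation scores. HER-2 enters as a status-mapped term, with reflex FISH
overriding an equivocal IHC 2+.

RoMMa then triages on the amMs plus a histologic rule:

| rule | call |
|---|---|
| amMs ≤ 9 | lowest risk |
| amMs ≤ 12, **or** NS < 6 and ER & PR H-score ≥ 150 and Ki-67 < 10% | low risk |
| amMs > 30 | high risk |
| otherwise | intermediate → send for ODX testing |

Cases with amMs ≤ 18 are additionally predicted to fall below the TAILORx
ODXRS < 26 boundary. Equation coefficients and all thresholds live in YAML
configs (`src/romma/data/magee_equations.yaml` documents the provenance of
the default coefficients); nothing is hard-coded.

## Worked example

```python
from romma import CaseRecord, average_magee, classify, load_equation_specs

specs = load_equation_specs()
case = CaseRecord(case_id="C1", patient_id="P1", nottingham_score=5,
                  er_h_score=250, pr_h_score=220, her2_ihc=1,
                  ki67_pct=6.0, tumor_size_cm=1.2)
magee = average_magee(case, specs)
print({eq: round(s, 1) for eq, s in magee.per_equation_scores.items()},
      round(magee.average_score, 1))
call = classify(magee, case)
print(call.category.value, call.predicted_odx_band.value, call.send_for_odx)
```

prints

```
{'eq1': 12.8, 'eq2': 14.4, 'eq3': 13.6} 13.6
low_risk low False
```

The amMs is 13.6 — above the ≤ 12 score cutoff — but the case meets the
histologic low-risk criteria (NS 5, both H-scores ≥ 150, Ki-67 6%), so
RoMMa calls it low risk, predicts a low ODXRS band, and does not recommend
send-out testing.

The same pipeline runs from the shell:

```bash
romma simulate --n 500 --seed 7 --out cohort.csv
romma score --input cohort.csv --out scored.csv
romma classify --input cohort.csv --out-calls calls.csv --out-summary summary.json
romma report --input cohort.csv --out-dir report/   # full bundle + run log
```

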