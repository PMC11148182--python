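# icar-pd1

Analysis pipeline for **functionality scoring of PD-1 ligands** in tumor
samples, and for asking whether that functionality predicts response to
anti-PD-1 therapy better than the standard PD-L1 Combined Positive Score
(CPS).

The underlying assay co-cultures a PD-1-overexpressing reporter cell line
with FFPE tumor tissue in a 96-well plate; the reporter secretes murine IL-2
in proportion to functional ligand engagement. Blocking the receptor
(pembrolizumab) or a single ligand (durvalumab for PD-L1, anti-CD273 for
PD-L2) suppresses the signal, and the drop quantifies how much *functional*
ligand the sample presents — as opposed to how much ligand merely stains
positive. The per-sample functionality score is

```
score = (unblocked response − blocked response) / log2(coverage mm²) × PC ratio
```

where tissue coverage normalises for the amount of tissue in the well and
the positive-control (PC) ratio harmonises signal levels across plates and
experiments. Downstream, a head-and-neck squamous cell carcinoma (HNSCC)
cohort is stratified at a score cutoff of 4 and analysed with the standard
clinical toolkit: RECIST responder classification, response-rate contingency
tables (Pearson χ² / Fisher / Wilcoxon rank-sum), Kaplan–Meier curves with
log-rank tests for OS and PFS, response-duration summaries, swimmer-plot
tables, and a cross-validated predictive evaluation (a single-round XGBoost
tree on the three scores, 3-fold CV, repeated over 100 bootstrap cohorts at
each size from 15 to 29).

Patient-level data for the original 29-patient cohort are not publicly
deposited, so the package ships a first-class synthetic generator that
emulates both layers — raw plate wells consistent with the score formula,
and a clinical cohort with response linked to the PD-1 score, CPS only
imperfectly concordant with PD-L1 functionality, and right-censored
survival — making every pipeline stage testable end to end.

## Worked example

Simulate a 29-patient study, score the plates, and run the full report:

```bash
icar-pd1 simulate --preset default --seed 42 --out-prefix demo
icar-pd1 score --plates demo_plates.csv --pc-reference 150 --out demo_scores.csv
icar-pd1 report --cohort demo_cohort.csv --seed 42 --out-dir demo_report
```

The scores table lists the three functionality scores per sample:

```
sample_id,pd1_score,pdl1_score,pdl2_score,qc_flags
P01,4.123245056672973,2.731134470275327,1.3921105863976457,
P02,8.415072333003575,0.7117816355588433,7.703290697444732,
```

and `demo_report/summary.json` contains, among other tables, the
response-rate stratification at the PD-1-score cutoff of 4:

```
{'stratum': 'pd1>4',  'responders': 11, 'total': 13, 'percent': 85}
{'stratum': 'pd1<=4', 'responders': 4,  'total': 16, 'percent': 25}
{'stratum': 'CPS_positive', 'responders': 8, 'total': 12, 'percent': 67}
{'stratum': 'CPS_negative', 'responders': 7, 'total': 16, 'percent': 44}
```

Read: in this simulated cohort 85 % of patients with a PD-1 functionality
score above 4 responded versus 25 % below, while CPS positivity separates
response much more weakly (67 % vs 44 %) — the pattern the assay is designed
to expose. The same JSON carries the OS/PFS log-rank results (here OS by
score stratum p = 0.78: this particular draw shows no survival separation),
mean response durations per stratum, and the per-size min/mean test AUC of
the predictive evaluation; `swimmer.csv`, `survival_curves.csv`,
`response_rates.csv` and `predictive_auc.csv` hold the full tables.

Library use mirrors the CLI:

```python
from icar_pd1 import GeneratorConfig, generate_cohort, stratify_by_score

patients, truth = generate_cohort(GeneratorConfig(seed=42))
strat = stratify_by_score(patients, "pd1", cutoff=4.0)
```

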