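# mistrat

Should multiple imputation be stratified by exposure group when estimating
causal effects via outcome regression? `mistrat` is a simulation toolkit
for studying that question: it generates cohort-like data with a binary
exposure, five binary confounders, a continuous outcome and an auxiliary
variable; imposes missing-at-random missingness through calibrated logistic
mechanisms; applies seven missing-data methods (complete-case analysis and
six chained-equations multiple-imputation variants, including MI performed
separately by exposure group); and evaluates bias, precision and coverage
of the exposure-effect estimator over Monte-Carlo replicates.

It is aimed at biostatisticians and epidemiologists who want to probe how
imputation-model choices (exposure interactions, stratification) interact
with effect modification and missingness mechanisms, using a fully
reproducible, scriptable pipeline.

## The model in brief

The target analysis is the no-interaction outcome regression

    E[Y | X, C] = θ0 + θ1 X + θ2 C1 + θ3 C2 + θ4 C3 + θ5 C4 + θ6 C5,

whose exposure coefficient θ1 equals the average causal effect
E[Y^(x=1)] − E[Y^(x=0)] under exchangeability given C, consistency,
positivity and no effect modification. Complete data are generated with a
controlled violation of that last assumption:

    E[Y | X, C] = α0 + α1 C1 + … + α5 C5 + α6 X + δ·α6 X·C5,

with δ ∈ {0, ±0.25, ±0.5, ±0.75} and α6 calibrated so that the
large-sample value of θ1 is 0.3 in every scenario. Missingness in Y alone,
or in (C4, C5, Y) sequentially, follows logistic models in A, X, C5 (and
earlier missingness indicators), with intercepts calibrated to 30% or
10/10/20% missingness, under three scenarios: (i) exposure only, (ii)
exposure + C5, (iii) exposure + C5 + their interaction.

Methods compared: `CCA`, `MI-NI` (no interactions), `MI-ExO` (X×Y),
`MI-ExC` (X×C5), `MI-ExOC`, `MI-ExI` (X × every incomplete variable) and
`MI-EG` (imputation run separately in each exposure group). Multiply
imputed fits are pooled with Rubin's rules (Barnard–Rubin degrees of
freedom).

## Worked example

Run one scenario cell — 30% exposure prevalence, n = 700, strong negative
interaction (δ = −0.75), outcome-only missingness scenario (iii) — with 500
replicates and m = 10 imputations:

```python
from mistrat import ScenarioTable, run_cell, summarize_frame

table = ScenarioTable(n_calibration=10**6)   # calibrates lazily, cacheable
cell = dict(prevalence=0.30, n=700, delta=-0.75,
            structure="outcome_only", mscenario="iii")
est = run_cell(cell, table, replicates=500, base_seed=7, m=10)
summary = summarize_frame(est[est.failure == ""], group_cols=("method",))
print(summary[["method", "mean_estimate", "relative_bias",
               "emp_se", "mod_se", "coverage"]].round(3))
```

```
   method  mean_estimate  relative_bias  emp_se  mod_se  coverage
0     CCA          0.368         22.690   0.151   0.147      92.0
1   MI-EG          0.299         -0.232   0.158   0.159      94.4
2  MI-ExC          0.300         -0.098   0.155   0.156      94.8
3   MI-NI          0.368         22.799   0.153   0.150      93.2
```

Reading: complete-case analysis and MI without interactions overestimate
θ1 by ~23% (mean 0.37 against a true effect of 0.30) because missingness
selects on the exposure and the effect-modifying confounder while their
imputation/analysis models ignore the interaction; their coverage slips
below the nominal 95%. MI with the exposure-confounder interaction and MI
by exposure group are approximately unbiased (|relative bias| < 0.3%, well
within the ±2.3% Monte-Carlo standard error at 500 replicates) with
near-nominal coverage. Model-based and empirical standard errors agree to
better than 0.01.

The same machinery is scriptable from the shell:

```sh
mistrat calibrate --out scenarios.json
mistrat simulate --prevalence 0.3 --structure outcome_only --scenario iii \
                 --delta -0.75 --reps 500 --m 10 --seed 7 --out results/cell
mistrat summarize results/cell/estimates.csv --out results/cell/summary.csv
mistrat report results/cell/summary.csv --out results/cell/fig.png
```

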