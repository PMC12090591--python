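# symptomnet

Regularized partial-correlation symptom networks for ordinal
patient-reported outcomes — built around the postoperative symptom burden of
non-small-cell lung cancer (NSCLC) patients assessed with the MD Anderson
Symptom Inventory (MDASI: 13 core symptoms plus 6 revised lung-cancer
items, each scored 0–10, 0 = absent).

Symptom research increasingly treats co-occurring symptoms as a *network*:
symptoms are nodes, conditional associations are edges, and the most
central node is the "core symptom" — the natural priority target for
intervention. This package implements that analysis end to end for ordinal
questionnaire data, for biostatisticians and outcomes researchers who want
a reproducible, tested version of the standard R workflow
(`qgraph::EBICglasso` + `bootnet`) in Python:

- **descriptives** — per-symptom prevalence (score ≥ 1) and severity
  summaries, questionnaire response rate, and the parameter-counting sample
  size planner: a *p*-symptom Gaussian graphical model estimates
  *p* + *p*(*p* − 1)/2 parameters, inflated for expected non-response.
- **network estimation** — Spearman correlation matrix → graphical lasso
  over a log-spaced penalty path → extended BIC selection:
  EBIC<sub>γ</sub> = −2*L* + *E* log *n* + 4 *E* γ log *p* with
  *L* = (*n*/2)[log det **K** − tr(**SK**)] and *E* the number of edges.
  Edge weights are the regularized partial correlations
  *w*<sub>ij</sub> = −*k*<sub>ij</sub>/√(*k*<sub>ii</sub>*k*<sub>jj</sub>).
  The coordinate-descent solver is implemented here (numba-accelerated) and
  cross-checked against closed forms, a slow independent optimizer, and
  scikit-learn.
- **centrality** — strength Σ<sub>j</sub>|*w*<sub>ij</sub>|, expected
  influence Σ<sub>j</sub>*w*<sub>ij</sub>, and closeness/betweenness on
  shortest paths with edge length 1/|*w*|.
- **stability** — nonparametric bootstrap CIs for edge weights, bootstrap
  difference tests for edge and node pairs, and the case-dropping
  correlation-stability (CS) coefficient: the largest proportion of
  patients that can be dropped while ≥ 95 % of subsamples keep a
  correlation ≥ 0.7 with the full-sample centralities (CS > 0.25
  acceptable, > 0.50 good).
- **synthetic data** — because the underlying patient data are not
  deposited, a latent Gaussian copula generator draws ordinal 0–10 scores
  from a *known* sparse precision matrix with per-symptom prevalence and
  mean severity calibrated to the published cohort table, so every stage is
  testable against ground truth.

## Worked example

The `analysis/` scripts run the whole study analogue; each one prints its
findings and writes tables under `results/`:

```bash
python analysis/01_simulate.py    # n = 367 patients x 19 symptoms
python analysis/02_describe.py
python analysis/03_network.py
python analysis/04_centrality.py
python analysis/05_stability.py
```

Output of the estimation and centrality steps on the simulated cohort:

```
selected lambda 0.1355 (gamma 0.5); 21 of 171 possible edges
strongest edges:
  S1--S2: +0.319
  S14--S15: +0.265
  S2--S6: +0.243
top-3 nodes by strength centrality:
  Shortness of breath    r_s=0.80 r_c=0.0000 r_b=22 EI=+0.80
  Pain                   r_s=0.72 r_c=0.0000 r_b=8  EI=+0.72
  Fatigue                r_s=0.56 r_c=0.0000 r_b=16 EI=+0.56
core symptom (highest strength): Shortness of breath

CS coefficient (strength): 0.50 (acceptable)
CS coefficient (expected_influence): 0.50 (acceptable)
```

Reading this: pain–fatigue (S1–S2) and cough–expectoration (S14–S15) are
the strongest conditional associations; shortness of breath carries the
largest summed edge weight, so it is the network's core symptom; closeness
is 0 here because the sparse EBIC-selected network leaves some rare
symptoms disconnected (the documented convention); and half the cohort can
be dropped before strength rankings degrade, i.e. the centrality ordering
is robust.

The same pipeline runs on real data from a scores CSV (one row per
patient, one column per symptom):

```python
from symptomnet import RunConfig, run_pipeline
run_pipeline(RunConfig(input_csv="scores.csv", out_dir="results/run", seed=1))
```

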