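# ionsig

Ion-channel expression profiling and correlation-weighted prognostic
signatures for tumor cohorts.

`ionsig` implements a complete discovery → signature → multi-cohort
validation workflow for expression-based prognostic markers, built around a
curated universe of 280 human ion-channel genes (24 channel families). It is
aimed at computational biologists studying how channel-gene expression
tracks clinical phenotype in breast cancer (p53 mutation status, estrogen/
progesterone receptor status, histological grade) and whether a grade-linked
gene panel stratifies patient survival.

## The method

**Screens.** Genes are screened against binary clinical status with a
two-tailed Welch *t*-test; a gene is differentially expressed when its
Benjamini–Hochberg adjusted *P* < 0.05 **and** its linear fold change
(ratio of geometric means, `2^(Δ mean log2)`) exceeds 1.25 in either
direction. Ordinal histological grade (1–3) is screened with the tie-aware
Spearman rank correlation; genes with adjusted *P* < 0.05 form the
signature. Ion-channel enrichment uses Fisher's exact test and gene-list
overlaps a cumulative hypergeometric tail.

**Risk score.** The signature carries each selected gene's discovery-cohort
correlation coefficient ρᵢ as its weight. A patient's risk score is

    s = Σᵢ ρᵢ (eᵢ − μᵢ) / τᵢ

where eᵢ is the patient's log2 expression of gene *i* and μᵢ, τᵢ are the
mean and SD of that gene **across all samples of the cohort being scored**
(standardization is always cohort-internal, so cohort scores are mean-zero
and the median sits near zero). Patients scoring strictly above the cohort
median are signature-positive; ties at the median are negative. Signature
genes missing from a cohort are simply skipped (no reweighting).

**Validation.** Kaplan–Meier curves, the two-group log-rank test, and Cox
proportional-hazards regression (Newton–Raphson on the partial likelihood,
Efron tie handling by default, Breslow switchable) — univariate, multivariate
against standard clinicopathological covariates, and stratified within
clinical subgroups. Cluster reproducibility of up/down-regulated gene blocks
is assessed with multiscale-bootstrap approximately-unbiased (AU) support
values.

**Synthetic cohorts.** A first-class generator produces cohorts with the
statistical structure the analysis assumes — a continuous latent
differentiation axis discretized into grade, planted signature genes with
signed grade/status effects, coupled clinical factors, and exponential
survival with hazard log-linear in a latent risk score — so the whole
pipeline is testable end to end without any downloads.

## Worked example

Simulate one discovery plus seven validation cohorts (n = 250 each, default
effect sizes), derive the signature from the discovery cohort, and validate
survival stratification everywhere:

```python
import ionsig as ig
from ionsig.pipeline import run_discovery, run_validation

study = ig.simulate_study(ig.default_study_configs(seed=42))
disc = run_discovery(study["DISCOVERY"][0])
print("signature genes:", len(disc.signature.genes))
rep = run_validation(disc.signature, [c for c, _ in study.values()])
print(rep.report[["cohort", "n", "events", "hr", "ci_low", "ci_high",
                  "logrank_p"]].round(3).to_string(index=False))
```

Output:

```
signature genes: 32
   cohort   n  events    hr  ci_low  ci_high  logrank_p
DISCOVERY 250     175 1.650   1.222    2.227      0.001
     VAL1 250     169 1.866   1.371    2.540      0.000
     VAL2 250     176 1.672   1.240    2.255      0.001
     VAL3 250     180 1.763   1.311    2.369      0.000
     VAL4 250     173 2.374   1.747    3.227      0.000
     VAL5 250     174 2.064   1.520    2.803      0.000
     VAL6 250     175 2.608   1.917    3.547      0.000
     VAL7 250     181 1.545   1.153    2.071      0.003
```

The grade screen recovered the 30 planted genes (plus two borderline false
positives) and the dichotomized risk score separates survival in every
cohort: signature-positive patients carry a 1.5–2.6-fold hazard of death,
with log-rank *P* ≤ 0.003 throughout. The last validation cohort is scored
with three signature genes masked, exercising the available-gene rule.

A command-line interface mirrors the library:

```bash
ionsig simulate --seed 2 --n-samples 250 --out sim
ionsig score sim_expression.tsv sim_clinical.tsv --out scores.tsv
ionsig validate sim_expression.tsv sim_clinical.tsv
ionsig fixtures-check
```

## Packaged reference tables

The package ships the published result tables it reproduces structurally:
the p53 differential-expression table (22 genes), the ER table (24 genes),
the grade-correlation table (30 genes, whose (symbol, ρ) pairs are the
packaged default signature), and the 280-gene ion-channel catalog. The
catalog is a reconstruction from standard HGNC nomenclature following the
published 24-family breakdown; the original supplementary gene list is not
redistributed here.

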