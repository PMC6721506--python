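# tksig — prognostic tyrosine-kinase signature discovery for TNBC

`tksig` is a reusable implementation of a prognostic gene-expression
signature discovery pipeline for triple-negative breast cancer (TNBC), the
breast-cancer subtype lacking estrogen receptor (ER), progesterone receptor
(PR) and ERBB2/HER2 expression.  It is aimed at computational biologists
working with pooled, multi-study bulk expression cohorts who want a fully
scripted, leakage-safe version of the classical learning/validation
signature workflow, together with a synthetic-cohort generator that makes
every step testable against known ground truth.

## What the pipeline does

1. **Harmonization.** Each study's log2 matrix is collapsed to genes (the
   most variable probe per gene is kept) and standardized per study against
   a luminal-A-like anchor subgroup: `z = (x − m_anchor) / s_anchor`.
   Because the anchors are a comparable reference in every study, this
   removes affine batch distortions without touching the outcome.
2. **Receptor calling and subtyping.** ER/PR/ERBB2 status is called per
   study from the bimodal expression of *ESR1*, *PGR* and *ERBB2* via a
   two-component Gaussian mixture (cutpoint at the posterior-0.5 crossing);
   samples negative for all three are the TNBC analysis subgroup.
3. **Signature discovery.** The TNBC set is split ~2/3 learning : 1/3
   validation, stratified by platform.  Each gene of an 86-gene tyrosine-
   kinase panel is screened in the learning set by univariate Cox regression
   on disease-free survival (Wald p ≤ 0.05); the screened genes enter a
   bidirectional AIC stepwise Cox search (AIC = −2·logL + 2k).  The final
   model's linear predictor `score_i = Σ_g β_g z_gi`, dichotomized at the
   median learning score, defines "low-risk" / "high-risk" classes; the
   frozen classifier (genes, β, cutoff) is then applied unchanged to the
   validation set and summarized by Kaplan–Meier curves, the log-rank test
   and the Cox hazard ratio (HR) of high- vs low-risk.
4. **Resampling null.** B random same-size gene subsets of the panel are
   pushed through exactly the same learning→classifier→validation recipe;
   the reported empirical p is the proportion of random signatures whose
   validation log-rank p beats the observed one (a smoothed
   `(1 + count)/(B + 1)` variant is reported alongside).
5. **Risk-class characterization.** Empirical-Bayes moderated t-tests
   (per-gene variances shrunk toward a moment-matched prior) with
   Benjamini–Hochberg FDR and fold-change filters yield the differential
   gene list; a centroid correlation-difference score
   `r(profile, centroid_high) − r(profile, centroid_low)` predicts class
   membership in held-out samples; Fisher-exact/Welch-t association tables
   relate the classes to clinical variables.

The survival core (Kaplan–Meier with Greenwood log-log bands, log-rank,
Newton–Raphson Cox with Efron tie handling) is implemented natively on
NumPy suffix sums so the resampling null's tens of thousands of Cox fits
run in minutes on one core.

## Worked example

```python
from tksig import (SimulationConfig, simulate_cohort, harmonize_cohort,
                   select_subgroup, split_cohort, TK_PANEL)
from tksig.pipeline import discover_signature, survival_data_for
from tksig.signature import evaluate_classifier

bundle = simulate_cohort(SimulationConfig(seed=11))      # 4 studies, 1640 samples
cohort, _ = harmonize_cohort(bundle.studies, bundle.clinical)
tn = select_subgroup(cohort, "TN", require_survival="dfs")
split = split_cohort(tn.matrix.columns, tn.clinical["platform"], seed=11)
model, screen = discover_signature(tn, list(TK_PANEL), split)
ev = evaluate_classifier(model, tn.matrix[split.validation_ids],
                         survival_data_for(tn, split.validation_ids, "dfs"))
print(len(tn.matrix.columns), model.provenance["n_screened"], model.genes)
print(round(ev["cox_high_vs_low"]["hr"], 2), f"{ev['logrank_p']:.2e}")
```

prints

```
775 8 ['ALK', 'EPHA4', 'FLT1', 'ITK', 'RET', 'TEK', 'ZAP70']
6.28 4.62e-27
```

i.e. 775 TNBC samples enter the analysis, 8 of the 86 panel genes pass the
univariate screen, the AIC search retains 7 of them (including all five
genes the generator planted with |β| = 0.8), and the frozen classifier
separates the held-out validation samples with a hazard ratio of 6.3 for
high- vs low-risk and a log-rank p of 5 × 10⁻²⁷.

The same analysis is available as a CLI over TSV/GMT/YAML artifacts:

```bash
tksig simulate   --config config.yaml
tksig preprocess --config config.yaml
tksig discover   --config config.yaml
tksig null       --config config.yaml --B 10000
tksig diffexp    --config config.yaml
tksig report     --config config.yaml
```

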