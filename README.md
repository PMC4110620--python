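# extremescan

Prognostic gene discovery from censored survival cohorts by extreme-group
logistic regression, concordance-AUC scoring, and revolving sliding-window
resampling.

## The problem

Expression studies of resected tumours (bulk microarray or RNA-seq) often
try to find genes whose expression in the primary tumour predicts clinical
outcome. The conventional route — split the cohort into expression
quantiles per gene, compare Kaplan-Meier curves with a log-rank test —
leans heavily on the accuracy of the survival times, which in practice are
right-censored, sparsely assessed, and contaminated by deaths unrelated to
the tumour. `extremescan` implements an alternative built for exactly that
situation: compare only the two ends of the survival spectrum.

The package is for computational biologists analysing cohorts with
per-sample survival (or recurrence) times and a genes × samples log-scale
expression matrix, and for methodologists who want the full pipeline —
selection, scanning, resampling, validation, baseline — as tested,
composable library functions.

## The method

1. **Stratify and select extremes.** After clinical stratification (e.g.
   early-stage cases only), sort cases by survival time and take two
   equal-sized groups: the *k* earliest deaths (events only) and the *k*
   longest survivors (long-followed censored cases allowed), plus extended
   pools of *m* ≥ *k* per side. Membership is purely rank-based — no
   arbitrary time cut-offs.

2. **Score each gene by pairwise concordance.** For gene *g* with values
   x₁ in the early class (n₁ cases) and x₀ in the survivor class (n₀
   cases), the accuracy is the area under the ROC curve, computed by the
   all-pairs counting rule

   AUC = ( #{(i,j): x₁ᵢ > x₀ⱼ} + ½·#{ties} ) / (n₁·n₀),

   i.e. the normalized Mann–Whitney U statistic, reported folded as
   max(AUC, 1−AUC). A univariable logistic fit P(early | x) =
   expit(β₀ + β₁x) supplies the slope sign and a likelihood-ratio
   (chi-square, 1 df) test of β₁.

3. **Resample group composition.** Windows of *k* cases slide over each
   ordered *m*-case pool against the fixed opposing core: sequentially
   (m−k+1 windows) or *revolving* with wrap-around (m windows, every case
   sampled exactly k times). The bidirectional design with m = 40, k = 20
   yields 80 comparisons per gene; a gene's score is the number of
   comparisons with folded AUC > 0.8. All-pairs designs (every early
   window × every late window, e.g. 30 × 30 = 900) and seeded bootstrap
   resampling are also provided.

4. **Validate.** Leave-one-out refits (genes × cases correctness matrix,
   clustered by prediction pattern), alternating split-half refits, and
   anchor-gene Pearson correlations.

5. **Baseline.** The expression-quantile Kaplan-Meier analysis the method
   competes with: per-gene log-rank chi-square across *q* quantiles, with
   an overlap report between the two rankings.

A synthetic cohort generator (`extremescan.simulate`) plants a correlated
signal-gene block, censoring, outlier cases, and optional advanced-stage
contamination, returning ground truth for every stage — the whole pipeline
runs with no downloads.

## Worked example

```sh
python examples/03_window_scan.py
```

```
genes with >= 20 hits of 80: 20
        hits  total  mean_auc
gene
G00001    80     80  0.985000
G00018    80     80  0.984375
G00002    80     80  0.983125
G00005    80     80  0.983125
G00016    80     80  0.983125
planted among them: 20
```

A 100-case cohort with 20 planted signal genes among 1000 is scanned with
the bidirectional revolving-window design. Each planted gene exceeds
folded AUC 0.8 in essentially all 80 window comparisons (`hits`), so the
hit-count ranking recovers exactly the planted block; noise genes almost
never clear the 20-of-80 bar. The other examples cover selection
(`01`), the concordance AUC and logistic fit (`02`), leave-one-out and
split-half validation with planted outlier cases (`04`), and the
Kaplan-Meier contrast under contamination (`05`).

The same pipeline runs from a shell via the thin CLI:

```sh
extremescan simulate --out sim --n-cases 100 --n-genes 1000 --seed 1
extremescan run-all --config config.yaml
```

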