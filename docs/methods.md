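# Methods

## Model and procedure

`extremescan` treats prognostic gene discovery as a sequence of two-class
comparisons. Cases are sorted by observed survival (or recurrence-free)
time; the analysis compares the *k* earliest events against the *k*
longest survivors and ignores the intermediate cases entirely. The
rationale: survival data in resection cohorts are right-censored and
noisy, and deaths unrelated to tumour progression blur any analysis that
uses the full time axis. Once a case is assigned to an extreme group, its
precise time is not used again — only ranks matter, so modest errors in
survival assessment do not propagate.

Each gene is scored alone. For expression values x₁ (early class, n₁
cases) and x₀ (survivor class, n₀ cases), the accuracy is the pairwise
concordance

  AUC = [#{x₁ᵢ > x₀ⱼ} + ½·#{x₁ᵢ = x₀ⱼ}] / (n₁·n₀),

which equals the normalized Mann–Whitney U statistic and the area under
the ROC curve of the corresponding univariable logistic model (the fitted
probability is monotone in x, and AUC is rank-invariant; a property test
asserts this equivalence on random fixtures). The reported accuracy is
folded, max(AUC, 1−AUC), because the counting rule is directionless; the
directional value and the logistic slope sign are retained so risk genes
and protective genes remain distinguishable. Ties receive half credit
(standard midrank convention; a design choice — the counting rule itself
does not address ties).

Significance per gene is the likelihood-ratio test of the logistic slope:
2·(ℓ_full − ℓ_null) referred to χ²(1). On 20-vs-20 comparisons, perfect or
quasi-separation is common; it is detected by disjoint class value ranges
and handled by a bounded maximum-likelihood refit with |slope| ≤ 15 on the
standardized covariate (a linear predictor spanning ±15 puts fitted
probabilities within 3·10⁻⁷ of 0/1, so the capped likelihood is
numerically at its supremum while coefficients stay finite). Such models
carry a `separation_flag`; their AUC is unaffected (rank-based) and their
LRT uses the capped likelihood. Ordinary fits go through statsmodels'
`Logit`.

## Window resampling

A single extreme-group comparison can hinge on which cases happened to
fall in the groups. The scan therefore re-runs every gene over families of
alternative group compositions drawn from extended, ordered pools of m
cases per side (default m = 40, k = 20):

- **sequential**: ranks i…i+k−1, giving m−k+1 windows (21 for 40/20) —
  simple, but mid-ranked cases are over-sampled;
- **revolving**: m wrap-around windows (indices mod m), each case sampled
  exactly k times — the default, equalizing case usage while preserving
  the survival ordering;
- **bootstrap**: B seeded random k-subsets, for cohorts whose ordering is
  less trustworthy (default B = 200).

The bidirectional design runs moving early windows against the fixed
survivor core and vice versa (2m = 80 comparisons); the all-pairs design
crosses two window families (e.g. 30 × 30 = 900 comparisons) and returns
the full per-gene AUC distribution for distribution-level tests
(two-sample Kolmogorov–Smirnov, via scipy). A gene's score is the number
of comparisons with folded AUC above a threshold (default 0.8, the
conventional bar for an excellent discriminatory model); ranking is by
hits, then mean AUC, then gene id. Because hit counting only needs the
AUC and the AUC of the fitted model equals the raw-value AUC, the scan
computes window AUCs directly from ranks rather than fitting m logistic
models per gene — identical results, orders of magnitude faster.

## Selection, filtering, validation, baseline

**Selection.** Stratification filters (stage set, adjuvant-therapy flag,
arbitrary subtype flags) run before ranking. The early pool takes
event-observed cases in ascending time order after optionally skipping the
first few events (perioperative deaths); the late pool takes all cases in
descending time order — long-followed censored cases are legitimate
survivors. Ties break events-first (early side) then stable input order.
The extended pools must be disjoint and time-separated; group-size
equality is enforced, never silently relaxed.

**Gene filter.** A gene enters the scan if its interquartile range across
all samples is ≥ `iqr_min` (default 1.0 log unit) *and* more than
`floor_fraction` (default 0.25) of its values exceed `floor_value`
(default 6.6, an adequate-expression floor on the log2 scale). Quartiles
use linear interpolation (type 7). On standard-score data the floor is
meaningless and only the IQR criterion applies. The filter is monotone in
both thresholds and order-invariant.

**Validation.** Leave-one-out refits every gene's model n times with one
case held out, classifying at probability 0.5; row means give per-gene
held-out accuracy, column means a per-case consensus that exposes cases
defying most gene models. Genes are clustered on their correctness vectors
(Hamming distance, average linkage — our choice; nothing in the procedure
dictates one). Split-half validation alternates cases by within-class
rank into odd/even halves; the two half-pairings (odd-vs-even and
crossed), each evaluated in both train/test directions, give four held-out
AUCs per gene. The held-out AUC is directional, with the direction taken
from the trained slope sign, so a model trained on the wrong direction
scores below 0.5 — training genuinely matters. (The alternating split is
one reading of "every other case" splitting; a literal within-class-only
split cannot train a two-class model.)

**KM baseline.** Cases are split into q near-equal expression quantiles
per gene (rank-based, ties broken by stable sample order) and compared by
the standard multi-group log-rank (Mantel–Cox) statistic on q−1 df — the
conventional reading of "a chi-square test of equality between quantiles".
Single-gene analyses use lifelines; genome-wide ranking uses an array
implementation of the same statistic (asserted equal to lifelines to
1e-8 on random instances) for speed. Quantiles with zero events are
flagged. `compare_methods` reports top-n overlap and Jaccard at several
depths between the scan and KM rankings.

## Synthetic cohorts

The generator draws two equal latent classes: early events with
exponential survival (mean 8 months, event observed) and survivors with a
guaranteed 60-month follow-up gap plus an exponential tail (mean 40
months), a `censor_rate` fraction (default 0.3) censored uniformly over
follow-up. This is deliberately the *minimal* structure the method
consumes — ordering and class membership — not a realistic disease model.

Signal genes load on one shared latent factor per case plus the class
shift `effect_delta` (default 2.5 noise sd, higher in survivors — the
direction an infiltrating-immune signal would take; configurable).
`signal_block_rho` (default 0.75) is the **target marginal correlation**
between signal genes over the pooled two-class cohort, matching how
anchor-gene correlations are reported in practice; the residual
within-class correlation is derived as ρ_resid = ρ(1+d²/4) − d²/4 and the
spec errors if the class shift alone already exceeds the target.
`outlier_flip_count` inverts the expression-class linkage of the most
extreme-ranked cases (so the flips land inside any core group), providing
ground truth for consensus-misprediction checks.

Optional contamination models an advanced-stage admixture: cases that die
on the early-class time scale while carrying survivor-like signal
expression (their progression is driven by other biology), plus a block
of progression-like genes elevated only in them. This is the structure
that erodes whole-cohort quantile analyses but is removed by clinical
stratification; the method-contrast test uses a modest 1.5-sd signal
(folded AUC ≈ 0.85, the realistic regime), 30 contamination cases and 100
progression genes at +2.5 sd.

What passing tests on these cohorts do **not** show: robustness to probe-
level artifacts, batch effects, non-Gaussian expression distributions,
heteroscedastic noise, or confounded clinical covariates — none of which
the generator emulates.

## Numerical choices and degenerate inputs

- AUC via midranks (`scipy.stats.rankdata`), exact for ties; vectorized
  across genes for scans.
- Constant covariate → non-informative model: slope 0, AUC 0.5, p = 1,
  flagged.
- LRT p-values clipped away from 0 at the smallest positive double; the
  statistic is floored at 0 against round-off.
- Zero-variance sample columns make standard-scoring impossible and raise,
  naming the sample.
- Quantile assignment gives remainder cases to the lowest-expression
  groups; deterministic under ties.
- One root seed per run; the bootstrap window generator and the synthetic
  generator take explicit seeds.

## Scale and defaults

Default problem sizes — 100-case cohorts, 2000-gene scans, 80-comparison
bidirectional designs, 2000-gene KM rankings — were chosen so that every
analysis completes in seconds on one CPU while keeping the statistical
regime of the target studies (group size 20, thousands of genes, ~30%
censoring). Full-array studies (≈ 10⁴ genes after filtering) scale
linearly and remain minutes on one CPU.

## Known limitations

- Univariable models only; no multivariable or penalized signatures (a
  deliberate scope decision, mirroring the method's design).
- No competing-risks handling and no imputation of missing times.
- The null distribution of window hit counts is heavy-tailed because
  overlapping windows are strongly dependent: in a 2000-gene null scan a
  few genes (~0.2%) reach folded AUC > 0.8 by chance and then hit in many
  correlated windows. Hit counts are a ranking device, not calibrated
  p-values; genome-scale inference should use the LRT p-values (which are
  calibrated — type-I error ≈ 0.05 at nominal 0.05) or permutation.
- Probe-to-gene collapsing assumes complete matrices (no per-array missing
  probes).
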