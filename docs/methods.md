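# Methods

## Scoring model

The screen is a reference-interval exceedance count, not a fitted
classifier. Let *x*ᵢₘ be participant *i*'s creatinine-normalized
concentration of metabolite *m* (µmol analyte / mmol creatinine; ratio
pseudo-metabolites such as Phe/Tyr are unitless and bypass the division).
The typically developing (TD) group defines, per metabolite, the full
observed span [min, max] of its normalized values — "0–100% of the TD
range". Elevation markers score a point strictly above the maximum;
depletion markers (N-formyl methionine is the one shipped) strictly below
the minimum. Equality at a bound scores 0: a value seen in TD is, by
definition, inside the TD range, and ties have measure zero for continuous
assays. The MDM Total Score is the per-participant point count, and
screen positivity is score ≥ k with k = 1 by default (one extreme
metabolite suffices under the dysbiosis hypothesis; k is a parameter).

Two analytic consequences structure the validation:

* **In-sample tautology.** Ranges built from the very TD set being
  evaluated cover every TD value, so each TD score is 0 and specificity is
  exactly 100%. Reports therefore label the evaluation mode (`insample`
  vs `deploy`) prominently, and ranges are designed to be frozen JSON
  artifacts applied to later samples.
* **Order-statistic leakage.** For exchangeable continuous draws, a fresh
  unaffected sample beats the maximum of n references with probability
  1/(n+1). With ~19 metabolites and n = 47 this compounds to a ≈ 1/3
  chance that a null participant exceeds *somewhere* — the inherent
  false-positive floor of a deployed max-based screen, and the quantity
  the calibration tests pin down.

## Univariate statistics

Group means, percent difference 100·(mean_A − mean_T)/mean_T, Welch's
unequal-variance t-test on raw and on square-root-transformed values
(urinary concentrations are strongly right-skewed; the transform tempers
the heavy upper tail), Benjamini–Hochberg step-up q-values flagged at
q < 0.05, the Mann–Whitney AUROC P(X>Y) + ½P(X=Y) oriented so > 0.5 means
the affected group is stochastically larger, the fraction of affected
participants outside the TD range, and the pooled below-LOD fraction.
Standard tests are delegated to scipy/statsmodels and cross-checked in the
test suite against hand-written formula oracles. Report formatting rounds
percent columns to integers, AUROC to two decimals, p to two significant
figures; underlying tables keep full precision. The quantitative-style
report can omit q-values (`include_q=False`) where no multiplicity
correction is intended. Correlations are pairwise-complete Pearson by
default (Spearman by flag); constant columns yield NaN and a warning.

## Missing data and censoring

Censored (below-LOD) and missing cells are distinct. Censoring policies:
`half_lod` (impute LOD/2 before normalization; the default for
statistics), `zero`, and `exclude`. Flags survive normalization
unchanged, so censored counts are conserved and reportable. Because an
imputed low value can never exceed a TD maximum, elevation scoring is
insensitive to the choice; for the single depletion marker the choice
matters and is therefore explicit. Missing cells are never imputed: they
are dropped pairwise from statistics and score 0 in indicators (logged).

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with a truth
channel for oracle tests:

* **Baseline** raw concentrations are log-normal, i.i.d. across
  participants (default log-sd 0.8; log-mean ln 10 in arbitrary raw
  units). Non-elevated affected participants are exchangeable with TD.
* **Creatinine** is log-normal (ln 8 mmol/L ± 0.45 log-sd, plausible for
  children of 2–11 years); all of a participant's normalized values share
  it, inducing the mild cross-metabolite correlation real urine shows.
* **Elevations**: per affected participant and metabolite, an event fires
  with probability pₘ; a fired event multiplies the baseline by a fold
  drawn log-uniformly from 100–1000× (the reported magnitude of extreme
  microbial elevations; depletion markers divide instead). With these
  folds a fired event manifests as an exceedance with probability ≈ 0.98.
* **Family coupling**: with probability c (default 0.75) an event
  consults a per-participant per-family shared uniform instead of its own
  draw — a comonotone mixture that preserves every marginal pₘ exactly
  while making within-family events co-occur. c was fixed once by a
  simulation sweep against the reported family-level co-elevation
  fractions (~64% tryptophan, ~60% phenylalanine; achieved ≈ 0.72/0.55).
  A single per-family factor cannot also reproduce the reported
  *cross*-family overlap (56% both), which is a known limitation.
* **Censoring**: an optional per-metabolite LOD at a quantile of the
  pooled marginal; censored cells are blanked, flagged, and the realized
  LOD written into the returned panel.
* **Reproducibility**: every draw comes from a labelled PCG64 substream
  (`SeedSequence([seed, sha256(label)])`), so identical seeds give
  bit-identical cohorts and adding a metabolite never reshuffles the
  draws of existing ones.

### Calibration

`calibrate_to_table` inverts the observed exceedance fraction into an
event probability. The observed fraction mixes true elevations with
order-statistic leakage, so the analytic first guess
p₀ = (t − leak)/(1 − leak), leak = 1/(n_TD + 1), is refined by three
Monte-Carlo fixed-point rounds (40 cohorts each, fixed internal seed;
achieved-vs-target fractions are logged). Targets at or near 1 are
infeasible with a finite fold range and raise an error. The package's
reference study condition — `default_semiquant_config` — calibrates the
19-metabolite panel to the published per-metabolite exceedance fractions
at 50 affected / 47 reference participants; under it the expected MDM
Total Score is the sum of achieved fractions (≈ 3.8, by linearity of
expectation) and mean sensitivity sits at ≈ 0.90.

### What passing tests do and do not show

The generator realizes exactly the assumptions the method leans on:
exchangeable continuous baselines and multiplicative spikes. Passing the
calibration suites shows the pipeline's arithmetic and the order-statistic
theory are right *under those assumptions*. Real cohorts add what the
generator deliberately omits — age/diet/batch structure, assay drift,
non-lognormal tails, correlated baselines beyond shared creatinine, and
misidentified compounds — so synthetic sensitivity/specificity say nothing
about clinical performance; they validate software, not the screen.

## Fisher discriminant analysis

The two-class Fisher direction solves (S_W + λI)w = μ₁ − μ₀ with S_W the
pooled within-class scatter. λ = 0 unless S_W is ill-conditioned
(condition number > 1e10), in which case λ = 1e-6·trace(S_W)/p is applied
and logged; an explicit λ = 0 on singular scatter raises an error advising
a ridge. Projections are oriented by the training-class means so the
affected class scores higher — fixed per fold in leave-one-out
cross-validation, where each participant is scored by a model fitted on
the remaining n−1 and the AUROC is computed on the pooled held-out scores
(per-fold AUROC is undefined for single observations). The combination
search enumerates all k-subsets of the feature pool lexicographically
(deterministic; a configurable budget guards C(n,k) blow-up), filters on
in-sample AUROC > floor, and optionally attaches LOOCV AUROC. Default
feature preprocessing is the square-root of the normalized values,
matching the univariate transform; log1p is available.

## Numerical and design choices

* Strict inequalities at range bounds; see scoring model above.
* Welch's test with both samples constant and equal returns t = 0, p = 1
  by convention (logged) rather than NaN.
* Percent difference requires a positive TD mean; otherwise flagged
  undefined, never 0.
* Classification ratios with empty denominators (e.g. PPV with no
  positive calls) are reported as absent, not 0.
* CSV dialect: comma-separated UTF-8, `.` decimal, one header row;
  `<LOD` and the empty string are the only special tokens. Floats are
  written as shortest round-tripping repr, so write→load is the identity.
* Reference ranges, scores, classification reports and run logs are JSON/
  CSV; every pipeline run records config, panel hash and library versions
  sufficient to re-execute it.

## Problem sizes

Monte-Carlo checks use 30–200 replicate cohorts (study scale, 97 × 19) or
100 cohorts × 100 independent metabolite trials for the order-statistic
law (creatinine variation disabled there so trials are independent);
these sizes put 3-SE Monte-Carlo bands well inside the asserted
tolerances while keeping the full suite under a minute.

## Limitations

* The max-based range is extremely sensitive to a single outlying
  reference child; no trimming/percentile option is currently offered
  because the method under study is explicitly min–max.
* The generator's family coupling reproduces within-family co-elevation
  only (see above).
* No age, sex, diet or batch effects are modelled; deployment-mode
  drift across laboratories is out of scope.
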