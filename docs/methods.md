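# Methods

## Data model and filtering

The interchange format is a plain delimited "ADAT-lite" table: metadata
columns (sample id, genotype, model, sex, cohort, age in months) followed by
one column per aptamer. Input may be raw-scale RFU (strictly positive,
log2-transformed on read — SomaScan deliverables are raw-scale) or already
log2; an explicit `scale` flag decides, defaulting to raw. All analysis is
on log2 RFU.

Panel filtering applies two rules: aptamers without a gene symbol are
dropped, and for a symbol measured by exactly one human-target and one
mouse-target aptamer the mouse-specific aptamer is kept. The pair rule is
deliberately narrow — symbols with three or more aptamers are all retained
and flagged in the filter report, because no principled resolution exists
without manual curation. Compound symbols ("UBE2N|UBE2V1") are atomic
strings here; enrichment splits them into components, and the clock drops
them as gene-level-ambiguous. Filtering is idempotent.

## Per-aptamer differential expression

Each aptamer gets an independent (optionally weighted) least-squares fit on
a treatment-coded design with intercept. The global analysis pools both
models with a wildtype-reference genotype contrast plus model, sex and
cohort covariates; model-specific analyses subset samples and the same spec
applies because categorical terms with a single observed level are dropped.
Cohort enters as a fixed covariate both in weight estimation and in the
fit, which covers batch blocking and batch adjustment with one mechanism.
Rank-deficient designs (e.g. cohort confounded with genotype) raise an
error naming the collinear columns.

**Precision weights.** A lowess curve (frac = 0.5) of the quarter-root
residual variance against mean log2 abundance is interpolated at each
observation's fitted value; weights are the inverse fourth power,
normalized to mean 1. When the fitted linear trend moves the quarter-root
sd by less than 5% of its median across the abundance range, the trend is
considered flat and unit weights are returned — log-scale protein data are
often near-homoscedastic, and near-unit noisy weights would only add
variance. Fewer than 50 aptamers also yields unit weights (with a warning):
the trend cannot be estimated stably.

**Moderation.** The scaled-F model for residual variances is fitted by
method of moments on log s²: with e_g = log s²_g − ψ(d/2) + log(d/2), the
prior degrees of freedom solve ψ′(d₀/2) = Var(e) − ψ′(d/2) via Newton
inversion of the trigamma function, and s₀² = exp(mean(e) + ψ(d₀/2) −
log(d₀/2)). Non-positive excess variance, or a failed inversion, falls back
to d₀ = ∞ (full shrinkage to the pooled variance; moderated t referred to a
normal). Posterior variances s̃² = (d₀s₀² + d·s²)/(d₀ + d); p-values from
t on d₀ + d degrees of freedom. Zero residual variance (degenerate
fixtures) reports t = signed infinity, p = 0, with a flag. Moderation and
weights are independently switchable and both default on.

FDR is Benjamini–Hochberg (step-up, monotone, ties get equal adjusted
values); DE means FDR < 0.05. The sex:genotype interaction is tested as the
product of the main-effect codings, with its own BH adjustment.

## Enrichment

Query = gene-level collapse of the top-k (default 500) aptamers ranked
ascending by (fdr, p, −|log2FC|, aptamer_id); the id key makes the order
total, and because BH is monotone the fdr-first comparator differs from a
p-ranking only at ties. Background = genes on the filtered panel. Sets with
fewer than 5 background genes (default) are not tested — single-gene sets
produce degenerate tails. The upper tail P(X ≥ k) is summed from log-pmf
values to avoid underflow. BH across tested sets; sets below FDR 0.1 are
flagged as reported; fold enrichment (k/n)/(K/N) is reported for all.

## Concordance

Cross-model agreement uses the union of aptamers significant (FDR < 0.05)
in either model-specific comparison: Pearson and Spearman correlations and
the OLS slope of model-B log2FC on model-A log2FC (with intercept), so the
slope reads as attenuation of B relative to A. The physiological-aging
comparison runs young-window vs old-window DE (defaults 3–6 and 18–21
months, FDR 0.1) on the reference cohort with a sex covariate, recomputes
progeroid DE on the same gene-level feature space at the same FDR, and
reports gene-level overlap; the shared percentage is relative to the
healthy-aging DE set.

## Aging clock

Features are genes measured by exactly one aptamer in each of the two
panels. Per iteration (seeded base_seed + i): a uniformly sized
without-replacement subset of the study's wild-type controls (at least
`min_train_controls`, leaving at least `min_infer_controls`) joins the full
reference cohort as training data; a binary batch feature (reference = 0,
study = 1) is appended, standardized and penalized like any other feature
(an unpenalized-batch mode exists; penalizing it matches the default
behavior of standard L1 solvers). "At least three wild-type controls" is
read as ≥ 3 from the combined control pool in each of training and
inference. Features are standardized with training-set statistics only.

The LASSO is solved by cyclic coordinate descent on the Gram system with
soft-threshold updates, an unpenalized intercept (y centered internally),
and convergence when the largest absolute coefficient change in a sweep
falls below 1e-7; full sweeps alternate with active-set sweeps. λ is chosen
by 10-fold CV (CV-minimum rule; one-standard-error rule by config) over a
geometric path of 100 values from λ_max down to 1e-3·λ_max. Path fits used
only for CV scoring run with a looser, y-scaled tolerance and a 1000-sweep
cap per λ — with more features than training samples the near-zero end of
the path saturates and exact convergence there is both slow and irrelevant
to penalty selection; the selected λ's final model is always re-solved at
the tight tolerance.

Age gap := predicted − chronological (positive = acceleration); group gaps
are medians over the pooled predictions of all iterations. Selection
frequency = fraction of clocks with a nonzero coefficient for a gene,
reported at ≥ 30% by default; the batch feature is excluded from the table.

## Synthetic cohorts

The generator reproduces the study design it is meant to exercise: a
reference cohort of 81 mice with ages uniform on [1, 30] months; four
case/control groups of 10 mice (5 male / 5 female), sampled at fixed ages
of 4.75 (Lmna pair) and 6.5 months (Zmpste24 pair) to mirror the study's
collection ages. Per-aptamer truth — baseline ~ N(10, 1.5²) log2 RFU, a
15% fraction of age-associated proteins with slopes ~ N(0, 0.05²) log2 RFU
per month (20% of them with an added sine bend whose amplitude is on the
order of a quarter of the linear span), genotype effects on 25% of
aptamers with magnitude |N(0, 0.8²)| and 85% negative signs, Zmpste24
effects = 0.47 × Lmna effects, five sex:genotype interaction proteins of
±1.5 log2 RFU, and per-cohort batch offsets ~ N(0, 0.2²) — is drawn from a
child stream of the seed shared by both cohort generators, so reference and
study cohorts agree on the underlying biology. The DE fraction and sign
balance mirror the study's reported proportions (about a third of aptamers
changed, 85% down); the batch-offset scale has no reported anchor and was
fixed once at a magnitude comparable to the residual noise. Noise is
homoscedastic Gaussian (sd 0.3 log2 RFU) by default, with a mean-dependent
mode (variance doubling across the baseline range) to exercise the
precision weights.

Age acceleration is injected by evaluating each age trajectory at
age + Δ_model (defaults 10 and 7 months), which makes the clock's age-gap
estimand equal Δ by construction — the point of the parameter-recovery
tests. One consequence worth knowing: the model-specific fold changes then
mix two cross-model ratios, the genotype-effect attenuation (0.47) and the
age-shift ratio (7/10); a recovery experiment for the attenuation alone
therefore switches Δ off, otherwise the regression slope estimates a
mixture that is no single injected parameter.

What the generator does not emulate: raw fluorescence physics, plate
effects, assay normalization artifacts, heavy-tailed or correlated noise
across proteins, and real biological covariance structure. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generative model, not performance on real plasma data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the stochastic checks at desk
scale chosen once: null calibration on 2000 aptamers (20 vs 20 samples);
interaction and attenuation checks on 300–400 aptamers over 20 seeds;
clock recovery on ~520 gene features with 50 resampling iterations; the
structural 200-iteration ensemble on ~80 features. The coordinate-descent
kernel is JIT-compiled with numba. Ties in BH are handled by stable
sorting; the hypergeometric tail and the λ path are computed in log/
geometric space; trigamma inversion uses Newton steps from x = 0.5 + 1/y.

## Known limitations

- The real study's headline numbers (2475 DE aptamers; 0.87/0.75/0.47;
  10- and 7-month gaps) depend on the deposited study data and the external
  reference cohort and are not reproduced here; the pipeline reproduces the
  procedures and the in-paper arithmetic, and demonstrates parameter
  recovery on synthetic cohorts.
- ADAT-native parsing is out of scope; tables must be exported to the
  documented CSV/TSV layout.
- Fixed-effect cohort adjustment only; no mixed models or surrogate
  variable inference.
- The λ-selection rule, feature standardization and batch-penalty choices
  for the original clock are not published; they are exposed as
  configuration with the defaults documented above.
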