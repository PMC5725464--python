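# Methods

## Setting and model

`armonize` reconciles differential-expression (DE) profiles produced by
several RNA-Seq callers over the same two-condition experiment. The raw
material is one table per method — gene id, log2 fold change, p-value,
FDR-adjusted q-value — merged into a gene × method log2FC matrix **Y**
with an explicit missing mask (a cell is missing when that caller did not
report that gene). All modeling operates on the log2FC scale; the package
deliberately does not re-run or re-implement any DE caller.

The working assumption behind the ensemble is a shared-signal observation
model: each well-behaved method observes a common per-gene effect θ_g
through its own channel,

    y_gm = a_m + b_m · θ_g + ε_gm,   ε_gm ~ N(0, σ_m²),

with method-specific bias a_m, gain b_m and noise σ_m. A method whose
profile does not load on the shared signal at all (the "outlier method")
contributes y_gm independent of θ. Under this model each method's profile
is linearly predictable from the others — except the outlier's, which is
exactly the property the ensemble uses to exclude it.

## Alternating regression (ARM)

Each method serves in turn as OLS response with the remaining methods as
regressors (intercept included by default). One rotation proceeds as:

1. **Usable rows.** Under the default `complete_case` policy, rows where
   the response and all current regressors are observed; under
   `mean_fill`, all rows where the response is observed, with missing
   regressor cells imputed by that regressor's mean over the domain.
   A fit requires at least (#regressors + 2) rows; designs collinear to
   machine precision raise a rank-deficiency error naming the dependent
   columns (pivoted QR).
2. **Predictability gate.** The full model must pass its overall F-test at
   level α (default 0.05). A response that no linear combination of the
   other methods explains is declared *non-predictable* outright. This
   global gate exists because the question "is this profile predictable at
   all?" is a single hypothesis; deciding it by scanning individual
   coefficients inflates the false-predictable rate several-fold.
3. **Backward elimination.** The regressor with the largest
   non-significant p-value is dropped and the model refitted until every
   retained coefficient is significant. Significance is judged against
   α/m (Bonferroni over the m initial candidate regressors; configurable
   to uncorrected α via `multiplicity="none"`). With the uncorrected
   threshold, four correlated candidate regressors plus survivor-selection
   bias across refits declare a pure-noise response predictable roughly
   one time in five — an error rate we consider unacceptable for an
   exclusion rule whose purpose is robustness; the corrected threshold
   brings it to ~2% (measured over 200 null replicates). A `single_pass`
   mode (fit once, report significance, no refit) is kept for comparison.
4. **Fitted values** come from the final refit, over the rows usable for
   the retained regressors (this domain re-expands as regressors leave).
   Non-predictable responses return an intercept-only record.

**Ensemble averaging.** Fitted profiles of the predictable rotations are
averaged per gene (mean and median both emitted; the mean feeds selection
by default). Non-predictable responses contribute no fitted values but
remain as candidate regressors inside the other rotations, where
non-significant coefficients neutralize them. Genes covered by no included
rotation are absent from the ensemble profile.

**Coreset selection.** The rotation-averaged profile is thresholded with
Tukey boxplot fences [Q1 − k·IQR, Q3 + k·IQR]. Quartiles use linear
interpolation of the order statistics at positions (n−1)·{0.25, 0.75}
(the numpy default; Tukey hinges differ slightly and can be compared
externally). Fence membership is strict: a value exactly on a fence is not
selected. k = 3 is the conservative default for ARM predictions; k = 1.5
gives standard whiskers. Selection is scale-equivariant: multiplying all
profiles by c > 0 scales fitted values and fences by c and leaves the
selected set unchanged.

This module is fully deterministic; all randomness lives in the generator.

## PCA alternative

Complete-case genes (observed in every method) are the observations,
methods the variables. Columns are centered (optionally unit-scaled;
unscaled covariance PCA is the default because log2FC columns share a
unit), PC1 is taken from the SVD, and per-gene PC1 scores are thresholded
with the same boxplot rule at k = 1.5. The score sign is fixed so the
method with the largest |loading| loads positively, making output
reproducible across linear-algebra backends. "One value per gene" is the
only reading of PC-based thresholding that supports a per-gene selection,
which is why scores (not loadings) are thresholded. No imputation is done
before the SVD.

## Consensus algebra

Per-method significant sets use q ≤ q_max (inclusive, default 0.05) and
optionally |log2FC| > lfc_min (strict), matching the conventional
"q ≤ 5%, log(FC) > 1.2" style of cutoff; genes lacking a q-value are never
significant. The union of sets is decomposed into Venn regions keyed by
the exact subset of methods calling each gene; region counts conserve the
union by construction. Fold changes of multiply-called genes are averaged
over the detecting methods' observed values, and direction agreement is
flagged (a log2FC of exactly 0 carries no direction and renders a gene
discordant).

## Expression inclusion filter

A gene enters downstream analysis only if it exceeds FPKM 1 (strictly) in
at least ⌈0.10 · n⌉ samples AND exceeds 10 reads (strictly) in at least as
many, with the conjunction required within every condition group by
default (`per_group=False` evaluates pooled; the group-wise reading of "in
both conditions" is the stricter and default one). The ceiling guards
against float artifacts (0.1 × 30 must quota 3, not 4). Thresholds are
strict and the quota inclusive — a gene at FPKM exactly 1.0 everywhere is
excluded.

## Pseudogene → parental gene

Parents are assigned from 12-column blast-tabular hit files: per
pseudogene, the hit with minimum e-value wins; ties break by maximum
bitscore, then lexicographically smallest subject id — the two extra tie
levels are this package's addition for determinism under input reordering.
An optional transcript→gene map collapses subjects before selection.
Winning identity below 90% sets a low-similarity flag that downstream
consumers should treat as a caveat (read-level evidence for such pairs is
weaker). Correlations between pseudogene and parent log2FC are computed
per expression-level quantile stratum (Pearson or Spearman, plus the OLS
slope); strata with fewer than 3 pairs or zero variance are flagged
degenerate rather than computed.

## Synthetic generator

The generator emits exactly the structure the ARM assumes, because that is
the hypothesis under test: θ_g = 0 for nulls and |θ_g| ~ U(2, 4) with
random sign for a fraction π_DE = 0.10 of genes; per-method noise
σ_m ~ U(0.3, 0.8); a_m = 0, b_m = 1; independent per-cell dropout at 15%;
and one outlier method emitting N(0, 2²) independent of θ. Defaults of
5,000 genes × 5 methods keep every statistical check well-powered while
running in seconds. Effect magnitudes ≥ 2 sit far outside the null
ensemble spread, so whisker selection of true DE genes is meaningful
without tuning. Method tables derive z = y/σ_m per observed cell,
two-sided normal p-values, and Benjamini–Hochberg q-values within each
table; the BH step-up is implemented in-repo (and cross-checked against
statsmodels in the tests) because fixtures and significance tests need it
standalone. Rows that dropout would leave fully missing get one uniformly
chosen cell re-exposed so the matrix invariant holds. Everything is a pure
function of (config, seed).

What the generator does **not** emulate: count-level sampling noise,
library-size and normalization artifacts, correlated missingness (real
callers drop genes systematically, e.g. by expression level, not at
random), inter-gene correlation, and method biases that depend on effect
size. Passing recovery tests therefore demonstrates that the ensemble
machinery behaves as designed under its own model — not that it will reach
the same recall on any particular real cohort.

## Evaluation configuration

The recovery checks (acceptance suite and `scripts/acceptance.py`) run the
ensemble with `missing_policy="mean_fill"` and k = 1.5. With
`complete_case` and 15% dropout, every included rotation's fitted domain
collapses to the genes observed in all four signal methods (≈ 0.85⁴ ≈ 52%
of genes), which caps recall against the full truth at ≈ 0.55 regardless
of ranking quality; the imputing policy extends predictions over each
response's observed domain (≈ 100% coverage) and is the configuration
under which whole-genome recall is a meaningful quantity. Measured under
the default study conditions: mean recall ≈ 0.97, precision ≈ 0.94 over
20 seeds; the outlier method is excluded in 96–100 of 100 replicates
across evaluation seeds.

## Numerical choices and degenerate inputs

- OLS via statsmodels; coefficient p-values are two-sided t-tests with
  residual degrees of freedom. Coefficients agree with a normal-equations
  solve to ~1e-11 relative error on random full-rank instances.
- Quartile convention: linear interpolation at (n−1)·q; IQR = 0 (constant
  vector) selects nothing.
- A perfect (zero-residual) fit makes every coefficient trivially
  significant; elimination behavior on such degenerate inputs is not
  meaningful and the tests perturb exact linear combinations accordingly.
- Zero total variance in the PCA submatrix, fewer than 4 finite values for
  fence selection, fewer than (p + 2) usable rows for a fit, and empty
  reference sets for percentage comparisons all raise typed errors (config
  / data / numerical), which the CLI maps to exit codes 2 / 3 / 4.
- Annotation-version percentages round half-up at two decimals so printed
  splits like 82.45 / 17.55 are reproduced exactly; the two percentages sum
  to 100.00 within one rounding ulp.
- The biotype table reports both conventions for parental genes: an
  overlapping roll-up row alongside true-biotype counts, and a strict
  partition where parental genes occupy their own row.

## Limitations

- Linearity: the ensemble is a linear reconciliation; systematic
  non-linear distortions between methods (e.g. fold-change compression at
  high expression) are absorbed into noise, not modeled.
- Mean-imputation attenuates coefficients slightly when many regressor
  cells are missing; with dropout well above ~30% per method,
  `complete_case` fits with reduced coverage become preferable.
- The quartile convention and the strict-fence rule make selections near a
  fence sensitive at the last ulp; ties exactly on a fence are excluded by
  design.
- Penalized regression (ridge/LASSO), isoform-level analysis and
  mixed-effects extensions are out of scope.
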