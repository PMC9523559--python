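# Methods

## The model

For individual *k* and mtDNA position *i*, deep sequencing yields read
counts A (reference allele, from the rCRS FASTA) and B (the cohort-wide
second most frequent allele). The heteroplasmy response is the
pseudocounted log-ratio

    y_ik = log2((B_ik + 2) / (A_ik + 2)).

The pseudocount keeps y finite for individuals carrying only the
reference allele; at ~3500× coverage it shifts estimates by well under 1 %
(the attenuation it induces on fitted slopes is quantified below). Each
phenotype — a pairwise metabolite concentration ratio MR_j, or a single
concentration for the P-gain comparison — enters an ordinary linear model

    y_ik = β0 + β1 MR_jk + β2 age_k + β3 sex_k + β4 Cov_ik + β5 batch_k + e_ijk

with total coverage Cov = A + B as a stabilizing covariate and the
sequencing plate as one-hot contrasts (first level reference). Inference
on β1 uses the Wald statistic z = β̂1/SE(β̂1) against the standard normal
(not a t distribution): the design targets cohorts of several hundred to a
few thousand individuals where the two are indistinguishable.

Assumptions worth making explicit: residuals are treated as homoskedastic
even though binomial sampling noise in y shrinks with coverage and with
the minor fraction; the alternative allele is defined cohort-wide, giving
one phenotype definition per position; missingness in the metabolite
panel is resolved *before* the scan, so every fit is complete-case by
construction.

## Scan strategy

The s × m fit matrix (positions × phenotypes) is evaluated by
Frisch–Waugh–Lovell decomposition. Covariates shared by all positions
(intercept, age, sex, batch) are projected out of y, the phenotypes and
the coverage columns once via a QR basis; the position-specific coverage
residual is then projected out analytically, after which each fit reduces
to a univariate slope with

    β̂1 = ⟨MR̃, ỹ⟩ / ‖MR̃‖²,   SE² = (RSS/df) / ‖MR̃‖²,
    df = n − p_shared − 1(coverage) − 1(phenotype).

The whole scan is a handful of matrix products. A test asserts agreement
with per-fit statsmodels OLS to ~1e-11, and that route remains available
as `fit_inverted_model`. Degenerate fits (phenotype residual numerically
zero, e.g. a constant ratio) are reported as NaN rows, never dropped
silently. A coverage column that is itself constant (possible in
fixtures) is detected and its contrast dropped, with df adjusted.

## Quality control

Step 1 (sequencing) applies, in order: contamination flag, overall mean
coverage < 1000× (strict), diabetes flag — then, on the retained cohort:
primer region 16 401–16 449 (inclusive, 49 positions), reference gap
(mt3107 plus any non-ACGT reference base), phantom mutations {3166, 3170,
16390}, blacklist {301, 302, 310, 316, 16182}, cohort mean coverage
< 1000× and homoplasmy. A position is homoplasmic when the *maximum* over
individuals of B/(A+B) is strictly below 0.007 — the least destructive
reading of "provides no heteroplasmy information": if any single
individual shows a callable minor fraction the position is kept. All
thresholds are strict (`<`), matching how they are printed. Exclusions
are attributed to the first matching rule, making ledger counts conserve
exactly (Σ rule counts + retained = input) — an invariant the report
object can verify itself. Filters are idempotent; NUMTs are deliberately
not removed (long-range PCR makes nuclear contamination unlikely), only
an annotation hook exists.

Step 2 (metabolites) runs completeness filter (≥80 % observed, boundary
kept) → outlier masking (|x − mean| > 3 SD on observed values, strict;
constant columns mask nothing) → PMM imputation. The order is a design
choice: masking before imputing means outliers are re-imputed from the
plausible support, and ratio enumeration then always sees a complete,
strictly positive matrix. The PMM is chained equations with OLS
predictions and 5 donors, 10 cycles, single completed dataset — single
rather than pooled multiple imputation because the scan consumes one
matrix and reports single association estimates. Imputed values are
always members of the observed support, preserving positivity.

Ratios are oriented by panel column order (earlier column = numerator).
Orientation is presentational: in log2 mode flipping a pair negates β1
and leaves |z|, p and the P-gain unchanged (tested). Default ratio scale
is untransformed with a log2 option; the two give materially similar
scans and the untransformed scale matches how effect sizes are usually
quoted for concentration ratios.

## Multiple testing

M_eff uses the Li–Ji eigenvalue rule. For large panels the eigenvalues of
the correlation matrix are taken from the singular values of the
standardized data matrix (rank ≤ n, zero-padded) — algebraically exact
and linear in m instead of quadratic. The significance gate is
p < α/M_eff AND P-gain > (number of metabolites), both strict. M_eff is
computed over the ratio phenotypes; given strong within-block
correlation, M_eff ≪ m. Genomic-control λ is reported per phenotype
across positions, mirroring one QQ plot per scan.

## The synthetic cohort

The generator runs the analysis model *forwards*. Heteroplasmy is
generated on the log2-odds scale: η_ik = baseline + position shift +
plate shift + β1·(MR − mean MR) + ε, θ = 2^η/(1+2^η), coverage ~
Poisson(3500 × lognormal library factor), B ~ Binomial(coverage, θ). The
logistic link makes the fitted log2-ratio response approximately linear
in MR, so β1 is a genuinely recoverable parameter. Defaults, chosen once:

| parameter | default | meaning / rationale |
|---|---|---|
| `mean_coverage` | 3500 reads | the emulated study's mean depth |
| `n_metabolites` | 151 | panel size; class mix 1/35/14/14/87 (hexose/acylcarnitine/amino acid/sphingomyelin/glycerophospholipid) |
| `baseline_logit` | −2.5 | minor fraction ≈ 0.15 at heteroplasmic sites; the study does not report its heteroplasmy distribution, so this is a free parameter set to a clearly heteroplasmic level where the log-ratio response is well conditioned |
| `position_sd` | 0.75 | across-site spread of heteroplasmy levels (fractions from <0.01 to ~0.5) |
| `noise_sd` | 1.0 | residual log2 spread; yields per-test partial R² of a few percent at the planted effect sizes, the regime reported scans operate in |
| `homoplasmic_fraction` | 0.43 | ≈ 7106/16 569, the emulated study's homoplasmic share |
| `block_correlation` / `block_size` | 0.5 / 5 | within-class block correlation of targeted panels |
| `log_conc_sd` | 0.35 | log-normal concentration spread; within-block ratios then have SD ≈ 0.35 on a mean-1 scale |
| `missing_rate` / `outlier_rate` | 0.02 / 0.005 | MCAR missingness and >3.5 SD injected outliers |
| `coverage_log_sd` | 0.15 | per-individual library-size variation |

What the generator does *not* emulate: NUMT reads, per-read sequencing
error profiles, haplogroup structure, non-MCAR missingness, and any
dependence of metabolite levels on age/sex (covariate effects on η are
plate shifts only). Passing tests therefore demonstrate correctness of
the statistical machinery under the stated model, not robustness to those
real-data complications.

The QC fixture generator is separate and deterministic in structure:
coverage 3500× (500× for flagged-low-coverage individuals, 900× cohort
mean at flagged-low-coverage positions), minor fraction 1 % at
heteroplasmic sites and exactly 0 at homoplasmic ones, so every exclusion
rule fires on the data itself and the ledger counts equal the
specification exactly.

## Calibration suites and problem sizes

The calibration experiments fix `position_sd = 0` and
`homoplasmic_fraction = 0` to probe the estimator's sampling distribution
at a single heteroplasmic site; everything else uses defaults. Sizes are
the package's own choices:

* **Null size/uniformity**: one cohort, n = 500, 2000 independent null
  positions each paired with one ratio (cyclic assignment), so the 2000
  p-values are mutually independent; checked against binomial 99 % bounds
  at the 5 % level and Kolmogorov–Smirnov uniformity at α = 0.01.
* **Recovery**: 200 replicates at n = 1000 for β1 ∈ {0.5, 0.909, 1.5}
  (0.909 is the scale of the strongest reported ratio effect); mean bias
  is compared to 3× the Monte-Carlo standard error and 95 % CI coverage
  must land in [0.92, 0.98]. The pseudocount induces a small attenuation
  (≲0.5 % at the default heteroplasmy level, growing as θ → 0), which is
  why calibration runs sit at a mid-range minor fraction.
* **Planted signal**: 50 seeded end-to-end runs (n = 200, 50 positions,
  10 metabolites → 45 ratios, β1 = 1.5); the planted pair must attain the
  scan's smallest ratio p-value in ≥95 % of runs.

## Numerical choices and edge cases

* Tie-break in alternative-allele calling: alphabetical (A<C<G<T) via
  first-argmax; the all-reference degenerate case yields the first
  non-reference base and is later removed as homoplasmic.
* B/(A+B) with A+B=0 is defined as 0.
* Phenotype-residual degeneracy threshold: ‖MR̃‖² ≤ 1e-12·max(‖MR‖², 1).
* p-values are clipped away from exact 0 to keep downstream log and
  P-gain arithmetic finite.
* All randomness flows from explicit integer seeds; per-stage streams are
  derived through `SeedSequence` so stages are independently reproducible.
* Count tensors default to uint16 planes (sufficient below ~65 000×
  coverage), keeping a 3021 × 16 569 cohort around 400 MB.

## Known limitations

* The cohort-wide alternative allele can mis-specify B at positions where
  different individuals carry different minor alleles; a per-individual
  definition would fragment the phenotype and is not implemented.
* M_eff is estimated from ratio phenotypes only; a joint trait × position
  correction is exposed as a flag-level idea but the decomposition of the
  implied correction factor is not identifiable from published numbers.
* Single imputation understates imputation uncertainty in SEs; with ≤20 %
  missingness per metabolite the effect on β1 is second-order.
* The homoplasmy call (max over individuals) is one of several defensible
  readings; mean-based or per-individual variants would retain fewer or
  different positions.
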