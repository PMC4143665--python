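# Methods

## Model

`pedsur` fits a Bayesian joint model for two quantitative traits measured
longitudinally on members of pedigrees. For trait k ∈ {1,2} of subject j in
family i at visit t,

    y_ijtk = β0k + X_ij′ βxk + Z_ijt′ βzk + Σ_g γ_gk β_gk SNV_ijg
             + p_ik + s_ijk + e_ijtk

* `X` are subject-constant covariates (e.g. sex, smoking), `Z` time-varying
  covariates (e.g. age at visit);
* `SNV_ijg` ∈ {0,1,2} is the minor-allele dosage of candidate variant g, all
  G variants entering the model simultaneously;
* p_i ~ N₂(0, Σp) is a family effect shared by every member of family i,
  s_ij ~ N₂(0, Σs) a subject effect shared by a subject's visits, and
  e_ijt ~ N₂(0, Σe) the visit-level residual. The off-diagonals of the three
  2×2 covariance matrices carry the cross-trait correlation at each level;
  the residual-level coupling is the seemingly-unrelated-regressions (SUR)
  structure.

Variable selection uses a spike-and-slab prior with Beta-Bernoulli
multiplicity control: γ_gk ~ Bernoulli(q_k), q_k ~ Beta(a, b) with a = 1 and
b = G by default, so the marginal prior odds that any one variant is
associated are 1/G however many candidates are supplied. This is what makes
the false-positive count stable as noise variants are added: enlarging G
automatically makes the prior more sceptical. The significance measure is
the posterior inclusion probability (PIP), the frequency with which
γ_gk = 1 across the models visited by the chain; the *median probability
model* selects the pairs with PIP ≥ 0.5.

"Univariate mode" constrains Σp, Σs, Σe to be diagonal, so the two traits
are modeled independently (the longitudinal and multiplicity machinery is
retained). It is both a comparator and a consistency check: when the
generating cross-trait correlations are zero the two modes must agree.

## Sampling scheme

All full conditionals are conjugate, so the sampler is a fixed-scan Gibbs
sampler; each sweep updates, in order:

1. **Active coefficients.** Intercepts, covariate coefficients, and the SNV
   coefficients with γ_gk = 1, both traits jointly, from the exact
   multivariate-normal full conditional of the Σe⁻¹-whitened stacked
   bivariate regression, given the current random effects.
2. **Indicators.** Each (g,k) in turn by a *collapsed* update: the slab
   coefficient β_gk ~ N(0, τ²) is integrated analytically against trait k's
   conditional likelihood (conditioning on the other trait's current
   residuals through Σe), giving a closed-form Bayes factor
   `log BF = −½ log(1 + τ² Sxx) + ½ Sxu²/(1/τ² + Sxx)`; γ_gk is drawn from
   Bernoulli(q·BF / (q·BF + 1 − q)), and β_gk is redrawn from its
   conditional normal when active (stored as 0 when inactive). Collapsing
   avoids the mixing pathologies of naive indicator-coefficient samplers and
   needs no pseudo-prior tuning.
3. **Inclusion probabilities.** q_k ~ Beta(a + Σγ_gk, b + G − Σγ_gk),
   per trait by default (`shared_q` pools both traits' indicators).
4. **Random effects.** Every p_i and s_ij from its bivariate-normal full
   conditional; units with equal observation counts are drawn in vectorized
   batches (the 2×2 posterior covariance is shared within a batch).
5. **Covariances.** Σp, Σs, Σe from conjugate inverse-Wishart full
   conditionals (Bartlett construction); in univariate mode, per-trait
   inverse-gamma draws of the diagonals (prior IG(ν0/2, s0_kk/2)), which is
   the correct Gibbs kernel for the diagonal model — zeroing the
   off-diagonals of Wishart draws would not be.

In univariate mode each trait consumes its own RNG stream (spawned from the
chain seed), making trait 1's chain bit-for-bit independent of trait 2's
data.

### Working scale

Traits are standardized internally (mean 0, SD 1) and covariate columns
centered; SNV dosage columns are centered but *not* scaled, keeping
coefficients per-allele. Reported coefficient summaries are mapped back to
raw trait units. Rationale: "noninformative" priors need a scale to be
defensible; standardization lets one default slab variance serve any trait.

### Defaults and numerical choices

| parameter | default | meaning |
|---|---|---|
| a, b | 1, G | Beta prior on q; prior odds of association 1/G |
| τ² | 100 | slab variance, standardized-trait scale |
| v0 | 10⁴ | prior variance of intercept/covariate coefficients |
| ν0, S0 | 3, 0.01·I | inverse-Wishart df and scale for each Σ |
| iterations / burn-in / thinning | 20 000 / 5 000 / 10 | chain schedule |

* Initialization is deterministic: per-trait least squares for the fixed
  effects, an empty model (γ = 0), zero random effects, and a
  method-of-moments split of the residual variance into family / subject /
  visit layers (within-family and within-subject residual cross-products).
* SPD guard: Cholesky factorizations retry once after symmetrizing and
  adding 1e-10 jitter, then raise.
* Degenerate SNV columns (zero variance after centering) give BF = 1
  exactly, i.e. the data are uninformative and the indicator samples its
  prior; monomorphic columns are dropped at assembly with a warning.
* Ties at the selection threshold are included (PIP ≥ 0.5).

## Medication adjustment

Antihypertensive treatment masks the untreated blood pressure. The
adjustment estimates the observation-level mean difference among
hypertensive observations, delta = mean(BP | htn=1, med=1) − mean(BP |
htn=1, med=0), and imputes untreated values as observed − delta for rows
with htn = 1 and med = 1, independently per trait. Stratum means pool all
subjects and visits (observation-level, not subject-level, means); the
report flags this pooling. Whatever delta's sign, the same subtraction is
applied. If no rows need adjustment the table passes through unchanged; a
needed-but-empty control stratum is a hard error.

## LD utilities

LD is composite genotype r² — the squared Pearson correlation of dosage
vectors on the shared non-missing subjects — appropriate for unphased family
data. False-positive accounting can discount selections that are indirect
effects: a selected noise variant is "LD-explained" when its maximum r² with
any selected true positive reaches a threshold (default 0.8).

## Synthetic data generator

The generator realizes exactly the model above, so parameter-recovery tests
are well-posed:

* **Pedigrees** grow by a branching template: a founder couple, a uniform
  number of children per couple, and marriage (to a new founder spouse) with
  fixed probability in non-final generations. Defaults (2–6 children, 3
  offspring generations, marriage probability 0.55) give ≈42 members per
  family on average, the multigenerational scale of the emulated study
  (20 pedigrees, ~849 individuals, 3 visits each).
* **Genotypes** by gene dropping: founder alleles Bernoulli(MAF) per
  chromosome, children inheriting one uniformly chosen allele per parent.
  Variants are independent unless an LD pair is requested, in which case the
  partner column copies the source's founder alleles with per-allele flip
  noise and is transmitted with the source's meioses — Mendelian consistency
  holds exactly and r² is controlled by the flip rate (ε = 0.02 gives
  r² ≈ 0.9 at MAF 0.3). `ensure_polymorphic` redraws founder columns that
  carry zero minor alleles (rare variants are ascertained as segregating),
  which conditions rare-variant frequencies slightly upward.
* **Phenotypes** from the model equation with configurable intercepts,
  covariate effects (sex; a per-subject smoking indicator; baseline age
  uniform on a range with constant per-visit increments), causal effect
  matrix, and the three covariance layers. An optional medication layer
  marks visits with latent systolic BP above a threshold as hypertensive,
  medicates such subjects with fixed probability, and shifts both observed
  traits additively — so the medication adjustment can be exercised
  end-to-end.
* **Benchmark scenario** (`gaw_like_scenario`): a 15-variant causal panel
  modeled on the GAW18 MAP4 simulated-effects frame (positions, MAFs
  0.0016–0.38, additive effects up to ≈11 mm Hg per allele; one panel
  variant has a null effect and is excluded from the causal truth sets),
  plus a chosen number of noise variants with MAFs drawn log-uniformly on
  [0.005, 0.5] (the source region is dominated by rare variation).
  Benchmark variance components are σp = (4, 6), σs = (5, 8), σe = (5, 7)
  with cross-trait correlation 0.55 at every layer and intercepts (75, 120)
  — diastolic/systolic-like scales with moderate familial aggregation.

What the generator does **not** emulate: real recombination or fine-scale
LD (independent variants by default), ascertainment, covariate–genotype
dependence, missing visits, or genotyping error. Passing recovery tests
therefore demonstrate correctness of the inference under the model's own
assumptions, not robustness to their violation.

## Validation strategy

* **Joint-distribution (Geweke-style) test**: prior-draw + data-simulation
  versus Gibbs-with-data-resimulation on a micro design; matching means of
  ~18 scalar functionals is a sharp detector of full-conditional errors.
* **Enumeration oracle**: with Σp, Σs, Σe fixed, every one of the 2^(2G)
  joint models has a closed-form Gaussian marginal likelihood (coefficients
  and random effects integrated analytically); exact PIPs from this
  enumeration are compared with Gibbs PIPs at G = 4.
* **Quadrature oracle**: the collapsed inclusion Bayes factor is checked
  against 1-D numerical integration of the slab marginal likelihood.
* **Moment oracles**: the generator's variance-component structure is
  verified against the closed-form decomposition (total variance,
  within-subject and within-family covariances), and conjugate update
  parameters against hand-derived formulas.

Test and validation problem sizes are deliberately modest (micro designs
for the oracle checks; 20-family studies with a few thousand observations
and chains of 5 000–20 000 post-burn-in draws for recovery, multiplicity,
and reduction checks) — large enough for the properties to be sharp, small
enough to run routinely.

## Comparators

* The **univariate** comparator is the same engine in diagonal-covariance
  mode.
* The **measured-genotype-style scan** (`mga_scan`) is a behavioral
  stand-in for the classical family-based single-SNV test: first-visit
  measurements, one trait and one SNV at a time, a linear mixed model with a
  family random intercept fit by maximum likelihood (statsmodels MixedLM),
  a 1-df likelihood-ratio test (ML, not REML, since the compared models
  differ in fixed effects), and Bonferroni correction. It deliberately uses
  a family intercept rather than a kinship-matrix polygenic term — its role
  is the qualitative contrast (false-positive inflation under Bonferroni
  when candidates are in LD with causal variants), not replication of any
  specific published implementation.

## Known limitations

* Exactly two traits; no kinship-matrix polygenic covariance (family
  membership is the only relatedness structure used).
* Gaussian traits only; no liability/ordinal outcomes.
* Candidate-gene scale: G in the tens-to-hundreds; the dense indicator scan
  is not meant for genome-wide panels.
* Missing covariates are a hard error (no imputation); missing dosages are
  an error unless mean-imputation is explicitly requested.
* Rare variants cluster in few families, so their effective sample size is
  far below the nominal carrier count; posterior uncertainty reflects this,
  but power against rare variants is intrinsically limited — weak or rare
  effects are routinely (and correctly) left unselected.
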