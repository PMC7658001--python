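# Methods

This note documents the models, numerical choices and limitations behind
`ewasnet`, in the order the pipeline runs.

## Generative model of the synthetic cohorts

The generator is the package's substitute for protected human methylation
data; its defaults define the study conditions every test and the
acceptance script operate under.

**Beta values.** For probe *j* in sample *i*, each of K pure cell types *c*
carries a logit-scale value

    l_cj + dev_ij ,   dev_ij = σ_m (√ρ_b L_bi + √(1−ρ_b) ε_ij) + covariate terms + Δ_j (dx_i − ½)

and the observed beta is the proportion-weighted mixture

    β_ij = Σ_c π_ic · expit(l_cj + dev_ij).

* `l_cj` is the logit of the type-*c* profile for probe *j*; profiles are
  Beta-distributed around a per-probe baseline (bimodal across the array,
  mid-range for causal/block probes, where a group difference of a few
  percent is representable). A small fraction of probes (5%) uses a low
  Beta concentration (15) and strongly discriminates cell types — the
  deconvolution panel; the rest use concentration 500.
* `π_i` ~ Dirichlet, with the concentration vector rescaled per diagnosis
  group: the cell-composition confound. Because β is *linear* in π given
  the deviations, the confound is exactly removable by the linear
  proportion covariates the analysis prescribes — mixing before the
  nonlinearity (a single squashed mixture logit) would leave residual,
  unremovable confounding, which is a statement about that generator, not
  about the adjustment.
* `L_b` is the latent factor of block *b* (within-block correlation ρ on
  the logit scale); `ε` is idiosyncratic; σ_m = 0.3, a typical M-value
  residual spread.
* Planted effects are specified on the beta scale (δ, the quantity a
  per-probe regression of β on diagnosis should recover) and converted to
  the logit shift Δ_j = δ_j / d̄_j, where d̄_j is the cohort-average
  derivative Σ_c π_c p(1−p) computed on the null deviations. The shift is
  applied ±Δ/2 to cases/controls, so the realized beta-scale difference
  equals δ up to third-order terms.

**Defaults and why.** 5,000 probes, cohorts of 500/100/400 samples, 96
causal probes with |δ| ~ U(0.01, 0.05) (the magnitude range of published
blood effect sizes for heavy alcohol use), 70% hypomethylation; one
50-probe mediator block with ρ = 0.9 inside the causal set (the replicated
signature *is* the coregulated module); six blood cell types. Cortisol is
`12 + γ·L + 0.04·(age−mean) + 0.8·male + N(0, σ_out)` with γ = −4 and
σ_out = 8 — the module explains ≈ 20% of outcome variance, a strong but
not implausible biomarker coupling. Coupled ROI BOLD eigenvariates are a
standardized monotone transform (x + 0.25x³) of the mediator latent with
correlation 0.45 — detectable by rank statistics at τ ≈ 0.3 — other ROIs
are pure noise. Right (not left) hippocampal volume couples to the latent
at 150 mm³ per latent SD. Smoking score is Poisson with a diagnosis-linked
rate (comorbidity) by default; `smoking_comorbid=False` makes smoking
independent, the configuration used for null-calibration runs because
comorbid smoking is deliberately an *unadjusted* confounder reserved for
the smoking sensitivity analysis.

**Reproducibility.** One seed governs everything; per-cohort generators
are spawned from a `SeedSequence`, so cohorts are independent but the
probe architecture (baselines, causal set, blocks, profiles) is shared —
replication needs common causal loci across cohorts.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: genomic autocorrelation along chromosomes,
SNP-under-probe artifacts, batch/chip-position effects, probe-specific
measurement error, family relatedness, and any nonlinearity of the true
covariate effects. The cell "reference" is exact by construction; real
reference panels are themselves estimated.

## Preprocessing

* The between-design scale correction multiplies each sample's type II
  intensities by (type I median / type II median) before quantile
  normalization; the two intensity matrices are normalized separately
  (with beta-ready M/U matrices, they are the two channels of information
  actually available; true per-dye handling would require raw scanner
  files, which are out of scope).
* Quantile normalization maps each sample onto the stratum's rank-wise
  mean distribution; ties take the average of the reference values at
  their tied ranks, making the operation deterministic and idempotent (to
  float tolerance). Strata with < 2 probes pass through with a warning.
* Beta offset: 100, the conventional intensity stabilizer; configurable.
* Deconvolution solves per sample min ‖Aw − y‖² with w ≥ 0 and Σw = 1
  (`simplex`) or Σw ≤ 1 (`sub_simplex`) by SLSQP with analytic gradients
  (ftol 1e-14); the test suite checks the objective against an exhaustive
  active-set QP enumeration to 1e-6. The panel is the top-k probes by
  between-type dispersion of the reference profiles (k = 100 by default;
  the calibration analyses use 300, where estimation error is small enough
  that the estimated proportions restore α-level calibration). With one
  profile value per type and no replicate variance, the between-type
  F-statistic reduces to this dispersion.

## EWAS

Plain OLS per probe (a moderated/empirical-Bayes variant is deliberately
out of scope), complete-case per probe, categorical covariates
dummy-encoded against the lexicographically first level, cell proportions
entered as K−1 columns (the simplex makes K collinear with the intercept).
Zero-variance responses return a missing row with reason code
`zero_variance` rather than p = 1 — no signal and no information are
different things. Consumption models use log1p by default (defined for
abstainers; plain log available). M-value PCs (logit β clipped to
[0.001, 0.999]) are available as covariates. BH-FDR is computed over all
non-missing p values and re-inserted in input order. Two-sided p values
throughout; no genomic-control inflation adjustment.

## Replication

The chance-overlap statistic needs a per-probe background rate; it is an
explicit input, defaulting to (discovery significant)/(discovery tested),
and is always reported rather than silently inferred. CI methods: Wilson
(default, best near boundaries), normal, Clopper–Pearson. For k/n = 96/203
the exact (Clopper–Pearson) interval is (0.40, 0.54) at two decimals;
Wilson's lower bound is 0.4054, which rounds to 0.41 — the three methods
agree within a percentage point but not at two-decimal rounding on the
lower bound. Direction consistency compares sign(b); zero or missing
effects are inconsistent with either sign.

## Coregulation network

Unsigned adjacency |cor|^β (the replicated probes contain both hyper- and
hypomethylated loci that co-associate). The scale-free fit regresses
log10(frequency) on log10(mean connectivity) over 10 degree bins (empty
bins dropped) and scores −sign(slope)·R² — scale-free topology has a
negative log-log slope, so good fits score positively. The chosen power is
the smallest candidate exceeding 0.8, else the best-scoring one; the
candidate set includes β = 9, the published small-network configuration,
which `build_modules(power=9)` applies directly.

Module detection is average-linkage clustering of 1 − TOM with a *static*
cut (dynamic tree cutting adds nothing at ≤ 100 probes). The default cut
height is data-driven: the cut sits in the middle of the largest gap
between consecutive merge heights in the upper half of the dendrogram,
i.e. between the within-module merges and the final between-module joins.
A fixed height cannot serve here because the TOM scale moves strongly
with the soft power (within-module TOM dissimilarity is ≈ 0.3 at β = 1
but ≈ 0.8 at β = 9); the gap rule adapts and reduces to the obvious cut
whenever modules are separated at all. An explicit `cut_height` overrides
it. Clusters under `min_module_size` (default 10) are unassigned; modules
are labelled by size.

Eigengenes are PC1 scores of the standardized module probes, scaled to
unit variance and sign-oriented so the mean correlation with member probes
is positive; this orientation is a convention — it flips the sign of every
downstream eigengene coefficient, so reported signs should always be read
against it. kME is the probe–eigengene Pearson correlation. Module–trait
association is provided under both published readings — eigengene–trait
correlation, and |kME| vs per-probe statistic across probes — with neither
privileged.

Probes are residualized on age, sex and ancestry before network
construction (`endophenotype.residualize`), matching the covariate set of
the module–trait models.

## Mediation network

The procedure is a significance-pattern classifier, not a causal-effect
decomposition. Direction convention: an edge hub→locus exists when the
*locus* associates with the outcome alone (p < α = 0.05) but not once the
hub enters the additive model — connectedness is thereby a property of the
hub, which is what makes per-hub counting meaningful; the opposite reading
is available behind `hub_assessed_alone=True`. Hubs are the top 30% of
|kME| with ceiling rounding and lexicographic tie-breaks. Age, sex and
ancestry enter both models, consistent with the module–outcome adjustment
set. Pairs with |cor| > 0.999 are skipped and recorded. No multiplicity
correction is applied across pairs; under a null outcome the expected
false-edge rate is ≈ α per evaluated pair, and the tests verify the
realized rate stays within binomial noise of it.

## Endophenotype models

OLS route: trait ~ [1, summary, covariates]; reported are the summary
coefficient ± SE, the overall model F with (k, n−k−1) df, and the
coefficient's two-sided p. Rank route (for BOLD, where residual normality
typically fails): the methylation summary is residualized on cell
proportions, then partial Kendall tau-b against each ROI adjusting for
age, sex, ancestry. Multiple adjusters are partialled out recursively in
the given order (each adjuster updates all remaining pairwise taus before
the next applies); p values use the normal approximation with the plain
tau variance 2(2n+5)/(9n(n−1)), an approximation that is slightly
conservative-to-liberal depending on tie structure — exact inference for
partial tau is not attempted. Categorical adjusters are rank-encoded by
lexicographic level order, a monotone-invariant choice. Left and right
structures are always analysed separately. Cohorts sharing a collection
protocol may be pooled for the cortisol model, with the cohort indicator
available as a covariate.

## Numerical and measurement choices

* OLS is delegated to statsmodels; the test suite holds it to the
  closed-form (XᵀX)⁻¹Xᵀy solution and classical SEs at 1e-10.
* TOM, adjacency and partial-tau implementations are vectorized; tests
  compare them to brute-force triple loops and exhaustive pair
  enumeration.
* Effect-recovery bias is measured on cohorts whose causal probes are
  independent: with a coregulated block inside the causal set, a single
  chance correlation between the block latent and diagnosis (SE ≈ 1/√n)
  shifts all member effects together — a shared sampling excursion that no
  probe count averages away and that is not estimator bias.
* Desk-scale problem sizes: calibration runs use 5,000 probes × 500
  samples; recovery runs 2,000 × 500; replicate-based checks use 20
  seeds. These sizes make all Monte-Carlo bands quoted in the tests tight
  enough to be meaningful while keeping the full suite in the
  single-digit-minutes range.

## Known limitations

* No IDAT parsing, detection p-values, background correction, or
  alternative normalizations (BMIQ, functional normalization).
* No mixed-model relatedness adjustment; family structure is assumed to be
  absorbed by PC covariates when present.
* The mediation classifier inherits all caveats of significance-based
  mediation logic: a "connected" edge is a pattern of p-values, not an
  estimated indirect effect.
* Static tree cutting with the gap rule assumes modules are separated by
  a height gap at all; overlapping or nested modules would need dynamic
  cutting.
* The synthetic generator's linear-mixture confound is the removable kind
  by design; real cell-composition confounding can be worse behaved.
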