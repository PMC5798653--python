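# Methods

## Design

The package implements a two-sample Mendelian randomization (MR) analysis:
genetic variants that robustly determine an exposure (here circulating IGF1
and IGFBP3, in SD units) are used as instrumental variables, and their
associations with a binary outcome (Alzheimer disease case-control
log-odds) are taken from an independent sample. Under the instrumental
variable assumptions — the variants determine the exposure, share no
confounders with the outcome, and affect the outcome only through the
exposure — the SNP-outcome associations identify the causal direction, and
ratios of coefficients identify its magnitude.

Two analysis modes are exposed deliberately. *Causal-inference* mode pools
the SNP-outcome log-odds directly (per exposure-raising allele copy); it
tests existence and direction of an effect under weaker modelling
assumptions but does not estimate risk change per unit of exposure.
*Magnitude* mode pools Wald ratios and yields log-odds of outcome per SD of
exposure. Both use the same fixed-effects inverse-variance-weighted (IVW)
meta-analysis; no random-effects fallback is offered, and MR-Egger,
weighted-median and mode-based estimators are out of scope (with ~9
instruments the IVW heterogeneity diagnostics are the pleiotropy check).

## Harmonization

Exposure and outcome tables come from different GWAS and may code the same
SNP on different alleles or strands. Records are aligned to the exposure's
coded allele: an allele swap negates the outcome beta and complements its
EAF; a strand mismatch complements alleles first; irreconcilable allele
sets are a hard error. Orientation then recodes each pair to its
exposure-raising allele (negating both betas when the coded allele is the
lowering one — subtracting the log-odds from zero). Standard errors are
never touched by sign operations, and every flip is appended to a per-SNP
audit trail so the mapping from published rows to analysis betas is
reviewable.

Palindromic (A/T, C/G) SNPs cannot be strand-resolved from alleles alone.
Default policy: resolve by EAF matching when both frequencies are available
and the outcome EAF is outside [0.42, 0.58]; otherwise drop with a
diagnostic. Both `drop_ambiguous` and `keep` (trust same-strand reporting)
are available. Additive allele effects are assumed throughout; indels and
multi-allelic sites are out of scope.

The molar-ratio coding expresses instruments on alleles expected to raise
the IGF1:IGFBP3 ratio (a proxy of free-IGF1 bioavailability): IGF1-only
SNPs keep their IGF1-raising orientation, IGFBP3-only SNPs are flipped to
their IGFBP3-lowering alleles, and a bivariate-opposite SNP (higher
IGF1 / lower IGFBP3 per allele, rs646776-like) enters as coded. SNPs
affecting both traits concordantly have no coherent ratio coding and are
rejected from this subset.

## Estimation and heterogeneity

The Wald ratio is θ̂_j = β̂_Yj/β̂_Xj. Its reported per-SNP standard error is
the first-order delta approximation with both variance terms,
√(σ_Yj²/β̂_Xj² + β̂_Yj²σ_Xj²/β̂_Xj⁴); the one-term form σ_Yj/|β̂_Xj| is
available as `delta1`. No covariance term is included: the two-sample
design makes the exposure and outcome errors independent. β̂_Xj = 0 is a
degenerate weak-instrument error, not a silent NaN.

IVW pooling uses w_j = se_j⁻², θ̂ = Σw_jθ̂_j/Σw_j, se = (Σw_j)^-1/2, with
two-sided normal p-values and no multiplicity adjustment. Cochran's
Q = Σw_j(θ̂_j − θ̂)² is referred to χ²(k−1) (p = 1 when k = 1) and
I² = max(0, (Q−(k−1))/Q)·100, floored at zero and reported to one decimal.
Per-SNP standardized residuals (θ̂_j − θ̂)/se_j square-sum to Q; the largest
|residual| flags the instrument most likely to act pleiotropically.

**Pooling weights.** Magnitude-mode pooling weights default to the
one-term variance. The two-term variance contains β̂_Yj, so using it for
weights correlates the weights with the very noise being averaged and
shrinks the pooled estimate toward zero — measured at the default design as
a bias of −0.0009 on θ = 0.1 (−0.00015 with one-term weights, 10⁵
replicates). The two-term form remains the per-SNP reporting default and
can be selected for pooling via `delta_method="delta2"`.

## Power

Binary-outcome MR power uses the normal approximation with information
term n·R²·K(1−K): power = Φ(|ln OR|·√(n·R²·K(1−K)) − z_{1−α/2}), inverted
for the minimum detectable OR. At the default design — total outcome
sample n = 54,162 with case fraction K = 0.314 and instrument R² = 6.5% —
the minimum detectable OR at 80% power and α = 0.05 is 0.90 in the
protective direction and its reciprocal 1.11 in the risk-raising
direction; the two directions are exact reciprocals under this formula.
z-quantiles are computed at full double precision. The SD = IQR/1.35
conversion (large-sample normal approximation, 2Φ⁻¹(0.75) ≈ 1.349) is
provided for rescaling exposure spreads reported as interquartile ranges.

## Synthetic data generator

Simulation is at the summary-statistics level. For SNP j with effect-allele
frequency p_j and target variance explained r2_j, the true per-allele
effect on an SD-scaled exposure is b_j = √(r2_j/(2p_jq_j)); observed
exposure betas are Normal(b_j, se_j²) with se_j = 1/√(2p_jq_j·n_exp), and
outcome log-odds are Normal(θ·b_j + pleiotropy_j, se²) with
se = 1/√(2p_jq_j·n·K(1−K)). These are the standard GWAS information
approximations; simulating at this level is sufficient for every
downstream computation and orders of magnitude faster than individual-level
genotypes.

Defaults are the study conditions: 9 instruments with per-SNP r² as
uniform shares of an aggregate 6.5% (the real per-SNP values are not
published; the uniform split is a synthetic choice), exposure GWAS
n = 30,884, outcome sample 17,008 cases / 37,154 controls, θ = 0, no
pleiotropy. Effect-allele frequencies default to an even spread over
[0.15, 0.85] — common variants, as expected of GWAS top hits. One seed
spawns independent substreams for the two tables (two-sample
independence); identical configs give bit-identical output. Allele labels
are assigned from a non-palindromic cycle, with 5 SNPs tabulated on the
lowering allele and a few outcome rows allele-swapped or
strand-complemented so harmonization is genuinely exercised. A
`noise_scale` override multiplies the sampling noise only (reported SEs
unchanged); at zero, Wald ratios recover θ exactly. The FOXO3-like
scenario sets θ = 0 and gives exactly one SNP a direct outcome effect
(default per-allele OR 1.04).

What the generator does **not** emulate: linkage disequilibrium between
instruments (the modelled loci are independent), winner's-curse inflation
of discovery betas, sample overlap between the two GWAS, population
stratification, and case-control covariate adjustment. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated sampling model, not robustness to those real-data complications.

## Monte-Carlo studies and problem sizes

The replication studies run the full estimator per replicate: null
calibration (CI coverage of θ = 0 and Q rejection at nominal 5%) and
analytic-vs-empirical power concordance and parameter recovery use 2,000
replicates each; pleiotropic-outlier detection (direct log-odds 0.5 on one
of nine SNPs, flagged by Q p < 0.05 with the largest |standardized
residual|) uses 500. The delta-method SE is validated against a
parametric-bootstrap SD of the ratio (40,000 draws per configuration, 100
configurations) for instruments with |β̂_X|/σ_X ≥ 10; below that the ratio
distribution grows heavy tails and the first-order approximation is not
trusted. IVW output is checked against an intercept-only weighted
least-squares fit to ten significant digits.

## Numerical and degenerate-input choices

- Rejections during table reading are total: every row becomes a record or
  a numbered diagnostic; unparseable numerics are collected, not skipped.
- Duplicate rsids for one trait are an ambiguity error at selection time.
- Pooling an empty set, non-positive SEs, out-of-range confidence levels
  and non-positive odds ratios raise immediately.
- Displayed ORs/CIs round to 2 decimals and p-values to 3 significant
  figures; TSV outputs keep full double precision, and write-then-read
  round-trips betas and SEs bit-exactly.

## Known limitations

- The packaged instrument panel uses two real rsids and synthetic
  placeholders; a real analysis must supply its own instrument-spec file
  with the published raising alleles.
- Magnitude mode is validated only on synthetic data, since the exposure
  betas it needs are not bundled.
- The power approximation ignores exposure-side estimation noise; the
  Monte-Carlo concordance study shows the resulting error is below one
  percentage point at the default design.
- Replication pooling consumes pre-computed replication-sample estimates;
  cohort-level model fitting (e.g. twin-cluster adjustment) is out of
  scope.
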