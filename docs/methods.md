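# Methods

## Model

`jcar` tests gene-level association of SNP genotypes and CpG methylation
with a continuous phenotype via the linear mixed model

    y = Xβ + g + m + ε,    ε ~ N(0, σ² K),

with g and m defined through conditional autoregressive (CAR)
specifications: each subject's effect, given everyone else's, is normal
with mean γ_l times the similarity-weighted average of the others and
variance σ_l² divided by the subject's total similarity mass. By the
standard Gaussian Markov random field argument (Brook's lemma), these
conditionals determine the joint laws

    g ~ N(0, σ_g² (D₁ − γ₁ S₁)⁻¹),    m ~ N(0, σ_m² (D₂ − γ₂ S₂)⁻¹),

provided D_l − γ_l S_l is symmetric positive definite. Sketch: the
conditional of component i under density p(g) ∝ exp(−g'(D−γS)g / 2σ²)
has precision D_ii/σ² and mean (γ/D_ii) Σ_{j≠i} s_ij g_j, which is
exactly the stated conditional; conversely the conditionals determine
the joint up to normalization. Positive definiteness holds iff γ lies in
(1/μ_min, 1/μ_max), where μ are the eigenvalues of D^{−1/2} S D^{−1/2};
for a nonnegative similarity matrix μ_max = 1, so the admissible upper
limit is γ < 1. The package enforces this with a tolerance of 1e−8 on
the smallest eigenvalue and reports the admissible interval when a
requested γ is outside it.

The error correlation K is the additive relationship matrix 2Φ from the
pedigree by default (so σ² is the residual variance of an outbred
singleton); the raw kinship matrix Φ is available via
`--kinship-scale kinship`. K = I for unrelated samples.

## Score test

The test of H₀: σ_g² = 0 and/or σ_m² = 0 is a linear score test on the
profiled restricted likelihood. Fixed effects are eliminated by
projection, never estimated: with r = rank(X), A is any (n−r) × n matrix
with A K^{−1/2} X = 0 and AA' = I, and y* = A K^{−1/2} y. Writing
R_l = K^{−1/2}(D_l − γ_l S_l)⁻¹K^{−1/2} and Q_l = A R_l A', each layer's
statistic is

    S_l = (df/2) · (y*' Q_l y*) / (y*' y*) − tr(R_l)/2,    df = n − r,

and the joint statistic is S = (S₁ + S₂)/2. Note the trace is of the
full n × n matrix R_l while the quadratic form lives in the projected
(n−r)-dimensional space; the statistic is therefore not centred at zero
in general, which is immaterial because the p-value construction below
thresholds on the observed value itself.

### p-value

Under H₀, y* ~ N(0, σ²I_{df}) for any valid A. The p-value is the
probability that a fresh null draw produces a statistic exceeding the
observed one. Since for fixed kernels S is a strictly increasing
function of the ratio u = y*'My*/y*'y* (M = Q₁ + Q₂ in joint mode), the
event {S_fresh > S_obs} equals {u_fresh > u_obs}, i.e.

    {y*' B y* > 0},    B = M − c·I_{df},    c = (4S_obs + tr_full)/df,

because 2S_obs = (df/2)·u_obs − tr_full/2 rearranges to c = u_obs, where
tr_full = tr(R₁ + R₂). Two consequences are exploited as internal
checks: the observed quadratic form y*'By* is exactly zero, and σ²
cancels (the event is scale-free), so under H₀ the p-value is *exactly*
uniform — the test is exactly calibrated at every n, which the null
simulations confirm. Single-layer modes use the identical derivation
with one layer, giving c = (2S_l + tr_l)/df.

The tail probability P[Σ λ_i z_i² > 0] over the spectrum {λ_i} of B is
computed by characteristic-function inversion (see below). Eigenvalues
below 1e−10 of the largest magnitude are dropped as numerically null.

### Invariances

The construction gives, and the suite verifies: invariance of the
p-value to y → a·y + Xb (a ≠ 0), to the choice of basis A (SVD- vs
QR-derived), and equivariance under consistent subject permutation.

## Quadratic-form tails

`quadform.davies_tail` evaluates P[Q > q], Q = Σ λ_i z_i², by numerical
inversion of the characteristic function:

    P[Q > q] = 1/2 + (1/π) ∫₀^∞ sin θ(u) / (u ρ(u)) du,
    θ(u) = ½ Σ arctan(λ_i u) − qu/2,   ρ(u) = Π (1 + λ_i²u²)^{1/4},

with `scipy.integrate.quad` (target absolute accuracy 1e−6, default).
The log-scale evaluation of ρ avoids overflow for long spectra. Two
independent cross-checks guard the implementation: a seeded Monte-Carlo
estimator (`mc_tail`), and closed forms (χ² tails; for the spectrum
{2, −1} at zero, P = (2/π)·arctan√2 from the Cauchy law of a normal
ratio — the inversion matches it to ~1e−15). If the integration fails
to converge, a moment-matching fallback is used and flagged in the
result: same-sign spectra get a three-moment shifted chi-square match
(a + b·χ²_v matching the first three cumulants); indefinite spectra are
split by sign, each part matched by a Satterthwaite gamma, and the tail
of the difference obtained by one-dimensional integration. The split
form is exact when each sign carries a single eigenvalue and tracks the
inversion to < 0.005 on random spectra; a single chi-square match is
badly biased for strongly indefinite spectra (0.485 vs 0.608 on
{2, −1}), which is why the sign-split form is used.

## Kernels and their data-driven defaults

- **IBS kernel** (genotypes, additive 0/1/2 coding):
  s_ij = Σ_k (2 − |g_ik − g_jk|) / (2K), in [0, 1]. Missing genotypes
  must be mean-imputed first; the kernel itself never sees missingness.
- **Gaussian kernel** (beta values or visit differences):
  s_ij = exp(−Σ_l (m_il − m_jl)² / 2σ²). The default bandwidth σ is the
  pooled sample standard deviation over all entries of the gene's
  methylation matrix, with the unbiased (N−1) denominator, computed per
  gene (overridable with `--bandwidth`).
- **Autocorrelation γ_l**: the mean of the column-by-column Pearson
  correlation matrix of the gene's markers, including the unit diagonal
  (`--gamma-diag exclude` averages off-diagonal entries only; both
  conventions are exposed because the inclusive reading is the plainer
  one but the exclusive one is also defensible). Constant columns are
  dropped from the correlation (undefined) but retained in the kernel
  (well defined); with fewer than two non-constant columns γ falls back
  to 0 with a warning. Since the diagonal contributes +1/K per column,
  the inclusive default is biased upward for small genes; it is always
  within the admissible PD range in practice because pairwise
  correlations average well below 1.

Similarity matrices are masked to zero diagonal, D is formed from the
row sums of the masked matrix, and a subject whose row sum is below
1e−10 triggers an error naming the subject (an isolated subject makes
the CAR improper; silent regularization would change the model).

## Kinship

Pedigree kinship uses the classical recursion over a topologically
sorted pedigree (founders unrelated and non-inbred; unknown single
parents treated as unique unnamed founders; inbreeding handled by the
recursion itself). The suite checks it against an exhaustive
gene-dropping oracle that enumerates every meiosis configuration on
small pedigrees — exact, not simulated.

## Preprocessing

Missing genotypes and methylation values are imputed with the per-column
(variable) mean. The phenotype is rank-based inverse-normal transformed:
rank r (average ranks for ties) maps to Φ⁻¹((r − 0.5)/n). Phenotype or
covariate missingness is handled by listwise deletion with counts
logged. VCF positions are converted to the internal 0-based half-open
convention; marker-to-gene assignment is containment in [start, end)
with an optional `--flank`. The phenotype table's subject order is
canonical; all other inputs are reordered to match, and mismatched id
sets are intersected with counts logged. In the visit-difference design
both methylation and phenotype are later-minus-earlier differences on
the subject intersection, and the phenotype difference is then
inverse-normal transformed.

## Synthetic-data generator

`simulate.SimScenario` bundles the generative conditions: sample
structure ("unrelated" or nuclear families given as children counts),
MAFs (default: drawn once per scenario from U(0.05, 0.5)), CpG means
(U(0.3, 0.7)) and SDs (0.1), variance components, CAR autocorrelations,
covariate effects, and a seed. Defaults were fixed once to represent a
typical gene in an array-based family study: ~10 common SNPs, ~10 CpG
sites, unit residual variance (matching an inverse-normal transformed
phenotype), covariates mimicking age and sex.

- **Genotypes**: founders binomial(2, MAF) under Hardy–Weinberg;
  offspring by Mendelian gene dropping (each transmitted allele
  Bernoulli with probability half the parent's allele count; loci
  unlinked).
- **Methylation**: per-site logit-normal. The logit-scale SD comes from
  the delta method, s = sd/(μ(1−μ)); the logit-scale mean is then
  root-found (Gauss–Hermite quadrature) so the beta-scale *mean* is
  matched closely rather than only to first order — the delta-method
  mean alone is biased by ~0.01 at μ = 0.3, sd = 0.1, which would be
  visible at simulation sample sizes. An optional within-family
  intercept on the logit scale adds familial correlation.
- **Phenotype**: y = Xβ + g + m + ε with g, m drawn from the exact CAR
  joint laws (triangular solve against the Cholesky factor of the
  precision matrix) using the analysis kernels (IBS; Gaussian with
  pooled-SD bandwidth) and the scenario's γ values; ε ~ N(0, σ²K) with
  K from the scenario's pedigree. σ_g² = σ_m² = 0 gives the exact null.

The generator reproduces the features the test is sensitive to — family
structure, kernel-shaped effect covariance, kinship-correlated errors —
but deliberately not linkage disequilibrium between SNPs, mQTL coupling
between genotypes and methylation, array batch effects, or beta-value
heteroscedasticity beyond the logit-normal shape. Passing calibration
and power checks on these data therefore validate the statistical
machinery, not robustness to those real-data complications.

`rejection_rate` reruns the *full* analysis pipeline (kernel and γ
re-estimation included) per replicate with per-replicate seeds spawned
deterministically from the scenario seed, and reports the empirical
rejection frequency with an exact Clopper–Pearson 95% interval.

## Effect-size scale of the CAR parameterization

A property worth stating explicitly: because the conditional variance is
σ_l²/Σ_{j≠i} s_ij and the IBS kernel's mean similarity is at least 0.625
under Hardy–Weinberg, genetic row sums grow like 0.7·n and the marginal
effect variance is ≈ σ_g²/(0.7 n) — at n = 200, σ_g² = 1 contributes
under 1% of phenotype variance. Moreover the dominant eigenvector of
(D − γS)⁻¹ is close to the all-ones direction, which the intercept
projection removes, so the genetic alternative is nearly isotropic in
the residual space and power rises only slowly with σ_g² (the validation
suite measures ~0.06–0.08 rejection at α = 0.05 for σ_g² ∈ {0.5, 1, 2},
against an exact 0.05 null). Interpreting σ_g² as a per-subject variance
requires multiplying by the typical row sum. The Gaussian methylation
kernel behaves differently: with the pooled-SD bandwidth, typical
pairwise similarities are ≈ e^{−L} for L CpG sites, row sums are O(1),
and σ_m² of order 1 produces readily detectable effects — the worked
example in the README exploits this. The power scenario in the
validation suite uses generative γ₁ = 0.9, near the admissible upper
bound, where the genetic alternative is most transmissible.

## Numerical choices

- Positive definiteness: kinship and CAR precision matrices require
  smallest eigenvalue > 1e−8 (precision) / 1e−10 (kinship); an optional
  jitter of 1e−8·I for the kinship inverse square root is applied only
  when explicitly enabled.
- rank(X) is the numerical rank at tolerance
  max(n, p)·eps·(largest singular value).
- Spectrum truncation before tail inversion: |λ| ≤ 1e−10·max|λ|.
- Ties in the inverse-normal transform get average ranks; the offset
  convention is (r − 0.5)/n.
- Per-gene failures in the scan are caught, flagged in the output row
  (`error:<type>`), and never abort the scan; genes with an empty
  required layer are emitted with `skipped:empty_layer`.
- Scan determinism: identical inputs and configuration produce
  byte-identical output files.

## Validation problem sizes

The deep end-to-end suite uses: 20 random spectra × 10⁶ Monte-Carlo
draws for the tail oracle; 50 random kinship/covariate pairs (n ≤ 100)
for the projection contracts; 2000 null replicates each for the
unrelated (n = 100) and family (30 quartets, n = 120) calibrations; 10⁴
replicate CAR draws at n = 6 for the generative law; and 200 replicates
per point for the rejection-rate curve at n = 200 over
σ_g² ∈ {0, 0.5, 1, 2}. These sizes give binomial/Monte-Carlo standard
errors well inside the asserted tolerances while keeping the whole suite
a few minutes on one CPU.

## Known limitations

- γ₁, γ₂, σ and the variance components are fixed or profiled, never
  estimated; sensitivity to the γ and bandwidth defaults is exposed via
  CLI overrides but not automated.
- No interactions between the omic layers; no more than two layers.
- No LD-aware or weighted kernels (e.g. MAF-weighted IBS).
- Gene boundaries are taken from the BED file as given (gene body plus
  optional flank); no annotation database access.
- The scan applies no multiple-testing correction; a Bonferroni
  reference threshold is printed in the summary only.
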