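# Methods

## The retrospective model

For SNP *j*, the genotype vector `Y_j` (allele counts 0/1/2 across the N
study subjects, cases first) is modelled retrospectively: its mean depends
on case-control status through the design `C = [1, c]` (`c_i ∈ {0,1}`),
`E[Y_j] = Cβ`, and relatedness between subjects induces

    Cov(Y_j) = σ_j² K,

with a SNP-specific scale `σ_j²` and one relatedness matrix `K` shared by
all SNPs. For subjects with known pedigrees `K` has diagonal `1 + f_i`
(inbreeding coefficient) and off-diagonals twice the pairwise kinship
coefficient; population structure in the broad sense (drift, admixture)
produces matrices of exactly the same form, which is what makes a single
machinery serve both power calculation and testing.

The best linear unbiased estimate of `β` is generalized least squares,
`β̂ = (C'K⁻¹C)⁻¹ C'K⁻¹ Y_j`, and the test of association is the Wald
statistic

    W = β̂₁² / (σ̂_j² [(C'K⁻¹C)⁻¹]₂₂)  ~  χ²₁  under H₀,

with the per-SNP scale estimated by the GLS residual mean square
`σ̂_j² = (Y_j − Cβ̂)' K⁻¹ (Y_j − Cβ̂)/(N − 2)` (two regression parameters,
hence N − 2). Because `σ̂_j²` is estimated per SNP, multiplying `K` by any
positive constant leaves `W` unchanged — only the *shape* of `K` matters,
which the tests assert as a scale-invariance property. With `K = I` the
statistic reduces exactly to the squared two-sample (Armitage-type) OLS
z-statistic.

Under a local alternative with count-scale effect `δ` (case-minus-control
difference in mean allele count; `δ = 0.2` ⇔ a 10-percentage-point allele
frequency difference ⇔ OR ≈ 1.5 per copy at p = 0.4), `W` is noncentral
χ²₁ with

    λ = δ² / (2p(1−p) · [(C'K⁻¹C)⁻¹]₂₂),

and power at level α is the upper-tail mass of χ²₁(λ) beyond the central
1−α quantile. All calculators report λ on this scale.

## Structure models and their kinship matrices

**Balding–Nichols drift.** A modern population separated from its ancestor
by fixation index `F` carries, for a SNP with ancestral frequency `p`, a
modern frequency `p' ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`: mean `p`, variance
`F·p(1−p)`. `F` here is *present-day-vs-ancestral*; a published pairwise
between-population index is twice this and must be halved (the
`--from-pairwise-fst` flag does so; e.g. the Yoruban-vs-European pairwise
value 0.153 enters the calculators as 0.0765).

**Isolated pair** (all cases population 1, all controls population 2, both
drifted by `F` from a shared ancestor): `K` has diagonal `1+F`,
within-population off-diagonals `2F`, zero across. The variance of the
case-control difference is `(2/n)[2p(1−p)(1+F) + (n−1)·4F·p(1−p)]`, so

    λ → δ²/(8F·p(1−p))   as n → ∞,

a hard ceiling: at F = 0.0005, p = 0.4, δ = 0.2 the bound is 41.67 and a
5000+5000 study achieves only λ = 34.73 (power 0.56 at α = 10⁻⁸, versus
208.33 and power > 0.9999 without structure). The between-population
frequency difference has SD `√(2Fp(1−p))` ≈ 1.5 percentage points at these
values — the effect only needs to beat this "typical" null difference.

**Complete admixture** (every case has ancestry fraction ν₁ from source 1,
every control ν₂; the two sources drifted independently by `F` from a
common ancestor): for individual fractions `a_i`,

    K_ii = 1 + F(a_i² + (1−a_i)²),
    K_ij = 2F(a_ia_j + (1−a_i)(1−a_j)),

which is the genotype covariance `2p(1−p)K` implied by
`q_i = a_i p₁ + (1−a_i) p₂` with independent Balding–Nichols draws `p₁, p₂`
(the Monte-Carlo covariance test verifies this entry-wise). The closed-form
λ follows from the variance of the two group means and their covariance;
its large-N bound is `δ²/(8F·p(1−p)(ν₁−ν₂)²)` — infinite when ν₁ = ν₂.
At F = 0.0765, ν₁/ν₂ = 0.25/0.20 the 5000+5000 design gives λ = 72.78
(bound 108.93).

**Incomplete admixture.** Real admixed populations are heterogeneous:
individual ancestry fractions are modelled Beta with mean ν and
heterogeneity `h = 1/(a+b+1)`, so the variance is `h·ν(1−ν)` (h = 1/3 at
ν = 0.5 is the uniform; h → 0 degenerates to complete admixture). The NCP
is computed exactly per realized draw of fractions via the matrix formula
and averaged over replicates (default 50, with Monte-Carlo SE; one
replicate = one fixed draw, both modes available since either convention is
defensible). `K` is diagonal-plus-rank-2, so `K⁻¹` is applied through the
Woodbury identity in O(N) — the dense path is kept as a cross-check
(agreement to 1e−8). Within-arm heterogeneity restores power: λ increases
with h, because overlapping ancestry distributions let the GLS separate the
effect from structure.

## Kinship estimation and smoothing

The method-of-moments estimator averages standardized outer products over
SNPs with the *pooled* frequency estimate `p̂_j` (appropriate under the
null; a documented limitation for strongly associated SNPs). Pooled
centering makes each row of `K̂` sum to zero exactly, so off-diagonals of
an unrelated panel center on `−1/(N−1)` rather than 0 — and, usefully, the
between-population structure of a two-population sample becomes **rank
one** in `K̂`, which is why adjusting for a single eigenvector already
restores honest variance estimates in that setting. Missing genotypes are
handled pairwise-complete with per-pair renormalization; SNPs with > 5 %
missingness or monomorphic pooled frequency are dropped (counts logged).

Eigenvalues of `K̂` are screened sequentially with the Tracy–Widom
statistic (moment-matched effective-marker normalization of the leading
residual eigenvalue; α = 0.05 per eigenvalue, no multiplicity correction,
matching the nominal-significance convention of eigenanalysis practice).
The GOE Tracy–Widom distribution is evaluated from the Hastings–McLeod
solution of Painlevé II (`q'' = sq + 2q³`, `q ~ Ai` at +∞) integrated once
with `scipy.integrate.solve_ivp`; the resulting quantile grid reproduces
the published percentage points (0.9793 at 95 %, 2.0234 at 99 %) to ~1e−4
and is cached per process.

Smoothing retains the top `L` eigenpairs and flattens the residual
subspace to the constant `γ = (trace K̂ − Σ_{l≤L} λ_l)/(N − L)`:

    K̃ = Σ_{l≤L} λ_l e_l e_l' + γ (I − Σ_{l≤L} e_l e_l'),

which preserves the retained eigenpairs and the total trace exactly, is
full-rank whenever γ > 0 (γ ≤ 0 raises, advising a smaller L), and is
idempotent under re-smoothing. `L = N` is defined as the exact
reconstruction (the γ formula is 0/0 there, and reconstruction is the
unique trace- and eigenpair-preserving completion). `L = 0` is a pure
ridge `(trace/N)·I`.

The expected cost of adjustment is computed analytically: under true
covariance `2p(1−p)K_true`, the expectation of the estimated
`Var(β̂₁)` when testing with `K̃_L` is
`[(C'K̃⁻¹C)⁻¹]₂₂ · 2p(1−p)·tr(PK_true)/(N−2)` with
`P = K̃⁻¹ − K̃⁻¹C(C'K̃⁻¹C)⁻¹C'K̃⁻¹`. The effective-n ratio reported is the
homogeneous-design variance over this expectation. On the marginal two-site
incomplete-admixture kinship (the expectation of the admixed `K` over
independent beta ancestry draws, which adds `2F·h·ν(1−ν)` to each diagonal)
the curve is non-decreasing in L and flat beyond the first two
eigenvectors — adjusting for many more components costs essentially
nothing, while under-adjusting (L = 0) understates the variance several-fold.

## The simulator

Genotypes are `Binomial(2, q_i)` with `q_i = a_i p₁ + (1−a_i) p₂`
(Hardy–Weinberg given the individual's ancestry-weighted frequency), which
reproduces the covariance `2p(1−p)K` of the theoretical constructions
exactly. Ancestral frequencies default to Uniform(0.1, 0.9); SNPs whose
pooled minor-allele frequency falls below 1 % are redrawn, mirroring the
standard MAF exclusion. Causal SNPs shift each case's frequency by `+δ/4`
and each control's by `−δ/4` (total count-scale difference δ), additively
rather than on the odds scale, with clipping to [0.01, 0.99] (a warning if
> 1 % of individuals clip). All randomness flows from one explicit seed;
identical seeds give byte-identical outputs. No missing data are generated
unless requested (`--missing-rate`), and there is no LD, genotyping-error,
or liability modelling — SNPs are independent given structure, exactly as
the power theory assumes. Passing calibration tests on these panels
therefore validates the *structure* machinery, not robustness to LD or
genotyping artifacts in real data.

## Scan filters and diagnostics

`run_scan` excludes SNPs with pooled MAF < 1 % or call rate < 95 % (counts
logged), shares one Cholesky factorization of `K` across all complete SNPs
in a batched solve (identical to per-SNP inversion to 1e−8; SNPs with
missing genotypes fall back to the exact per-SNP path on the observed
subset, dropping matching rows/columns of K). Monomorphic SNPs are flagged
with W = 0, p = 1. `inflation_diagnostics` reports
`λ_GC = median(χ²₁ quantiles)/0.4549` and QQ coordinates.

## Problem sizes and numerical conventions

The stochastic validation studies run at desk scale, chosen to leave
Monte-Carlo error well inside the asserted tolerances: type-I calibration
on 500+500 samples × 20 000 null SNPs (binomial SE 0.0015 at α = 0.05),
power calibration on 2000 causal SNPs at 500+500, drift-magnitude recovery
on 10⁵ SNPs, covariance-oracle checks on 10⁵ replicate SNPs × 10 samples.
Closed forms are exact at every n and are used for all large-n queries; the
dense matrix path is cross-checked against them at n ≤ 500. Symmetry and
reduction identities are asserted at 1e−10 absolute; PSD with eigenvalue
floor −1e−8·trace/N; smoothing contracts at 1e−8; closed-form-vs-matrix
equivalence at 1e−6 relative. The genome-wide α in the worked power
example is 10⁻⁸ (the value consistent with λ = 34.73 giving 56 % power).
Unequal per-population drift is accepted by the isolated-pair kinship
construction (optional `F2`); the simulator draws both populations at a
shared F.

## Known limitations

* Pooled-frequency centering biases `K̂` off-diagonals by −1/(N−1) and the
  estimator assumes the null when testing strongly associated SNPs.
* The power calculators treat `K` as known; using an estimated `K̂` adds
  sampling noise that the expected-variance calculator quantifies only
  through the smoothing rank, not through marker count.
* Only two ancestral sources, no covariates beyond the intercept + status
  design, no ascertainment/liability modelling, no LD.
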