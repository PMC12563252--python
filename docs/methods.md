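# Methods

## Model and estimation

One trait of a multi-harvest randomized-complete-block trial with a
single plant (plot) per genotype×block is modeled as

    y = X m + Z g + W p + T i + e

with fixed harvest×block combination effects `m` (cell-means coding, so
X always has full column rank equal to the number of combinations with
data) and independent Gaussian random terms: genotype `g` (variance
σ²g, q levels), permanent plot `p` (σ²perm, one level per observed
genotype×block), genotype×measurement interaction `i` (σ²gm, one level
per observed genotype×harvest) and residual `e` (σ²e). Harvests are an
ordered calendar but enter the model as unordered factor levels; block
and harvest appear in the fixed part only through their combination.
Missing cells are absent rows — the equations are assembled from
whatever cells exist, so unbalanced trials (dead plants, partial first
year) need no special handling.

Variance components are estimated by EM-REML. Each iteration solves
Henderson's mixed-model equations with shrinkage ratios λk = σ²e/σ²k
and applies the expectation-maximization updates

    σ²e ← (y'y − sol'rhs) / (N − r(X))
    σ²k ← (ûk'ûk + σ²e·tr(C^kk)) / nk

where C^kk is the corresponding diagonal block of the inverse
coefficient matrix and nk the number of levels of effect k (q for
genotype, the observed plot count for the permanent term, the observed
genotype×harvest count for the interaction). Iteration stops when the
maximum relative change of any component falls below `tol`
(default 1e-8) or after `max_iter` (default 1000) iterations; the
convergence flag is reported, never raised as an error. Components are
clamped at a floor of 1e-10 × the phenotypic variance so the shrinkage
ratios stay finite; a fit at the floor represents an effectively-zero
component. EM approaches a zero boundary at a geometrically slowing
rate, so fits whose truth puts a component at zero routinely end
non-converged by the relative-change criterion while the deviance is
already stable to many digits; the `reliable` flag of the deviance
table propagates this honestly rather than hiding it.

No derivative-based or average-information accelerator is used: the
estimator is plain EM by design, and its slow boundary behavior is
treated as a reporting matter, not an excuse to switch algorithms.

### Solving the equations

All four own-blocks of the Henderson coefficient matrix are diagonal
for one-observation-per-cell incidence. The interaction block — by far
the largest (q·m columns) — is absorbed through its Schur complement,
leaving a dense symmetric system of order r(X)+q+plots (~500 for an
84×4×13 trial) that is factorized by Cholesky; the traces of the
inverse blocks (including the absorbed one) and the log-determinant
come from the same factorization. Cross-product matrices are built once
per design; one EM iteration then costs one dense factorization of the
reduced system. Level order is sorted label order everywhere, making
solutions, traces and deviances reproducible across runs.

### Deviance

The REML deviance (−2 × restricted log-likelihood, including the
(N−r(X))·log 2π constant) is computed from the same factorization via

    −2lR = (N−p)·log σ²e + log|C_λ| − Σk nk·log λk + (y'y − sol'rhs)/σ²e + (N−p)·log 2π

which equals the direct evaluation log|V| + log|X'V⁻¹X| + y'Py up to
floating-point error (verified against a dense-V oracle in the tests).
Only deviance *differences* between nested fits are interpreted; the
additive constant conventions of other software may differ. The
deviance analysis (ANADEV) refits the model three times with one random
term removed and assigns χ²(1) codes at 3.84 (5%) and 6.63 (1%),
boundary-inclusive. Small negative LRTs (beyond −1e-4) trigger a
warning — they signal non-convergence, and the affected row is flagged.

## Genetic parameters

h² = σ²g/σ²f, ρ = (σ²g+σ²perm)/σ²f, c²perm and c²gm as fractions of
σ²f, r_gmed = σ²g/(σ²g+σ²gm), CVg = 100·σg/µ, CVe = 100·σe/µ,
CVr = CVg/CVe, VIe = CVe/√r and VIg = CVg/√r with r = number of blocks.
Genotype-mean heritability is

    h²mg = σ²g / (σ²g + σ²perm/b + σ²gm/m + σ²e/(b·m))

— each non-genetic component divided by the number of independent
realizations averaged into a genotype mean (b blocks, m harvests). This
form degenerates correctly for m = 1 or b = 1 and guarantees
h²mg ≥ h². Selection accuracy is √h²mg. CV quantities are reported as
NaN when µ ≤ 0; the rest of the parameter set is still computed.

## Ranking, gains and stability

Genotypes are ranked on u+g+gem = µ + ĝᵢ + mean of the genotype's
interaction BLUPs, descending for higher-is-better traits. The
selection gain at rank k is 100·(GSₖ − µ)/µ where GSₖ is by default the
cumulative mean of µ + ĝ over ranks 1..k (gain basis "g"); basing gains
on the full u+g+gem is available as an option and the basis in force is
recorded in every report. The genotypic-effect basis is the
conservative convention: interaction deviations are not capitalized as
permanent gain.

Per-harvest genotypic values Vg_ij = (mean of the harvest's fitted
harvest×block effects) + ĝᵢ + îᵢⱼ (zero interaction for unobserved
cells) feed the stability indices: MHVG (harmonic mean of the row),
PRVG (mean of entries divided by their environment mean), MHPRVG
(harmonic mean of those ratios), and the ×µ rescalings. Harmonic means
require strictly positive Vg; a nonpositive entry is a hard error
naming the genotype and harvest, because such a trait (on that scale)
is simply unsuited to harmonic-mean indices.

## MGIDI

Inputs are the per-genotype u+g+gem values of the traits included in
the ideotype. Each trait is linearly rescaled to 0–100 with 100 at the
desired end; the ideotype scores 100 everywhere. Factor analysis uses
principal-axis loadings of the trait correlation matrix, Kaiser
retention (eigenvalue ≥ 1, inclusive with a 1e-9 float tolerance),
varimax rotation, a deterministic sign convention (dominant loading of
each factor positive) and regression-method scores B = R⁻¹L applied to
the standardized rescaled data; the ideotype is standardized with the
same column means and standard deviations. MGIDIᵢ is the Euclidean
distance (with square root — a monotone choice that does not affect
ranking) between genotype and ideotype scores. Selection takes the
⌈intensity·g⌉ closest genotypes or an explicit count; with 84 genotypes
a nominal 15% intensity gives ⌈12.6⌉ = 13, so reports always state the
count actually used. Ties (in ranking or distances) are broken by
genotype label order and flagged.

## Synthetic trials

The generator draws exactly the model the analysis assumes: Gaussian
effects at configured variance fractions of a total phenotypic variance
σ²f, fixed harvest×block effects with standard deviation
`fixed_effect_rel_sd`·σf (default 0.5 — seasonal harvest-to-harvest
swings of the same order as the within-trial variation), genotype
effects optionally correlated across traits via a user-supplied PSD
matrix, and iid row dropout at a configurable missingness rate
(default 0). Every effect has its own substream spawned from the master
seed, so a given config+seed reproduces the dataset bit for bit.

The default panel has 12 traits of a perennial forage grass trial
(tiller number, fresh/leaf/stem/inflorescence/total dry matter,
leaf:stem ratio, harvest index, cold tolerance, persistence, growth
habit, plant height) at 84 genotypes × 4 blocks × 13 harvests. Trait
means and residual CVs are set to values typical of such trials, and
the variance-fraction decompositions span the realistic range — from
interaction-dominated tiller counts (f_gm ≈ 0.77) to score traits with
f_g ≈ 0.45; σ²f is back-derived as (CVe·µ/100)²/f_e. Ordinal scores
(growth habit 1–4, cold tolerance 1–5) are produced by rounding a
latent Gaussian trait onto the bounds (equal-width unit categories);
binary persistence thresholds a latent trait at a configured survival
rate. Their recorded "true" components refer to the latent scale, so
recovery experiments use continuous traits.

What the generator does **not** emulate: temporal autocorrelation
between harvests beyond the shared interaction term, spatial field
structure, genotype-specific mortality, and the positivity/skewness of
real biomass measurements — with realistic CVs above ~40% a Gaussian
trait produces occasional negative values, which is why harmonic-mean
stability indices are only exercised on the better-behaved traits in
synthetic data. Passing tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness
to violations of them.

## Verification design

Independent oracles, never sharing code with the implementation:
dense-V restricted-likelihood evaluation (determinant + quadratic
form), multi-start Nelder-Mead optimization of that likelihood,
balanced-design ANOVA method-of-moments components, and hand-computed
harmonic means and Euclidean distances. Parameter recovery runs 20
replicates of the full 84×4×13 design for an interaction-dominated and
a genotype-dominated trait (EM tolerance 1e-6, cap 300 iterations —
fraction-level accuracy is reached long before the last digits of the
components settle). The null calibration of the genotype LRT uses 200
replicates at the full genotype count (q = 84) with a reduced 2-block ×
4-harvest layout: the χ²-mixture reference for a boundary LRT is an
asymptotic statement in the number of genotype levels, and the reduced
layout keeps 200 double fits tractable while preserving q.

## Known limitations

* EM-only estimation is slow near variance boundaries; non-convergence
  flags are common for effectively-zero components and should be read
  together with the component value.
* Finite-sample boundary LRTs are conservative relative to the
  0.5χ²₀+0.5χ²₁ reference; rejection rates at the 3.84 threshold fall
  below the asymptotic 2.5% for small genotype counts.
* No pedigree/kinship, no multi-location structure, no heterogeneous
  residual variances across harvests, no spatial adjustment.
* Ordinal and binary traits are analyzed with the same linear model as
  continuous ones (as is standard practice in these trials); their
  variance components are on the observed scale and are not
  transformed back to a latent threshold scale.
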