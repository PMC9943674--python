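# Methods

## The model

`dragonet` estimates a Gaussian graphical model (GGM) over two paired
omics layers — e.g. promoter methylation and gene expression measured on
the same samples. Let X⁽¹⁾ (n × p₁) and X⁽²⁾ (n × p₂) be the two layers
with rows aligned by sample. Under a joint multivariate-normal model, a
missing edge between variables i and j corresponds to a zero entry θᵢⱼ of
the precision matrix Θ = Σ⁻¹, and the partial correlation is

    ρ̂ᵢⱼ = −θ̂ᵢⱼ / √(θ̂ᵢᵢ θ̂ⱼⱼ).

In omics data p = p₁ + p₂ usually rivals or exceeds n, so the empirical
covariance is singular (or nearly so) and cannot be inverted directly.
The estimator therefore shrinks the joint block covariance toward a
diagonal target, with one intensity per layer:

    Σ̂ = [ (1−λ₁) S⁽¹'¹⁾              √(1−λ₁)√(1−λ₂) S⁽¹'²⁾ ]
        [ √(1−λ₁)√(1−λ₂) S⁽²'¹⁾      (1−λ₂) S⁽²'²⁾          ]
        + diag(λ₁T⁽¹⁾, λ₂T⁽²⁾),

where S⁽ᵏ'ˡ⁾ are unbiased (1/(n−1)) covariance blocks and
T⁽ᵏ⁾ = diag(S⁽ᵏ'ᵏ⁾). Two limits anchor the design: λ₂ = 1 decouples the
layers entirely (layer 1 falls back to ordinary single-layer shrinkage),
and λ₁ = λ₂ reduces to single-penalty shrinkage of the appended data —
the layer-agnostic baseline we call the GGM throughout. Σ̂ is positive
definite whenever both penalties are positive and no feature is constant,
so Θ̂ = Σ̂⁻¹ always exists away from the λ = 0 boundary; the inversion
uses a Cholesky factorization and fails loudly (pointing at the
penalties) rather than jittering silently.

Two layers get two penalties because their effective sparsity and
measurement noise differ: a sparsely connected, noisy layer should be
shrunk harder than a densely connected one. Single-penalty shrinkage
must compromise between the layers; the two-penalty form removes that
compromise at no extra fitting cost.

## Penalty selection

λ₁ and λ₂ minimize the expected squared Frobenius risk E‖Σ̂ − Σ‖²_F.
Up to an additive constant the risk is

    R(λ₁, λ₂) = λ₁T₁⁽¹⁾ + λ₂T₁⁽²⁾ + λ₁²T₂⁽¹⁾ + λ₂²T₂⁽²⁾
                + λ₁λ₂T₃ + √(1−λ₁)√(1−λ₂) T₄,

with coefficients built from two per-entry moments of the covariance
estimates: the sampling variance var(sᵢⱼ), estimated by the standard
w-statistic formula n/(n−1)³ · Σₘ(wₘᵢⱼ − w̄ᵢⱼ)² with
wₘᵢⱼ = (xₘᵢ−x̄ᵢ)(xₘⱼ−x̄ⱼ), and the second moment E(sᵢⱼ²), estimated by
the plug-in sᵢⱼ² (which is unbiased for its own expectation
var(sᵢⱼ) + σᵢⱼ²). On the diagonal λ₁ = λ₂ this recovers the classical
single-penalty optimum Σvar(sᵢⱼ)/Σsᵢⱼ² over all off-diagonal entries,
which is how the baseline selects its single λ.

The minimizer is found by a 101 × 101 grid over the closed unit square
followed by bounded Nelder–Mead refinement. The grid stage is not
cosmetic: the √(1−λ) term has unbounded slope at λ = 1, so purely local
methods started in the interior can stall; the boundary is included in
the grid, and grid ties break toward smaller λ₁ + λ₂. The constrained
(baseline) selector does the same in one dimension. The reported risk
value omits the λ-independent constant and is only meaningful relative
to other (λ₁, λ₂).

`monte_carlo_risk` estimates the true risk surface for a known Σ by
simulation and exists purely to validate the analytic surface. Because
Σ̂ is affine in the data blocks at fixed penalties, ‖Σ̂ − Σ‖²_F collapses
to a quadratic in (λ₁, λ₂, √((1−λ₁)(1−λ₂))) with eight data-dependent
scalar coefficients per replicate; the implementation accumulates those
instead of assembling Σ̂ at every grid point, which is algebraically
identical and far cheaper. On a reduced balanced design (p₁ = 20,
p₂ = 40, n = 500) the mean analytic surface and the Monte-Carlo surface
locate the same argmin to within one 0.02 grid cell; a single dataset's
analytic argmin scatters around the true one with spread ≈ 0.03 per
coordinate at that problem size, shrinking as p grows.

## Significance

Shrinkage compresses partial correlations into the interval
(−(1−λ), 1−λ), so a null model for ρ̂ must account for the shrinkage.
The null density used is

    f(ρ) = ((1−λ)² − ρ²)^((κ−3)/2) / ( B(1/2, (κ−1)/2) (1−λ)^(κ−2) ),

a scaled symmetric Beta law: t = ρ/(1−λ) satisfies
t² ~ Beta(1/2, (κ−1)/2). Two-sided p-values are regularized
incomplete-beta tails, floored at the smallest positive normal float.
For n ≫ p the shape parameter is κ = n − 1 − (p − 2) with p = p₁ + p₂
(the full conditioning set); in the regimes this estimator is built for
(p ≳ n) κ is instead fitted by maximum likelihood on *simulated null
data*: draw X₁, X₂ with i.i.d. standard-normal entries at the same
(n, p₁, p₂), rerun the estimator with the penalties fixed at the values
selected on the observed data, and fit κ per block on the resulting null
partial correlations. The log likelihood is linear in κ given one pass
over the samples, so the MLE costs essentially nothing. One null
replicate is the default; a repeat count is available (and used in the
calibration tests, where κ stability matters).

Each block gets its own effective shrinkage in f: λ₁ for (1,1), λ₂ for
(2,2), and 1 − √((1−λ₁)(1−λ₂)) for the cross block — the exact factor by
which the cross block of Σ̂ is scaled. This choice is a modeling
decision rather than a derived fact; the per-block κ MLE absorbs
residual misspecification, and the end-to-end calibration tests verify
that null p-values are uniform per block across twelve penalty settings
spanning strong to weak regularization.

Multiple testing is adjusted by Benjamini–Hochberg **within each block
separately**; controlling the FDR at level α in every block also
controls it at α across the union. The layer-agnostic baseline is
agnostic here too: it fits one κ on all null partial correlations pooled
and runs one global BH pass — it has no notion of blocks by
construction.

## Edge ranking for recovery benchmarks

ROC and precision-recall curves rank all unordered pairs by ascending
BH-adjusted q-value, ties broken by descending |ρ̂|. Raw |ρ̂| is not
comparable across blocks whose shrinkage differs, and raw per-block
p-values ignore that blocks differ sharply in edge density; the adjusted
q-value rescales each block by its own discovery density and measurably
improves cross-block ranking in unbalanced designs. For the pooled
baseline the global adjustment is monotone in p, so its ranking
coincides with the |ρ̂| ranking. AUC is computed as the midrank
Mann–Whitney U with tie correction; AUC-PR is stepwise average
precision. FDR with zero discoveries is recorded as missing, not zero.

## Synthetic data

The generator emulates a paired transcriptome/methylome design: a narrow
layer (p₁ = 100) and a wide layer (p₂ = 500) with sparse within- and
cross-layer conditional dependencies. A ground-truth precision matrix is
built in four steps: start from the identity; fill an exact,
seed-independent number of uniformly chosen off-diagonal positions per
block (round-half-up of η·N_block, mirrored for symmetry) with
Uniform(−1, 1) draws; replace each diagonal entry by Σⱼ|θᵢⱼ| (the sum
includes the pre-existing diagonal 1) plus ε = 10⁻⁴, which enforces
strict diagonal dominance and hence positive definiteness for every
seed; normalize θᵢⱼ ← θᵢⱼ/√(θᵢᵢθⱼⱼ) to unit diagonal. Data are drawn
from N(0, Θ⁻¹) via the Cholesky factor of Θ, and independent N(0, 0.1²)
measurement noise is added to every entry. Random streams are split into
structure/value and sample/noise substreams so edge placement is
reproducible independently of n.

The four named study designs vary the per-block edge densities
η(1,1)/η(1,2)/η(2,2): A = 0.05/0.05/0.05 (balanced, 248/2500/6238
edges), B = 0.05/0.05/0.005, C = 0.05/0.005/0.005, and D, which is
specified by explicit counts of 500 edges per block (its densities are
only rounded summaries of count/positions, so the counts are taken as
authoritative).

What the generator does *not* emulate: non-Gaussian marginals (real
methylation beta values are bounded and bimodal — the nonparanormal
transform in the I/O layer exists for exactly that gap), heteroscedastic
noise, modular or scale-free topology, batch structure, and missing
data. Passing recovery benchmarks on these simulations therefore shows
correctness of the estimator under its own assumptions, not performance
on any particular real data set.

The three-variable `regulator_toy` (one regulator driving genes A and B
with effect 1.0 and noise sd 0.5) illustrates why partial correlation is
the right object: A and B are strongly Pearson-correlated but
conditionally independent given the regulator. Its coefficients are
illustrative defaults, not calibrated to any external data.

## Benchmark protocol and problem sizes

Sample-size scans evaluate n on the grid {2⁶, ⌊2⁶·⁵⌋, …, 2¹⁴} =
{64, 90, 128, …, 16384}; each (study, n) cell runs 20 independent
replicates, each with a freshly generated precision matrix, and reports
the median AUC with quartiles. The confidence threshold "minimal n" is
the smallest grid n whose median AUC strictly exceeds 0.8. Paired
difference curves (two-penalty minus single-penalty) run both estimators
on identical replicate datasets, which removes network-to-network
variability from the difference. Replicates are seeded as
SeedSequence((base_seed, n_index, replicate)), so any cell is
reproducible in isolation.

The test suite and `scripts/acceptance.py` run these scans over
truncated grids bracketing the crossings (up to n = 512 for the
study-B scan, n = 2048 for the difference curve) with 20 replicates for
scans and 10 for paired curves; calibration checks use reduced layer
widths (p₁ = 25, p₂ = 125) for the twelve-setting null-uniformity sweep
and the full p = 600 design at n = 4096 for the FDR check. These sizes
were chosen so the whole suite completes in minutes on one core while
keeping every claim at the scale that makes it meaningful.

## Numerical choices

- Features are standardized (mean 0, unit sample sd, ddof = 1) before
  covariance and moment computation by default; targets remain diag(S)
  either way. Constant features are rejected at load time with the
  feature named.
- Cholesky-based inversion, no jitter; the error message names the
  remedy (nonzero penalties).
- p-values are floored at the smallest positive normal float; q-values
  inherit the floor. Partial correlations at or beyond the null support
  edge are clamped just inside before likelihood evaluation.
- The κ MLE optimizes over log κ on [log 2.001, log 10⁷] by bounded
  scalar minimization; κ ≤ 1 (non-normalizable density) is rejected.
- Grid ties in penalty selection break toward smaller λ₁ + λ₂; the
  refined optimum is accepted only if it does not exceed the best grid
  value.
- Numbers are serialized with 12 significant digits; TSV round-trips are
  lossless at that precision.

## Known limitations

- Exactly two layers; more layers would need both a generalized risk
  polynomial and per-block-pair effective shrinkage.
- Gaussian likelihood only; heavy-tailed or zero-inflated features
  should be transformed (e.g. nonparanormal) upstream.
- The cross-block effective shrinkage is a reasoned convention, not a
  derived sampling result; calibration absorbs it in practice.
- The null simulation assumes the selected penalties are fixed rather
  than re-estimated per null draw, so κ̂ conditions on the observed
  data's regularization level.
- Risk-optimal shrinkage (Frobenius loss on Σ̂) is not the same
  objective as edge-ranking quality; the benchmark studies show the two
  mostly agree, but at the smallest sample sizes stronger-than-optimal
  shrinkage of a sparse layer can rank edges slightly better than the
  risk minimum.
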