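# Methods

## Uniform design construction

U\*-type tables are generated by the good-lattice-point rule: for *n* runs,
candidate column *g* (any integer 1 ≤ g ≤ n coprime to n+1) is
hᵢ = (i·g) mod (n+1), i = 1..n, which is always a permutation of 1..n.
Among all size-*s* subsets of candidate columns the one minimizing the
centered L2 discrepancy is chosen, with ties broken toward the
lexicographically smallest multiplier set so construction is deterministic.
Discrepancy is evaluated on the unit cube with levels placed at cell
centers, x = (level − 0.5)/n, using the standard closed double-sum form.
Exhaustive subset search is quadratic in the number of candidate columns
and perfectly adequate at the tens-of-runs scale this package targets; it
is not meant for designs with hundreds of factors.

The bundled 10-run, 3-factor design is shipped as a fixture rather than
regenerated: its realized values are exactly the training run sheet, and
its three columns coincide with multipliers {1, 5, 7} mod 11. The general
constructor is not required to reproduce this particular table (different
software makes different, equally admissible subset choices); the fixture
removes that ambiguity from everything downstream.

## Quadratic response surface

Fitting is ordinary least squares on the replicate-*mean* responses, via QR
factorization of the monomial design matrix (better conditioned than the
normal equations on raw-unit monomials; an explicit rank check names the
collinear terms on failure). Raw replicate titers are not part of the
bundled tables, only means ± SD; under balanced replication a replicate-level
fit has identical coefficients, so coefficients are the reproducible
quantity. The ANOVA table therefore uses the means-fit convention —
df_model = p − 1 = 7, df_resid = n − p = 2 for the default 8-term model on
10 runs — and reports both dfs explicitly. On the bundled data this
convention reproduces the reference diagnostics (F = 105.55, R² = 99.7%,
S = 65.41) as well as all eight coefficients. Per-term sums of squares are
partial (t²·MSE_resid), standard errors come from (XᵀX)⁻¹·MSE_resid, and
P-values from the t distribution with df_resid.

The default term set keeps the intercept, three linear, three square terms
and the X1X3 interaction; X1X2 and X2X3 are dropped for their high
correlation with the main effects on this design. Term sets are fully
configurable (`TermSet.full_quadratic`, `.drop`).

The stationary point solves the exact linear system ∇Y = b + Hx = 0 and
classifies the Hessian by its eigenvalues. If the stationary point is not
an interior maximum of the factor box, the box maximum is found instead by
a dense grid scan (101 points per axis by default) polished with L-BFGS-B,
and the result is flagged `method="fallback"`. A singular Hessian (to a
relative determinant tolerance of 1e-12) raises rather than returning an
arbitrary point.

## Neural surrogate

Inputs **and** the response are min-max scaled to [0, 1] over the training
range; predictions are inverse-transformed. Scaling the response, not just
the inputs, is what makes goal MSEs of order 1e-5 meaningful for titers
near 12,000 U/mL. The network is 3-h-1 with log-sigmoid hidden units and a
linear output.

Training is a from-scratch Levenberg–Marquardt loop on the scaled data:
Δw = −(JᵀJ + μI)⁻¹Jᵀe with the analytic error Jacobian. A step is accepted
only when it lowers the MSE (then μ ← μ·0.1); otherwise μ ← μ·10 and the
step is retried, up to μ_max = 1e10, at which point training stops with the
best-so-far parameters and a `mu_overflow` status — divergence never raises
silently. Defaults: μ₀ = 1e-3, goal MSE 1e-5 (scaled), max 1000 epochs.
These damping defaults follow widespread LM-backprop practice; the
configured `learning_rate` (default 0.01) is used only by the
gradient-descent fallback, since LM itself has no learning rate.

Weights are initialized Nguyen–Widrow-style from the run's seed (hidden
weight vectors normalized to 0.7·h^(1/n_in) with biases tiling the input
cube), with plain uniform(−0.5, 0.5) as an option. Training is bit-for-bit
reproducible from the seed.

The architecture search trains each hidden size in 3..12 (and each
configured algorithm) from 5 restart seeds and selects the minimum test-set
scaled MSE, ties breaking toward fewer neurons and then the lower seed. Of
the classical training-algorithm names accepted in the configuration, only
Levenberg–Marquardt is implemented natively; the others map to a plain
batch gradient-descent fallback (recorded as such in the selection report)
or raise `NotImplementedError` if unrecognized — LM is the algorithm of
record here and the search's purpose is the hidden-size sweep.

## Genetic algorithm

Real-coded: one chromosome per candidate, one gene per factor. Each run
draws a uniform random initial population in the box and iterates rank-based
roulette selection (rank weights tolerate negative fitness) with elitism 1,
arithmetic blend crossover (probability 0.4, per-pair random blend factor),
per-gene uniform-reset mutation (probability 0.2) and clipping to the box.
Defaults: population 20, 100 generations, 10 seeded restarts; the overall
best across restarts is returned together with every restart's
population-best trace (monotone non-decreasing whenever elitism ≥ 1).
The default search box is the hull of all bundled experimental conditions
(Asn 50–200, Glu 200–400, Pro 50–200 mg/L); `box="levels"` restricts to the
design's level ranges.

## Sensitivity analyses

**Mean-value perturbation.** For factor *i*, n = 30 offsets are drawn
uniformly on [−σᵢ, σᵢ], where σᵢ is the sample SD (n−1 denominator) of that
training input column; the other factors sit at their training means. Sᵢ is
the sample standard deviation of the 30 model outputs. The spread-based
reading is used because sensitivity is a dispersion, not a magnitude: a raw
root-mean-square of outputs near 12,000 U/mL would be dominated by the
location and rank every factor identically. That literal RMS form remains
available via `statistic="rms"` for completeness. Draws are independent per
factor and seeded. For a linear model f = aX, Sᵢ → |a|σᵢ/√3 (the SD of a
uniform variate), which the tests verify against a 10⁶-draw Monte-Carlo
oracle.

**Coded-range sweep.** Each factor is swept over coded values −2..2
(step 0.1 by default) with the others at coded 0, using the bundled affine
coded-value map. Slopes are least-squares lines over the center interval
[−1, 1] and the edge intervals [−2, −1] and [1, 2] — least squares over the
grid rather than two-point secants, for stability on curved responses.

## Comparison metrics

RMSE uses denominator n. error% is the mean absolute percent error with the
observed value in the denominator. Correlations are stored as fractions and
reported as percents. The report treats precomputed prediction columns and
live surrogates uniformly, so reference columns can be audited with the
same code path. Four error% cells and the test-set correlation of the
bundled reference columns reproduce exactly; the bundled reference RMSE
cells do not follow from the reference prediction columns under any
denominator (recomputation gives ≈39/5.7/588/314 against quoted
32.21/4.84/483.12/237.58) and are reported, not asserted.

## Synthetic data generator

Emulates the study's data-generating process: a known 3-factor quadratic
(or any supplied surface) evaluated at a realized design, plus i.i.d.
additive Gaussian replicate noise, SD 280 U/mL by default — the center of
the 268.6–289.6 U/mL band of replicate SDs in the bundled tables — with
replicate means and sample SDs stored exactly as a wet-lab table would be.
It is homoscedastic and normal by construction, so passing tests demonstrate
correct recovery under those assumptions only; real fermentation noise may
be heteroscedastic, skewed or autocorrelated across batches, and nothing
here validates robustness to that. Probe sizes used in the tests: 10⁴
replicates for the noise-convergence check, a 5×5×5 noiseless grid for
surrogate-recovery checks.

## Known limitations

- The analytic optimum path requires all square terms; pure-linear models
  must use the GA or the grid fallback.
- The LM implementation is dense and batch-mode; it is sized for tens of
  parameters and tens to hundreds of samples, not large networks.
- GA constraint handling is box-only.
- ANOVA on 10 means with 8 terms leaves 2 residual df; its P-values are
  accordingly coarse, which is a property of the design, not the code.
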