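# udopt

Design-of-experiments and surrogate-model optimization for fermentation
media, built around a worked case study: maximizing the titer of iturin A
(a lipopeptide antifungal from *Bacillus subtilis*) in fed-batch
fermentation by tuning the mid-run additions of three amino acids —
asparagine (X1), glutamic acid (X2) and proline (X3), all in mg/L.

The package is for bioprocess engineers and modellers who want to compare
two routes from a small, space-filling experiment to an optimized medium:

1. **Uniform design + quadratic response surface.** A good-lattice-point
   uniform design U\*_n(n^s) spreads *n* runs over the factor box with *n*
   levels per factor (columns are scored by centered L2 discrepancy). The
   responses are fit by ordinary least squares to the second-order polynomial

   Y = β₀ + Σᵢ βᵢXᵢ + Σᵢ βᵢᵢXᵢ² + Σᵢ<ⱼ βᵢⱼXᵢXⱼ

   (by default the reduced 8-term set with only the X1X3 interaction), with
   a full ANOVA table, and optimized analytically by solving ∇Y = 0 and
   classifying the Hessian.

2. **Neural surrogate + genetic algorithm.** A 3-h-1 feed-forward network
   (log-sigmoid hidden layer, linear output, inputs and response min-max
   scaled to [0, 1]) trained by a from-scratch Levenberg–Marquardt loop,
   with a cut-and-try search over 3–12 hidden neurons selected on test-set
   scaled MSE. The fitted surrogate is maximized over the factor box by a
   real-coded genetic algorithm (population 20, crossover 0.4, mutation 0.2,
   100 generations, seeded restarts).

Both surrogates get two sensitivity analyses — the mean-value perturbation
statistic S (SD of model outputs under uniform ±1 SD perturbations of one
input) and a coded-range sweep reporting center and edge slopes — and a
head-to-head comparison report (RMSE, Pearson correlation, mean absolute
percent error) on training and unseen test data.

The 10-run training table, 15-run test table, coded-value map and factor
level grids of the case study ship as packaged CSV fixtures, so the whole
pipeline runs without downloads; a synthetic surface generator (quadratic
truth + Gaussian replicate noise, SD 280 U/mL by default) backs the test
suite with known ground truth.

## Worked example

```sh
udopt run --out-dir demo --seed 42
```

runs the full pipeline on the bundled tables in about two seconds and
prints `run complete: demo/summary.json`. From that summary:

- The quadratic refit on the 10 training means has R² = 0.9973,
  F = 105.55, S = 65.41, and its analytic stationary point (an interior
  maximum) is at Asn 133.0, Glu 291.7, Pro 146.1 mg/L with a predicted
  titer of 13487.1 U/mL. Evaluating instead the rounded reference
  coefficients (`udopt.rsm.reference_equation()`) puts the optimum at
  (133.1, 292.0, 145.9) and 13509.1 U/mL.
- The architecture search selects a 3-8-1 network at this seed
  (train MSE 7.0e-6, test MSE 0.037, scaled); the GA maximum of that
  surrogate is 13213.7 U/mL at Asn 174.2, Glu 399.6, Pro 157.6 mg/L —
  above the best observed training titer of 13057.1 U/mL.
- Mean-value perturbation sensitivities rank the inputs
  Asn (S = 199.9) > Pro (121.1) > Glu (30.0): near the data center the
  response reacts most to asparagine.
- The comparison table shows the neural surrogate generalizing better than
  the quadratic on the unseen test runs (error 2.81% vs 4.12%, correlation
  90.3% vs 78.6%), matching the bundled reference prediction columns'
  pattern (2.19% vs 4.15%, 92.6% vs 78.6%).

Every number above is recomputable from the persisted artifacts
(`rsm_model.json`, `ann_model.json`, `ga_*.json`, `comparison.csv`), and a
fixed `--seed` makes `summary.json` byte-identical across runs.

The same stages are available as individual subcommands (`udopt design`,
`fit-rsm`, `train-ann`, `optimize`, `sensitivity`, `compare`,
`fixtures export`) and as plain library calls under `udopt.design`,
`udopt.rsm`, `udopt.ann`, `udopt.ga`, `udopt.sensitivity`,
`udopt.evaluation`.

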