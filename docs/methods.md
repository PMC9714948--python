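# Methods

## The estimator

Hi-LASSO is a two-stage bootstrap feature selector for linear (or
logistic) models in the high-dimension, low-sample-size regime (p ≫ n).
Both stages repeat the same move B times: draw n samples with
replacement and a random subset of q of the p predictors, and fit a
penalized regression on that submatrix. Because only q predictors are
candidates in a draw, a predictor's coefficient in a draw where it was
not a candidate is *unknown*, and this package records it as missing
(NaN), never as zero.

**Procedure 1 (importance).** Predictor subsets are drawn uniformly;
each draw is fit with an Elastic-Net whose penalty is chosen by
cross-validation within the draw. The importance score of predictor j is
the mean of |coefficient| over the draws in which j was a candidate.
Averaging absolute values matters under multicollinearity: two draws can
estimate the same predictor with opposite signs, and a signed average
(as in Random LASSO's importance) cancels them.

**Procedure 2 (estimation).** Predictor subsets are drawn with
probability proportional to importance, and each draw is fit with an
Adaptive LASSO whose per-predictor penalty weight is 1/importance_j —
the *same global* weight vector in every draw, which is what gives the
procedure its oracle-style weighting; per-draw (local) weights would
vary with which predictors happen to be co-candidates. The final
coefficient of predictor j is the signed mean over the draws where j was
a candidate. A predictor never drawn in procedure 2 is reported as
missing with a warning (the exported table shows 0 plus a
`never_sampled` flag).

**Selection (PSTFSboot).** Predictor j was a candidate k_j times and
nonzero d_j times. Under the null that j is noise, a nonzero estimate is
assumed as likely for j as for the average candidate, giving
d_j ~ Binomial(k_j, pi0) with the pooled rate pi0 = Σd / Σk. The
p-value is the exact binomial upper tail P(X ≥ d_j); predictors with
p < alpha are selected. No multiple-testing correction is applied — the
p-values are exposed so users can layer any correction downstream. The
parametric family here is a design choice: "nonzero out of k candidacies"
is the simplest exchangeable model of the bootstrap selection events, the
pooled rate keeps it estimable when every k_j is small, and the exact
tail avoids a normal approximation that would be poor at k ≈ L. The two
pieces are isolated behind `estimate_null_rate` / `binomial_pvalues` so a
different null can be swapped in.

**Random LASSO baseline.** Implemented with the same machinery for
contrast: importance is |signed sum|/B, procedure 2 uses plain LASSO
(no adaptive weights), the final coefficient is the signed sum over all
B draws divided by B (zeros counted for draws where the predictor was
not a candidate — a systematic shrinkage by the factor k_j/B), and
selection thresholds |beta| at 1/n. Its q and B are set as for Hi-LASSO
so the aggregation and testing rules are the only differences.

## Hyper-parameters

| parameter | default | meaning |
|---|---|---|
| q1, q2 | min(n, p) | predictors per draw; around the sample size is the empirically good region — larger q invites more within-draw collinearity, smaller q inflates B |
| L | 30 | desired average number of candidacies per predictor; sets B = ceil(L·p/q). Around 30 the per-predictor binomial has enough trials to resolve p-values near alpha; beyond ~50 returns diminish |
| alpha | 0.05 | PSTFSboot significance threshold (strict inequality) |
| zero_tol | 0.0 | a coefficient counts as nonzero iff |value| > zero_tol; 0 is exact because coordinate descent returns exact zeros off the active set |
| floor_eps | 1e-10 | relative floor on importance so never-selected predictors keep a positive procedure-2 sampling probability |
| mixing | 0.5 | stage-1 Elastic-Net L1 fraction; the L2 share stabilizes fits under the collinearity the method targets |
| lambda_grid_size | 30 | penalties on the geometric CV grid per draw; fits are repeated ~2B times, so a moderate grid is the cost-accuracy compromise this package defaults to |
| cv_folds | 5 | per-draw penalty selection |

## Randomness and reproducibility

A single `random_state` seeds everything. Per-draw seeds are derived
from it by (stage, draw index) through independent seed-sequence
substreams, and weighted q-of-p sampling without replacement uses
exponential keys (Efraimidis–Spirakis: take the q smallest
Exp(1)/prob_j), so a draw is a pure function of its seed and inclusion
probability is monotone in the weights. Results are therefore bitwise
identical across `n_jobs` settings and across reruns; bootstrap
execution order cannot perturb anything.

## Synthetic data

`make_scenario` draws X with iid multivariate-normal rows (independent,
AR(1), or block-constant correlation; AR(1) and block structures are
generated by recursion/factor construction, so p = 10,000 needs no
p × p covariance), plants `n_causal` nonzero coefficients with random
signs, and adds iid Gaussian noise. Six (p, n) sizes are registered,
Dataset I (100, 50) through Dataset VI (10,000, 400), spanning p/n from
1 to 50. The non-size fields default to this package's own stand-in
design — 10 causal predictors, |beta| ~ U(1, 3), AR(1) rho = 0.5,
noise sd 1 — chosen as a classic sparse-regression simulation with
non-trivial correlation; every field is overridable, so other scenario
designs at the same sizes can be encoded without code changes.

`make_semi_real` emulates the gene-expression benchmark construction on
any expression-like matrix with a survival-months vector: rank genes by
|correlation| with raw survival months (Pearson by default, Spearman
optional), take the top 20 as the support, draw their coefficient
magnitudes from N(4, 1) keeping the correlation sign, and add noise with
sd equal to the sd of log survival months. Ties at the support boundary
break by gene order and are logged. `synthetic_expression_cohort`
provides a synthetic stand-in cohort (block-correlated Gaussian
"expression", log-normal survival driven by 20 genes) so the semi-real
path is testable offline.

What these generators do not emulate: heavy-tailed and count-valued
expression distributions, batch effects, censoring in survival,
non-linear gene–outcome links. Passing tests on them demonstrates the
selector's statistical behavior under the stated model, not performance
on any particular cancer cohort.

## Numerical choices

- Columns are standardized per draw (mean 0, population sd 1; response
  centered in regression mode); coefficients are mapped back to the
  original scale before aggregation, so importance and final estimates
  are comparable across draws with different candidate sets.
- The Adaptive LASSO is solved by rescaling columns by
  importance/max(importance) and fitting a plain LASSO; the rescaled and
  direct weighted-penalty formulations agree to solver tolerance (tested
  against an independent coordinate-descent oracle).
- Non-converged coordinate-descent fits log a warning and keep the best
  iterate; a solver error inside a draw aborts with the draw index.
- "Nonzero" is exact (active-set) zero versus not; `zero_tol` exists for
  approximate backends.
- Kuncheva index with unequal set sizes (possible for threshold-based
  selectors) replaces s by the geometric mean of the two sizes and logs
  that the generalized form was used; benchmark tables report the sample
  standard deviation (ddof = 1) over repeats.

## Problem sizes used in the checked experiments

The test suite and acceptance script run the full pipeline at desk
scale: Dataset I/II at their registered sizes with 10 repeats and
Dataset IV with 3, PSTFSboot calibration at p = n = 50 over 40
pure-noise replicates (60 in the acceptance script), support recovery at
p = 10, n = 50, and stability over 4 re-runs on a 150 × 300 synthetic
cohort. These sizes keep a full run to minutes on one CPU while leaving
every code path exercised end to end; the two largest registered
scenarios (p = 10,000) run through the identical code and are exercised
only via the registry.

## Known limitations

- The PSTFSboot binomial null assumes the nonzero events of a predictor
  are independent across draws at a common rate. Bootstrap draws reuse
  the same dataset, so a predictor that is correlated with the realized
  noise (or with a causal predictor) tends to be nonzero in *most*
  draws: the per-predictor counts d_j are overdispersed relative to
  Binomial(k_j, pi0), and the selected fraction under a pure-noise null
  exceeds the nominal alpha (about 0.25 at alpha = 0.05 in the
  p = n = q = 50 calibration run that the test suite and acceptance
  script compute). The reported alpha is therefore a ranking threshold,
  not a type-I-error rate; the test suite measures this honestly rather
  than asserting nominal calibration.
- L is enforced in expectation only for procedure 1; weighted sampling
  in procedure 2 makes per-predictor candidacy counts uneven by design.
- The logistic mode cross-validates deviance with saga/liblinear solvers
  and is substantially slower per draw than the regression path.
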