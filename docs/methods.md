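# Methods

## Model and assumptions

The package fits a multi-trial joint regression: one linear predictor per
reading trial, coupled by a nuclear-norm penalty on the stacked weight matrix
W ∈ R^{D×m},

    J(W, b) = Σ_i ‖X_i w_i + 1_N b_i − Y‖² + λ Σ_i ‖w_i‖² + γ ‖W‖_* .

The implicit assumptions are: (i) the criterion score is linear in the
(standardized) indicators; (ii) every trial measures the same latent ability,
so the per-trial weight vectors span a low-dimensional subspace — the nuclear
norm, as the convex envelope of rank, encodes this; (iii) a single shared
score vector Y is regressed on every trial's features, so a per-trial fit can
only succeed to the extent that a trial's features carry the common signal.

Because ‖W‖_* is not differentiable, the solver minimises the smoothed
surrogate Trace(Wᵀ(WWᵀ + δI)^{−1/2}W). Differentiating gives closed-form
per-trial updates with the reweighting matrix D_r = ½(WWᵀ + δI)^{−1/2}; a
sweep updates all w_i (fixed D_r and biases), then all b_i, then D_r, then
the objective. With D_r fixed the (w_i, b_i) update is the exact per-trial
penalised least-squares solution, so each sweep is a
majorise-minimise/block-descent step and the objective trace is
non-increasing (asserted in tests to 1e-9 relative slack).

## Tunable parameters

| parameter | default | role |
|---|---|---|
| λ (`lam`) | 1 | per-trial ridge weight; controls variance of each w_i (unitless after z-scoring) |
| γ (`gam`) | 1 | nuclear-norm weight; larger values pull the w_i toward a shared direction and shrink rank |
| δ (`delta`) | 1e-8 | smoothing floor of the inverse square root; makes D_r well defined for rank-deficient W (including the zero start) |
| `tol` | 1e-6 | relative objective-change stopping rule \|J(t)−J(t−1)\| ≤ tol·max(1, \|J(t−1)\|) |
| `max_iter` | 100 | sweep cap; hitting it sets `converged_=False` with a warning, not an error |
| `init` | ridge warm start | the γ = 0 per-trial solution; well-posed, close to the fixed point. A zeros start is available but crosses a slow rank-reduction regime |

λ = γ = 1 are the reference defaults for cohort-scale data. Both matter
relative to the loss scale: after per-trial z-scoring, X_iᵀX_i ≈ N·I, so
with N in the tens the penalties are mild.

## Numerical choices

- All linear systems are solved by Cholesky factorisation, never by explicit
  inverses; a factorisation failure (λ = γ = 0 with collinear features)
  raises a `SingularTrialError` naming the trial.
- D_r and the trace surrogate are computed from a symmetric eigendecomposition
  of WWᵀ + δI with eigenvalues floored at δ.
- Normalization z-scores each feature within each trial using the population
  SD (ddof = 0) of the training fold; zero-variance columns are centered only,
  with a warning.
- Ties and degenerate inputs in screening are resolved explicitly: all-equal
  observations give F = 0, p = 1; zero within-group variance with distinct
  means gives F = ∞, p = 0 with a warning.
- Convergence tail: iteratively-reweighted trace-norm solvers have a small
  tail of slow instances — when two singular values of the solution are
  nearly equal near a rank boundary, sweeps make steady but tiny progress
  along a flat valley. On small random problems (N = 30, D = 5, m = 4,
  λ = γ = 1) the median is a handful of sweeps but roughly 1% of instances
  need more than 50 (the acceptance test for the 50-sweep bound documents
  this). The objective is nonetheless within ~1e-4 relative of the convex
  optimum by then, which is what the solver-versus-oracle check measures.

## Design decisions where the procedure was open

- **Per-trial biases.** The stationarity equations determine one intercept
  per trial; the output is the length-m vector b.
- **Update order.** Within a sweep: all w_i, then all b_i, then D_r, then J.
  Each linear solve thus uses the freshest reweighting matrix from the
  previous sweep's W.
- **Prediction aggregation.** How m per-trial predictions combine into one
  score is a convention: the unweighted mean (median available). Clipping to
  [0, 100] is off by default.
- **Error metric.** "Average error out of 100" is read as mean absolute error
  on the centesimal scale; RMSE is available.
- **Contribution statistics.** Indicator contribution is the mean absolute
  weight per feature row, normalized to sum to 1; trial contribution is the
  column absolute-weight sum, reported raw and max-normalized. These are this
  package's definitions — no formula is fixed by the source material — and
  they satisfy the qualitative orderings one expects (a zero row contributes
  nothing; identical columns contribute equally).
- **Splitting.** Half-splits are random participant-level partitions
  (⌈N/2⌉/⌊N/2⌋); an optional stratified mode balances the folds around the
  median score. Imputation and normalization statistics come from the
  training fold only.
- **Missing values.** Blink-family cells can be empty in real recordings; the
  default strategy replaces a missing cell by its trial-feature training
  mean, equivalent to zero after z-scoring.

## The screening count

On the bundled published screening table, the α = 0.05 rule flags 13 of 15
indicators (fixation position Y, p = 0.83, and regression length, p = 0.19,
are excluded). The source study's running text elsewhere describes fourteen
indicators as sensitive, including regression length; the table-based count
of 13 is used here as authoritative, and this discrepancy is deliberately
surfaced rather than silently resolved.

## What the synthetic generator emulates — and what it does not

The generator reproduces the *structure* of the motivating study: N = 74
participants in balanced high/low ability groups, m = 42 trials, 16
eye-tracking indicators on instrument-plausible scales plus 3 exam-score
columns, criterion scores spanning 48.8–90.83, 1-SD group mean shifts on the
13 table-sensitive indicators, ~10% missing cells in blink columns, and an
exactly rank-2 true weight matrix whose dominant component is shared across
trials (the trial-varying component is 1.5% of its size, echoing the narrow
band of trial contributions such studies report).

Each participant has a stable standardized profile observed in every trial
plus trial-level noise at 4% of the between-participant SD (`trial_noise`);
exam columns are constant across trials. Scores are generated from the
standardized features through W*, noise of 0.5 points is added, and the
result is affinely mapped onto the score range — W*, b* and the noise
realisation are rescaled by the same map so the generative identity holds
exactly on the 0–100 scale (consequently the realised noise SD differs from
the nominal one by the per-seed map slope, which is near 1).

This is a *stable-participant regime*, chosen so that the true weights are
identifiable from a single cohort: the expected recovery error decomposes
into a measurement-noise term (≈ 0.025 relative Frobenius at N = 74), a
trial-noise term (≈ 0.020: trial i's own feature noise enters the per-trial
regression un-averaged), and the unrecovered trial-varying weight component
(0.015). Real eye-tracking data is very different in one key respect:
trial-to-trial within-person variability of eye-movement indicators is
typically as large as or larger than between-person variability. Passing
recovery tests in this regime therefore demonstrates correctness of the
estimator and pipeline, not that weights would be recoverable this accurately
from a real 74-participant cohort. Likewise the generator works at the
indicator level only — no gaze samples, saccade kinematics or pupil
waveforms — and no synthetic result is claimed to reproduce any published
F statistics or error figures.

## Problem sizes used in tests and the acceptance script

Solver-versus-oracle and convergence checks run on N = 30, D = 5, m = 4
problems (20 and 100 instances); recovery and evaluation checks use the
default 74×42×19 cohort (10 seeds for recovery, 100 half-splits for
evaluation); screening power uses 50 cohort draws. These sizes make the full
suite run in well under a minute while keeping every statistical assertion
comfortably powered.

## Known limitations

- The model is linear; no interactions or nonlinear effects.
- The nuclear-norm solver targets the smoothed surrogate at fixed δ; for
  solutions with singular values near √δ the iteration slows (see above).
- Screening applies no multiple-testing correction, by design.
- The repeated-evaluation error summary excludes failed runs (aborting if
  more than 20% fail), which slightly biases summaries optimistic in
  pathological settings.
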