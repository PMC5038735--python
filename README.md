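# mtjl — multi-trial joint learning of reading ability from eye-tracking data

`mtjl` implements a computational model that predicts a reader's ability score
(0–100 points) from eye-movement indicators recorded while they read a series
of short sentences. It is aimed at researchers in educational measurement and
physiological computing who have per-trial eye-tracking feature tables
(fixations, saccades, regressions, blinks, pupil size, plus optional exam
scores) and a criterion score per participant.

## The model

Each participant completes m reading trials. Trial i yields a feature matrix
X_i ∈ R^{N×D} (N participants, D indicators) and every participant has one
reading score, collected in Y ∈ R^N. The model fits one linear predictor per
trial but couples all trials through a low-rank penalty on the stacked weight
matrix W = [w_1, …, w_m] ∈ R^{D×m}:

    min_{w_i, b_i}  Σ_i ‖X_i w_i + 1_N b_i − Y‖²  +  λ Σ_i ‖w_i‖²  +  γ ‖W‖_*

where ‖W‖_* is the nuclear norm (the sum of singular values, the convex
surrogate of matrix rank). The low-rank term expresses that the m trials
measure the same underlying ability, so their weight vectors should be nearly
collinear. The solver uses the smoothed trace identity
‖W‖_* ≈ Trace(Wᵀ(WWᵀ + δI)^{−1/2}W), which yields closed-form
iteratively-reweighted updates

    w_i = (X_iᵀX_i + λI + γ D_r)^{−1} X_iᵀ(Y − 1 b_i),
    b_i = mean(Y − X_i w_i),
    D_r = ½ (WWᵀ + δI)^{−1/2},

swept until the objective stabilises. Predictions for a new participant are
the mean of the m per-trial predictions. On top of the regression, the package
provides one-way ANOVA screening of indicators between high- and low-ability
groups, a synthetic cohort generator with known ground truth, and a repeated
half-split evaluation pipeline.

## Worked example

```python
import numpy as np
from mtjl import (MTJLRegressor, MTJLHyperparams, screen_indicators,
                  repeated_evaluation)
from mtjl.synthetic import SyntheticConfig, generate_cohort, impute_missing

data, truth = generate_cohort(SyntheticConfig(seed=0))
print(data.n_participants, data.n_trials, data.n_features)   # 74 42 19

table = screen_indicators(data, truth.group_labels, alpha=0.05)
print(int(table.sensitive.sum()))                            # 15

data = impute_missing(data, "train_mean")                    # fill blink gaps
model = MTJLRegressor(lam=1.0, gam=1.0).fit(data)
print(model.converged_, model.n_iter_)                       # True 2

report = repeated_evaluation(data, MTJLHyperparams(), n_runs=100, base_seed=0)
print(f"{report.mean_error:.2f} +/- {report.std_error:.2f}") # 0.33 +/- 0.09
```

The cohort mimics the structure of a 74-participant reading study: 42 trials,
16 eye-tracking indicators plus 3 entrance-exam scores, scores spanning
48.80–90.83 points, and sporadically missing blink values. Screening flags 15
of the 19 columns as sensitive (the 14 with built-in group shifts plus, at
this seed, one false positive at α = 0.05). The fit converges in 2
reweighting sweeps from its ridge warm start, and the repeated half-split
evaluation predicts held-out scores with a mean absolute error of 0.33 ± 0.09
points over 100 random splits. `report.indicator_contributions` gives the
normalized mean absolute weight per indicator — here saccade rate (0.123),
Chinese exam score (0.114) and fixation rate (0.105) lead, matching the
generator's built-in weighting.

A command line mirrors the library:

```sh
mtjl simulate --out cohort/ --seed 0
mtjl screen   --data cohort/ --out screening.csv
mtjl fit      --data cohort/ --out model.json --lambda 1 --gamma 1
mtjl evaluate --data cohort/ --out report.json --n-runs 100 --seed 0
```

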