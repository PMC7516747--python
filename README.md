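# immigrate

Interaction-aware, margin-based feature selection and classification for
tabular biomedical data.

Relief-family algorithms score features by contrasting each sample's
distance to its nearest same-class neighbor ("hit") against its nearest
other-class neighbor ("miss"). They are fast and model-free, but a plain
feature-weight vector cannot say *why* a feature matters — in particular it
cannot separate a feature's main effect from its interactions with other
features, which is often the interesting biology (e.g. co-regulated gene
pairs). This package learns a full symmetric weight **matrix** W instead:
diagonal entries weight single features, off-diagonal entries weight
feature *pairs*, and the whole matrix is read directly as an interaction
map.

## The model in brief

Distances use the quadratic-Manhattan form
`q(x_i, x_j) = |x_i − x_j|ᵀ W |x_i − x_j|` (element-wise absolute value,
`W ⪰ 0` symmetric, ‖W‖_F = 1). Each training instance carries softmin
probability distributions α over its hits and β over its misses, and the
fitted objective

```
C = Σ_n [ Σ_h α_nh q(x_n,x_h) − Σ_m β_nm q(x_n,x_m) ]
    + σ Σ_n [ E_miss(n) − E_hit(n) ]
```

maximizes the probabilistic hypothesis-margin while stabilizing it by a
max–min entropy principle (spread hit mass evenly, concentrate miss mass).
Both alternating steps are exact: α, β are closed-form softmins of the
q-distances, and W is the spectral minimizer of `tr(WΣ)` over unit-Frobenius
PSD matrices, built from the negative eigenvalues of the hit-minus-miss
scatter Σ. When Σ is diagonal the update reduces exactly to classical
closed-form Relief, which the package also ships as a baseline.

On top of the core learner the package provides

- prediction by softmin-weighted class margin (σ → 0 recovers 1-NN),
- weight pruning (threshold 1/A) and σ tuning by internal CV,
- a two-stage fit for wide tables (diagonal screening at 2/A, then full
  interactions on the kept features),
- AdaBoost ensembles with sample-weighted base fits and geometric σ
  annealing from 4 to 0.2,
- a contaminated two-Gaussian interaction benchmark with an exact Bayes
  oracle, and
- the evaluation harness: repeated stratified 10-fold CV (100 paired
  trials) with a two-stage paired t-test win/tie/loss comparison.

See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

```python
import numpy as np
from immigrate import (InteractionGaussianConfig, generate_dataset,
                       fit_immigrate, predict_batch)

# two interacting Gaussian classes, 100 samples each, 10% contamination
data = generate_dataset(InteractionGaussianConfig(noise_fraction=0.10, seed=7))
model = fit_immigrate(data, sigma=1.0, seed=0)
print("iterations:", model.n_iterations)
print(np.round(model.W.W, 3))

test = generate_dataset(InteractionGaussianConfig(noise_fraction=0.10, seed=8))
print("held-out accuracy:",
      np.mean(predict_batch(model, test.features) == test.labels))
```

Output:

```
iterations: 10
[[0.58  0.358]
 [0.358 0.638]]
held-out accuracy: 0.935
```

The fit converged within its default ten-round cap. The learned matrix
puts substantial weight on the off-diagonal entry w12 = 0.358: the
classifier has discovered that the two features discriminate *jointly*
(the classes differ along x1 − x2), not merely individually. Held-out
accuracy of 0.935 sits close to the exact likelihood-ratio ceiling for
this contaminated mixture (≈ 0.954 by the package's Monte-Carlo Bayes
oracle). Raising the contamination toward 50% progressively erodes w12 —
the robustness trend the test suite checks.

The same functionality is available from the shell:

```sh
immigrate simulate --seed 7 --noise-fraction 0.10 --out data.csv
immigrate fit data.csv --sigma 1.0 --out model.json --weights-out weights.csv
immigrate predict model.json data.csv --out predictions.csv
immigrate compare data.csv --method-a immigrate --method-b relief_1nn --sigma 1.0
```

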