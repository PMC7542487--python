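# srmkl — style-regularized multiple-kernel LSSVM

`srmkl` is a Python package for binary classification of **stylized data**:
datasets whose samples arrive in groups that share a common systematic
distortion — a writer's hand, a recording session, an EEG electrode set.
Ordinary kernel classifiers see only the pooled geometry of the samples;
when each group is warped by its own affine "style", the pooled decision
boundary degrades even though every group is internally easy to separate.
The package is aimed at biomedical signal classification (its motivating
application is epileptic-EEG recognition, where each Bonn recording set
behaves as one style), but it consumes any feature table with group ids.

## The model

Training data `D = {(x_j^k, y_j^k)}` is partitioned into N style groups
(t_j samples in group j, labels ±1). Three ingredients are learned jointly:

1. **A least-squares SVM (LSSVM).** The hinge loss is replaced by squared
   error under equality constraints, so for a fixed Gram matrix K the dual
   variables come from one linear solve: with `K̃ = K + I/λ`,

       b = (1ᵀK̃⁻¹y)/(1ᵀK̃⁻¹1),   α = K̃⁻¹(y − b·1),

   and the KKT conditions give `α_j = λ e_j` for the training residuals.

2. **Multiple kernel learning (MKL).** K is a convex combination
   `K = Σ_i μ_i K_i` of M base Grams (default bank: seven gaussians at
   scaled median-distance widths, a linear kernel, polynomials of degree 2
   and 3), with μ on the probability simplex. The min–max problem over
   (μ, α) is a semi-infinite linear program solved by the standard
   cutting-plane scheme: each inner LSSVM solve contributes one linear cut,
   a small LP over the accumulated cuts updates μ, and the loop stops when
   the bound gap closes.

3. **Style regularization.** Each group gets a feature-space matrix A_j that
   maps the group toward a standard style, penalized by
   `λγ Σ_j ‖A_jᵀ − I‖_F²`. The stationarity condition forces the rank-one
   structure `A_jᵀ = I + (1/2λγ) w v_jᵀ`, where w is the classifier weight
   vector and v_j a group-local combination of mapped samples — so every
   transformed kernel value reduces to original kernel values (the kernel
   trick), and the whole style adaptation is a rank-two correction of the
   combined Gram. γ → ∞ pins every A_j at the identity and recovers the
   plain multi-kernel model.

Training alternates MKL fits on the style-transformed Gram with closed-form
style updates; the first iteration is exactly plain MK-LSSVM. Prediction
follows three rules: **Rule 1** ignores style; **Rule 2** applies the
trained A_j of a test sample's (known) group to the cross-kernel values;
**Rule 3** handles an unseen style group by temporary Rule-1 labels, a
refit with the group appended as a new style, and a final Rule-2 pass.

## Worked example

```python
import numpy as np
from srmkl import (SynthConfig, SplitPlan, generate, make_splits,
                   fit_sr, evaluate)

ds = generate(SynthConfig(n_groups=3, per_group=40, dim=4, class_sep=2.0,
                          style_strength=2.0, noise_sd=1.0, seed=1))
train, test = make_splits(ds, SplitPlan(0.5), seed=1001)

model = fit_sr(train, lam=1.0, gamma=0.1, max_outer=20)
print("outer iterations:", model.n_iter)
print("objective trace:", np.round(model.objective_trace, 4))
print("kernel weights mu:", np.round(model.mkl.weights.mu, 4))

baseline = fit_sr(train, lam=1.0, gamma=0.1, max_outer=1)   # plain MK-LSSVM
print("accuracy, plain MK-LSSVM (Rule 1):", evaluate(baseline, test, rule=1))
print("accuracy, SR-MKL-SVM   (Rule 2):", evaluate(model, test, rule=2))
```

Output:

```
outer iterations: 4
objective trace: [13.0188  5.3967  2.424   7.2033]
kernel weights mu: [0.8081 0.     0.     0.     0.     0.     0.     0.1919 0.     0.    ]
accuracy, plain MK-LSSVM (Rule 1): 0.75
accuracy, SR-MKL-SVM   (Rule 2): 0.8333333333333334
```

The generator draws three style groups, each a rotated and shifted copy of
two Gaussian classes; at `style_strength=2` the distortions badly hurt the
pooled classifier. The objective trace shows the alternation descending and
then aborting at an uphill step (the best iterate is kept — alternating a
min problem with a regularized least-squares block carries no global descent
guarantee). The SILP concentrates weight on the widest gaussian kernel plus
the linear kernel, and style-aware Rule-2 prediction recovers about eight
points of accuracy over the unstyled baseline on this seed.

The same flow is available from a shell:

```sh
srmkl generate --out data.csv --style-strength 2 --seed 1
srmkl fit --data data.csv --model model --lam 1.0 --gamma 0.1
srmkl predict --model model --data data.csv --rule 2 --out pred.csv
srmkl evaluate --model model --data data.csv --rule 2
```

An optional front-end (`srmkl.eeg_pipeline`) loads the Bonn University
epilepsy EEG sets A–E from their ASCII distribution, extracts kernel-PCA
features (70 components by default), and assembles the four benchmark
train/test designs; it is never needed by the test suite.

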