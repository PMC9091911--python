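# lmadapt

Robust **l**atent **m**ulti-source domain **adapt**ation for feature-vector
classification, built for the cross-subject / cross-dataset setting of
EEG-based emotion recognition: several labeled *source* subjects (or
datasets) and one *unlabeled* target subject whose feature distribution
differs from every source.

## The model

Given `S` labeled source domains `{X^a, Y^a}` and unlabeled target features
`X^t` (all `d × n`, e.g. differential-entropy EEG features), the model
jointly learns per source `a` a composite classifier `T_a = W_a + Θ_aᵀ P_a`
with an orthonormal-row latent subspace `Θ_a` (`Θ_a Θ_aᵀ = I_r`), a target
classifier `W_t`, per-source target label estimates `F_a`, a shared estimate
`F`, and simplex weights `ϑ`, `η` over the sources, by minimizing

```
min  Σ_a [ ϑ_a^q1 ‖Y^a − X^aᵀ T_a‖₂,₁                      robust source fit
         + α (‖T_a‖₂,₁ + ‖T_a − Θ_aᵀ P_a‖_F²)              sparse complexity
         + η_a^q2 ( ‖F_a − X^tᵀ T_a‖₂,₁                    prediction consistency
                  + tr(Θ_a C_a Θ_aᵀ)                        distribution alignment
                  + ‖F_a − F‖_F² ) ]
     + ‖X^tᵀ W_t − F‖_F² + β (‖W_t‖₂,₁ + tr(Fᵀ L F))       target model
     + (λ/2) ‖[P_1, …, P_S]‖_*                              low-rank coupling

s.t. Σ ϑ_a = Σ η_a = 1,  ϑ, η ≥ 0,  Θ_a Θ_aᵀ = I_r .
```

`C_a = X_a L_a X_aᵀ + Λ_a` combines a k-NN graph Laplacian (locality
preservation on the packed pair `X_a = [X^a, X^t]`) with `Λ_a`, the sum of
marginal and class-conditional MMD alignment matrices (target class
memberships from pseudo-labels). The l2,1 norms make the source fits robust
to outlier samples and drive whole feature rows to zero; the trace norm
couples the latent classifiers so correlated discriminative structure is
shared across sources. A kernelized variant replaces every feature matrix by
its empirical kernel map (RBF, Laplacian, inverse-distance or
inverse-squared-distance kernels, optionally stacked as a multi-kernel map).

Optimization is alternating closed-form block-coordinate descent on an IRLS
(majorize-minimize) surrogate: each l2,1 / trace-norm term becomes a frozen
diagonal-weighted quadratic, every block then has an exact solve (the
subspaces via an eigen step with a monotonicity safeguard), and the objective
is non-increasing across iterations. The loop stops when the relative
objective range over a 6-iteration window falls below `1e-5`.

Prediction fuses the source ensemble and the target model,
`ŷ = argmax [ δ Σ_a ϑ_a xᵀT_a + (1−δ) xᵀW_t ]`, with `δ = 0.5` by default.

## Worked example

The synthetic generator emulates the cross-subject setting:
class-conditional Gaussian features shared across domains, each domain
perturbed by a random affine shift.

```python
import numpy as np
from lmadapt import LMAClassifier, chance_level
from lmadapt.synthetic import easy_preset, generate_problem

problem, y_true = generate_problem(easy_preset(seed=0))   # 3 sources + target
sources = [(X.values.T, Y.to_labels()) for X, Y in problem.sources]
clf = LMAClassifier().fit(sources, problem.target.values.T)

print("iterations:", len(clf.trace_.objective), "| stopped by:", clf.trace_.stopped_by)
print("objective: %.3f -> %.3f" % (clf.trace_.objective[0], clf.trace_.objective[-1]))
print("source weights (vartheta):", np.round(clf.state_.vartheta, 3))
print("alignment weights (eta):  ", np.round(clf.state_.eta, 3))
print("target accuracy: %.3f" % clf.score(problem.target.values.T, y_true))
mean, ub = chance_level(n=120, c=3, reps=200, seed=0)
print("chance level: %.2f%% (95%% upper bound %.2f%%)" % (mean, ub))
```

prints

```
iterations: 36 | stopped by: window
objective: 166.360 -> 33.985
source weights (vartheta): [0.455 0.241 0.305]
alignment weights (eta):   [0.099 0.629 0.272]
target accuracy: 0.992
chance level: 32.88% (95% upper bound 33.45%)
```

The objective decreases monotonically until the window rule fires; `ϑ`
upweights the sources whose robust regression fits best and `η` those whose
distributions align best with the target; the fused prediction recovers 99%
of the unlabeled target's classes, far above the ~33% empirical chance level
of 3-class random prediction.

A command-line interface mirrors the library:

```
lmadapt simulate --out-dir data --seed 0
lmadapt fit --sources data/source_0_features.csv:data/source_0_labels.csv \
            --sources data/source_1_features.csv:data/source_1_labels.csv \
            --sources data/source_2_features.csv:data/source_2_labels.csv \
            --target data/target_features.csv --out model.h5
lmadapt chance --n 3000 --classes 3
```

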