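# cuckoofuse

Adaptive-weight soft-voting fusion for probabilistic classifiers, with
Cuckoo Search weight optimization and agreement-based evaluation.

## The problem

Ordinal severity staging from medical images — here, dementia severity
graded *none < very mild < mild < moderate* from brain MRI — is usually
attacked with several convolutional classifiers whose per-class probability
outputs disagree in informative ways. Probability-level ("soft voting")
fusion combines them: for models A and B with per-sample class-probability
vectors P_A and P_B, the fused prediction is either the plain average

    P_final = (P_A + P_B) / 2

or the weighted sum

    P_final = w_A · P_A + w_B · P_B,   w_A, w_B ∈ [0, 1],

with the predicted stage taken as the row argmax. The weights are **not**
constrained to sum to one — the decision is scale-invariant — and the best
pair is found by **Cuckoo Search**: a population metaheuristic in which
candidate weight vectors ("eggs" in "nests") are perturbed by heavy-tailed
Lévy flights, displace random nests when fitter, and a fraction `pa` of the
worst nests is abandoned and re-drawn each generation. Fitness is
validation accuracy of the fused argmax labels (or, optionally, Scott's Pi
against truth). The search keeps an archive of the best weight vectors for
reuse.

Evaluation follows the conventions of the severity-staging literature:
one-vs-rest precision/recall/F1 per class, their micro-averages (equal to
accuracy for single-label tasks), micro ROC-AUC over the flattened
one-vs-rest expansion, and **Scott's Pi**,

    π = (P_o − P_e) / (1 − P_e),

the chance-corrected agreement between two label streams with P_e computed
from their *pooled* marginal distribution; optional linear/quadratic
weights discount adjacent-stage near-misses.

The package also implements the reservation-first class-imbalance protocol
used with the OASIS-derived severity dataset (67,222 / 13,725 / 5,002 / 488
scans per class): reserve a real-image test set per class *before* any
resampling, balance the remaining pool to a per-class target by
undersampling majorities and duplicating minorities, then split
train/validation with per-class proportional allocation. A synthetic
generator produces correlated pairs of probabilistic classifiers of
controllable skill so every stage is testable without images.

## Worked example

```sh
cuckoofuse simulate --counts 100,80,50,20 --seed 7 --rho 0.6 \
    --skill-a 0.9 --skill-b 0.75 --out-dir demo
cuckoofuse agree demo/model_a.csv demo/model_b.csv --out demo/agree.csv
```

`agree.csv` holds the pairwise model-vs-model Scott's Pi matrix:

```
model,model_a,model_b
model_a,1.0,0.6822281936066543
model_b,0.6822281936066543,1.0
```

The two simulated models (skills 0.9 and 0.75, error correlation 0.6)
agree at π ≈ 0.68 — well above chance, far from redundant. Optimizing the
fusion weights:

```sh
printf 'predictions:\n  - demo/model_a.csv\n  - demo/model_b.csv\nfitness: accuracy\nseed: 7\n' > demo/opt.yaml
cuckoofuse optimize --config demo/opt.yaml --sweep-grid 0.05 --out-dir demo/opt
# INFO cuckoofuse: best weights [0.18499307299412238, 0.0] fitness 0.928000 (345 evaluations)
```

On this 250-sample problem the search learns that the weaker, correlated
model adds nothing: the best weights put all mass on model A
(any positive w_A with w_B = 0 gives the same argmax), reaching fused
accuracy 0.928 — the archive in `demo/opt/search.json` and the
per-generation history in `demo/opt/history.csv` document the search, and
`demo/opt/sweep.csv` the 0.05-grid weight sweep. Evaluating a single model:

```sh
cuckoofuse evaluate demo/model_a.csv --out demo/report.json
# INFO cuckoofuse: accuracy 0.9280 micro-F1 0.9280 -> demo/report.json
```

The report's micro precision, recall and F1 all equal the accuracy
(0.928, the pooled-counts identity for single-label tasks), alongside
per-class rows, micro ROC-AUC and Scott's Pi vs truth (0.897 here).

Everything is also available as a library:

```python
import numpy as np, cuckoofuse as cf

rng = np.random.default_rng(0)
pair = cf.SimPairSpec(cf.SimModelSpec(0.95), cf.SimModelSpec(0.85), rho=0.5)
a, b = cf.simulate_correlated_pair(rng.integers(0, 4, 5000), pair,
                                   cf.DEMENTIA_SCHEME, rng)
fit = cf.make_accuracy_fitness([a, b], cf.DEMENTIA_SCHEME)
res = cf.cs_optimize(fit, 2, cf.CSConfig(seed=0))
fused = cf.weighted_fuse([a, b], res.best_weights)
report = cf.evaluate(a.truth, fused.probs, cf.DEMENTIA_SCHEME.names)
```

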