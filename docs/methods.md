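# Methods

## Fusion model

Each classifier m emits an N × K matrix of class probabilities (rows sum to
1 within 1e-6; out-of-tolerance rows are rejected at load time, with an
explicit `renormalize=True` opt-in — silent repair would corrupt every
downstream metric). Weighted fusion applies the literal weighted sum
`P[i,k] = Σ_m w_m P_m[i,k]` with each w_m in [0, 1] and **no sum-to-one
constraint**: the decision is the row argmax, which is invariant to a
common positive scaling of the weights, so near-one-sum pairs such as
(0.5, 0.45) are meaningful search points and fused rows are deliberately
left unnormalized. Plain averaging is the special case w_m = 1/M and is
implemented as exactly that, so the two paths agree bit-for-bit. Argmax
ties break toward the lowest class index — the least severe stage under the
scheme ordering — a conservative, deterministic rule. Fusion is defined for
M ≥ 2 models; the pairwise case is the primary use.

Downstream, only the argmax labels feed the agreement metrics; ROC-AUC
ranks the raw weighted sums, which is rank-equivalent to any common
rescaling.

## Metrics

* **Accuracy** is correct/total. For a single-label multi-class task the
  one-vs-rest micro-averaged precision, recall and F1 (pool Σ TP, Σ FP,
  Σ FN over classes, then the binary formulas) all equal accuracy; the
  suite computes them independently and the tests assert the identity.
* **Per-class precision/recall/F1** come from one-vs-rest confusion counts
  (delegated to scikit-learn's `multilabel_confusion_matrix`). A zero
  denominator yields value 0 plus an `undefined` flag rather than an
  exception, so batch evaluation never aborts.
* **Micro ROC-AUC** flattens the N × K one-hot truth and score matrices
  into N·K binary decisions and scores them with the trapezoidal AUC
  (ties count 1/2); per-class one-vs-rest AUCs are also reported. Macro
  AUC variants are out of scope.
* **Scott's Pi** is authored here: π = (Po − Pe)/(1 − Pe) with Pe from the
  pooled marginals m_k = (count_a(k) + count_b(k))/(2N). The default is the
  standard unweighted form; `linear` (1 − |i−j|/(K−1)) and `quadratic`
  (1 − ((i−j)/(K−1))²) disagreement weights are opt-in for ordinal use,
  applied to both Po and Pe. When both streams are degenerate on one class,
  Pe = 1 and π is undefined: the result carries a flag instead of raising
  (and maps to fitness −1 inside the optimizer, ranking such candidates
  last). On inputs with identical marginals π coincides with Cohen's kappa;
  the tests exploit this as an independent cross-check against
  scikit-learn's kappa.

Two agreement modes exist because both are useful: model-vs-model π (the
pairwise complementarity matrix) and stream-vs-truth π (a performance
score). The CLI reports each explicitly (`agree` vs `evaluate`/`optimize`).

## Cuckoo Search

Weights are searched as a free box in [0, 1]^M, continuously (no 0.05
grid; a `grid_sweep` helper reproduces sweep tables when wanted). Per
generation:

1. **Egg laying.** Every nest proposes `x' = x + α·L ⊙ (x − x_best)` where
   L is a Mantegna Lévy step — component-wise `u/|v|^(1/β)` with
   `u ~ N(0, σ_u²)`, `v ~ N(0, 1)` and the closed-form σ_u(β) — clipped to
   bounds. The incumbent best (x = x_best) instead takes a pure Lévy
   perturbation of magnitude α, so it keeps exploring its own
   neighbourhood. The proposal displaces a *randomly chosen* nest when
   fitter.
2. **Abandonment.** The worst ⌈pa·n⌉ nests are re-drawn uniformly in
   bounds, maintaining diversity.
3. **Bookkeeping.** A global archive of the top-A (weights, fitness) pairs
   is updated at every evaluation; ties break by smaller Euclidean norm,
   then lexicographic order, making archives (and hence results) fully
   deterministic per seed. The best-so-far history is non-decreasing by
   construction.

Defaults: 25 nests, pa = 0.25, β = 1.5, step scale α = 0.05 (in weight
units), bounds [0, 1] per weight, at most 200 generations, stopping after
10 consecutive generations with best-fitness improvement below 1e−6,
archive size 10. These are standard Cuckoo Search settings sized to the
2-weight problem; the fitness is deterministic for fixed weights (a frozen
validation prediction set), so no re-evaluation noise handling is needed.
A non-finite fitness aborts with the offending weight vector named.
Optimization is post hoc over fixed validation predictions; no interleaving
with classifier training is modelled.

## Balancing protocol

Ordering is reservation-first and enforced by construction: the per-class
test set (counts or fractions; fractions rounded half-up by default, other
modes available) is drawn uniformly without replacement *before* any
resampling, so the test set contains only original samples. The remaining
pool is balanced to a fixed per-class target — majorities subsampled
without replacement, minorities kept in full plus duplicates drawn with
replacement. Oversampling is duplication only (no SMOTE, no geometric
augmentation: synthesized medical images risk destroying diagnostic
structure); duplicates carry `#r<k>` suffixes so leakage checks can spot
replicas anywhere downstream. The train/validation split allocates per
class proportionally (largest-remainder apportionment), preserving the
balance just created; with four classes of 6,000 and a 19,000/5,000 split
each class contributes 4,750/1,250. Whether the original protocol
stratified this split is not documented; stratification is the choice here
because an unstratified split would partially undo the rebalancing.

The manifest imposes no total-count constraint: the published per-class
counts sum to 86,437 even though the dataset is described as roughly
80,000 scans, and the package simply takes per-class counts as given.

## Synthetic generator

The generator emulates the *outputs* of trained image classifiers, not the
images: per sample, a model's modal class equals the truth with probability
`skill`; otherwise a wrong class is drawn with probability proportional to
`confusion_bias^(d−1)` at ordinal distance d (default 0.5, reflecting that
real severity-stage confusions concentrate between neighbouring grades;
`None` gives uniform errors). The probability row is a Dirichlet draw with
mass `concentration` (default 20 — sharp but unsaturated, keeping ROC-AUC
informative) added to one component, after which the largest component is
swapped into the modal slot. The swap makes argmax == modal *surely*, so
empirical argmax accuracy is exactly Binomial(n, skill) and the
skill-recovery tests are exact rather than approximate.

Correlated pairs share "hard cases" through a mixture copula: per sample,
with probability ρ both models' error events are driven by one shared
uniform draw, otherwise by independent draws. ρ = 1 with equal skills gives
identical error sets; ρ = 0 gives joint-error rate equal to the product of
the marginal error rates; agreement (model-vs-model π) rises monotonically
in ρ. Joint-error correlation is controlled; *which* wrong class each model
picks remains independent — real model pairs may also correlate in error
direction, which this generator does not emulate. All generators take
explicit `numpy` Generators; there is no global random state.

What passing tests show — and do not show. The synthetic models have
exchangeable, stationary errors and well-calibrated-by-construction rows;
real CNN outputs are miscalibrated, class-dependent and correlated in ways
ρ alone cannot capture. Green tests certify the arithmetic, the protocol
and the optimizer's behaviour under these controlled conditions, not
classifier performance on real MRI data.

## Problem sizes and numerical choices

The acceptance workflow runs the balancing protocol at the full published
counts (86,437 manifest entries — label bookkeeping only, no images) and
the fusion/optimization stages on the 5,000-sample validation split with a
skill-0.95/skill-0.85 pair at ρ = 0.5. Optimizer oracle tests use
500-sample problems against an exhaustive 0.01-step grid search, 20 seeds.
Row-sum tolerance is 1e-6 at the I/O boundary and 1e-9 for fused-row
conservation; probabilities are serialized as shortest round-trip decimals
so read∘write is bit-exact. Reservation rounding is half-up (20% of 488 →
98). Degenerate inputs: empty probability matrices, all-zero weight
vectors, single-class schemes and infeasible reservations are rejected
with typed errors naming the offender.

## Known limitations

* No stacking/meta-learner, rank- or majority-vote fusion; no other
  metaheuristics (PSO, GA) and no multi-objective search.
* No confidence intervals on metrics, no calibration analysis, no macro
  AUC.
* The CLI's `simulate` emits exactly one correlated pair; larger model
  ensembles are available through the library API.
* No image I/O of any kind; the package starts where classifier
  probabilities end.
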