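# Methods

## The feature map

A protein sequence over the 20 standard amino acids is represented by
188 numbers in [0, 1]:

* **Composition** (20): per-letter occurrence counts divided by the
  sequence length *L*, in alphabetical order A…Y. The block sums to 1.
* **Per-property blocks** (8 × 21): each physicochemical property
  partitions the alphabet into three disjoint groups, and contributes
  - *content* (3): per-group residue counts / *L* (sums to 1);
  - *distribution* (15): for group *i* with *n_i* occurrences at
    1-based positions p₁ < … < p_{n_i}, the positions of the first,
    25%, 50%, 75% and 100%-th occurrence, each / *L*. The quantile
    index is k = ⌈q·n_i⌉, the classic
    composition/transition/distribution convention: it is exact at the
    endpoints, degenerates to the single position at n_i = 1, and makes
    each group's five values non-decreasing. A group with no
    occurrences contributes five zeros (the position of a nonexistent
    residue is undefined; zero is the conventional sentinel and keeps
    the value inside [0, 1]);
  - *dipeptide composition* (3): among the L−1 adjacent pairs, counts
    of pairs spanning groups (1,2), (1,3) and (2,3) — order-insensitive,
    lexicographic pair order — divided by *L*. Dividing by the number
    of *pairs* (L−1) is arguably more natural; both normalizers are
    supported (`normalizer="L"`, the default, or `"L-1"`) and differ by
    the factor (L−1)/L ≈ 1.

The eight property tables are shipped in `groupings.py`. One published
variant of the hydrophobicity row assigns only 19 distinct letters
(its second group is printed with a duplicated T and no Y); since the
three groups must partition the alphabet — every descriptor above is
defined through group membership — the second group is completed to
`GASTPHY`. Users can override any table via a YAML file mapping
property names to three letter-strings; each row is validated as a
partition at load time.

Composition and content are invariant under residue permutation;
distribution and dipeptide blocks are not — they are what distinguishes
this representation from a bag of letters.

## The ensemble

Training data: feature matrix with labels in {−1, +1}, *n* positives
and *l* negatives, typically *l* ≫ *n*. Standard boosting reweights
every sample; here the weight distribution *W_t* lives on the
negatives only, because positives are scarce (every round uses all of
them) while the large negative pool is what must be exploited
selectively.

Round *t* = 1…T:

1. draw *n* negatives with replacement with probabilities *W_t* (with
   replacement because it is well defined for any weight vector,
   including nearly degenerate ones);
2. fit base learner *h_t* on the balanced 2*n*-row subset, using
   algorithm kind `registry[(t−1) mod len(registry)]`;
3. compute ε_t = unweighted fraction of **all** *l* training negatives
   misclassified by *h_t*;
4. multiply the weights of those misclassified negatives by
   f_t = log_size(size·(1−ε_t)/ε_t) with size = *l*, then renormalize.

The factor's fixed point f = 1 at ε_t = 0.5 means a chance-level
learner leaves the distribution unchanged; better-than-chance learners
concentrate future sampling on the negatives they got wrong, and the
log base *l* keeps the growth per round modest on large pools
(f ≤ 2.1 at ε ≥ 1/(2l) for l = 600, versus the exponential updates of
standard boosting). ε is clamped into [1/(2l), 1 − 1/(2l)] so the
logarithm stays finite when a learner is perfect or perfectly wrong on
the negatives.

Prediction is a weighted vote: score(x) = Σ α_t·h_t(x) / Σ α_t ∈
[−1, 1], label = sign, with an exact tie resolved to the negative
class (the majority class of the application's prior). The vote weight
α_t = ln((1 − e_t)/e_t), where e_t is the learner's unweighted error on
the full training set clamped into [1/(2m), 1 − 1/(2m)], is the
standard boosting vote weight; it is clamped to [0, 10] so that a
perfect learner cannot monopolize the vote and a worse-than-chance
learner gets zero weight rather than a negated vote. If every α_t
clamps to zero the vote falls back to uniform. Uniform voting is also
available as an option (`vote="uniform"`).

Design points that were genuinely open and how they were fixed:

* **Round-to-algorithm assignment**: cycle through the registry in
  order; default T = 20 = the roster size, so each kind trains once.
* **Roster**: 20 scikit-learn kinds chosen to span the same families as
  the classic heterogeneous-ensemble setups (3 nearest-neighbour
  variants k ∈ {1, 5, 15}; six tree flavours from stump to entropy and
  randomized trees; random forest and extra-trees; linear and RBF SVM,
  logistic, ridge, SGD, perceptron; Gaussian naive Bayes; nearest
  centroid; a majority-class baseline). Shallow pruned trees stand in
  for classic rule learners (RIPPER-style), which have no scikit-learn
  counterpart.
* **A failed fit skips the round** with a warning (the effective T
  decreases); training errors out only if every round fails.

Everything is deterministic given (data, registry, T, seed): the master
seed drives a generator that yields per-round sampling and learner
seeds, and the full weight history W₁…W_{T+1} is stored on the model
for audit.

## Evaluation

Confusion counts with the DNA-binding class positive, and
SE = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total,
MCC = (TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FP)(TN+FN)),
P = TP/(TP+FP), R = SE, F1 = 2PR/(P+R). SE/SP/ACC are held as
percentages, P/R/F1 as fractions (F1 is printed as a percentage in the
text report). A metric whose denominator is zero — e.g. SE on a
negatives-only test set — is reported as 0 and flagged in
`degenerate`, rather than NaN, so reports stay machine-comparable.

## Synthetic data

The generator emulates only the *shape* of a DNA-binding benchmark:
residue-wise independent sampling, negatives uniform (1/20 per
letter), positives with total extra probability mass δ ∈ [0, 0.5]
spread equally over an enriched letter set (default {R, K} — the
positive-charge bias of real binders) and the remaining letters
rescaled uniformly. Defaults: 146 positives vs 2,125 negatives (a
heavily imbalanced benchmark shape), lengths uniform on 100–300
residues, δ = 0.3, which is a strong, cleanly separable signal.

Because residues are independent, the class signal lives in the
composition and content blocks; distribution and dipeptide blocks are
near-uninformative noise. Passing tests on this data therefore
demonstrate the mechanics of the pipeline — feature correctness,
weight algebra, determinism, the benefit of more negatives — but say
nothing about accuracy on real proteins, where ordering structure,
domain architecture and homology all matter and the signal is far
weaker. At δ = 0.3 the two classes are separated by several standard
deviations in the enriched-letter composition, so most classifiers
saturate near MCC = 1; the weak-shift settings used in the examples
(δ ≈ 0.05–0.1) are more representative of a hard problem.

## The negative-count experiment

`split_validation` takes the FIRST n_pos_val positives and FIRST
n_neg_val negatives in dataset row order — input order is part of the
protocol and preserved end-to-end — and `sweep_negatives` trains on
all remaining positives plus the first n remaining negatives for each
requested n. Prefix subsets nest (smaller training sets ⊂ larger), so
the sweep isolates the effect of adding negatives from resampling
noise. Output is one row per n, in request order: n, ACC, MCC, SE, SP,
F1.

## Problem sizes and numerical choices

* The test suite's stochastic checks use 150/1500 training and 50/500
  held-out sequences over 5 seeds, and a 150/2200 sweep over
  n ∈ {100, 400, 1600} — large enough for stable means, small enough
  to keep the full suite fast.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; repeated runs are bitwise identical.
* Tolerances: weight-vector normalization to 1e−9; feature values are
  exact rational arithmetic in double precision, checked against a
  brute-force reference at 1e−12.

## Known limitations

* Base learners are scikit-learn implementations; numerical
  bit-compatibility with other toolkits' versions of the same
  algorithm families is out of scope.
* No evolutionary (PSSM), structural or pseudo-composition features;
  the representation is strictly sequence-compositional.
* Binary classification only; no probability calibration of the vote
  score beyond its [−1, 1] normalization.
* The dipeptide ÷L default slightly underweights short sequences'
  pair fractions relative to ÷(L−1); switch normalizers if comparing
  across very short peptides.
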