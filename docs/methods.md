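# Methods

## Problem setting

Several fixed (pre-trained) feature extractors each emit one feature block —
an `n × d_b` matrix over the same `n` samples — and a classifier must be
trained on some fusion of the blocks. Plain concatenation (CFS) keeps
everything; the weighted strategies scale blocks (AWFS, MOWFS) or individual
columns (FOWFS) by weights in [0, 1], and the optimized strategies choose
those weights by minimizing a wrapper cost with a metaheuristic. Entries
with optimized weight above 0.5 form the highest-ranked feature set used for
final classification: whole blocks for MOWFS, single columns for FOWFS. The
selection rule is strict (a weight of exactly 0.5 is dropped), and an empty
ranked set is an error in the library (`DegenerateSelectionError`); callers
may opt into keeping the full weighted set instead (`on_degenerate="full"`),
which is what the command-line runner does, with a warning.

## Jellyfish search

AJS maintains `pop_size` candidate weight vectors. Per candidate per
iteration it draws the time-control value `fTC = |(1 − t/T)·(2u − 1)|`,
`u ~ U(0,1)`:

- `fTC ≥ c0` (default 0.5): **ocean-current drift** — move along
  `best − φ·u'·mean(positions)` by a random fraction;
- otherwise **passive motion** with probability `fTC` — a small positive
  step `ω·u·(upper − lower)` per dimension — or **active motion**: move
  toward a uniformly chosen partner if the partner's cost is no worse, away
  from it otherwise.

Out-of-bound coordinates re-enter from the opposite bound (modular
wrapping). A move is accepted only if it improves that candidate's cost
(greedy acceptance, as in the original jellyfish-search formulation); the
incumbent best over all evaluations is the returned solution, so the
best-so-far trace is monotone by construction.

Numerical conventions worth stating:

- The time-control function is used with an absolute value so its range is
  [0, 1) and the drift branch is reachable; without it the expression ranges
  over (−1, 1) and a threshold at 0.5 would almost never fire.
- The bound-wrapping rule's lower branch applies when a coordinate falls
  *below* the lower bound.
- The drift and active steps use one scalar uniform draw per move; the
  passive step draws per dimension to keep its exploration isotropic.
- Ties in active motion (equal costs) move toward the partner.
- `φ = 3` and `ω = 0.1` follow the original optimizer; no application-
  specific values are established, and both are configurable.
- Population initialization is uniform over the box.
- Defaults: population 10, 50 iterations (510 cost evaluations per run).

The GA baseline is real-coded with roulette-wheel selection on
`(worst − cost) + 1e−12` (degenerating to uniform selection when all costs
are equal), per-gene arithmetic crossover with probability 0.8, per-gene
Gaussian mutation (probability 0.1, σ = 0.1 of the box span) and one elite.
The PSO baseline uses inertia 1.0 damped by 0.99 per iteration, cognitive
and social coefficients 1.5 and 2.0, velocities clamped to the box span and
positions clipped to the box. GA/PSO rates not fixed by convention are this
package's choices.

## Wrapper cost

The cost of a weight vector is the mean squared error between one-hot true
labels and the wrapper classifier's predicted class-probability vectors on
held-out rows: the weighted fused matrix is split by a stratified shuffle
split (30% validation), the classifier is fitted on the remainder, and the
MSE is averaged over `n_splits = 3` such splits. A single 90-sample fold
proved too easy to overfit — feature subsets that spuriously helped one
fold were kept — and averaging over three folds stabilizes the per-column
signal at three times the cost; the evaluation budget stays bounded by the
optimizer's iteration count. The cost is deterministic given the weights
and the seed.

The wrapper classifier is configurable (DT, NB, MLP, SVM through their
scikit-learn implementations with library-default hyperparameters and fixed
seeds; the SVM exposes probability estimates). Note that decision trees and
Gaussian naive Bayes are invariant to positive per-feature rescaling, so
they provide no gradient for *weight* optimization beyond the zero boundary;
the RBF-kernel SVM is the sensible default for the optimized strategies.

In the Model/Results interface the outer stratified train/test partition
(default 80/20) is drawn once at model construction and weights are
estimated on the training rows only, so held-out metrics are leakage-free.

## AWFS adaptation rule

The adaptive strategy measures each block's standalone validation accuracy
and rescales by the best block's accuracy, giving weights in (0, 1] with the
strongest block at 1. This is the simplest data-driven reading of "adaptive
weighting"; it is a stand-in where no precise rule is established, and it is
symmetric (identical blocks receive identical weights).

## Evaluation and comparison

Multiclass metrics are macro-averaged: precision, sensitivity (recall), F1
and one-vs-rest ROC-AUC (classes absent from the scored fold are skipped
with a warning). The Friedman statistic over `k` methods and `N` datasets
uses rank sums `R` with rank `k` for the best method per dataset and average
ranks on ties:

    FM = 12 / (N·k·(k+1)) · ΣR² − 3·N·(k+1)

A `paper_rounding` flag truncates the leading coefficient to three decimals
before multiplying, reproducing a common hand-calculation shortcut
(0.083 × 1922 − 144 = 15.526 instead of the full-precision 16.1667 for
R = (32, 27, 13), N = 12, k = 3); it is off by default.

The package ships the published validation-accuracy and recognition tables
for the HAM 10000 (7 lesion classes) and BCN 20000 (8 classes) dermoscopy
benchmarks as CSV fixtures, transcribed cell-by-cell including evident
typos. The delta report computes each strategy's improvement over CFS in
percentage points strictly from those cells; prose claims that disagree
with their own source tables are not forced to match.

## Synthetic data

The generator emulates the *shape* of deep-feature tables: several blocks of
configurable width, class labels drawn from a (by default skewed, one
~65% dominant class) categorical distribution, and class-conditional
Gaussian columns. `effect_size` is the block-level class-mean separation in
noise-standard-deviation units: each informative column's class means are
drawn `N(0, (effect/√n_informative)²)`, so the centroid separation across
the block is of order `effect_size` however many columns carry it. What it
does **not** emulate: the heavy inter-column correlation, non-Gaussianity
and nonlinear class structure of real CNN features — so passing recovery
tests show the optimizer finds planted linear-Gaussian structure, not that
the method reaches any particular accuracy on dermoscopy images.

The two-block probe used by the parameter-recovery experiments has 300
samples, 3 balanced classes and two 20-column blocks: one fully informative
with block separation 2.5, one pure noise. At this size a full MOWFS or
FOWFS run (510 SVM fits) takes seconds per seed on one CPU, and ten-seed
experiments stay within minutes.

## Known limitations

- The wrapper cost is nearly invariant to *uniform* rescaling of all
  weights for most classifiers, so the absolute placement of weights around
  the 0.5 threshold is weakly identified; block selection can legitimately
  come back empty (hence the degenerate-selection handling above).
- Metaheuristic weight estimates carry no closed-form uncertainties; the
  convergence trace and multi-seed dispersion are the available diagnostics.
- The image-to-feature adapter requires a user-supplied backbone callable;
  no pre-trained CNN weights are bundled, and the deterministic mock
  backbone exists for contract tests only.
- More than three blocks is supported structurally but untested against any
  published configuration.
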