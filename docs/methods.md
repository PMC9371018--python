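# Methods

This note documents the models and procedures implemented in `catimpute`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Problem setting

The package targets *discrete* (categorical) missing data in small tabular
classification datasets: a few hundred to a couple of thousand rows, a
handful of mostly categorical attributes, and a class column used for
downstream evaluation. Missing cells are marked by a sentinel (`"?"`, the
UCI convention). A table splits into the complete rows `Dcom` and the
incomplete rows `Dmiss`; the distinct patterns of simultaneously-missing
attributes among `Dmiss` rows are the table's *missing types*
`MT = {mt_1, ..., mt_n}`.

## One-hot coding

Categorical attributes are encoded as indicator blocks in domain order;
the declared domain order is canonical and fixes every tie-break in the
package (decoding argmax ties, mode ties, k-NN vote ties). Numeric
attributes — inputs only, never imputation targets — occupy one position,
min–max scaled to [0, 1] with bounds taken from the complete rows and
out-of-range values clipped; a constant column scales to 0.5. Decoding a
score block takes the category at the position of the maximum score,
breaking ties toward the lowest domain index.

## Amputation

The three mechanisms follow the standard taxonomy: MCAR (missingness
independent of all data), MAR (driven by an observed conditioning
attribute) and NMAR (driven by the deleted cell's own value). The
taxonomy defines the mechanisms but no generator, so the generator is this
package's design:

* Per eligible attribute (categorical, non-class) exactly
  `round(rate * n_rows)` cells are deleted — exact budgets rather than
  Bernoulli draws, so realized rates are deterministic and testable. The
  supported rate grid mirrors the usual experimental range, 10–30% in
  steps of 5%.
* MAR/NMAR deletion uses weighted sampling without replacement: rows whose
  driver value lies in the driver attribute's *high-frequency half*
  (most frequent categories accumulating at least 50% of the mass) carry
  `dependence_odds` (default 9) times the weight of the rest. The default
  conditioning for MAR is the next eligible attribute, cyclically.
  Weights use pre-amputation values even if the conditioning cell is later
  masked itself — a documented approximation of MAR.
* Row protection: no row may lose its last observed eligible attribute;
  over-constrained draws are skipped in key order and the run aborts with
  a configuration error if the budget cannot be met.

`mechanism_diagnostic` validates a run empirically with a chi-squared
independence test between each attribute's mask and its driver values.
Calibration at n = 1000, odds 9, rate 0.2: the MCAR mask is rejected at
the ~5% nominal level, while the planted MAR/NMAR dependence is detected
in essentially every seed.

Masked-cell sets at different rates under the same seed are *not* nested;
only the budgets are monotone in the rate.

## The network core

A dense multilayer perceptron with rectifier hidden layers and logistic
sigmoid outputs, trained with an independent-per-unit binary cross-entropy
over the concatenated one-hot target blocks (no per-block normalization)
and mini-batch momentum gradient descent:

    v <- beta * v + (1 - beta) * grad        (velocity, zero at step 0)
    w <- w - alpha * v

Defaults: alpha = 0.001, beta = 0.9, batch 256, 1000 epochs, three hidden
layers of 32 units. Initialization is Glorot-uniform with zero biases.
Batches are re-shuffled every epoch from a seeded stream; the last short
batch is kept; datasets smaller than the batch size train full-batch.
Loss predictions are clipped at 1e-12 inside the loss only; gradients flow
through the unclipped sigmoid outputs. Backpropagation is the exact
gradient of the mean loss (finite-difference-verified in the test suite).

A consequence worth stating plainly: because the velocity is an
*exponential moving average* of gradients, the asymptotic parameter step
is `alpha * grad` — roughly ten times smaller at beta = 0.9 than the
common deep-learning-framework formulation `v <- beta*v - alpha*grad`,
which accumulates rather than averages. Combined with the mean-over-units
loss normalization, convergence at alpha = 0.001 is slow: simple
deterministic mappings on a few hundred rows need on the order of 10^4
epochs to be learned by every random initialization. Test and benchmark
epoch budgets are chosen accordingly (see below); users imputing real
data with the default 1000 epochs should expect conservatively-trained
networks and may raise `epochs` or `learning_rate`.

## The per-missing-type imputation scheme

1. Detect the missing types of the incomplete rows.
2. Prefill the table provisionally: frequency-weighted random fills when
   the data are MCAR, per-column mode fills under MAR/NMAR. The mechanism
   tag is a user-supplied input — it is known by construction in
   simulation studies; no inference of the mechanism is attempted.
3. For each missing type `mt`, train one network mapping the one-hot
   encoding of the attributes outside `mt` (class column included — it is
   always observed) to the one-hot blocks of the attributes in `mt`.
   Training rows are all rows whose *originally* missing attributes are
   disjoint from `mt`: their targets are genuinely observed, while their
   inputs may contain prefilled values. This is what lets rows of other
   missing types enlarge a type's training set beyond `Dcom`.
4. Predict each incomplete row through its own type's network, decode the
   output blocks by per-block argmax, and write only the originally
   missing cells; observed cells are never altered. A single pass is made:
   model outputs are not fed back to refine prefills iteratively.

One model per type with a joint multi-attribute output head was chosen
over one model per (type, attribute); it matches the multi-output
architecture the scheme describes and shares the input representation
across target attributes.

The *plain MLP* baseline is the same per-type procedure with momentum
forced to 0 and no prefill benefit (each type trains on `Dcom` only), so
an A/B comparison against the full scheme isolates exactly the momentum
and prefill pathways.

## Baseline imputers

* **mode** — most frequent observed value per attribute; frequency ties
  break to the earlier category in domain order.
* **random** — a draw from the attribute's observed empirical
  distribution, so more frequent values are more likely chosen.
* **hot-deck** — all missing cells of a row are copied from the complete
  row minimizing the Hamming distance over the one-hot encoding of the
  row's observed categorical attributes; distance ties take the lowest
  donor index. The donor pool is all complete rows; no within-class decks
  are built.
* **k-NN** (k = 5 by default, capped at the donor-pool size) — the k
  nearest complete rows by the same metric vote with weight
  1/(1+distance); a "weighted average" is undefined for categories, so
  the vote winner is taken, with ties broken by higher donor frequency and
  then domain order. k = 1 coincides with hot-deck by construction.
* **tree / forest** — per (missing type, target attribute), a delegated
  scikit-learn CART (Gini) or random forest with library defaults is
  trained on the complete rows, features being the one-hot encoding of the
  type's observed attributes.
* **autoencoder** — a network with equal input and output width over the
  full one-hot encoding, trained to reproduce the complete rows;
  incomplete rows are mode-prefilled (regardless of mechanism), passed
  forward once, and only their originally missing blocks are replaced by
  the decoded reconstruction. Because training inputs always contain the
  true value of every attribute, the network favours the copy path, and
  reconstructions lean toward the prefill — a known weakness of
  non-denoising reconstruction imputers that the redundant-attribute test
  quantifies.

Distances exclude numeric attributes (the Hamming metric is defined on
binary strings); numeric attributes are never imputation targets, and a
numeric missing cell raises an error rather than being silently filled.

## Downstream evaluation

Imputation quality is scored by repeated stratified k-fold classification
accuracy (k = 10, 5 repeats by default; the per-repeat accuracy is the
mean over folds, and the reported spread is the population std over repeat
means). Stratification is a deliberate addition: small multi-class
tables otherwise produce label-free folds. The benchmark grid crosses
datasets × mechanisms × rates × imputers × classifiers, shares one
amputation mask per (dataset, mechanism, rate) across imputers so method
comparisons are paired, and always includes an un-amputed "origin"
control per (dataset, classifier). Per-cell seeds are derived by hashing
the master seed with the cell's names, so results are independent of grid
iteration order and the grid is resumable. Per-cell failures are recorded
in the output row, not raised.

The evaluation classifier panel (SVM, Gaussian naive Bayes, CART, k-NN)
is delegated to scikit-learn with default hyper-parameters; cheap
deterministic stub classifiers (majority, nearest-row) are provided for
smoke tests.

## Synthetic data

`gen_latent_class` draws rows from a latent-class mixture: each row's
class is drawn from the mixture weights, each attribute equals the class's
modal category with probability `1 - noise` (else uniform over the other
categories), and the class column is the latent class itself. Defaults —
1000 rows, 6 attributes of 4 categories, 4 balanced classes, noise 0.1 —
give a table the size and shape of the small UCI classification sets this
problem is usually studied on, with genuine inter-attribute dependence
(verified against a permutation null on mutual information). Because the
label *is* the latent class, bad imputation measurably degrades
downstream classification.

`gen_functional` builds the sharpest possible recovery fixture: A2 is a
fixed total mapping of a uniform A1, corrupted uniformly over the whole
domain with probability `noise`, with a binary class given by the half of
the domain A1 falls in. At noise 0 the imputation ceiling is exactly 1.

What these fixtures do **not** emulate: skewed real-world marginals,
mixed continuous/categorical interactions, label noise, and missingness
produced by anything other than the package's own amputation module.
Passing tests demonstrate internal correctness and the relative ordering
of methods under controlled dependence — not absolute accuracy on any
real dataset.

## Experiment sizes used by the tests and the acceptance script

* Gradient verification: 100 random nets with dims within [6, 8, 8, 4],
  central differences at h = 1e-6; coordinates whose perturbation crosses
  a rectifier kink are skipped (the central difference is invalid there).
* Codec round-trip: 1000 random tables up to 100 × 10.
* Amputation calibration: exact budgets on 200-row tables over
  3 mechanisms × 5 rates × 20 seeds; independence/power diagnostics at
  n = 1000 over 100 seeds per mechanism.
* Functional recovery: n = 500, MCAR at rate 0.2, 12000 epochs, 5 seeds —
  the epoch budget reflects the slow-optimizer account above; every seed
  reaches perfect recovery there.
* Paired dominance: latent-class data (n = 1000, 6 attributes, noise
  0.1), MCAR at rate 0.2, 200 epochs, 5 paired seeds; the scheme's mean
  cell-fill accuracy exceeds the mode's and the plain MLP's. At this
  deliberately short budget all networks are undertrained, so the margin
  over the mode is modest; k-NN-style donors dominate in raw fill accuracy
  on this fixture — the comparison isolates the momentum+prefill effect,
  not state-of-the-art fill accuracy.
* Benchmark determinism: one 240-row dataset × 3 mechanisms × 2 rates ×
  {mode, knn, imlp} × 2 stub classifiers, 10-fold × 2 repeats at 100
  epochs, run twice and compared as CSV text.

## Known limitations

* The mechanism tag must be supplied; mechanisms are not inferred.
* No multiple imputation, no chained equations, no iterative refinement
  of prefills, and no uncertainty on fills.
* Numeric attributes are carried as scaled inputs only.
* Momentum in the written exponential-moving-average form converges
  slowly at the default learning rate (see the network-core section).
* Ordinal structure inside domains is ignored by all distance metrics.
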