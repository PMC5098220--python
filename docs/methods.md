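# Methods

## The model

`ppisign` treats sign prediction on PPI edges as multi-label
classification over `{activation, inhibition, others}`: without
directionality, a pair can legitimately carry both activation and
inhibition, and *others* collects physically interacting pairs with
neither. Multi-label learning is reduced to multi-class by **label
combination** — each distinct label set observed in training becomes one
class code — so a single multi-class model covers all combinations. The
codec learns its combinations from the data rather than hard-coding four
classes, because whether a dual-labelled (activation+inhibition) class
exists depends on the dataset.

The classifier is one-vs-rest ℓ2-regularized logistic regression. Each
binary problem minimizes the primal objective
`½ωᵀω + C Σ log(1 + exp(−y ωᵀx))` with an **unregularized intercept**.
Assumptions worth stating:

* **Linearity in the {0,1,2} encoding.** A shared term contributes twice
  the weight of a one-sided term. The model cannot express "shared vs
  merely carried" non-linearly; what it can do is learn per-term weights
  whose sums separate the classes. This is sufficient when class-relevant
  terms are rarely carried by chance (see the generator notes below).
* **Comparable decision values.** The fusion rule compares raw margins
  across one-vs-rest scorers and across the two instance kinds; no
  calibration is applied. Probability calibration is deliberately out of
  scope — the fusion only needs an ordering.

### Solver

Each binary problem is solved by L-BFGS on the primal followed by a
damped-Newton polish. The polish exists because the package's contract is
on the *returned point*, not the optimizer's internal stopping rule: at
return, the gradient ∞-norm is ≤ `tol` (default 1e-4) unless the
iteration budget (`max_iter`, default 1000) ran out, in which case the
model's `converged` flag says so. The objective is strongly convex (the
ridge gives the Hessian a unit floor), so the Newton step with step
halving cannot diverge. A class absent from a training split keeps a zero
scorer; it can never win the argmax against fitted classes.

Default `C = 1.0`. The penalty parameter trades data fit against the
noise carried by homolog instances; on the synthetic worlds, C in
[1, 10] changes macro-F by under 0.04 and C = 1 was best, consistent with
common practice for this objective. `C`, `tol` and `max_iter` are exposed
on the API and CLI.

### Feature space

The vocabulary `U` is the sorted union of target *and* homolog term sets
over training proteins — homolog instances must be encodable over the
same universe, since one model scores both instance kinds. Terms seen
only at prediction time are dropped (logged): the feature space is fixed
by training. All three GO aspects are used; no evidence-code filter is
applied by default (an optional filter exists). GO-DAG ancestors are
deliberately **not** added to term sets: ancestor features are strongly
correlated with their descendants and would work against the feature
independence that a linear model leans on; homolog transfer recovers
cross-level term relationships instead.

The homolog term set of a protein is the union over all retained hits
(E-value ≤ 10, self-hits removed, ties broken by accession). `max_hits`
can cap the union at the best hits; the default (all hits) maximizes GO
coverage, which is the point of the transfer.

## Pipeline conventions

* Pairs are unordered; duplicate rows merge by label union (this is
  exactly how a pair annotated with both signs becomes multi-label), and
  training/test overlap removal uses the same unordered identity.
* The *others* class is sampled uniformly without replacement from the
  physical-PPI universe minus the labelled pairs, sized at
  `others_ratio × |activation|` (default 1:1) to limit bias toward the
  dominant class. Sampling happens once per dataset, not per fold.
* Cross-validation folds are assigned per pair, so a pair's target and
  homolog instances always travel together — splitting them would leak
  label information. Folds are seeded and unstratified; the vocabulary
  and codec are rebuilt from the training folds only. A fold whose
  training split degenerates to one class is skipped with a warning.
* Class-weighting/resampling for imbalance is off by default; over- and
  under-sampling were reported unhelpful for this task in the source
  data, and the imbalance pattern itself is informative.
* At prediction time a null instance **abstains** (`ABSTAIN` in output,
  `None` in the API) rather than disappearing: interactome-wide output
  accounts for every input edge, with doubly-null edges flagged
  unpredictable.

## The synthetic-data generator

`generate_world` emulates the study conditions end to end: a GO
vocabulary (600 terms by default), proteins with ~6 background terms each
(Poisson count truncated at ≥ 1), 10% unannotated proteins (GO sparsity),
three homologs per protein whose term sets are noisy copies of the
query's true biology (20% term substitution — evolutionary divergence),
300/100/300 labelled pairs (the 3:1 activation:inhibition imbalance of
real curated sets), and a physical-PPI universe of which 20% of edges
carry an unlabelled planted sign.

Class structure is planted as **shared signal terms**: a pair of class
`c` shares one of `c`'s 8 signal terms with probability
`signal_strength` (0.9). *Others* carries no signature — it is sampled
from the unsigned part of the universe, mirroring how negatives are
drawn from the PPI space in practice and calibrating the "no shared
signal" region on the distribution predictions actually run on. With
probability `p_dual` (0.05) an activation pair also shares an inhibition
term and becomes dual-labelled. Dropped-out proteins keep annotated
homologs, exercising the null-vector/homolog-substitute path.

Two sizing choices matter and are deliberate:

* **Protein pool ≫ pair count** (2500 proteins for ~700 pairs). A protein
  recurring across many pairs carries several classes' signal terms, and
  its one-sided (value-1) occurrences then mimic shared signal for a
  linear scorer. Low pair-degree matches real curated training sets and
  keeps the planted structure recoverable; in the limit of fully disjoint
  pairs (30k proteins) the noiseless world is classified almost
  perfectly (exact match ≈ 0.99).
* **Vocabulary width 600 with 8 signal terms per class.** Background
  co-occurrence by chance is then rare (as in real GOA, where the term
  space is vastly larger than any protein's annotation), while each
  signal term accrues enough shared occurrences — even in the small
  inhibition class — to earn a confident weight.

What the generator does **not** emulate: GO DAG topology (terms are
exchangeable symbols), realistic E-value distributions, protein families
/ phylogenetic correlation between homologs of different proteins, and
hub-dominated degree distributions. Passing tests therefore show that
the method recovers co-occurrence-driven sign structure under sparsity,
imbalance and homolog noise — not that real interactomes meet those
assumptions.

A residual behavior worth knowing: classifiers partially memorize
protein identity through value-1 background terms, which inflates the
signed fraction predicted on unlabelled universes by roughly the
model's per-edge error rate (~0.03–0.12 absolute under the default
conditions). The interactome test tolerance covers this; it is a
property of linear models on recurring proteins, not a bug in the
sampling.

## Numerical and degenerate-input choices

* Metric ratios with empty denominators (0/0) are defined as 0 and
  logged; an evaluation with zero scored instances of one kind yields an
  explicit all-zero report rather than an error.
* Decision-value ties in fusion go to the target instance — its features
  are the proteins' own annotations, the more direct evidence.
* Vocabulary order is lexicographic; codec order is by canonical
  comma-joined string; fold assignment, others-sampling and world
  generation are pure functions of their seeds. Reported metrics are
  reproducible bit-for-bit for a fixed seed.
* GAF records with fewer than 15 fields or malformed GO IDs are skipped
  with a warning (never fatal); an unreadable file is fatal. Homolog
  rows with non-numeric E-values are skipped with a warning.
* Model archives are single JSON files carrying weights, codec,
  vocabulary, config and a vocabulary fingerprint; loading verifies the
  fingerprint and a format version string.

## Problem sizes

The test suite and the acceptance script run entirely on generated
worlds: 5 × (700-pair, 10-fold) cross-validations plus permuted-label
baselines, one 700-pair noiseless run on a 30k-protein pool, and one
800-edge interactome scan — about half a minute end to end on one CPU.
These sizes give stable metric estimates (seed-to-seed macro-F spread
under ±0.02) while keeping the whole pipeline cheap to re-run.

## Known limitations

* Directionality of activation/inhibition (who acts on whom) is out of
  scope by design.
* Decision values from independently trained one-vs-rest scorers are
  compared without calibration; the fusion rule is one documented
  resolution of an under-determined choice.
* The multi-label evaluation counts a dual-label prediction toward both
  labels (binary label-vector reading); fractional credit schemes are
  not implemented.
* Homolog search itself is not run; the package consumes a hit table.
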