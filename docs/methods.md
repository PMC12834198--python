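# Methods

## Scope and model

`fedistill` is a desk-scale, fully deterministic simulator of a federated
ensemble in which N heterogeneous participants exchange *soft labels*
(class-probability vectors) instead of data or parameters, and in which a
permissioned RBAC ledger gates every submission. It covers six layers:
synthetic cohort generation and non-IID partitioning, the tabular
preprocessing chain, the five local model types, the distillation
mathematics, the ledger semantics, and the multi-round orchestration with
a bootstrap comparison statistic. It deliberately does **not** model a
blockchain runtime (no EVM, consensus, gas, or latency), deep local
models, learned temperatures, or multiclass problems beyond generic
support in the math.

## Synthetic cohort

The generator emulates the schema of the classic Pima-style diabetes
benchmark: eight numeric clinical features and a Bernoulli(prevalence)
outcome, default prevalence 0.35. Features are class-conditional
Gaussians; the positive class mean is shifted upward on glucose, BMI, age
and pedigree by `effect_scale` times a per-feature effect size, and
physiologically nonnegative features are clipped at zero (pregnancies are
also rounded to integers). Two calibration choices matter:

* **Relative effect sizes** follow the real cohort's ordering — glucose
  carries the strongest class signal, then BMI, age, pedigree.
* **Overall magnitude** at `effect_scale = 1` is set so the Bayes-optimal
  accuracy is about 0.90. This places the simulator in the accuracy regime
  the emulated study operates in (initial local accuracies in the 0.6–0.9
  band with real headroom for collaborative improvement). With effect
  sizes copied literally from the real cohort, the ceiling is ~0.75 and
  every local model saturates immediately, which makes the federation's
  contribution unmeasurable.

What the generator does **not** reproduce: the real data's zero-inflation
(missing insulin/skin-thickness coded as 0), feature correlations, and
heavy tails. Passing tests therefore demonstrate the *mechanics* of the
federation under a controlled signal, not clinical performance on real
records.

### Non-IID partitioning

Shared validation (15%), test (15%) and unlabeled pool (20%) sets are
label-stratified. The remaining training pool is split into disjoint
shards sized by each participant's data fraction (largest-remainder
rounding, so totals are conserved). Each shard's positive-label proportion
is drawn from a Beta distribution with concentration `1/skew` centred on
the global prevalence — the binary case of the standard Dirichlet
label-skew construction; `skew = 0` degenerates to IID assignment. The
default is `skew = 0.1` (concentration 10, shard-level positive
proportions ≈ 0.35 ± 0.14): heterogeneous but not degenerate. Stronger
skew (concentration ≤ 2) routinely hands *all* positive records to one
shard, leaving other participants with single-class data and an
untrainable classifier — a failure mode of the construction, not of the
federation — so each shard additionally reserves at least one record of
each class when its size allows.

## Preprocessing

Applied in pipeline order, fitted on training rows only:

1. **Outlier removal** — union of per-column Tukey fences (quartiles by
   linear interpolation, multiplier 1.5) and multivariate local outlier
   factor (k = 20, Euclidean, density-ratio threshold 1.5; computed via
   scikit-learn, cross-checked in tests against a brute-force
   recomputation). Flagged rows are removed — the simpler, auditable
   action versus winsorizing. Removing more than 10% of rows raises a
   data-quality warning but proceeds.
2. **Binning** — ordinal `glucose_bin` with the standard clinical edges
   (140, 200 mg/dL; left-closed, so exactly 140 falls in the upper bin)
   and `insulin_bin` with training-data quartile edges.
3. **Z-scoring** — moments from the union of training shards; zero-spread
   columns map to zero.
4. **SMOTE** — synthetic minority points `x + u (x_nn - x)`,
   `u ~ U(0,1)`, toward one of k = 5 minority nearest neighbours
   (implemented in-package; originals preserved verbatim). Balancing runs
   per participant on the *effective* local training set — the private
   shard plus the currently appended pseudo-labels — after splitting, so
   nothing leaks into the shared sets. Balancing the shard alone is not
   enough: confident pseudo-labels inherit the pool's majority-class tilt,
   and an unbalanced append drifts every local model toward the majority
   class over rounds. When a minority class is too small for k-NN
   interpolation (≤ k members) the orchestrator skips balancing for that
   participant rather than failing the round; the standalone
   `smote_balance` operation still raises, since silently under-balancing
   a direct call would hide a data problem.

## Local models

The five-participant roster maps resource levels to architectures: random
forest (130 trees, depth 15, feature fraction 0.75; 50% of the data),
KNN (k = 5; 5%), gradient-boosted trees (learning rate 0.01, depth 10,
180 rounds; 30%), decision tree (gini, unbounded; 10%), and a linear SVM
(C = 1; 5%). The SVM has no native probabilities; its signed margin is
squashed through a logistic sigmoid — a monotone calibrated mapping that
avoids the extra cross-validation randomness of Platt scaling. The
positive class for precision/recall is the diabetic label (1);
zero-denominator metrics are reported as 0 with a `degenerate` flag so
aggregate tables never contain undefined entries.

## Distillation mathematics

* **Logit reconstruction.** Four of the five model kinds emit
  probabilities, not logits, so temperature scaling reconstructs logits
  as `log(p + eps)` with `eps = 1e-12`; this proxy is exactly invariant
  under softmax at T = 1, which is the anchoring property the scaling
  needs. Note that hard 0/1 probability rows (a pure tree leaf, a
  unanimous KNN vote) remain extreme after smoothing — `log(eps)` keeps
  their margin enormous at any moderate T — so consensus among hard
  classifiers can still clear the confidence threshold. This is a known
  limitation of probability-side temperature scaling.
* **Weights.** Round 1 uses the roster's static weights (no validation
  accuracy exists before the first exchange); from round 2 the weights
  are shared-validation-accuracy proportional. Clipping caps any weight
  at 0.5 (the largest static share) and redistributes the excess
  proportionally among uncapped weights until feasible (water-filling);
  the cap relaxes to 1/N when fewer than three participants survive
  gating, since caps below 1/N are infeasible.
* **Filtering.** Acceptance is inclusive (`max P(x) >= tau`, tau = 0.7);
  argmax ties take the lowest class index so replays are byte-stable.
  Pseudo-labels are *replaced* each round, not accumulated — accumulation
  would duplicate pool instances without bound and progressively swamp
  the private shards.

With tau = 0.7 and binary classes, a zero-signal cohort
(`effect_scale = 0`) produces first-round acceptance near zero (the
smoothed soft-voted ensemble cannot reach 0.7 without class signal);
later rounds may accept majority-class consensus rows through the
hard-probability channel above, but the pseudo-labels then simply restate
the majority class and accuracy does not drift — the confirmation-bias
guard tested in the suite.

## Ledger semantics

An in-process, append-only transaction log models the access-control
semantics of a role-based smart contract. Six functions are exposed:
register, assign-role, submit-update, validator-approve, mark-aggregated,
and query. Submission checks run in a fixed order — identity, role,
round, timestamp, metadata, payload — and the rejection reason is the
first failing check, so reason strings are deterministic. Metadata
verification recomputes the submitter's accuracy on the shared validation
set and compares with the declared value within 1e-6. Accepted payloads
are hashed with SHA-256 over a canonical serialization (sorted JSON keys,
`repr` float formatting) so digests are platform-stable. A submission
enters aggregation only after a quorum (default 2 of 3) of distinct
validator approvals; approvals are themselves log records, which is what
makes replay from the log byte-exact. All failures are recorded
rejections, never exceptions, mirroring contract reverts.

## Orchestration and statistics

A round executes: local retraining (shard + current pseudo-labels,
rebalanced) → soft labels on the pool → temperature scaling →
ledger-gated submission and quorum approval → weighting and clipping →
aggregation → confidence filtering → pseudo-label refresh → evaluation on
the shared test set. A round with zero quorum-approved submissions aborts
with an explicit error rather than aggregating an empty ensemble. Every
random draw is keyed through `numpy.random.SeedSequence` on
(seed, stage, round, participant), so a (config, seed) pair fully
determines every artifact written, byte for byte.

The bootstrap comparison resamples test instances with replacement
(B = 1000 by default) and evaluates both prediction vectors on the same
resample, giving paired metric differences and an empirical two-sided
95% percentile interval; significance is the CI excluding zero.

## Problem sizes

Default simulations use a 1000-record cohort, 5 participants and 15
rounds (≈10 s per run); the acceptance script averages 5 seeds and the
improvement test in the suite does the same. Bootstrap coverage is
checked with 100 replications of n = 500 / B = 1000. These sizes were
chosen as the smallest at which the shard-level sample sizes still
resemble the emulated study's data shares.

## Known limitations

* Soft labels are exchanged in-process; there is no transport, encryption
  or differential-privacy layer, and ledger "addresses" are plain strings.
* The accuracy-consistency check models only one adversary class
  (metadata inflation); probability-shifting attacks below the tolerance
  pass the gate by construction.
* Temperature scaling cannot soften hard 0/1 probability rows (see
  above), so tree-heavy ensembles filter less conservatively than
  calibrated ones.
* The synthetic cohort's independence of features understates the
  difficulty of real clinical data; reported accuracies characterise the
  mechanism, not clinical utility.
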