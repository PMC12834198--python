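"""Synthetic diabetes-style cohorts and non-IID partitioning.

The generator emulates the schema of the classic Pima-style diabetes
benchmark — 8 numeric clinical attributes plus a binary outcome — so that
every downstream stage (preprocessing, local training, distillation,
ledger-gated aggregation) is testable without downloading any external
dataset.  At ``effect_scale=1`` the class-conditional mean shifts mirror
the effect sizes reported for real diabetic vs non-diabetic groups
(glucose about one pooled standard deviation, BMI ~0.7, age ~0.55,
pedigree ~0.25); ``effect_scale=0`` yields label-independent features.

Partitioning assigns disjoint training shards to heterogeneous
participants with Dirichlet label-proportion skew, plus three shared,
label-stratified index sets: a validation subset (used for the dynamic
aggregation weights), a test subset (reported metrics) and an unlabeled
pool on which soft labels are exchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FEATURE_COLUMNS = [
    "pregnancies",
    "glucose",
    "blood_pressure",
    "skin_thickness",
    "insulin",
    "bmi",
    "pedigree",
    "age",
]
OUTCOME_COLUMN = "outcome"

# Marginal (mean, sd) per feature, loosely matching the published cohort.
_BASE_MOMENTS = {
    "pregnancies": (3.8, 3.2),
    "glucose": (121.0, 30.0),
    "blood_pressure": (72.0, 12.0),
    "skin_thickness": (29.0, 10.0),
    "insulin": (140.0, 90.0),
    "bmi": (32.0, 7.0),
    "pedigree": (0.47, 0.33),
    "age": (33.0, 11.0),
}

# Standardised upward mean shift for positives at effect_scale=1.  The
# ratios between features mirror the real cohort's class differences
# (glucose strongest, then BMI, age, pedigree); the overall magnitude is
# calibrated so the Bayes-optimal accuracy is ~0.90, the regime the
# emulated federation operates in.
_EFFECT_SIZES = {
    "glucose": 1.9,
    "bmi": 1.33,
    "age": 1.05,
    "pedigree": 0.48,
}

_NONNEGATIVE = {"pregnancies", "glucose", "blood_pressure", "skin_thickness",
                "insulin", "bmi", "pedigree", "age"}


@dataclass
class Cohort:
    """Feature matrix with named clinical columns and binary outcomes."""

    features: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels length mismatch")
        if len(self.features) < 1:
            raise ValueError("cohort must contain at least one record")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be 0/1")
        if self.features.isna().any().any():
            raise ValueError("cohort contains missing values")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_csv(self, path: str | Path) -> None:
        out = self.features.copy()
        out[OUTCOME_COLUMN] = self.labels
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        """Read a cohort CSV (8 named feature columns + ``outcome``).

        Accepts the real benchmark CSV as long as its header uses the
        canonical column names.
        """
        df = pd.read_csv(path)
        missing = [c for c in FEATURE_COLUMNS + [OUTCOME_COLUMN] if c not in df.columns]
        if missing:
            raise ValueError(f"cohort CSV missing columns: {missing}")
        return cls(features=df[FEATURE_COLUMNS].astype(float),
                   labels=df[OUTCOME_COLUMN].to_numpy())


@dataclass(frozen=True)
class ParticipantProfile:
    """One row of the simulated heterogeneous roster.

    ``static_weight`` is the a-priori aggregation weight used in round 0,
    before any shared-validation accuracy exists; ``data_fraction`` is the
    share of the training pool assigned to this participant's shard.
    """

    id: int
    name: str
    model_kind: str
    hyperparameters: Mapping[str, object]
    data_fraction: float
    resource_level: str
    static_weight: float


def default_roster() -> list[ParticipantProfile]:
    """The five-participant roster used throughout: a large hospital
    (random forest), an urban health kiosk (KNN), a regional clinic
    (gradient-boosted trees), a community clinic (decision tree) and a
    personal health tracker (linear SVM)."""
    return [
        ParticipantProfile(
            id=1, name="large_hospital", model_kind="random_forest",
            hyperparameters={"n_estimators": 130, "max_depth": 15, "max_features": 0.75},
            data_fraction=0.50, resource_level="very_high", static_weight=0.50),
        ParticipantProfile(
            id=2, name="urban_health_kiosk", model_kind="knn",
            hyperparameters={"n_neighbors": 5, "algorithm": "auto"},
            data_fraction=0.05, resource_level="low", static_weight=0.05),
        ParticipantProfile(
            id=3, name="regional_clinic", model_kind="gradient_boosted_trees",
            hyperparameters={"learning_rate": 0.01, "max_depth": 10, "n_estimators": 180},
            data_fraction=0.30, resource_level="high", static_weight=0.30),
        ParticipantProfile(
            id=4, name="community_health_clinic", model_kind="decision_tree",
            hyperparameters={"max_depth": None, "criterion": "gini"},
            data_fraction=0.10, resource_level="medium", static_weight=0.10),
        ParticipantProfile(
            id=5, name="personal_health_tracker", model_kind="linear_svm",
            hyperparameters={"kernel": "linear", "C": 1.0},
            data_fraction=0.05, resource_level="very_low", static_weight=0.05),
    ]


def validate_roster(roster: Sequence[ParticipantProfile]) -> None:
    if not roster:
        raise ValueError("roster must be nonempty")
    if sum(p.data_fraction for p in roster) > 1 + 1e-9:
        raise ValueError("data fractions must sum to <= 1")
    if abs(sum(p.static_weight for p in roster) - 1.0) > 1e-9:
        raise ValueError("static weights must sum to 1")


@dataclass
class Partition:
    """Disjoint index sets: per-participant shards plus the three shared
    subsets (validation, test, unlabeled pool)."""

    shards: dict[int, np.ndarray]
    shared_validation: np.ndarray
    shared_test: np.ndarray
    shared_unlabeled_pool: np.ndarray

    def all_sets(self) -> list[np.ndarray]:
        return list(self.shards.values()) + [
            self.shared_validation, self.shared_test, self.shared_unlabeled_pool]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "shards": {str(k): sorted(int(i) for i in v) for k, v in self.shards.items()},
            "shared_validation": sorted(int(i) for i in self.shared_validation),
            "shared_test": sorted(int(i) for i in self.shared_test),
            "shared_unlabeled_pool": sorted(int(i) for i in self.shared_unlabeled_pool),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Partition":
        payload = json.loads(Path(path).read_text())
        return cls(
            shards={int(k): np.asarray(v, dtype=np.int64)
                    for k, v in payload["shards"].items()},
            shared_validation=np.asarray(payload["shared_validation"], dtype=np.int64),
            shared_test=np.asarray(payload["shared_test"], dtype=np.int64),
            shared_unlabeled_pool=np.asarray(payload["shared_unlabeled_pool"], dtype=np.int64),
        )


def generate_cohort(n: int, prevalence: float = 0.35, effect_scale: float = 1.0,
                    seed: int = 0) -> Cohort:
    """Draw a synthetic cohort with class-conditional Gaussian features.

    Labels are Bernoulli(``prevalence``); for positive records the glucose,
    BMI, age and pedigree means shift upward by ``effect_scale`` times the
    calibrated per-feature effect size.  Identical arguments (including
    seed) give bit-identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must lie in (0, 1)")
    if not (math.isfinite(prevalence) and math.isfinite(effect_scale)):
        raise ValueError("parameters must be finite")
    if effect_scale < 0:
        raise ValueError("effect_scale must be nonnegative")

    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < prevalence).astype(np.int64)
    data = {}
    for col in FEATURE_COLUMNS:
        mean, sd = _BASE_MOMENTS[col]
        shift = _EFFECT_SIZES.get(col, 0.0) * effect_scale * sd
        x = rng.normal(mean, sd, size=n) + shift * labels
        if col in _NONNEGATIVE:
            x = np.clip(x, 0.0, None)
        if col == "pregnancies":
            x = np.round(x)
        data[col] = x
    return Cohort(features=pd.DataFrame(data, columns=FEATURE_COLUMNS), labels=labels)


def _largest_remainder(fractions: Sequence[float], total: int) -> list[int]:
    """Integer shard sizes conserving the total (largest-remainder method)."""
    raw = [f * total for f in fractions]
    sizes = [int(math.floor(r)) for r in raw]
    short = int(round(sum(fractions) * total)) - sum(sizes)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def _stratified_take(rng: np.random.Generator, pos: list[int], neg: list[int],
                     size: int, prevalence: float) -> np.ndarray:
    """Pop a label-stratified sample of ``size`` indices from pos/neg stacks."""
    n_pos, n_neg = _feasible_counts(int(round(size * prevalence)), size, len(pos), len(neg))
    take = [pos.pop() for _ in range(n_pos)] + [neg.pop() for _ in range(n_neg)]
    return np.asarray(sorted(take), dtype=np.int64)


def _feasible_counts(want_pos: int, size: int, avail_pos: int, avail_neg: int
                     ) -> tuple[int, int]:
    """Honor the requested positive count as far as stock allows, backfilling
    from the other class so the set size is conserved."""
    n_pos = min(want_pos, avail_pos)
    n_neg = min(size - n_pos, avail_neg)
    n_pos = min(n_pos + (size - n_pos - n_neg), avail_pos)
    return n_pos, n_neg


def partition_non_iid(cohort: Cohort, roster: Sequence[ParticipantProfile],
                      skew: float = 0.1, val_frac: float = 0.15,
                      test_frac: float = 0.15, pool_frac: float = 0.20,
                      seed: int = 0) -> Partition:
    """Split a cohort into shared stratified subsets and non-IID shards.

    Per-shard positive-label proportions are drawn from a Beta distribution
    with concentration ``1/skew`` centred on the global prevalence (the
    binary case of Dirichlet label-skew); ``skew=0`` degenerates to IID
    assignment.  Shard sizes follow each profile's ``data_fraction`` of the
    remaining training pool via the largest-remainder method.  When a shard
    has room, it is guaranteed at least one record of each class so local
    training stays well-posed.
    """
    validate_roster(roster)
    if skew < 0 or not math.isfinite(skew):
        raise ValueError("skew must be a finite nonnegative real")
    for name, frac in [("val_frac", val_frac), ("test_frac", test_frac),
                       ("pool_frac", pool_frac)]:
        if not (0 < frac < 1):
            raise ValueError(f"{name} must lie in (0, 1)")
    if val_frac + test_frac + pool_frac >= 1:
        raise ValueError("shared fractions must sum to < 1")

    rng = np.random.default_rng(seed)
    n = cohort.n
    prevalence = float(cohort.labels.mean())
    pos = list(rng.permutation(np.flatnonzero(cohort.labels == 1)))
    neg = list(rng.permutation(np.flatnonzero(cohort.labels == 0)))

    shared_validation = _stratified_take(rng, pos, neg, int(round(val_frac * n)), prevalence)
    shared_test = _stratified_take(rng, pos, neg, int(round(test_frac * n)), prevalence)
    shared_pool = _stratified_take(rng, pos, neg, int(round(pool_frac * n)), prevalence)

    pool_size = len(pos) + len(neg)
    sizes = _largest_remainder([p.data_fraction for p in roster], pool_size)

    shards: dict[int, np.ndarray] = {}
    for s, (profile, size) in enumerate(zip(roster, sizes)):
        if size == 0:
            shards[profile.id] = np.asarray([], dtype=np.int64)
            continue
        if skew == 0:
            q = prevalence
        else:
            conc = 1.0 / skew
            q = float(rng.beta(conc * prevalence, conc * (1.0 - prevalence)))
        want_pos = int(round(q * size))
        if size >= 2:  # keep both classes representable where possible
            want_pos = min(max(want_pos, 1), size - 1)
        # reserve one record of each class for every shard still to come,
        # so no participant is starved of a whole class by an extreme draw
        reserve = sum(1 for sz in sizes[s + 1:] if sz >= 2)
        n_pos, n_neg = _feasible_counts(
            want_pos, size, max(len(pos) - reserve, 0), max(len(neg) - reserve, 0))
        take = [pos.pop() for _ in range(n_pos)] + [neg.pop() for _ in range(n_neg)]
        shards[profile.id] = np.asarray(sorted(take), dtype=np.int64)

    return Partition(shards=shards, shared_validation=shared_validation,
                     shared_test=shared_test, shared_unlabeled_pool=shared_pool)
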