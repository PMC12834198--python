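"""Multi-round federation driver and the bootstrap comparison statistic.

One federated round executes, in order: local (re)training with the
current pseudo-labels, soft-label prediction on the shared unlabeled
pool, temperature scaling, ledger-gated submission (identity, role,
round, timestamp, metadata and payload checks plus multi-validator
quorum), accuracy-proportional weighting with clipping, weighted
soft-vote aggregation, confidence filtering, pseudo-label refresh
(replace, not accumulate) and evaluation on the shared test set.

`bootstrap_compare` implements the percentile-bootstrap difference test
between two classifiers on a shared test set: B resamples of the test
instances with replacement, per-resample metric difference
``delta(b) = M_A(b) - M_B(b)``, and an empirical two-sided
(alpha/2, 1-alpha/2) percentile confidence interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from fedistill.synthetic_cohort import (
    Cohort, ParticipantProfile, Partition, default_roster, generate_cohort,
    partition_non_iid,
)
from fedistill.preprocessing import (
    PreprocessConfig, remove_outliers, engineer_bins, zscore, apply_zscore,
    smote_balance,
)
from fedistill.participants import (
    LocalModel, SoftLabelMatrix, build_model, train_local, predict_soft, evaluate,
)
from fedistill.distillation import (
    DistillConfig, WeightVector, GlobalPrediction, temperature_scale,
    compute_weights, clip_and_renormalize, aggregate, filter_confident,
)
from fedistill.trust_ledger import Ledger, SubmissionMetadata, canonical_payload


class RoundAbortError(RuntimeError):
    """Raised when no quorum-approved submission reaches aggregation."""


@dataclass
class RoundState:
    round: int
    weights: WeightVector
    global_prediction: GlobalPrediction
    per_participant_metrics: list[dict]
    ensemble_metrics: dict
    accepted_pseudo_count: int


@dataclass
class BootstrapResult:
    B: int
    deltas: np.ndarray
    ci_low: float
    ci_high: float
    mean_a: float
    mean_b: float

    @property
    def mean_delta(self) -> float:
        return float(self.deltas.mean())

    @property
    def significant(self) -> bool:
        """Two-sided significance: the CI excludes zero."""
        return not (self.ci_low <= 0.0 <= self.ci_high)


@dataclass
class FederationConfig:
    """Everything that determines a run, grouped in blocks mirroring the
    JSON run-config layout."""

    n: int = 1000
    prevalence: float = 0.35
    effect_scale: float = 1.0
    skew: float = 0.1
    val_frac: float = 0.15
    test_frac: float = 0.15
    pool_frac: float = 0.20
    rounds: int = 15
    quorum: int = 2
    n_validators: int = 3
    accuracy_tolerance: float = 1e-6
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    distill: DistillConfig = field(default_factory=DistillConfig)
    roster: list[ParticipantProfile] = field(default_factory=default_roster)

    @classmethod
    def from_json(cls, path: str | Path) -> "FederationConfig":
        blob = json.loads(Path(path).read_text())
        kwargs = {}
        kwargs.update(blob.get("cohort", {}))
        kwargs.update(blob.get("partition", {}))
        kwargs.update(blob.get("federation", {}))
        kwargs.update(blob.get("ledger", {}))
        if "preprocess" in blob:
            kwargs["preprocess"] = PreprocessConfig(**blob["preprocess"])
        if "distill" in blob:
            kwargs["distill"] = DistillConfig(**blob["distill"])
        if "roster" in blob:
            kwargs["roster"] = [ParticipantProfile(**p) for p in blob["roster"]]
        return cls(**kwargs)


@dataclass
class PreparedFederation:
    """Preprocessed arrays and ledger shared by all rounds of one run."""

    config: FederationConfig
    partition: Partition
    X: np.ndarray                    # standardized features incl. bin columns
    y: np.ndarray
    models: dict[int, LocalModel]
    ledger: Ledger
    pseudo_features: np.ndarray | None = None
    pseudo_labels: np.ndarray | None = None

    def shard(self, pid: int) -> tuple[np.ndarray, np.ndarray]:
        idx = self.partition.shards[pid]
        return self.X[idx], self.y[idx]

    @property
    def validation(self) -> tuple[np.ndarray, np.ndarray]:
        idx = self.partition.shared_validation
        return self.X[idx], self.y[idx]

    @property
    def test(self) -> tuple[np.ndarray, np.ndarray]:
        idx = self.partition.shared_test
        return self.X[idx], self.y[idx]

    @property
    def pool(self) -> np.ndarray:
        return self.X[self.partition.shared_unlabeled_pool]


def _subseed(seed: int, *parts: int) -> int:
    ss = np.random.SeedSequence([int(seed)] + [int(p) for p in parts])
    return int(ss.generate_state(1)[0] % (2**31))


def prepare_federation(config: FederationConfig, seed: int) -> PreparedFederation:
    """Generate, clean, partition and standardise the cohort; register all
    parties on a fresh ledger; fit the round-0 models on shards alone."""
    cohort = generate_cohort(config.n, config.prevalence, config.effect_scale,
                             seed=_subseed(seed, 0))
    cohort, _ = remove_outliers(cohort, config.preprocess)
    partition = partition_non_iid(
        cohort, config.roster, skew=config.skew, val_frac=config.val_frac,
        test_frac=config.test_frac, pool_frac=config.pool_frac,
        seed=_subseed(seed, 1))
    train_union = np.concatenate(list(partition.shards.values()))
    cohort = engineer_bins(cohort, config.preprocess, fit_rows=train_union)
    X_raw = cohort.features.to_numpy(dtype=float)
    X, _, _ = zscore(X_raw, fit_rows=train_union)

    ledger = Ledger(quorum=config.quorum)
    for p in config.roster:
        ledger.register_client(_address(p.id), "model_provider")
    for v in range(config.n_validators):
        ledger.register_client(f"0xvalidator{v + 1}", "validator")
    ledger.register_client("0xaggregator", "aggregator")

    data = PreparedFederation(config=config, partition=partition, X=X,
                              y=cohort.labels, models={}, ledger=ledger)
    for p in config.roster:
        model = build_model(p)
        Xs, ys = data.shard(p.id)
        Xs, ys = _maybe_smote(Xs, ys, config.preprocess.smote_k,
                              _subseed(seed, 2, p.id))
        train_local(model, Xs, ys, seed=_subseed(seed, 3, 0, p.id))
        Xv, yv = data.validation
        model.last_validation_accuracy = evaluate(model, Xv, yv)["accuracy"]
        data.models[p.id] = model
    return data


def _address(pid: int) -> str:
    return f"0xparticipant{pid}"


def _maybe_smote(X: np.ndarray, y: np.ndarray, k: int,
                 seed: int) -> tuple[np.ndarray, np.ndarray]:
    # Shards can be tiny under heavy label skew; balancing is skipped when
    # the minority class is too small for k-NN interpolation.
    counts = np.bincount(y, minlength=2)
    if counts.min() > k and counts[0] != counts[1]:
        return smote_balance(X, y, k=k, seed=seed)
    return X, y


def round0_metrics(data: PreparedFederation) -> list[dict]:
    """Shared-test metrics of the freshly trained local models (the
    pre-collaboration baseline)."""
    Xt, yt = data.test
    out = []
    for p in data.config.roster:
        m = evaluate(data.models[p.id], Xt, yt)
        m.update({"round": 0, "participant": p.id})
        out.append(m)
    return out


def run_round(data: PreparedFederation, t: int, seed: int) -> RoundState:
    """Execute federated round ``t`` >= 1 (round 0 is shard-only training
    done by :func:`prepare_federation`)."""
    config = data.config
    roster = config.roster
    Xv, yv = data.validation
    Xt, yt = data.test
    pool = data.pool

    # 1. local retraining with the current pseudo-labeled pool appended;
    #    class balancing runs on the participant's effective training set
    #    (shard + pseudo), since confident pseudo-labels inherit the
    #    majority-class tilt of the pool
    for p in roster:
        Xs, ys = data.shard(p.id)
        if data.pseudo_labels is not None and len(data.pseudo_labels) > 0:
            Xs = np.vstack([Xs, data.pseudo_features])
            ys = np.concatenate([ys, data.pseudo_labels])
        Xs, ys = _maybe_smote(Xs, ys, config.preprocess.smote_k,
                              _subseed(seed, 2, t, p.id))
        train_local(data.models[p.id], Xs, ys, seed=_subseed(seed, 3, t, p.id))
        data.models[p.id].last_validation_accuracy = \
            evaluate(data.models[p.id], Xv, yv)["accuracy"]

    # 2. soft labels on the shared pool, temperature-scaled
    scaled: dict[int, SoftLabelMatrix] = {}
    for p in roster:
        soft = predict_soft(data.models[p.id], pool)
        soft.round = t
        scaled[p.id] = temperature_scale(soft, config.distill.temperature,
                                         config.distill.epsilon)

    # 3. ledger-gated submission + quorum approval
    eligible: list[int] = []
    validators = sorted(data.ledger.validator_set)
    for p in roster:
        acc = data.models[p.id].last_validation_accuracy
        meta = SubmissionMetadata(
            sender=_address(p.id), round=data.ledger.current_round,
            declared_accuracy=acc, timestamp=data.ledger._clock + 1,
            payload=canonical_payload(scaled[p.id].probs))
        rec = data.ledger.submit_model_update(
            meta, recomputed_accuracy=evaluate(data.models[p.id], Xv, yv)["accuracy"],
            tolerance=config.accuracy_tolerance)
        if rec.status == "accepted":
            for v in validators[:config.quorum]:
                data.ledger.validator_approve(rec.index, v)
            if data.ledger.is_aggregation_eligible(rec.index):
                eligible.append(p.id)
    if not eligible:
        raise RoundAbortError(f"round {t}: no quorum-approved submissions")

    # 4. weights: static profile weights bootstrap round 1; dynamic
    #    accuracy-proportional weights afterwards
    profiles = [p for p in roster if p.id in eligible]
    accs = np.array([data.models[p.id].last_validation_accuracy for p in profiles])
    if t <= 1:
        statics = np.array([p.static_weight for p in profiles])
        wv = WeightVector(round=t, weights=statics / statics.sum(),
                          source_accuracies=accs)
    else:
        wv = compute_weights(accs, round=t)
    # a cap below 1/N is infeasible; small ensembles relax it to uniform
    wv = clip_and_renormalize(
        wv, cap=max(config.distill.weight_cap, 1.0 / len(profiles)))

    # 5. aggregation, confidence filtering, pseudo-label refresh
    global_pred = aggregate([scaled[p.id] for p in profiles], wv)
    global_pred = filter_confident(global_pred, tau=config.distill.tau)
    accepted = np.flatnonzero(global_pred.accepted_mask)
    data.pseudo_features = pool[accepted]
    data.pseudo_labels = np.array(
        [global_pred.pseudo_labels[int(i)] for i in accepted], dtype=np.int64)
    data.ledger.mark_aggregated("0xaggregator", data.ledger.current_round)

    # 6. evaluation on the shared test set
    per_participant = []
    for p in roster:
        m = evaluate(data.models[p.id], Xt, yt)
        m.update({"round": t, "participant": p.id})
        per_participant.append(m)
    ens_scaled = [temperature_scale(predict_soft(data.models[p.id], Xt),
                                    config.distill.temperature,
                                    config.distill.epsilon)
                  for p in profiles]
    ens = aggregate(ens_scaled, wv)
    ensemble_metrics = evaluate(ens.probs.argmax(axis=1), yt)
    ensemble_metrics.update({"round": t, "participant": "ensemble"})

    return RoundState(round=t, weights=wv, global_prediction=global_pred,
                      per_participant_metrics=per_participant,
                      ensemble_metrics=ensemble_metrics,
                      accepted_pseudo_count=int(len(accepted)))


def run_federation(config: FederationConfig, seed: int,
                   out_dir: str | Path | None = None
                   ) -> tuple[list[RoundState], dict]:
    """Run the full multi-round federation; returns the per-round states
    and a final report (per-participant accuracy trajectories, their
    mean/SD across rounds, and the ledger audit report).

    When ``out_dir`` is given, writes ``metrics.csv`` (round, participant,
    accuracy, precision, recall, f1), ``ledger.jsonl``, ``report.json``
    and ``weights.jsonl``.
    """
    data = prepare_federation(config, seed)
    baseline = round0_metrics(data)
    states: list[RoundState] = []
    for t in range(1, config.rounds + 1):
        states.append(run_round(data, t, seed))

    rows = [dict(m) for m in baseline]
    for st in states:
        rows.extend(dict(m) for m in st.per_participant_metrics)
        rows.append(dict(st.ensemble_metrics))
    metrics = pd.DataFrame(rows)[
        ["round", "participant", "accuracy", "precision", "recall", "f1"]]

    report: dict = {"seed": seed, "rounds": config.rounds, "participants": {}}
    for p in config.roster:
        traj = [m["accuracy"] for st in states
                for m in st.per_participant_metrics if m["participant"] == p.id]
        r0 = next(m["accuracy"] for m in baseline if m["participant"] == p.id)
        report["participants"][str(p.id)] = {
            "model_kind": p.model_kind,
            "round0_accuracy": r0,
            "final_accuracy": traj[-1],
            "mean_accuracy": float(np.mean(traj)),
            "sd_accuracy": float(np.std(traj, ddof=1)) if len(traj) > 1 else 0.0,
        }
    report["ensemble_final"] = {k: states[-1].ensemble_metrics[k]
                                for k in ("accuracy", "precision", "recall", "f1")}
    report["audit"] = data.ledger.audit_report()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "metrics.csv", index=False,
                       float_format="%.10f")
        data.ledger.write_log(out / "ledger.jsonl")
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        with open(out / "weights.jsonl", "w") as fh:
            for st in states:
                fh.write(json.dumps({
                    "round": st.round,
                    "weights": [repr(float(w)) for w in st.weights.weights],
                    "accepted_pseudo_count": st.accepted_pseudo_count,
                }, sort_keys=True) + "\n")
    report["_metrics_frame"] = metrics
    return states, report


# ---------------------------------------------------------------------------
# bootstrap comparison
# ---------------------------------------------------------------------------

_METRICS = ("accuracy", "precision", "recall", "f1")


def _metric_per_resample(preds: np.ndarray, truth: np.ndarray,
                         idx: np.ndarray, metric: str) -> np.ndarray:
    p = preds[idx]          # B x n
    y = truth[idx]
    if metric == "accuracy":
        return (p == y).mean(axis=1)
    tp = ((p == 1) & (y == 1)).sum(axis=1).astype(float)
    fp = ((p == 1) & (y == 0)).sum(axis=1).astype(float)
    fn = ((p == 0) & (y == 1)).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        if metric == "precision":
            return prec
        if metric == "recall":
            return rec
        denom = prec + rec
        return np.where(denom > 0, 2 * prec * rec / denom, 0.0)


def bootstrap_compare(preds_a: np.ndarray, preds_b: np.ndarray, truth: np.ndarray,
                      metric: str = "accuracy", B: int = 1000,
                      alpha: float = 0.05, seed: int = 0) -> BootstrapResult:
    """Percentile-bootstrap difference between two prediction vectors.

    Resamples test instances with replacement B times; the same resample
    indices evaluate both classifiers, so each ``delta(b)`` is a paired
    difference.  The two-sided CI excluding zero declares a significant
    difference at level ``alpha``.
    """
    a = np.asarray(preds_a, dtype=np.int64)
    b = np.asarray(preds_b, dtype=np.int64)
    y = np.asarray(truth, dtype=np.int64)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("prediction and truth vectors must share one length")
    if B < 1:
        raise ValueError("B must be >= 1")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    rng = np.random.default_rng(seed)
    n = y.size
    idx = rng.integers(0, n, size=(B, n))
    m_a = _metric_per_resample(a, y, idx, metric)
    m_b = _metric_per_resample(b, y, idx, metric)
    deltas = m_a - m_b
    lo, hi = np.percentile(deltas, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(B=B, deltas=deltas, ci_low=float(lo), ci_high=float(hi),
                           mean_a=float(m_a.mean()), mean_b=float(m_b.mean()))
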