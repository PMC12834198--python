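"""Mathematical core of the federation: temperature scaling, accuracy-
proportional dynamic weights with clipping, weighted soft-vote aggregation,
and confidence-filtered pseudo-label emission.

For participant i at round t with shared-validation accuracy ``Acc_i``:

* dynamic weight      ``W_i = Acc_i / sum_j Acc_j`` (then capped and
  renormalised by proportional water-filling),
* global prediction   ``P(x) = sum_i W_i * P_i(x)`` row-wise on the shared
  unlabeled pool,
* pseudo-label emitted for x iff ``max(P(x)) >= tau`` (argmax, lowest
  class index on exact ties).

Temperature scaling smooths each participant's rows before aggregation:
logits are reconstructed as ``log(p + eps)`` — invariant under softmax at
T=1 — divided by T, and softmaxed back.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import softmax

from fedistill.participants import SoftLabelMatrix


@dataclass
class DistillConfig:
    temperature: float = 2.0
    tau: float = 0.7
    weight_cap: float = 0.5
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (0.5 < self.tau <= 1.0):
            raise ValueError("tau must lie in (0.5, 1]")
        if not (0 < self.weight_cap <= 1.0):
            raise ValueError("weight_cap must lie in (0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class WeightVector:
    round: int
    weights: np.ndarray
    source_accuracies: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.source_accuracies = np.asarray(self.source_accuracies, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if (self.weights < -1e-12).any():
            raise ValueError("weights must be nonnegative")


@dataclass
class GlobalPrediction:
    round: int
    probs: np.ndarray
    accepted_mask: np.ndarray | None = None
    pseudo_labels: dict[int, int] | None = None


def temperature_scale(soft: SoftLabelMatrix, T: float, epsilon: float = 1e-12) -> SoftLabelMatrix:
    """Smooth (T>1) or sharpen (T<1) probability rows via logit division.

    T=1 reproduces the input up to the epsilon floor; T -> infinity tends
    to the uniform distribution.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    logits = np.log(soft.probs + epsilon)
    probs = softmax(logits / T, axis=1)
    probs /= probs.sum(axis=1, keepdims=True)
    return SoftLabelMatrix(participant_id=soft.participant_id, round=soft.round,
                           probs=probs)


def compute_weights(accuracies: np.ndarray, round: int = 0) -> WeightVector:
    """Accuracy-proportional contribution weights (unclipped)."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size == 0 or (acc < 0).any():
        raise ValueError("accuracies must be a nonempty nonnegative vector")
    total = acc.sum()
    if total <= 0:
        raise ValueError("at least one accuracy must be positive")
    return WeightVector(round=round, weights=acc / total, source_accuracies=acc)


def clip_and_renormalize(wv: WeightVector, cap: float = 0.5) -> WeightVector:
    """Cap weights and redistribute the excess proportionally (water-filling).

    Iterates: set weights above ``cap`` to ``cap``, spread the removed mass
    over the currently-uncapped weights in proportion to their size, until
    every weight is within the cap.  The sum stays 1 and the ordering of
    weights is preserved.
    """
    n = wv.weights.size
    if cap < 1.0 / n - 1e-12:
        raise ValueError(f"cap {cap} is infeasible for {n} weights (needs >= 1/N)")
    w = wv.weights.copy()
    capped = np.zeros(n, dtype=bool)
    for _ in range(n):
        over = (w > cap + 1e-15) & ~capped
        if not over.any():
            break
        excess = (w[over] - cap).sum()
        w[over] = cap
        capped |= over
        free = ~capped
        if not free.any():
            break
        w[free] += excess * w[free] / w[free].sum()
    w = np.minimum(w, cap)
    w /= w.sum()
    return WeightVector(round=wv.round, weights=w, source_accuracies=wv.source_accuracies)


def aggregate(softlabels: list[SoftLabelMatrix], wv: WeightVector) -> GlobalPrediction:
    """Row-wise convex combination of participant soft labels."""
    if len(softlabels) != wv.weights.size:
        raise ValueError("number of soft-label matrices must match weights")
    shapes = {s.probs.shape for s in softlabels}
    if len(shapes) != 1:
        raise ValueError(f"soft-label matrices disagree in shape: {shapes}")
    stacked = np.stack([s.probs for s in softlabels])        # N x n x C
    probs = np.tensordot(wv.weights, stacked, axes=(0, 0))   # n x C
    probs /= probs.sum(axis=1, keepdims=True)
    rnd = softlabels[0].round
    return GlobalPrediction(round=rnd, probs=probs)


def filter_confident(global_pred: GlobalPrediction, tau: float = 0.7) -> GlobalPrediction:
    """Keep rows whose maximum ensemble probability reaches ``tau``
    (inclusive); the pseudo-label is the argmax, lowest class index on an
    exact tie.  Rejected rows carry no label."""
    probs = global_pred.probs
    accepted = probs.max(axis=1) >= tau
    labels = {int(i): int(probs[i].argmax()) for i in np.flatnonzero(accepted)}
    return GlobalPrediction(round=global_pred.round, probs=probs,
                            accepted_mask=accepted, pseudo_labels=labels)
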