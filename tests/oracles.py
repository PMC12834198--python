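"""Independent straight-line recomputations used as test oracles.

These are deliberately naive (loops, no shared code with the package) so
they stand alone as a second route through the same mathematics.
"""

import math

import numpy as np


def chain_oracle(prob_matrices, accuracies, T, cap, tau, eps=1e-12):
    """Scalar-loop recomputation of the full distillation chain:
    temperature scaling -> accuracy-proportional weights -> cap with
    proportional redistribution -> weighted soft vote -> confidence filter.

    Returns (scaled_list, weights, global_probs, accepted, labels).
    """
    scaled = []
    for P in prob_matrices:
        out = []
        for row in P:
            logit = [math.log(p + eps) / T for p in row]
            mx = max(logit)
            ex = [math.exp(l - mx) for l in logit]
            s = sum(ex)
            out.append([e / s for e in ex])
        scaled.append(out)

    total = sum(accuracies)
    w = [a / total for a in accuracies]
    while max(w) > cap + 1e-15:
        over = [i for i, wi in enumerate(w) if wi > cap]
        excess = sum(w[i] - cap for i in over)
        for i in over:
            w[i] = cap
        free = [i for i in range(len(w)) if i not in over and w[i] < cap]
        fs = sum(w[i] for i in free)
        for i in free:
            w[i] += excess * w[i] / fs
    s = sum(w)
    w = [wi / s for wi in w]

    n = len(prob_matrices[0])
    C = len(prob_matrices[0][0])
    global_probs = []
    for r in range(n):
        row = [sum(w[i] * scaled[i][r][c] for i in range(len(w))) for c in range(C)]
        s = sum(row)
        global_probs.append([v / s for v in row])

    accepted, labels = [], {}
    for r, row in enumerate(global_probs):
        ok = max(row) >= tau
        accepted.append(ok)
        if ok:
            labels[r] = row.index(max(row))
    return (np.array([np.array(s) for s in scaled]), np.array(w),
            np.array(global_probs), np.array(accepted), labels)


def run_chain(prob_matrices, accuracies, T, cap, tau):
    """The same chain through the package's own operations."""
    from fedistill.distillation import (
        aggregate, clip_and_renormalize, compute_weights, filter_confident,
        temperature_scale,
    )
    from fedistill.participants import SoftLabelMatrix

    softs = [temperature_scale(
        SoftLabelMatrix(participant_id=i, round=0, probs=P), T)
        for i, P in enumerate(prob_matrices)]
    wv = clip_and_renormalize(compute_weights(np.asarray(accuracies)), cap)
    gp = filter_confident(aggregate(softs, wv), tau)
    return ([s.probs for s in softs], wv.weights, gp.probs,
            gp.accepted_mask, gp.pseudo_labels)
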