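"""Independent brute-force reference implementations used as test oracles.

Every function here is written as directly as possible from the defining
formula (double loops, exhaustive pair counting, O(n^2) structural
components) and shares no code with the package implementation.
"""

import numpy as np


def supcon_loss_naive(z, labels, tau):
    z = np.asarray(z, float)
    labels = np.asarray(labels).reshape(-1)
    n = len(labels)
    total, anchors = 0.0, 0
    for i in range(n):
        positives = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not positives:
            continue
        anchors += 1
        inner = 0.0
        for j in positives:
            s_ij = z[i] @ z[j] / tau
            denom = sum(np.exp(z[i] @ z[k] / tau) for k in range(n) if k != i)
            inner += np.log(np.exp(s_ij) / denom)
        total += inner / len(positives)
    return -total / anchors if anchors else 0.0


def intra_class_similarity_naive(z, labels, tau):
    z = np.asarray(z, float)
    labels = np.asarray(labels).reshape(-1)
    n = len(labels)
    out = np.zeros((n, 1))
    for i in range(n):
        sims = [z[i] @ z[j] / tau for j in range(n)
                if j != i and labels[j] == labels[i]]
        out[i, 0] = np.mean(sims) if sims else 0.0
    return out


def weighted_ce_naive(probs, labels, w0, w1):
    probs = np.asarray(probs, float)
    labels = np.asarray(labels).reshape(-1)
    total = 0.0
    for i, y in enumerate(labels):
        if y == 1:
            total += w1 * np.log(probs[i, 1] + 1e-12)
        else:
            total += w0 * np.log(probs[i, 0] + 1e-12)
    return -total / len(labels)


def auc_pair_counting(labels, scores):
    labels = np.asarray(labels).reshape(-1)
    scores = np.asarray(scores, float).reshape(-1)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def cross_attention_naive(q, k, v, wq, wk, wv, wout, heads):
    """Single-token multi-head cross attention, explicit per-head loops.

    ``wq/wk/wv/wout`` are the (d, d) combined projection matrices used as
    ``x @ W``; head h occupies output slice [h*dh, (h+1)*dh).
    """
    q, k, v = (np.asarray(a, float) for a in (q, k, v))
    b, d = q.shape
    dh = d // heads
    qp, kp, vp = q @ wq, k @ wk, v @ wv
    attended = np.zeros((b, d))
    pooled = np.zeros((b, 1))
    for i in range(b):
        for h in range(heads):
            sl = slice(h * dh, (h + 1) * dh)
            logit = qp[i, sl] @ kp[i, sl] / np.sqrt(dh)
            weight = np.exp(logit) / np.exp(logit)  # softmax over one key
            attended[i, sl] = weight * vp[i, sl]
            pooled[i, 0] += weight / heads
    return attended @ wout, pooled


def delong_slow(labels, scores_a, scores_b):
    """O(n^2) DeLong structural components and two-sided p-value."""
    from scipy import stats

    labels = np.asarray(labels).reshape(-1)

    def components(scores):
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        m, n = len(pos), len(neg)
        psi = np.zeros((m, n))
        for i in range(m):
            for j in range(n):
                psi[i, j] = 1.0 if pos[i] > neg[j] else (0.5 if pos[i] == neg[j] else 0.0)
        auc = psi.mean()
        v10 = psi.mean(axis=1)
        v01 = psi.mean(axis=0)
        return auc, v10, v01

    auc_a, v10_a, v01_a = components(np.asarray(scores_a, float))
    auc_b, v10_b, v01_b = components(np.asarray(scores_b, float))
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var = s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m \
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    diff = auc_a - auc_b
    if var <= 0:
        return diff, 1.0
    z = diff / np.sqrt(var)
    return diff, 2 * float(stats.norm.sf(abs(z)))


def numeric_gradient(fn, tensor, eps=1e-6):
    """Central finite differences of scalar ``fn()`` w.r.t. ``tensor.data``."""
    grad = np.zeros_like(tensor.data)
    it = np.nditer(tensor.data, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        tensor.data[idx] += eps
        hi = fn()
        tensor.data[idx] -= 2 * eps
        lo = fn()
        tensor.data[idx] += eps
        grad[idx] = (hi - lo) / (2 * eps)
    return grad
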