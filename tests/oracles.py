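"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the implementations under test.
"""

from __future__ import annotations

import numpy as np


def q_bruteforce(layers, labels, gamma, omega):
    """Literal four-index evaluation of the multilayer quality function.

    ``layers``: L x K x K array. ``labels``: L x K integers. Intralayer term
    (A_ijl - gamma * k_i k_j / 2m_l) over all ordered pairs including i = j;
    interlayer term omega for the same node in adjacent layers. Normalized
    by total intralayer weight plus total coupling weight.
    """
    layers = np.asarray(layers, dtype=float)
    labels = np.asarray(labels)
    L, K, _ = layers.shape
    total = 0.0
    two_mu = 2.0 * omega * K * (L - 1)
    for l in range(L):
        A = layers[l]
        k = A.sum(axis=0)
        twom = k.sum()
        two_mu += twom
        for i in range(K):
            for j in range(K):
                if labels[l, i] == labels[l, j]:
                    null = gamma * k[i] * k[j] / twom if twom > 0 else 0.0
                    total += A[i, j] - null
    for l in range(L - 1):
        for i in range(K):
            if labels[l, i] == labels[l + 1, i]:
                total += 2.0 * omega
    if two_mu == 0.0:
        return 0.0
    return total / two_mu


def _restricted_growth_strings(n):
    """All set partitions of n elements as label vectors (canonical form)."""
    out = []
    labels = [0] * n

    def rec(pos, max_label):
        if pos == n:
            out.append(tuple(labels))
            return
        for lab in range(max_label + 2):
            labels[pos] = lab
            rec(pos + 1, max(max_label, lab))

    rec(1, 0)  # element 0 always labelled 0
    return np.array(out, dtype=np.int64)


def exhaustive_q_max(layers, gamma, omega):
    """Maximum quality over *all* assignments of node-layer tuples.

    Feasible for K * L <= 10 or so. Returns (q_max, best_labels L x K).
    """
    layers = np.asarray(layers, dtype=float)
    L, K, _ = layers.shape
    N = L * K
    parts = _restricted_growth_strings(N)  # (P, N)
    # build the full supra matrix naively
    B = np.zeros((N, N))
    two_mu = 2.0 * omega * K * (L - 1)
    for l in range(L):
        A = layers[l]
        k = A.sum(axis=0)
        twom = k.sum()
        two_mu += twom
        for i in range(K):
            for j in range(K):
                null = gamma * k[i] * k[j] / twom if twom > 0 else 0.0
                B[l * K + i, l * K + j] = A[i, j] - null
    for l in range(L - 1):
        for i in range(K):
            B[l * K + i, (l + 1) * K + i] = omega
            B[(l + 1) * K + i, l * K + i] = omega
    same = parts[:, :, None] == parts[:, None, :]  # (P, N, N)
    scores = np.einsum("pij,ij->p", same, B)
    best = int(np.argmax(scores))
    q_max = scores[best] / two_mu if two_mu > 0 else 0.0
    return float(q_max), parts[best].reshape(L, K)


def bh_stepup_reference(pvals):
    """Naive Benjamini-Hochberg step-up q-values (O(m^2))."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order):
        best = min(
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        )
        q[idx] = min(best, 1.0)
    return q


def pooled_t_reference(x, y):
    """Hand-rolled pooled-variance two-sample t statistic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (nx + ny - 2)
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
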