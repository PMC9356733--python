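"""Multilayer modularity maximization and allegiance aggregation.

The quality function scored here is

    Q = (1/2mu) * sum_{ijlr} [ (A_ijl - gamma_l * V_ijl) * delta_lr
                               + delta_ij * omega_jlr ] * delta(g_il, g_jr)

with V the per-layer Newman-Girvan null model (k_i k_j / 2m_l), uniform
structural resolution gamma, and ordinal interlayer coupling: omega_jlr is
``omega`` when j is the same node in adjacent layers (|l - r| = 1) and zero
otherwise. 2mu is the total intralayer edge weight plus the total interlayer
coupling weight, 2*omega*K*(L-1).

Optimization is a generalized Louvain scheme on the supra-modularity matrix
over node-layer tuples: randomized greedy local moves (strict gain only)
alternating with community aggregation until no improving move exists.
Repeated stochastic runs are aggregated into a module-allegiance matrix of
co-assignment probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .network import MultilayerNetwork

__all__ = [
    "ModularityParams",
    "CommunityAssignment",
    "AllegianceMatrix",
    "null_model_layer",
    "supra_modularity_matrix",
    "multilayer_q",
    "genlouvain_once",
    "consensus_allegiance",
]


@dataclass(frozen=True)
class ModularityParams:
    gamma: float = 1.0
    omega: float = 0.4
    n_runs: int = 100
    seed: int = 0
    max_passes: int = 64

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass(frozen=True)
class CommunityAssignment:
    """Per-layer, per-node community labels (positive integers) from one run."""

    labels: np.ndarray  # L x K, int, labels >= 1
    q_value: float

    def __post_init__(self):
        labs = np.asarray(self.labels)
        if labs.ndim != 2:
            raise ValueError("labels must be L x K")
        if labs.min() < 1:
            raise ValueError("community labels must be positive integers")


@dataclass(frozen=True)
class AllegianceMatrix:
    """Node-pair co-assignment probabilities over layers and runs."""

    P: np.ndarray
    n_layers: int
    n_runs: int
    node_ids: tuple | None = None

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("P must be square")
        if not np.allclose(P, P.T):
            raise ValueError("P must be symmetric")
        if P.min() < -1e-12 or P.max() > 1 + 1e-12:
            raise ValueError("P entries must lie in [0, 1]")
        if not np.allclose(np.diag(P), 1.0):
            raise ValueError("P must have unit diagonal")
        object.__setattr__(self, "P", P)


def null_model_layer(A: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Newman-Girvan null model for one layer: gamma * k_i k_j / (2 m).

    An all-zero layer yields an all-zero null model.
    """
    A = np.asarray(A, dtype=float)
    k = A.sum(axis=0)
    twom = k.sum()
    if twom == 0.0:
        return np.zeros_like(A)
    return gamma * np.outer(k, k) / twom


def _coupling_weight(K: int, L: int, omega: float) -> float:
    return 2.0 * omega * K * (L - 1)


def supra_modularity_matrix(net: MultilayerNetwork, params: ModularityParams):
    """Dense supra-modularity matrix over node-layer tuples and 2mu.

    Element (l*K + i, l*K + j) is A_ijl - gamma*V_ijl; entries coupling the
    same node in adjacent layers equal omega; everything else is zero.
    """
    L, K = net.n_layers, net.n_nodes
    N = L * K
    B = np.zeros((N, N), dtype=float)
    two_mu = 0.0
    for l in range(L):
        A = net.layers[l]
        two_mu += A.sum()
        B[l * K:(l + 1) * K, l * K:(l + 1) * K] = A - null_model_layer(A, params.gamma)
    if params.omega > 0:
        idx = np.arange((L - 1) * K)
        B[idx, idx + K] = params.omega
        B[idx + K, idx] = params.omega
    two_mu += _coupling_weight(K, L, params.omega)
    return B, two_mu


def multilayer_q(net: MultilayerNetwork, assign: CommunityAssignment,
                 params: ModularityParams) -> float:
    """Evaluate the multilayer modularity of a given assignment.

    The intralayer sum runs over all ordered pairs including i = j (the
    diagonal contributes a partition-independent -V_iil per node).
    """
    labels = np.asarray(assign.labels)
    L, K = net.n_layers, net.n_nodes
    if labels.shape != (L, K):
        raise ValueError(
            f"assignment shape {labels.shape} does not match network ({L}, {K})"
        )
    total = 0.0
    two_mu = _coupling_weight(K, L, params.omega)
    for l in range(L):
        A = net.layers[l]
        two_mu += A.sum()
        same = labels[l][:, None] == labels[l][None, :]
        total += ((A - null_model_layer(A, params.gamma)) * same).sum()
    for l in range(L - 1):
        total += 2.0 * params.omega * np.count_nonzero(labels[l] == labels[l + 1])
    if two_mu == 0.0:
        return 0.0
    return float(total / two_mu)


@njit(cache=True)
def _sweep(M, labels, order, w):  # pragma: no cover - exercised via wrapper
    """One randomized pass of greedy local moves; returns number moved.

    A move is accepted only for a strictly positive modularity gain; among
    candidate communities the maximal gain wins (first index on exact ties).
    """
    n = M.shape[0]
    moved = 0
    for t in range(n):
        v = order[t]
        cv = labels[v]
        for j in range(n):
            w[labels[j]] += M[v, j]
        w[cv] -= M[v, v]  # exclude self-loop from the community weight
        best_c = cv
        best_gain = 1e-12  # strict improvement; reject ties
        base = w[cv]
        for c in range(n):
            gain = w[c] - base
            if gain > best_gain:
                best_gain = gain
                best_c = c
        if best_c != cv:
            labels[v] = best_c
            moved += 1
        for j in range(n):
            w[labels[j]] = 0.0
        w[cv] = 0.0
        w[best_c] = 0.0
    return moved


@njit(cache=True)
def _sweep_refine(M, ref, group, grp_of, order, w):  # pragma: no cover
    """Refinement pass: like _sweep but a node may only join communities
    inside its parent (phase-one) community."""
    n = M.shape[0]
    moved = 0
    for t in range(n):
        v = order[t]
        cv = ref[v]
        for j in range(n):
            w[ref[j]] += M[v, j]
        w[cv] -= M[v, v]
        best_c = cv
        best_gain = 1e-12
        base = w[cv]
        for c in range(n):
            if grp_of[c] == group[v]:
                gain = w[c] - base
                if gain > best_gain:
                    best_gain = gain
                    best_c = c
        if best_c != cv:
            ref[v] = best_c
            moved += 1
        for j in range(n):
            w[ref[j]] = 0.0
        w[cv] = 0.0
        w[best_c] = 0.0
    return moved


def _refine_partition(M, labels, rng, max_sweeps):
    """Split-capable refinement: re-cluster from singletons within each
    community of ``labels``; the subsequent aggregation level may then
    reassemble the pieces differently (escapes greedy merge lock-ins)."""
    n = M.shape[0]
    ref = np.arange(n)
    grp_of = labels.copy()
    w = np.zeros(n, dtype=float)
    for _ in range(max_sweeps):
        order = rng.permutation(n)
        if _sweep_refine(M, ref, labels, grp_of, order, w) == 0:
            break
    return ref


#: total KL retry budget per convergence cycle (attempts = budget / n)
_KL_BUDGET = 4096


@njit(cache=True)
def _kl_round(B, labels, order, w):  # pragma: no cover - via wrapper
    """One Kernighan-Lin-style round: every element makes its best move
    regardless of sign, the best prefix of the move chain is kept.

    Escapes shallow local optima that require a few coordinated moves.
    Returns the (non-negative) total gain of the kept prefix.
    """
    n = B.shape[0]
    moved_v = np.empty(n, dtype=np.int64)
    moved_from = np.empty(n, dtype=np.int64)
    cum = 0.0
    best_total = 0.0
    best_prefix = 0
    for t in range(n):
        v = order[t]
        cv = labels[v]
        for j in range(n):
            w[labels[j]] += B[v, j]
        w[cv] -= B[v, v]
        best_c = -1
        best_g = -1e300
        for c in range(n):
            if c != cv:
                g = w[c] - w[cv]
                if g > best_g:
                    best_g = g
                    best_c = c
        labels[v] = best_c
        moved_v[t] = v
        moved_from[t] = cv
        cum += best_g
        if cum > best_total + 1e-12:
            best_total = cum
            best_prefix = t + 1
        for j in range(n):
            w[labels[j]] = 0.0
        w[cv] = 0.0
        w[best_c] = 0.0
    for t in range(n - 1, best_prefix - 1, -1):
        labels[moved_v[t]] = moved_from[t]
    return best_total


def _phase_local_moves(M, labels, rng, max_sweeps):
    n = M.shape[0]
    w = np.zeros(n, dtype=float)
    total = 0
    for _ in range(max_sweeps):
        order = rng.permutation(n)
        moved = _sweep(M, labels, order, w)
        total += moved
        if moved == 0:
            break
    return total


def _aggregate(M, compact, n_comms):
    onehot = np.zeros((M.shape[0], n_comms), dtype=float)
    onehot[np.arange(M.shape[0]), compact] = 1.0
    return onehot.T @ M @ onehot


def _louvain(B: np.ndarray, rng: np.random.Generator, max_sweeps: int) -> np.ndarray:
    """Iterated multi-level Louvain with split-capable refinement.

    Each level alternates greedy local moves with a refinement that
    re-clusters every community from singletons (constrained within the
    community); aggregation is over refined pieces while the next level
    starts from the community grouping, so later moves can relocate pieces
    and thereby split earlier merges. The whole cycle restarts from the
    fine level until a full pass makes no improving move. Accepted moves
    strictly increase Q, so termination is guaranteed.
    """
    n0 = B.shape[0]
    final = np.arange(n0)
    w = np.zeros(n0, dtype=float)
    while True:
        while True:
            total_moved = 0
            piece = np.arange(n0)  # node -> aggregated unit
            M = B
            _, cur = np.unique(final, return_inverse=True)  # unit -> community
            while True:
                moved = _phase_local_moves(M, cur, rng, max_sweeps)
                total_moved += moved
                ref = _refine_partition(M, cur, rng, max_sweeps)
                uref, refc = np.unique(ref, return_inverse=True)
                if uref.size == M.shape[0]:
                    if moved == 0:
                        break
                    continue  # converged refinement; retry at this level
                parent = np.empty(uref.size, dtype=np.int64)
                parent[refc] = cur
                M = _aggregate(M, refc, uref.size)
                piece = refc[piece]
                _, cur = np.unique(parent, return_inverse=True)
            final = cur[piece]
            if total_moved == 0:
                break
        # retry budget inversely proportional to problem size keeps the
        # refinement cost bounded by O(budget * n) overall
        tries = max(1, _KL_BUDGET // max(n0, 1))
        gain = 0.0
        for _ in range(tries):
            gain = _kl_round(B, final, rng.permutation(n0), w)
            if gain > 1e-12:
                break
        if gain <= 1e-12:
            break
    _, out = np.unique(final, return_inverse=True)
    return out + 1


def genlouvain_once(net: MultilayerNetwork, params: ModularityParams,
                    rng) -> CommunityAssignment:
    """One stochastic generalized-Louvain run.

    ``rng`` is a :class:`numpy.random.Generator` (or anything accepted by
    ``np.random.default_rng``). The returned ``q_value`` is the independently
    re-evaluated modularity of the returned labels.
    """
    rng = np.random.default_rng(rng)
    B, _ = supra_modularity_matrix(net, params)
    flat = _louvain(B, rng, params.max_passes)
    labels = flat.reshape(net.n_layers, net.n_nodes)
    assign = CommunityAssignment(labels=labels, q_value=0.0)
    q = multilayer_q(net, assign, params)
    return CommunityAssignment(labels=labels, q_value=q)


def _coassignment(labels: np.ndarray) -> np.ndarray:
    """Fraction of layers in which each node pair shares a community."""
    eq = labels[:, :, None] == labels[:, None, :]
    return eq.mean(axis=0)


def consensus_allegiance(net: MultilayerNetwork, params: ModularityParams,
                         subject_tag: int = 0) -> AllegianceMatrix:
    """Allegiance matrix averaged over ``params.n_runs`` seeded runs.

    Run r draws its generator from the sub-stream (seed, subject_tag, r) so
    per-subject results are reproducible regardless of execution order.
    """
    K = net.n_nodes
    P = np.zeros((K, K), dtype=float)
    for r in range(params.n_runs):
        ss = np.random.SeedSequence([int(params.seed), int(subject_tag), r])
        assign = genlouvain_once(net, params, np.random.default_rng(ss))
        P += _coassignment(assign.labels)
    P /= params.n_runs
    np.fill_diagonal(P, 1.0)
    P = (P + P.T) / 2.0
    return AllegianceMatrix(P=P, n_layers=net.n_layers, n_runs=params.n_runs,
                            node_ids=net.node_ids)
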