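"""Two-level map-equation community detection with Markov-time scaling.

The map equation scores a partition of a directed weighted network by the
description length (bits per step) of a random walk encoded with one index
codebook over modules and one codebook per module:

    L = q H(Q) + sum_m p_m H(P_m)

where q is the total module-entry flow, H(Q) the entropy of entry flows,
and each module codebook covers its nodes' visit rates plus the module
exit flow.  Node visit rates come from the stationary distribution of the
network's Markov chain, made ergodic by unrecorded teleportation (rate tau,
targets weighted by in-link weight); link flows use the teleportation-free
step.  Minimizing L over partitions finds modules a random walker stays in
long: flow communities.

Markov time t rescales all module-entry and module-exit flows linearly
inside every codelength term.  At t = 1 this is the standard two-level map
equation; larger t makes boundary crossings costlier and so coarsens the
structure.

The optimizer is a seeded, stochastic, recursive greedy search in the
Louvain style (single-node moves, module aggregation, repeated outer
refinement loops), run over an ensemble of seeds; an exhaustive
Bell-enumeration oracle is provided for small networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

_LOG2 = np.log(2.0)


def _plogp(x: float) -> float:
    return x * np.log(x) / _LOG2 if x > 0.0 else 0.0


@dataclass(frozen=True)
class MapEqConfig:
    """Detection parameters: Markov time 2, teleportation 0.15,
    100 seeds (0..99), 20 outer optimization loops."""

    markov_time: float = 2.0
    teleport: float = 0.15
    n_seeds: int = 100
    outer_loops: int = 20
    tol: float = 1e-12
    patience: int = 5  # consecutive non-improving outer loops before stopping

    def __post_init__(self):
        if self.markov_time <= 0:
            raise ValueError("markov_time must be positive")
        if not 0.0 <= self.teleport < 1.0:
            raise ValueError("teleport rate must be in [0, 1)")


@dataclass
class NodeFlow:
    """Stationary node visit rates and link flows of a network.

    Adjacency lists exclude self-loops: a self-loop never crosses a module
    boundary, so it contributes to visit rates only.
    """

    nodes: np.ndarray  # cell ids, aligned with indices
    p: np.ndarray  # visit rates, sums to 1
    out_idx: list  # out_idx[i]: np arrays of target indices (j != i)
    out_f: list  # matching flows p_i * w_ij
    in_idx: list
    in_f: list

    @property
    def n(self) -> int:
        return len(self.p)

    @property
    def out_tot(self) -> np.ndarray:
        return np.array([f.sum() for f in self.out_f])

    @property
    def in_tot(self) -> np.ndarray:
        return np.array([f.sum() for f in self.in_f])


@dataclass
class Partition:
    """Two-level partition: every node in exactly one community (ids 1..k)."""

    nodes: np.ndarray
    labels: np.ndarray  # 1-based, contiguous
    codelength: float | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.nodes):
            raise ValueError("labels and nodes length mismatch")
        uniq = np.unique(self.labels)
        if len(uniq) and (uniq[0] != 1 or uniq[-1] != len(uniq)):
            raise ValueError("community ids must be contiguous from 1")

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))

    def as_dict(self) -> dict:
        return {int(c): int(m) for c, m in zip(self.nodes, self.labels)}

    def members(self, community: int) -> np.ndarray:
        return self.nodes[self.labels == community]

    def blocks(self) -> set:
        """Label-free representation: set of frozensets of node ids."""
        return {frozenset(int(c) for c in self.members(m))
                for m in np.unique(self.labels)}

    def to_csv(self, path) -> None:
        pd.DataFrame({"cell_id": self.nodes, "community_id": self.labels}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "Partition":
        df = pd.read_csv(path)
        return cls(nodes=df["cell_id"].to_numpy(), labels=df["community_id"].to_numpy())

    def write_clu(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"*Vertices {len(self.nodes)}\n")
            for m in self.labels:
                fh.write(f"{int(m)}\n")


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Contiguous 1-based ids in order of first appearance."""
    out = np.empty_like(labels)
    seen = {}
    for i, m in enumerate(labels):
        if m not in seen:
            seen[m] = len(seen) + 1
        out[i] = seen[m]
    return out


# ---------------------------------------------------------------------------
# flow computation
# ---------------------------------------------------------------------------


def compute_node_flow(network, tau: float = 0.15, tol: float = 1e-12,
                      max_iter: int = 100_000) -> NodeFlow:
    """Stationary visit rates and link flows of a transport network.

    The walker follows links with probability ``1 - tau`` and teleports to
    nodes in proportion to their total in-link weight with probability
    ``tau`` (unrecorded teleportation: only link steps are encoded, so link
    flows are ``p_i * w_ij``).  Power iteration to an L1 tolerance.
    """
    nodes, W = _as_matrix(network)
    n = W.shape[0]
    rowsums = np.asarray(W.sum(axis=1)).ravel()
    if np.any(np.abs(rowsums - 1.0) > 1e-9):
        raise ValueError("network is not row-stochastic; prune and normalize first")
    win = np.asarray(W.sum(axis=0)).ravel()
    if win.sum() <= 0:
        raise ValueError("network has no link weight")
    telep = win / win.sum()

    p = np.full(n, 1.0 / n)
    WT = W.T.tocsr() if sparse.issparse(W) else W.T
    for _ in range(max_iter):
        p_new = (1.0 - tau) * (WT @ p) + tau * telep
        p_new = p_new / p_new.sum()
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            break
        p = p_new

    Wc = W.tocoo() if sparse.issparse(W) else sparse.coo_matrix(W)
    out_idx = [[] for _ in range(n)]
    out_f = [[] for _ in range(n)]
    in_idx = [[] for _ in range(n)]
    in_f = [[] for _ in range(n)]
    for i, j, w in zip(Wc.row, Wc.col, Wc.data):
        if i == j or w == 0.0:
            continue
        f = p[i] * w
        out_idx[i].append(j)
        out_f[i].append(f)
        in_idx[j].append(i)
        in_f[j].append(f)
    return NodeFlow(
        nodes=np.asarray(nodes),
        p=p,
        out_idx=[np.array(a, dtype=int) for a in out_idx],
        out_f=[np.array(a, dtype=float) for a in out_f],
        in_idx=[np.array(a, dtype=int) for a in in_idx],
        in_f=[np.array(a, dtype=float) for a in in_f],
    )


def _as_matrix(network):
    """Accept a TransportNetwork, (nodes, matrix) pair, or square array."""
    if hasattr(network, "transition_matrix"):
        return network.transition_matrix()
    if isinstance(network, tuple) and len(network) == 2:
        return network
    W = np.asarray(network, dtype=float)
    return np.arange(W.shape[0]), W


# ---------------------------------------------------------------------------
# codelength
# ---------------------------------------------------------------------------


def codelength(flow: NodeFlow, partition, t: float = 1.0) -> float:
    """Two-level map-equation description length, in bits.

    ``partition`` is a Partition aligned with ``flow.nodes`` or a plain
    label array.  Module entry/exit flows are scaled by the Markov time
    ``t`` in every term; self-loops never contribute to exit flow.
    """
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    if len(labels) != flow.n:
        raise ValueError("partition does not match flow nodes")
    mods = np.unique(labels)
    midx = {m: k for k, m in enumerate(mods)}
    nm = len(mods)
    qe = np.zeros(nm)
    qx = np.zeros(nm)
    sp = np.zeros(nm)
    for i in range(flow.n):
        mi = midx[labels[i]]
        sp[mi] += flow.p[i]
        for j, f in zip(flow.out_idx[i], flow.out_f[i]):
            mj = midx[labels[j]]
            if mi != mj:
                qx[mi] += t * f
                qe[mj] += t * f
    Q = qe.sum()
    L = _plogp(Q)
    L -= sum(_plogp(x) for x in qe)
    L -= sum(_plogp(x) for x in qx)
    L += sum(_plogp(s + x) for s, x in zip(sp, qx))
    L -= sum(_plogp(x) for x in flow.p)
    return float(L)


# ---------------------------------------------------------------------------
# greedy optimizer
# ---------------------------------------------------------------------------


class _State:
    """Incremental module aggregates for the partition-dependent terms.

    The node-rate entropy term -sum_i plogp(p_i) is partition-independent
    and excluded here; `score` is the four module-dependent terms only.
    """

    __slots__ = ("qe", "qx", "sp", "size", "Q", "score", "t")

    def __init__(self, flow, labels, t):
        n = flow.n
        self.t = t
        self.qe = np.zeros(n)
        self.qx = np.zeros(n)
        self.sp = np.zeros(n)
        self.size = np.zeros(n, dtype=int)
        for i in range(n):
            m = labels[i]
            self.sp[m] += flow.p[i]
            self.size[m] += 1
            for j, f in zip(flow.out_idx[i], flow.out_f[i]):
                if labels[j] != m:
                    self.qx[m] += t * f
                    self.qe[labels[j]] += t * f
        self.Q = self.qe.sum()
        self.score = self._full_score()

    def _full_score(self):
        s = _plogp(self.Q)
        occ = np.flatnonzero(self.size > 0)
        s -= sum(_plogp(self.qe[m]) for m in occ)
        s -= sum(_plogp(self.qx[m]) for m in occ)
        s += sum(_plogp(self.sp[m] + self.qx[m]) for m in occ)
        return s

    def move_delta(self, v_p, v_out, v_in, a, b, foa, fia, fob, fib):
        """Score change of moving node v (rates/boundary flows given, already
        scaled by t) from module a to module b."""
        qe, qx, sp = self.qe, self.qx, self.sp
        qx_a = qx[a] - (v_out - foa) + fia
        qe_a = qe[a] - (v_in - fia) + foa
        qx_b = qx[b] + (v_out - fob) - fib
        qe_b = qe[b] + (v_in - fib) - fob
        Q2 = self.Q + (qe_a - qe[a]) + (qe_b - qe[b])
        d = _plogp(Q2) - _plogp(self.Q)
        d -= _plogp(qe_a) + _plogp(qe_b) - _plogp(qe[a]) - _plogp(qe[b])
        d -= _plogp(qx_a) + _plogp(qx_b) - _plogp(qx[a]) - _plogp(qx[b])
        d += _plogp(sp[a] - v_p + qx_a) + _plogp(sp[b] + v_p + qx_b)
        d -= _plogp(sp[a] + qx[a]) + _plogp(sp[b] + qx[b])
        return d

    def apply(self, v_p, v_out, v_in, a, b, foa, fia, fob, fib):
        qe, qx, sp = self.qe, self.qx, self.sp
        self.Q -= qe[a] + qe[b]
        qx[a] = qx[a] - (v_out - foa) + fia
        qe[a] = qe[a] - (v_in - fia) + foa
        qx[b] = qx[b] + (v_out - fob) - fib
        qe[b] = qe[b] + (v_in - fib) - fob
        self.Q += qe[a] + qe[b]
        sp[a] -= v_p
        sp[b] += v_p
        self.size[a] -= 1
        self.size[b] += 1


def _local_moves(flow, labels, t, rng, tol):
    """Sweep single-node moves to the best neighboring module until stable.

    Candidate modules are scanned in ascending id; a move requires a strict
    codelength improvement (> tol bits).  Returns the updated state.
    """
    state = _State(flow, labels, t)
    out_tot = np.array([t * f.sum() for f in flow.out_f])
    in_tot = np.array([t * f.sum() for f in flow.in_f])
    n = flow.n
    while True:
        n_moved = 0
        for v in rng.permutation(n):
            a = labels[v]
            gain_out = {}
            for j, f in zip(flow.out_idx[v], flow.out_f[v]):
                m = labels[j]
                gain_out[m] = gain_out.get(m, 0.0) + t * f
            gain_in = {}
            for j, f in zip(flow.in_idx[v], flow.in_f[v]):
                m = labels[j]
                gain_in[m] = gain_in.get(m, 0.0) + t * f
            cand = set(gain_out) | set(gain_in)
            cand.discard(a)
            if state.size[a] > 1:
                # allow splitting off into a fresh module
                empty = np.flatnonzero(state.size == 0)
                if empty.size:
                    cand.add(int(empty[0]))
            if not cand:
                continue
            foa = gain_out.get(a, 0.0)
            fia = gain_in.get(a, 0.0)
            best_m, best_d = a, -tol
            for m in sorted(cand):
                d = state.move_delta(
                    flow.p[v], out_tot[v], in_tot[v], a, m,
                    foa, fia, gain_out.get(m, 0.0), gain_in.get(m, 0.0),
                )
                if d < best_d:
                    best_m, best_d = m, d
            if best_m != a:
                state.apply(
                    flow.p[v], out_tot[v], in_tot[v], a, best_m,
                    foa, fia, gain_out.get(best_m, 0.0), gain_in.get(best_m, 0.0),
                )
                labels[v] = best_m
                n_moved += 1
        if n_moved == 0:
            break
    return state


def _aggregate(flow, labels):
    """Collapse modules into super-nodes; inter-module flows become links."""
    comp = _relabel(labels) - 1
    ns = comp.max() + 1
    p_s = np.bincount(comp, weights=flow.p, minlength=ns)
    acc = {}
    for i in range(flow.n):
        mi = comp[i]
        for j, f in zip(flow.out_idx[i], flow.out_f[i]):
            mj = comp[j]
            if mi != mj:
                acc[(mi, mj)] = acc.get((mi, mj), 0.0) + f
    out_idx = [[] for _ in range(ns)]
    out_f = [[] for _ in range(ns)]
    in_idx = [[] for _ in range(ns)]
    in_f = [[] for _ in range(ns)]
    for (i, j), f in sorted(acc.items()):
        out_idx[i].append(j)
        out_f[i].append(f)
        in_idx[j].append(i)
        in_f[j].append(f)
    sup = NodeFlow(
        nodes=np.arange(ns),
        p=p_s,
        out_idx=[np.array(a, dtype=int) for a in out_idx],
        out_f=[np.array(a, dtype=float) for a in out_f],
        in_idx=[np.array(a, dtype=int) for a in in_idx],
        in_f=[np.array(a, dtype=float) for a in in_f],
    )
    return sup, comp


def _search(flow, labels, t, rng, tol):
    """One full Louvain cycle: node moves, then recursive aggregation."""
    state = _local_moves(flow, labels, t, rng, tol)
    score = state.score
    while True:
        sup, comp = _aggregate(flow, labels)
        if sup.n == len(np.unique(labels)) and sup.n == flow.n:
            break
        sup_labels = np.arange(sup.n)
        sup_state = _local_moves(sup, sup_labels, t, rng, tol)
        if sup_state.score < score - tol and len(np.unique(sup_labels)) < sup.n:
            labels[:] = sup_labels[comp]
            score = sup_state.score
        else:
            break
    return score


def optimize(flow: NodeFlow, config: MapEqConfig = MapEqConfig(), seed: int = 0) -> Partition:
    """Greedy two-level search from one seed; deterministic given the seed.

    Starts from singleton modules, then runs up to ``outer_loops``
    refinement loops (node-level fine-tuning of the best partition followed
    by recursive aggregation), keeping the best codelength seen.  Stops
    early after ``patience`` non-improving loops.  Never returns a worse
    partition than the single-module one.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t = config.markov_time
    n = flow.n
    if n == 0:
        raise ValueError("empty flow")

    best = np.arange(n)
    best_score = _search(flow, best, t, rng, config.tol)
    stall = 0
    for _ in range(1, config.outer_loops):
        trial = best.copy()
        score = _search(flow, trial, t, rng, config.tol)
        if score < best_score - config.tol:
            best, best_score = trial, score
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    one_module = np.zeros(n, dtype=int)
    if _State(flow, one_module, t).score < best_score - config.tol:
        best = one_module
    labels = _relabel(best)
    return Partition(nodes=flow.nodes.copy(), labels=labels,
                     codelength=codelength(flow, labels, t))


def ensemble_detect(network, config: MapEqConfig = MapEqConfig(),
                    flow: NodeFlow | None = None):
    """Run the optimizer over seeds 0..n_seeds-1.

    Returns (best partition, list of all partitions).  The best partition
    minimizes the codelength; ties break toward the lowest seed.
    """
    if flow is None:
        flow = compute_node_flow(network, tau=config.teleport)
    ensemble = []
    best = None
    for seed in range(config.n_seeds):
        part = optimize(flow, config, seed)
        ensemble.append(part)
        if best is None or part.codelength < best.codelength - config.tol:
            best = part
    return best, ensemble


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------


def _set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=int)
    maxes = np.zeros(n, dtype=int)

    def rec(i):
        if i == n:
            yield labels.copy()
            return
        top = maxes[i - 1] if i > 0 else -1
        for m in range(top + 2):
            labels[i] = m
            maxes[i] = max(top, m)
            yield from rec(i + 1)

    yield from rec(0)


def brute_force(flow: NodeFlow, t: float = 1.0, max_nodes: int = 10) -> Partition:
    """Global codelength minimum by enumerating every set partition.

    Bell-number enumeration: feasible only for small networks
    (B(10) = 115975); the independent oracle for the greedy optimizer.
    """
    if flow.n > max_nodes:
        raise ValueError(f"brute force limited to {max_nodes} nodes")
    best_labels, best_L = None, np.inf
    for labels in _set_partitions(flow.n):
        L = codelength(flow, labels, t)
        if L < best_L - 1e-15:
            best_labels, best_L = labels, L
    labels = _relabel(best_labels + 1)
    return Partition(nodes=flow.nodes.copy(), labels=labels, codelength=best_L)
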