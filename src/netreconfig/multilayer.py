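"""Multilayer modularity and time-resolved reconfiguration metrics.

An ordinal multilayer network couples each node to itself in the temporally
adjacent layers.  The quality of a joint community partition g (an L x N
label array) is the multilayer modularity

    Q = (1/2mu) * sum_{ijsr} [ (A_ij^s - gamma * k_i^s k_j^s / (2 m_s)) d_sr
                               + omega * d_ij * [|s - r| = 1] ] * d(g_is, g_jr)

with per-layer Newman-Girvan null terms (layer strengths k^s, total weight
2 m_s), intra-layer resolution gamma, ordinal inter-layer coupling omega,
and normalization 2mu = sum_s 2 m_s + 2 * omega * N * (L - 1).

Optimization uses a generalized Louvain scheme: a randomized greedy
node-move phase over the supra-modularity structure, then aggregation of
communities into super-nodes, iterated until no move improves Q.  Because
the optimizer is stochastic, analyses run it repeatedly and keep the run
with the highest Q.

From the optimal partition, two node metrics summarize reconfiguration:

* flexibility  — the fraction of adjacent-layer transitions in which the
  node changes community;
* promiscuity  — the fraction of all communities in the partition that the
  node joins at least once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tvfc import ConnectivityStack, NodeMetricVector

#: cap applied before atanh so perfect correlations stay finite
_Z_CAP_R = 1.0 - 1e-7
#: minimum modularity gain for a Louvain move to be accepted (prevents cycling)
_MIN_GAIN = 1e-10


@dataclass
class MultilayerNetwork:
    """L nonnegative symmetric N x N layers with coupling parameters."""

    layers: np.ndarray  # L x N x N, zero diagonal
    gamma: float = 1.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3 or self.layers.shape[1] != self.layers.shape[2]:
            raise ValueError("layers must be L x N x N")
        if (self.layers < 0).any():
            raise ValueError("layer weights must be nonnegative")
        if self.gamma <= 0 or self.omega < 0:
            raise ValueError("gamma must be > 0 and omega >= 0")

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]


@dataclass
class MultilayerPartition:
    """An L x N community labeling with its modularity value."""

    labels: np.ndarray
    q_value: float
    n_runs: int = 1
    best_run_index: int = 0
    seed: int = 0


def prepare_layers(stack: ConnectivityStack) -> MultilayerNetwork:
    """Convert raw windowed correlations into modularity-ready layers.

    Negative correlations are set to zero, the remainder Fisher
    z-transformed (atanh), and the diagonal zeroed.  Off-diagonal r = 1 is
    capped just below 1 so z stays finite.
    """
    if stack.transform_state != "raw_r":
        raise ValueError("prepare_layers expects raw correlations")
    layers = np.clip(stack.layers, 0.0, _Z_CAP_R)
    layers = np.arctanh(layers)
    idx = np.arange(stack.n_nodes)
    layers[:, idx, idx] = 0.0
    return MultilayerNetwork(layers=layers)


# ---------------------------------------------------------------------------
# Modularity value
# ---------------------------------------------------------------------------

def _layer_nulls(net: MultilayerNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-layer strengths k (L x N) and total weights 2m (L,)."""
    k = net.layers.sum(axis=2)
    two_m = k.sum(axis=1)
    return k, two_m


def coupling_mass(net: MultilayerNetwork) -> float:
    """2 * omega * N * (L - 1): total ordinal-coupling weight (both directions)."""
    return 2.0 * net.omega * net.n_nodes * (net.n_layers - 1)


def modularity_value(net: MultilayerNetwork, labels: np.ndarray) -> float:
    """Multilayer modularity Q of a given L x N partition."""
    labels = np.asarray(labels)
    if labels.shape != (net.n_layers, net.n_nodes):
        raise ValueError(
            f"labels must be shaped {(net.n_layers, net.n_nodes)}, got {labels.shape}"
        )
    k, two_m = _layer_nulls(net)
    total = 0.0
    for s in range(net.n_layers):
        same = labels[s][:, None] == labels[s][None, :]
        total += net.layers[s][same].sum()
        if two_m[s] > 0:
            null = np.outer(k[s], k[s])[same].sum() / two_m[s]
            total -= net.gamma * null
    # ordinal coupling: node i, layers s and s+1 (counted in both directions)
    for s in range(net.n_layers - 1):
        total += 2.0 * net.omega * (labels[s] == labels[s + 1]).sum()
    two_mu = two_m.sum() + coupling_mass(net)
    if two_mu <= 0:
        return 0.0
    return float(total / two_mu)


# ---------------------------------------------------------------------------
# Generalized Louvain
# ---------------------------------------------------------------------------

def _modularity_blocks(net: MultilayerNetwork) -> np.ndarray:
    """Dense per-layer modularity blocks B_s = A_s - gamma * k k^T / 2m_s."""
    k, two_m = _layer_nulls(net)
    blocks = net.layers.copy()
    for s in range(net.n_layers):
        if two_m[s] > 0:
            blocks[s] -= net.gamma * np.outer(k[s], k[s]) / two_m[s]
    return blocks


def _phase_one_layered(
    blocks: np.ndarray, omega: float, labels: np.ndarray, rng: np.random.Generator
) -> bool:
    """Greedy node moves on the layered supra-modularity structure.

    ``labels`` is L x N (modified in place).  Returns True if any move was
    accepted.  A node's gain for joining community c is the sum of its
    modularity-block row over c's members in its own layer (excluding
    itself), plus omega for each temporally adjacent copy of itself already
    in c; candidates are the communities present in the node's own layer and
    those of its temporal copies.
    """
    L, N = labels.shape
    improved_any = False
    while True:
        improved = False
        for s in rng.permutation(L):
            B = blocks[s]
            lab_s = labels[s]
            # candidate communities: those present in this layer plus the
            # temporal copies' communities in the adjacent layers
            pool = [lab_s]
            if s > 0:
                pool.append(labels[s - 1])
            if s < L - 1:
                pool.append(labels[s + 1])
            cand = np.unique(np.concatenate(pool))
            pos = {int(c): k for k, c in enumerate(cand)}
            member = np.zeros((N, cand.size))
            member[np.arange(N), [pos[int(c)] for c in lab_s]] = 1.0
            S = B @ member  # S[i, c] = sum of B[i, j] over layer-s members of c
            for i in rng.permutation(N):
                gains = S[i].copy()
                cur = pos[int(lab_s[i])]
                gains[cur] -= B[i, i]  # a node carries its self-weight along
                if omega > 0:
                    if s > 0:
                        gains[pos[int(labels[s - 1, i])]] += omega
                    if s < L - 1:
                        gains[pos[int(labels[s + 1, i])]] += omega
                best = int(np.argmax(gains))
                if gains[best] - gains[cur] > _MIN_GAIN:
                    lab_s[i] = cand[best]
                    S[:, cur] -= B[:, i]
                    S[:, best] += B[:, i]
                    improved = True
        if not improved:
            break
        improved_any = True
    return improved_any


def _aggregate(
    blocks: np.ndarray, omega: float, labels: np.ndarray, n_comm: int
) -> np.ndarray:
    """Collapse communities into super-nodes: dense C x C quality matrix.

    Entry [c, d] is the summed supra-modularity weight between communities c
    and d, including intra-layer block weight and ordinal coupling; the
    diagonal holds internal weight (self-loops).
    """
    L, N = labels.shape
    M = np.zeros((n_comm, n_comm))
    for s in range(L):
        lab = labels[s]
        # accumulate block into community x community
        for c in range(n_comm):
            members = lab == c
            if members.any():
                M[c] += np.bincount(lab, weights=blocks[s][members].sum(axis=0), minlength=n_comm)
    for s in range(L - 1):
        np.add.at(M, (labels[s], labels[s + 1]), omega)
        np.add.at(M, (labels[s + 1], labels[s]), omega)
    return M


def _phase_one_generic(M: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy node moves on an aggregated (dense, symmetric) quality matrix."""
    C = M.shape[0]
    labels = np.arange(C)
    while True:
        improved = False
        for u in rng.permutation(C):
            gains = np.bincount(labels, weights=M[u], minlength=C)
            current = labels[u]
            gains[current] -= M[u, u]  # self-loop moves with u
            best = int(np.argmax(gains))
            if gains[best] - gains[current] > _MIN_GAIN:
                labels[u] = best
                improved = True
        if not improved:
            return labels


def _compact(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Renumber labels to 0..C-1 preserving first-appearance order."""
    flat = labels.ravel()
    uniq, inv = np.unique(flat, return_inverse=True)
    order = np.full(uniq.size, -1, dtype=int)
    seen = 0
    for v in inv:
        if order[v] < 0:
            order[v] = seen
            seen += 1
    return order[inv].reshape(labels.shape), seen


def louvain_optimize(net: MultilayerNetwork, seed: int = 0) -> MultilayerPartition:
    """One stochastic generalized-Louvain run to a local optimum of Q.

    Starts from the all-singletons partition, alternates a randomized greedy
    node-move phase with community aggregation, and stops when no move
    improves Q.  Every accepted move strictly increases Q; on a flat
    landscape the initial singleton partition is returned.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L, N = net.n_layers, net.n_nodes
    blocks = _modularity_blocks(net)

    labels = np.arange(L * N).reshape(L, N)
    moved = _phase_one_layered(blocks, net.omega, labels, rng)
    labels, n_comm = _compact(labels)

    # aggregation passes on the collapsed super-node graph
    while moved and n_comm < L * N:
        M = _aggregate(blocks, net.omega, labels, n_comm)
        merged = _phase_one_generic(M, rng)
        merged_compact, n_new = _compact(merged.reshape(1, -1))
        if n_new == n_comm:
            break
        labels = merged_compact.ravel()[labels]
        n_comm = n_new

    labels, _ = _compact(labels)
    q = modularity_value(net, labels)
    return MultilayerPartition(
        labels=labels, q_value=q, n_runs=1, seed=seed if isinstance(seed, int) else 0
    )


def best_of_runs(net: MultilayerNetwork, n_runs: int = 100, seed: int = 0) -> MultilayerPartition:
    """Run the stochastic optimizer ``n_runs`` times, keep the highest Q.

    Run seeds are derived deterministically from ``seed``; ties in Q are
    broken by the lowest run index.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_runs)
    best: MultilayerPartition | None = None
    best_idx = 0
    for r, child in enumerate(children):
        part = louvain_optimize(net, np.random.default_rng(child))
        if best is None or part.q_value > best.q_value + 1e-15:
            best, best_idx = part, r
    assert best is not None
    best.n_runs = n_runs
    best.best_run_index = best_idx
    best.seed = seed
    return best


# ---------------------------------------------------------------------------
# Reconfiguration metrics
# ---------------------------------------------------------------------------

def flexibility(partition: MultilayerPartition) -> NodeMetricVector:
    """Fraction of adjacent-layer transitions where a node changes community."""
    labels = np.asarray(partition.labels)
    if labels.shape[0] < 2:
        raise ValueError("flexibility needs at least 2 layers")
    changes = (labels[1:] != labels[:-1]).sum(axis=0)
    return NodeMetricVector("flexibility", changes / (labels.shape[0] - 1))


def promiscuity(partition: MultilayerPartition) -> NodeMetricVector:
    """Fraction of all communities a node joins at least once across layers."""
    labels = np.asarray(partition.labels)
    n_total = len(np.unique(labels))
    if n_total < 1:
        raise ValueError("partition has no communities")
    values = np.array([len(np.unique(labels[:, i])) for i in range(labels.shape[1])])
    return NodeMetricVector("promiscuity", values / n_total)
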