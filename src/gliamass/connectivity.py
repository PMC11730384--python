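"""Multiplex functional connectivity of simulated network dynamics.

Four functional layers are estimated from each simulation batch: phase
locking values of alpha-band LFP (LFP-PLV), absolute Pearson correlations
of the low-passed alpha-band LFP amplitude envelopes (LFP-AEC), and
absolute Pearson correlations of the low-passed extracellular glutamate
and GABA dynamics (Glu_e-C, GABA_e-C).  The layers form a node-aligned
multiplex network with identity interlayer coupling, analyzed through
supra-network topology metrics (clustering coefficient, path length, edge
overlap, eigenvector versatility), two-level map-equation communities and
code length, and Von-Neumann-entropy-based structural reducibility with
the quantum Jensen-Shannon divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal
import scipy.sparse
import scipy.sparse.csgraph
from numpy.typing import NDArray

from .activity import hilbert_envelope
from .filters import ALPHA_BAND, SLOW_CUTOFF, bandpass_alpha, lowpass_slow
from .simulate import SimulationResult

__all__ = [
    "FunctionalLayer",
    "MultiplexNetwork",
    "TopologySummary",
    "bandpass_alpha",
    "lowpass_slow",
    "plv",
    "aec",
    "plv_layer",
    "aec_layer",
    "correlation_layer",
    "threshold_top_fraction",
    "fisher_mean",
    "build_multiplex",
    "eigenvector_versatility",
    "multilayer_clustering_coefficient",
    "multilayer_path_length",
    "edge_overlap",
    "map_equation_communities",
    "map_equation_code_length",
    "von_neumann_entropy",
    "qjsd",
    "structural_reducibility",
    "summarize_topology",
]

EDGE_TRIM_S = 1.0             # s discarded per end after zero-phase filtering
LAYER_NAMES = ("LFP_PLV", "LFP_AEC", "GLUE_C", "GABAE_C")


def _trim_edges(x, n: int):
    return x[n:-n] if 0 < 2 * n < x.shape[0] else x


# ----------------------------------------------------------------------
# bivariate measures
# ----------------------------------------------------------------------

def plv(x_i: NDArray, x_j: NDArray) -> float:
    """Phase locking value of two band-limited series, in [0, 1]."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError("series length mismatch")
    phi_i = np.angle(scipy.signal.hilbert(x_i - x_i.mean()))
    phi_j = np.angle(scipy.signal.hilbert(x_j - x_j.mean()))
    return float(np.abs(np.mean(np.exp(1j * (phi_i - phi_j)))))


def aec(x_i: NDArray, x_j: NDArray, fs: float | None = None) -> float:
    """Absolute Pearson correlation of the two low-passed amplitude
    envelopes of band-limited series, in [0, 1]."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError("series length mismatch")
    env = hilbert_envelope(np.column_stack([x_i, x_j]))
    if fs is not None:
        env = lowpass_slow(env, fs)
        env = _trim_edges(env, int(round(EDGE_TRIM_S * fs)))
    if env.std(axis=0).min() == 0:
        raise ValueError("constant envelope: correlation undefined")
    return float(abs(np.corrcoef(env[:, 0], env[:, 1])[0, 1]))


def _phases(x: NDArray) -> NDArray:
    return np.angle(scipy.signal.hilbert(x - x.mean(axis=0), axis=0))


def plv_layer(x: NDArray, fs: float, trim_s: float = EDGE_TRIM_S) -> NDArray:
    """All-pairs PLV matrix of (T, N) band-limited series."""
    phi = _trim_edges(_phases(np.asarray(x, dtype=float)),
                      int(round(trim_s * fs)))
    z = np.exp(1j * phi)
    # PLV_ij = |<z_i conj(z_j)>| computed as a Gram matrix.
    G = np.abs(z.conj().T @ z) / phi.shape[0]
    np.fill_diagonal(G, 0.0)
    return 0.5 * (G + G.T)


def aec_layer(x: NDArray, fs: float, trim_s: float = EDGE_TRIM_S) -> NDArray:
    """All-pairs absolute envelope-correlation matrix of (T, N) series."""
    env = lowpass_slow(hilbert_envelope(np.asarray(x, dtype=float)), fs)
    return _abs_corr(_trim_edges(env, int(round(trim_s * fs))))


def _abs_corr(x: NDArray) -> NDArray:
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"constant series for region(s) {dead.tolist()}")
    C = np.abs(np.corrcoef(x.T))
    np.fill_diagonal(C, 0.0)
    return 0.5 * (C + C.T)


def correlation_layer(series_matrix: NDArray, fs: float | None = None,
                      lowpass: bool = True, trim_s: float = EDGE_TRIM_S) -> NDArray:
    """Absolute Pearson-correlation matrix of (T, N) slow dynamics.

    With ``fs`` given and ``lowpass`` enabled, the series are low-passed at
    0.5 Hz (zero phase) and edge-trimmed first.
    """
    x = np.asarray(series_matrix, dtype=float)
    if fs is not None and lowpass:
        x = _trim_edges(lowpass_slow(x, fs), int(round(trim_s * fs)))
    return _abs_corr(x)


def threshold_top_fraction(W: NDArray, f: float = 0.25) -> NDArray:
    """Keep the ceil(f * N(N-1)/2) strongest undirected edges.

    Retained edges keep their weights; ties are broken deterministically by
    (i, j) lexicographic order of the upper-triangle entries.
    """
    if not 0 < f <= 1:
        raise ValueError("threshold fraction must be in (0, 1]")
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("layer must be symmetric")
    iu, ju = np.triu_indices(n, k=1)
    weights = W[iu, ju]
    keep = int(np.ceil(f * len(weights)))
    # Stable sort on -weight preserves (i, j) lexicographic order for ties.
    order = np.argsort(-weights, kind="stable")[:keep]
    out = np.zeros_like(W)
    out[iu[order], ju[order]] = weights[order]
    return out + out.T


def fisher_mean(r_values) -> float:
    """Back-transformed arithmetic mean of Fisher's z-transformed
    correlation coefficients: tanh(mean(atanh(r)))."""
    r = np.asarray(r_values, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher transform undefined at |r| = 1")
    return float(np.tanh(np.mean(np.arctanh(r))))


# ----------------------------------------------------------------------
# multiplex containers
# ----------------------------------------------------------------------

@dataclass
class FunctionalLayer:
    """One thresholded functional connectivity layer."""

    name: str
    weights: NDArray
    threshold_fraction: float | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        n = W.shape[0]
        if W.shape != (n, n):
            raise ValueError("layer weights must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError(f"layer {self.name}: weights not symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError(f"layer {self.name}: nonzero diagonal")
        if W.min() < 0 or W.max() > 1 + 1e-12:
            raise ValueError(f"layer {self.name}: weights outside [0, 1]")
        self.weights = 0.5 * (W + W.T)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))


@dataclass
class MultiplexNetwork:
    """Node-aligned functional layers with identity interlayer coupling.

    The supra-adjacency stacks the intra-layer matrices on the block
    diagonal and links each node to its own replica in every other layer
    with weight 1.
    """

    layers: list[FunctionalLayer]
    labels: list[str] = field(default_factory=list)
    interlayer_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("need at least one layer")
        n = self.layers[0].n_nodes
        if any(l.n_nodes != n for l in self.layers):
            raise ValueError("all layers must share the node set")
        if not self.labels:
            self.labels = [f"node{i:03d}" for i in range(n)]

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def supra_adjacency(self) -> NDArray:
        """(N*L) x (N*L) supra-adjacency; replica index = layer*N + node."""
        N, L = self.n_nodes, self.n_layers
        S = np.zeros((N * L, N * L))
        eye = self.interlayer_weight * np.eye(N)
        for a in range(L):
            S[a * N:(a + 1) * N, a * N:(a + 1) * N] = self.layers[a].weights
            for b in range(L):
                if a != b:
                    S[a * N:(a + 1) * N, b * N:(b + 1) * N] = eye
        return S


def build_multiplex(result: SimulationResult,
                    threshold_fraction: float = 0.25) -> MultiplexNetwork:
    """Estimate the four functional layers of one simulation batch.

    LFP series are alpha-band filtered before the PLV and envelope
    computations; envelope and concentration series are low-passed at
    0.5 Hz; every layer is thresholded independently to its top 25%
    strongest connections.
    """
    fs = result.fs
    x_alpha = bandpass_alpha(result.lfp, fs)
    raw = {
        "LFP_PLV": plv_layer(x_alpha, fs),
        "LFP_AEC": aec_layer(x_alpha, fs),
        "GLUE_C": correlation_layer(result.field("Glu_e"), fs),
        "GABAE_C": correlation_layer(result.field("GABA_e"), fs),
    }
    layers = [
        FunctionalLayer(name=k, weights=threshold_top_fraction(v, threshold_fraction),
                        threshold_fraction=threshold_fraction)
        for k, v in raw.items()
    ]
    return MultiplexNetwork(layers=layers)


# ----------------------------------------------------------------------
# supra-network topology
# ----------------------------------------------------------------------

def eigenvector_versatility(m: MultiplexNetwork) -> NDArray:
    """Multilayer eigenvector centrality, max-normalized to [0, 1].

    Leading eigenvector of the supra-adjacency (non-negative by
    Perron-Frobenius on the largest connected component); a physical
    node's score is the sum over its layer replicas.
    """
    S = m.supra_adjacency()
    NL = S.shape[0]
    n_comp, comp = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(S), directed=False)
    if n_comp > 1:
        warnings.warn("disconnected supra-network: scoring largest component only")
        sizes = np.bincount(comp)
        keep = comp == np.argmax(sizes)
    else:
        keep = np.ones(NL, dtype=bool)
    sub = S[np.ix_(keep, keep)]
    vals, vecs = np.linalg.eigh(sub)
    lead = vecs[:, -1]
    lead = np.abs(lead)  # Perron vector sign fix
    full = np.zeros(NL)
    full[keep] = lead
    N, L = m.n_nodes, m.n_layers
    node_score = full.reshape(L, N).sum(axis=0)
    if node_score.max() == 0:
        return node_score
    return node_score / node_score.max()


def multilayer_clustering_coefficient(m: MultiplexNetwork) -> float:
    """Mean local weighted clustering over supra-nodes.

    Triads are formed by intra-layer edges (interlayer identity links
    connect only node replicas and create no triangles in the multiplex
    block structure, so they are excluded).  Per supra-node, the
    geometric-mean weight of closed triads is summed and divided by the
    open-triad count k(k-1); weights in [0, 1] keep the coefficient in
    [0, 1].
    """
    N, L = m.n_nodes, m.n_layers
    S = np.zeros((N * L, N * L))
    for a in range(L):
        S[a * N:(a + 1) * N, a * N:(a + 1) * N] = m.layers[a].weights
    NL = S.shape[0]
    W3 = np.cbrt(S)
    num = np.diag(W3 @ W3 @ W3)  # 2 x sum of geometric-mean triangle weights
    deg = (S > 0).sum(axis=1)
    denom = deg * (deg - 1)
    cc = np.zeros(NL)
    mask = denom > 0
    cc[mask] = num[mask] / denom[mask]
    if not mask.any():
        return 0.0
    return float(cc.mean())


def multilayer_path_length(m: MultiplexNetwork) -> tuple[float, int]:
    """Mean shortest-path distance over connected supra-node pairs.

    Edge lengths are 1/weight for intra-layer edges and 1 for interlayer
    (identity) edges.  Returns (mean distance, number of disconnected
    ordered pairs excluded).
    """
    S = m.supra_adjacency()
    N, L = m.n_nodes, m.n_layers
    lengths = np.zeros_like(S)
    nz = S > 0
    lengths[nz] = 1.0 / S[nz]
    # Interlayer identity edges have length exactly 1.
    for a in range(L):
        for b in range(L):
            if a != b:
                idx = np.arange(N)
                lengths[a * N + idx, b * N + idx] = 1.0
    D = scipy.sparse.csgraph.shortest_path(
        scipy.sparse.csr_matrix(lengths), method="D", directed=False)
    iu = np.triu_indices(S.shape[0], k=1)
    d = D[iu]
    finite = np.isfinite(d)
    if not finite.any():
        raise ValueError("supra-network fully disconnected")
    return float(d[finite].mean()), int((~finite).sum())


def edge_overlap(m: MultiplexNetwork) -> float:
    """Mean fraction of layers sharing each present edge, in [1/L, 1]."""
    L = m.n_layers
    presence = np.stack([l.weights > 0 for l in m.layers]).sum(axis=0)
    iu = np.triu_indices(m.n_nodes, k=1)
    counts = presence[iu]
    present = counts > 0
    if not present.any():
        raise ValueError("no edges in any layer")
    return float((counts[present] / L).mean())


# ----------------------------------------------------------------------
# map equation
# ----------------------------------------------------------------------

def _plogp(x: NDArray) -> NDArray:
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out


def map_equation_code_length(S: NDArray, modules: NDArray) -> float:
    """Two-level map-equation description length (bits) of a partition.

    For an undirected weighted walk, visit rates are proportional to
    supra-node strength; module exit rates are the weight fractions of
    edges leaving each module.  A single-module partition has code length
    equal to the entropy of the visit-rate distribution.
    """
    S = np.asarray(S, dtype=float)
    strength = S.sum(axis=1)
    total = strength.sum()
    if total == 0:
        raise ValueError("empty network")
    p = strength / total
    labels = np.unique(modules)
    q = np.zeros(len(labels))
    p_mod = np.zeros(len(labels))
    for k, lab in enumerate(labels):
        inside = modules == lab
        # weight of edges leaving the module, as a fraction of total weight
        q[k] = S[np.ix_(inside, ~inside)].sum() / total
        p_mod[k] = p[inside].sum()
    q_tot = q.sum()
    # index codebook
    L_index = 0.0
    if q_tot > 0:
        L_index = q_tot * (-np.sum(_plogp(q / q_tot)))
    # module codebooks
    L_mod = 0.0
    for k, lab in enumerate(labels):
        inside = modules == lab
        denom = q[k] + p_mod[k]
        if denom == 0:
            continue
        probs = np.concatenate([[q[k]], p[inside]]) / denom
        L_mod += denom * (-np.sum(_plogp(probs)))
    return float(L_index + L_mod)


def map_equation_communities(m: MultiplexNetwork | NDArray,
                             seed: int = 0) -> tuple[NDArray, float]:
    """Two-level map-equation communities of the supra-network.

    Greedy Louvain-style optimization with deterministic tie-breaks: nodes
    are repeatedly moved to the neighboring module that most reduces the
    description length; converged passes aggregate modules and repeat until
    no improvement.  For a multiplex input, physical-node communities are
    obtained by majority vote over layer replicas (ties to the smaller
    community id).  Returns (community labels per physical node or supra
    node, code length in bits).
    """
    if isinstance(m, MultiplexNetwork):
        S = m.supra_adjacency()
        N, L = m.n_nodes, m.n_layers
    else:
        S = np.asarray(m, dtype=float)
        N, L = S.shape[0], 1
    n_comp, comp = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(S), directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        keep = np.flatnonzero(comp == np.argmax(sizes))
        sub = S[np.ix_(keep, keep)]
        sub_labels, code = _infomap_greedy(sub)
        labels = np.full(S.shape[0], -1)
        labels[keep] = sub_labels
        # isolated replicas: own singleton communities
        nxt = labels.max() + 1
        for i in np.flatnonzero(labels < 0):
            labels[i] = nxt
            nxt += 1
    else:
        labels, code = _infomap_greedy(S)
    if L > 1:
        reps = labels.reshape(L, N)
        node_labels = np.empty(N, dtype=int)
        for i in range(N):
            vals, counts = np.unique(reps[:, i], return_counts=True)
            node_labels[i] = vals[np.argmax(counts)]  # ties -> smaller id
        labels = _relabel(node_labels)
    else:
        labels = _relabel(labels)
    return labels, code


def _relabel(labels: NDArray) -> NDArray:
    _, inv = np.unique(labels, return_inverse=True)
    return inv


def _infomap_greedy(S: NDArray) -> tuple[NDArray, float]:
    """Greedy two-level minimization of the map equation.

    Node-move sweeps from a singleton start, interleaved with exhaustive
    pairwise module merges while either improves the description length;
    finally compared against the single-module partition.  Intended for
    desk-scale supra-networks (hundreds of supra-nodes).
    """
    n = S.shape[0]
    labels = np.arange(n)
    labels, _ = _move_pass(S, labels)
    improved = True
    while improved:
        improved = False
        code = map_equation_code_length(S, labels)
        uniq = np.unique(labels)
        best_val, best_pair = code, None
        for ai in range(len(uniq)):
            for aj in range(ai + 1, len(uniq)):
                trial = labels.copy()
                trial[trial == uniq[aj]] = uniq[ai]
                val = map_equation_code_length(S, trial)
                if val < best_val - 1e-12:
                    best_val, best_pair = val, (uniq[ai], uniq[aj])
        if best_pair is not None:
            labels[labels == best_pair[1]] = best_pair[0]
            labels, _ = _move_pass(S, labels)
            improved = True
    best_code = map_equation_code_length(S, labels)
    one = np.zeros(n, dtype=int)
    one_code = map_equation_code_length(S, one)
    if one_code < best_code - 1e-12:
        return one, one_code
    return _relabel(labels), best_code


def _move_pass(S: NDArray, labels: NDArray) -> tuple[NDArray, bool]:
    """Sweep nodes in index order, moving each to the best neighbor module."""
    n = S.shape[0]
    moved_any = False
    for _ in range(20):  # bounded repeat until stable
        moved = False
        for i in range(n):
            neigh = np.flatnonzero(S[i] > 0)
            candidates = sorted(set(labels[neigh]) - {labels[i]})
            if not candidates:
                continue
            base = map_equation_code_length(S, labels)
            best_lab, best_val = labels[i], base
            for lab in candidates:
                trial = labels.copy()
                trial[i] = lab
                val = map_equation_code_length(S, trial)
                if val < best_val - 1e-12:
                    best_val, best_lab = val, lab
            if best_lab != labels[i]:
                labels[i] = best_lab
                moved = moved_any = True
        if not moved:
            break
    return labels, moved_any


# ----------------------------------------------------------------------
# Von Neumann entropy, QJSD, reducibility
# ----------------------------------------------------------------------

def _density_matrix(W: NDArray) -> NDArray:
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("layer must be symmetric")
    Lap = np.diag(W.sum(axis=1)) - W
    tr = np.trace(Lap)
    if tr == 0:
        raise ValueError("empty layer (no edges)")
    return Lap / tr


def von_neumann_entropy(W: NDArray) -> float:
    """Von Neumann entropy (bits) of the trace-normalized graph Laplacian."""
    lam = np.linalg.eigvalsh(_density_matrix(W))
    lam = np.clip(lam, 0.0, None)
    return float(-np.sum(_plogp(lam)))


def _entropy_of_density(rho: NDArray) -> float:
    lam = np.clip(np.linalg.eigvalsh(rho), 0.0, None)
    return float(-np.sum(_plogp(lam)))


def qjsd(W_a: NDArray, W_b: NDArray) -> float:
    """Quantum Jensen-Shannon distance between two layers, in [0, 1].

    Square root of the divergence between the layer density matrices
    (log base 2); zero iff the density matrices coincide.
    """
    rho_a = _density_matrix(W_a)
    rho_b = _density_matrix(W_b)
    mix = 0.5 * (rho_a + rho_b)
    js = _entropy_of_density(mix) - 0.5 * (_entropy_of_density(rho_a)
                                           + _entropy_of_density(rho_b))
    return float(np.sqrt(max(js, 0.0)))


@dataclass
class ReducibilityResult:
    merge_sequence: list[tuple[int, int]]   # merged cluster indices per step
    quality_curve: list[float]              # quality after 0, 1, ... merges
    best_n_merges: int
    reduced_layers: list[NDArray]
    reduced_members: list[list[int]]        # original layer indices per group


def structural_reducibility(m: MultiplexNetwork | list[NDArray]) -> ReducibilityResult:
    """Greedy layer aggregation guided by QJSD with average linkage.

    Walks the QJSD dendrogram; after each merge (arithmetic mean of member
    layers) the quality q = (h_agg - mean layer entropy)/h_agg is
    evaluated, where h_agg is the entropy of the arithmetic-mean aggregate
    of all layers.  The configuration maximizing q is returned, preferring
    fewer merges on ties.
    """
    if isinstance(m, MultiplexNetwork):
        layer_mats = [l.weights for l in m.layers]
    else:
        layer_mats = [np.asarray(W, dtype=float) for W in m]
    L = len(layer_mats)
    if L < 2:
        raise ValueError("need at least two layers")
    aggregate = np.mean(layer_mats, axis=0)
    h_agg = von_neumann_entropy(aggregate)

    def quality(groups: list[list[int]]) -> float:
        ents = [von_neumann_entropy(np.mean([layer_mats[i] for i in g], axis=0))
                for g in groups]
        return (h_agg - float(np.mean(ents))) / h_agg if h_agg > 0 else 0.0

    groups: list[list[int]] = [[i] for i in range(L)]
    qualities = [quality(groups)]
    merges: list[tuple[int, int]] = []
    configs = [list(map(list, groups))]
    # average-linkage distances on the original QJSD matrix
    D = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            D[i, j] = D[j, i] = qjsd(layer_mats[i], layer_mats[j])
    active = list(range(L))
    members: dict[int, list[int]] = {i: [i] for i in range(L)}
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                gi, gj = active[ai], active[aj]
                d = np.mean([D[x, y] for x in members[gi] for y in members[gj]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, gi, gj)
        _, gi, gj = best
        merges.append((gi, gj))
        members[gi] = members[gi] + members[gj]
        active.remove(gj)
        groups = [members[g] for g in active]
        qualities.append(quality(groups))
        configs.append(list(map(list, groups)))
    # Maximal quality; exact ties resolve toward more merges, so fully
    # redundant (identical) layers collapse to a single layer.
    qmax = max(qualities)
    best_idx = max(k for k, v in enumerate(qualities) if v >= qmax - 1e-12)
    chosen = configs[best_idx]
    reduced = [np.mean([layer_mats[i] for i in g], axis=0) for g in chosen]
    return ReducibilityResult(
        merge_sequence=merges, quality_curve=qualities,
        best_n_merges=best_idx, reduced_layers=reduced,
        reduced_members=chosen)


@dataclass
class TopologySummary:
    clustering_coefficient: float
    path_length: float
    disconnected_pairs: int
    edge_overlap: float
    code_length: float
    versatility: NDArray
    communities: NDArray


def summarize_topology(m: MultiplexNetwork, seed: int = 0) -> TopologySummary:
    """Global and nodal topology metrics of one multiplex network."""
    pl, excl = multilayer_path_length(m)
    communities, code = map_equation_communities(m, seed=seed)
    return TopologySummary(
        clustering_coefficient=multilayer_clustering_coefficient(m),
        path_length=pl,
        disconnected_pairs=excl,
        edge_overlap=edge_overlap(m),
        code_length=code,
        versatility=eigenvector_versatility(m),
        communities=communities,
    )
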