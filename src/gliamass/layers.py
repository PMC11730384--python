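"""Structural connectivity layers and network feedback terms.

Two weighted layers couple the nodes: a neuronal layer (white-matter
tracts between pyramidal populations) and an astrocytic layer (gap-junction
syncytium restricted to adjacent regions, weighted by reciprocal distance).
Both are row-normalized with zero diagonal before simulation so that every
node receives a convex combination of its neighbors' activity.

Empirical matrices (e.g. tractography-derived connectomes) are loaded from
CSV/TSV or MatrixMarket files; surrogate generators emulate their
topological character for desk-scale experiments: a modular, hub-heavy
small-world matrix for the neuronal layer and a first-neighbor lattice for
the astrocytic layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse
from numpy.typing import NDArray

from .model import sigmoid
from .params import ModelParameters

__all__ = [
    "StructuralLayers",
    "normalize_layer",
    "surrogate_neuronal_layer",
    "surrogate_astrocytic_layer",
    "load_layer",
    "save_layer",
    "neuronal_feedback",
    "astrocytic_feedback",
    "surrogate_layers",
]

_ROW_SUM_TOL = 1e-12


@dataclass
class StructuralLayers:
    """Pair of row-stochastic structural matrices plus node metadata."""

    Omega_Pyr: NDArray
    Omega_Ast: NDArray
    labels: list[str] = field(default_factory=list)
    coords: NDArray | None = None

    def __post_init__(self) -> None:
        self.Omega_Pyr = np.asarray(self.Omega_Pyr, dtype=float)
        self.Omega_Ast = np.asarray(self.Omega_Ast, dtype=float)
        n = self.Omega_Pyr.shape[0]
        if self.Omega_Pyr.shape != (n, n) or self.Omega_Ast.shape != (n, n):
            raise ValueError("layer matrices must be square and equally sized")
        if not self.labels:
            self.labels = [f"node{i:03d}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("label count does not match node count")
        for name, W in (("Omega_Pyr", self.Omega_Pyr), ("Omega_Ast", self.Omega_Ast)):
            if np.any(np.diag(W) != 0):
                raise ValueError(f"{name} has nonzero diagonal entries")
            rs = W.sum(axis=1)
            if np.max(np.abs(rs - 1.0)) > _ROW_SUM_TOL:
                raise ValueError(f"{name} rows do not sum to 1 (normalize first)")

    @property
    def n_nodes(self) -> int:
        return self.Omega_Pyr.shape[0]

    def checksum(self) -> str:
        import hashlib
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.Omega_Pyr).tobytes())
        h.update(np.ascontiguousarray(self.Omega_Ast).tobytes())
        return h.hexdigest()[:16]


def normalize_layer(W: NDArray) -> NDArray:
    """Zero the diagonal and normalize each row to unit sum.

    Relative weights within a row are preserved.  A row with no
    off-diagonal mass is an isolated region and is rejected by name.
    """
    W = np.array(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"layer must be square, got shape {W.shape}")
    if np.any(W < 0):
        raise ValueError("layer weights must be non-negative")
    np.fill_diagonal(W, 0.0)
    row_sums = W.sum(axis=1)
    dead = np.flatnonzero(row_sums == 0)
    if dead.size:
        raise ValueError(
            f"node(s) {dead.tolist()} have no off-diagonal mass; "
            "an isolated region cannot receive input"
        )
    return W / row_sums[:, None]


def surrogate_neuronal_layer(N: int, n_communities: int = 4, p_in: float = 0.7,
                             p_out: float = 0.15, hub_fraction: float = 0.125,
                             seed: int = 0, max_retries: int = 20) -> NDArray:
    """Weighted modular surrogate for the neuronal (tractography) layer.

    Plants ``n_communities`` communities with dense/heavy intra-community
    connections, sparse/light inter-community connections, and boosts the
    connection weights of a designated hub community (an analogue of the
    strongly connected precuneus regions of empirical connectomes).
    Returns an unnormalized, connected, zero-diagonal weight matrix;
    deterministic given ``seed``.
    """
    if N < 4:
        raise ValueError("need at least 4 nodes")
    if not p_in > p_out:
        raise ValueError("community contrast requires p_in > p_out")
    rng = np.random.default_rng(seed)
    membership = np.arange(N) % n_communities
    n_hubs = int(round(hub_fraction * N))
    w_boost = p_in / p_out  # intra-community edges denser AND heavier
    for _ in range(max_retries):
        same = membership[:, None] == membership[None, :]
        prob = np.where(same, p_in, p_out)
        upper = np.triu(rng.random((N, N)) < prob, k=1)
        # Log-normal weights give the heavy-tailed strength distribution of
        # tractography connectomes; intra-community edges are heavier.
        w = rng.lognormal(mean=0.0, sigma=0.5, size=(N, N))
        w = np.where(same, w_boost * w, w)
        W = np.where(upper, w, 0.0)
        W = W + W.T
        # Hub boost: first n_hubs nodes of community 0 (precuneus analogue).
        if n_hubs:
            hubs = np.flatnonzero(membership == 0)[:n_hubs]
            W[hubs, :] *= 2.0
            W[:, hubs] *= 2.0
        np.fill_diagonal(W, 0.0)
        n_comp = scipy.sparse.csgraph.connected_components(
            scipy.sparse.csr_matrix(W), directed=False)[0]
        if n_comp == 1:
            return W
    raise RuntimeError(
        f"could not draw a connected surrogate in {max_retries} attempts "
        f"(N={N}, p_in={p_in}, p_out={p_out})"
    )


def surrogate_astrocytic_layer(coords: NDArray | None = None, N: int | None = None,
                               k_neighbors: int = 2) -> NDArray:
    """First-neighbor lattice surrogate for the astrocytic layer.

    With explicit ``coords`` (N x 3 positions, mm), each node connects to
    its ``k_neighbors`` nearest neighbors with weight = 1/Euclidean
    distance and the adjacency is symmetrized.  Without coordinates, a ring
    of ``N`` unit-spaced nodes stands in for the 1-D cortical mantle:
    each node connects to its two ring neighbors.
    """
    if coords is None:
        if N is None:
            raise ValueError("provide coords or N")
        if N < 3:
            raise ValueError("need at least 3 nodes for a ring")
        angle = 2.0 * np.pi * np.arange(N) / N
        radius = 1.0 / (2.0 * np.sin(np.pi / N))  # unit spacing between neighbors
        coords = np.column_stack([radius * np.cos(angle),
                                  radius * np.sin(angle),
                                  np.zeros(N)])
        k_neighbors = 2
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the node count")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    off = ~np.eye(n, dtype=bool)
    if np.any(dist[off] == 0):
        i, j = np.argwhere((dist == 0) & off)[0]
        raise ValueError(f"duplicate coordinates for nodes {i} and {j}")
    W = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(dist[i])
        neighbors = [j for j in order if j != i][:k_neighbors]
        W[i, neighbors] = 1.0 / dist[i, neighbors]
    W = np.maximum(W, W.T)  # symmetric sparsity pattern
    np.fill_diagonal(W, 0.0)
    return W


def surrogate_layers(N: int, seed: int = 0, n_communities: int = 4,
                     p_in: float = 0.7, p_out: float = 0.15) -> StructuralLayers:
    """Convenience constructor: normalized surrogate neuronal + ring layers."""
    n_communities = max(2, min(n_communities, N // 2))
    pyr = normalize_layer(surrogate_neuronal_layer(
        N, n_communities=n_communities, p_in=p_in, p_out=p_out, seed=seed))
    ast = normalize_layer(surrogate_astrocytic_layer(N=N))
    return StructuralLayers(Omega_Pyr=pyr, Omega_Ast=ast)


def load_layer(path: str | Path, format: str | None = None) -> NDArray:
    """Read a raw square weight matrix from CSV, TSV, or MatrixMarket.

    Returns the matrix as stored; validation and normalization are separate
    explicit steps (:func:`normalize_layer`).
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".mtx": "matrixmarket"}.get(
            path.suffix.lower(), "csv")
    if format == "matrixmarket":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        W = np.asarray(mat, dtype=float)
    elif format in ("csv", "tsv"):
        delim = "," if format == "csv" else "\t"
        # Optional header row of labels: probe the first line.
        with open(path) as fh:
            first = fh.readline()
        skip = 0
        try:
            [float(tok) for tok in first.strip().split(delim)]
        except ValueError:
            skip = 1
        W = np.loadtxt(path, delimiter=delim, skiprows=skip, ndmin=2)
    else:
        raise ValueError(f"unknown format {format!r}")
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"{path}: matrix is not square, shape {W.shape}")
    bad = np.argwhere(~np.isfinite(W))
    if bad.size:
        raise ValueError(f"{path}: non-finite entry at row {bad[0][0]}, column {bad[0][1]}")
    neg = np.argwhere(W < 0)
    if neg.size:
        raise ValueError(f"{path}: negative weight at row {neg[0][0]}, column {neg[0][1]}")
    return W


def save_layer(W: NDArray, path: str | Path) -> None:
    """Write a matrix as CSV/TSV/MatrixMarket at 17 significant digits."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(W))
    else:
        delim = "\t" if path.suffix.lower() == ".tsv" else ","
        np.savetxt(path, np.asarray(W, dtype=float), delimiter=delim, fmt="%.17g")


def neuronal_feedback(F_Pyr_vec: NDArray, layers: StructuralLayers,
                      omega_Pyr: float) -> NDArray:
    """Excitatory network input Q_Pyr = omega_Pyr * Omega_Pyr @ F_Pyr."""
    F_Pyr_vec = np.asarray(F_Pyr_vec, dtype=float)
    if F_Pyr_vec.shape[-1] != layers.n_nodes:
        raise ValueError(
            f"firing-rate vector length {F_Pyr_vec.shape[-1]} does not match "
            f"{layers.n_nodes} nodes")
    return omega_Pyr * (layers.Omega_Pyr @ F_Pyr_vec)


def astrocytic_feedback(Glu_e_vec: NDArray, layers: StructuralLayers,
                        p: ModelParameters) -> tuple[NDArray, NDArray]:
    """Gliotransmission network inputs (Q_Ast_Glu, Q_Ast_GABA).

    Both terms are driven by extracellular glutamate only (no GABA-induced
    gliotransmission): neighbours' Glu_e passes through the astrocytic
    binding sigmoid and is mixed by the lattice weights.
    """
    Glu_e_vec = np.asarray(Glu_e_vec, dtype=float)
    if Glu_e_vec.shape[-1] != layers.n_nodes:
        raise ValueError(
            f"concentration vector length {Glu_e_vec.shape[-1]} does not match "
            f"{layers.n_nodes} nodes")
    bound = sigmoid(Glu_e_vec, p.m_Glu_Ast, p.r_Glu_Ast, p.theta_Glu_Ast)
    mixed = layers.Omega_Ast @ np.asarray(bound)
    return p.omega_Glu * mixed, p.omega_GABA * mixed
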