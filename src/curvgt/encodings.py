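"""Attribute and structural encodings injected as attention bias.

Three learnable encoders turn precomputed graph structure into per-head bias
matrices added inside self-attention:

* degree encoding eta: a degree-indexed embedding table (one d-vector per
  integer degree, one reserved row for the virtual node) added to the node
  features, H(0) = X + D;
* edge-path encoding gamma(i, j): the mean over the deterministic shortest
  path i -> j of per-position linear maps of the edge features,
  gamma = (1/N) sum_k <x_{e_k}, w_k>, assembled into the matrix Gamma;
* curvature encoding phi(i, j): a learnable scalar per curvature bucket
  applied to kappa*(i, j), assembled into the matrix Phi (diagonal 0).

A formulation with one free vector per node (degree) or one free scalar per
pair (curvature) cannot share parameters across graphs; indexing by degree
value and by curvature bucket keeps both encodings graph-size independent
while preserving monotonicity in the underlying structure.  Pairs involving
the virtual node use dedicated learnable scalars.  Bias matrices are
(n+1) x (n+1) with the virtual node as the LAST row/column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import GraphError, WeightedGraph, degree, shortest_path_nodes
from .nn import Tensor, concat
from .ricci import CurvatureMatrix

__all__ = [
    "DegreeEncoder",
    "PathEdgeEncoder",
    "CurvatureEncoder",
    "EncodingBias",
    "encode_degrees",
    "encode_edge_path",
    "encode_curvature",
    "build_bias",
]

DIAGONAL = "diagonal"
VIRTUAL = "virtual"


class DegreeEncoder:
    """Embedding table over integer degrees, plus one reserved virtual-node row.

    Degrees above ``max_degree`` clamp to the last ordinary row, so the lookup
    is total for any graph.
    """

    def __init__(self, max_degree: int, dim: int, rng: np.random.Generator,
                 scale: float = 0.02):
        self.max_degree = int(max_degree)
        self.dim = int(dim)
        # rows 0..max_degree: ordinary degrees; row max_degree+1: virtual node
        self.table = Tensor(rng.normal(0.0, scale, (self.max_degree + 2, self.dim)),
                            requires_grad=True)

    @property
    def virtual_row(self) -> int:
        return self.max_degree + 1

    def row_index(self, d: int) -> int:
        return min(int(d), self.max_degree)

    def parameters(self) -> list[Tensor]:
        return [self.table]


class PathEdgeEncoder:
    """Per-position, per-head weight vectors w_k for the edge-path encoding.

    Path positions beyond ``k_max`` reuse w_{k_max}; a dedicated scalar covers
    virtual-node pairs.  Graphs without edge features are treated as carrying
    a constant scalar feature 1 per edge, so the encoding degenerates to a
    learnable per-position mean.
    """

    def __init__(self, q: int, k_max: int, heads: int, rng: np.random.Generator,
                 scale: float = 0.02):
        self.q = int(q)
        self.k_max = int(k_max)
        self.heads = int(heads)
        self.weights = Tensor(rng.normal(0.0, scale, (heads, self.k_max, self.q)),
                              requires_grad=True)
        self.virtual = Tensor(rng.normal(0.0, scale, (heads,)), requires_grad=True)

    def position(self, k: int) -> int:
        """0-based weight index for 1-based path position k."""
        return min(k, self.k_max) - 1

    def parameters(self) -> list[Tensor]:
        return [self.weights, self.virtual]


class CurvatureEncoder:
    """Learnable scalar per curvature bucket, per head.

    ``n_buckets`` uniform buckets over ``bucket_range`` plus two overflow
    buckets; bucket index is monotone in kappa.  A dedicated scalar covers
    virtual-node pairs and the diagonal maps to 0.
    """

    def __init__(self, heads: int, rng: np.random.Generator, n_buckets: int = 32,
                 bucket_range: tuple[float, float] = (-2.0, 2.0), scale: float = 0.02):
        lo, hi = bucket_range
        if not hi > lo:
            raise GraphError("bucket_range must be increasing")
        self.edges = np.linspace(lo, hi, n_buckets + 1)
        self.n_buckets = n_buckets + 2  # + low/high overflow
        self.heads = int(heads)
        self.scalars = Tensor(rng.normal(0.0, scale, (heads, self.n_buckets)),
                              requires_grad=True)
        self.virtual = Tensor(rng.normal(0.0, scale, (heads,)), requires_grad=True)

    def bucket(self, kappa: float) -> int:
        if np.isnan(kappa):
            raise GraphError("NaN curvature cannot be encoded")
        # curvatures on unweighted graphs are small-denominator rationals that
        # can land exactly on bucket boundaries; rounding absorbs LP round-off
        # so isomorphic graphs always bucket identically
        return int(np.searchsorted(self.edges, round(kappa, 9), side="right"))

    def parameters(self) -> list[Tensor]:
        return [self.scalars, self.virtual]


@dataclass
class EncodingBias:
    """Per-head (n+1) x (n+1) bias matrices; last row/column is the virtual node."""

    gamma: list[Tensor]
    phi: list[Tensor]

    @property
    def heads(self) -> int:
        return len(self.gamma)


def encode_degrees(g: WeightedGraph, enc: DegreeEncoder) -> Tensor:
    """Degree-embedding matrix D (n x d); caller forms H(0) = X + D."""
    idx = np.array([enc.row_index(degree(g, i)) for i in range(g.n)])
    return enc.table[idx]


def _path_feature_stack(g: WeightedGraph, pairs: list[tuple[int, int]], k_max: int,
                        q: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair padded path-position edge features: (n_pairs, k_max, q) and 1/N."""
    M = np.zeros((len(pairs), k_max, q))
    inv_n = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        path = shortest_path_nodes(g, i, j)
        n_edges = len(path) - 1
        inv_n[r] = 1.0 / n_edges
        for k in range(n_edges):
            e = g.edge_id(path[k], path[k + 1])
            feat = g.edge_features[e] if g.edge_features is not None else np.ones(1)
            M[r, min(k + 1, k_max) - 1] += feat
    return M, inv_n


def encode_edge_path(g: WeightedGraph, x: int, y: int, enc: PathEdgeEncoder,
                     head: int = 0) -> Tensor:
    """gamma(x, y): mean of per-position embedded edge features along the path."""
    if x == y:
        raise GraphError("edge-path encoding is undefined for x == y")
    q = g.edge_features.shape[1] if g.edge_features is not None else 1
    M, inv_n = _path_feature_stack(g, [(x, y)], enc.k_max, q)
    total = None
    for k in range(enc.k_max):
        term = Tensor(M[0, k].reshape(1, q)) @ enc.weights[head, k].reshape(q, 1)
        total = term if total is None else total + term
    return (total * inv_n[0]).reshape(())


def encode_curvature(kappa, enc: CurvatureEncoder, head: int = 0) -> Tensor:
    """phi for a single pair: bucket scalar for finite kappa, virtual scalar, or 0."""
    if kappa == DIAGONAL:
        return Tensor(0.0)
    if kappa == VIRTUAL:
        return enc.virtual[head]
    return enc.scalars[head, enc.bucket(float(kappa))]


def build_bias(g: WeightedGraph, cmat: CurvatureMatrix, degree_enc: DegreeEncoder,
               path_enc: PathEdgeEncoder, curv_enc: CurvatureEncoder,
               heads: int) -> EncodingBias:
    """Assemble per-head Gamma and Phi (n+1 x n+1, virtual node last).

    Both matrices are built by gathering from a value vector with an integer
    slot matrix, so gradients flow back into the encoder parameters.  Pair
    values are computed once per unordered pair and mirrored, making Gamma and
    Phi symmetric by construction.
    """
    if path_enc.heads < heads or curv_enc.heads < heads:
        raise GraphError("encoder head count smaller than requested heads")
    n = g.n
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    q = g.edge_features.shape[1] if g.edge_features is not None else 1

    # ---- Phi: slots = [buckets..., virtual, zero]
    zero_slot_phi = curv_enc.n_buckets + 1
    virt_slot_phi = curv_enc.n_buckets
    phi_idx = np.full((n + 1, n + 1), zero_slot_phi, dtype=int)
    for i, j in pairs:
        kappa = cmat.get(i, j)
        b = curv_enc.bucket(kappa)
        phi_idx[i, j] = phi_idx[j, i] = b
    phi_idx[n, :n] = phi_idx[:n, n] = virt_slot_phi
    # (virtual, virtual) and the diagonal stay at the zero slot

    # ---- Gamma: slots = [pair values..., virtual, zero]
    M, inv_n = _path_feature_stack(g, pairs, path_enc.k_max, q)
    n_pairs = len(pairs)
    gamma_idx = np.full((n + 1, n + 1), n_pairs + 1, dtype=int)
    for r, (i, j) in enumerate(pairs):
        gamma_idx[i, j] = gamma_idx[j, i] = r
    gamma_idx[n, :n] = gamma_idx[:n, n] = n_pairs

    gammas, phis = [], []
    for h in range(heads):
        vals_phi = concat([curv_enc.scalars[h], curv_enc.virtual[h].reshape(1),
                           Tensor([0.0])])
        phis.append(vals_phi[phi_idx])

        pair_vals = None
        for k in range(path_enc.k_max):
            term = Tensor(M[:, k, :]) @ path_enc.weights[h, k].reshape(q, 1)
            pair_vals = term if pair_vals is None else pair_vals + term
        pair_vals = (pair_vals.reshape(n_pairs) * Tensor(inv_n)) if n_pairs else Tensor(np.zeros(0))
        vals_gamma = concat([pair_vals, path_enc.virtual[h].reshape(1), Tensor([0.0])])
        gammas.append(vals_gamma[gamma_idx])

    return EncodingBias(gamma=gammas, phi=phis)
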