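"""Weights, four centrality measures and thresholded/MST centrality graphs.

A similarity network is derived from a sequence-distance matrix by the
transform  d~_uv = d_uv^q + delta  (default q = 0.01, delta = 1e-200) with
edge weights  w_uv = 1 / (d~_uv + 1).  The tiny exponent compresses the
150-plus orders of magnitude spanned by E-value distances into a usable
numeric range, and the offset delta keeps transformed distances strictly
positive so zero-distance sequence pairs still have finite, nonzero edge
lengths.  Diagonal entries of both W and D~ are 0.

Centralities (all on the undirected weighted graph):

* weighted degree      C_WD(u) = sum_v w_uv
* closeness            C_C(u)  = (|V|-1) / sum_v d~(u,v), where d~(u,v) is
  the shortest *path* distance — E-value distances violate the triangle
  inequality, so a path may shortcut a direct edge;
* betweenness          C_B(u)  = sum_{j<k, j!=u!=k} g_jk(u)/g_jk, with the
  edge variant counting shortest paths through an edge;
* eigenvector          W x = lambda x, leading eigenpair, x normalized to
  unit Euclidean norm with nonnegative entries.

Shortest-path ties are counted with a relative length tolerance (default
1e-12).  delta = 1e-200 is far below the float ulp of any d^q-scale path
length, so a detour through a zero-distance pair is mathematically longer
(+delta per extra hop) yet float-invisible; the path-count recursion
therefore only accepts predecessors whose distance from the source is
strictly smaller, which reproduces the infinitesimal-delta semantics and
stays cycle-free on zero-distance cores.

Disconnected graphs (after edge thresholding) are handled per component:
closeness uses the component size for |V|, shortest paths never cross
components, and eigenvector centrality is computed component-wise with a
degeneracy warning since the leading eigenvalue is only unique for a
connected nonnegative matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from sklearn.base import BaseEstimator, TransformerMixin

from .cluster import mst_edges
from .distance import DistanceMatrix
from .errors import InvariantError
from .io import GraphDocument

DEFAULT_Q = 0.01
DEFAULT_DELTA = 1e-200
DEFAULT_TIE_TOL = 1e-12


@dataclass(frozen=True)
class SimilarityNetwork:
    """Weight matrix W and transformed distances D~ over named nodes.

    ``mask`` is the boolean adjacency (off-diagonal True where an edge is
    present); a network straight from a distance matrix is complete, a
    thresholded or tree network is not.  W is zero at absent edges.
    """

    ids: tuple[str, ...]
    weights: np.ndarray
    lengths: np.ndarray
    mask: np.ndarray
    q: float = DEFAULT_Q
    delta: float = DEFAULT_DELTA

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("weights", "lengths"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (n, n):
                raise InvariantError(f"{name} has wrong shape")
            if not np.array_equal(arr, arr.T):
                raise InvariantError(f"{name} is not symmetric")
            if np.any(np.diag(arr) != 0):
                raise InvariantError(f"{name} has a nonzero diagonal")
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.shape != (n, n) or not np.array_equal(mask, mask.T):
            raise InvariantError("mask must be a symmetric boolean matrix")
        if np.any(np.diag(mask)):
            raise InvariantError("mask diagonal must be False")
        if np.any(self.lengths[mask] <= 0):
            raise InvariantError("present edges must have positive length")
        expected_w = 1.0 / (self.lengths + 1.0)
        if not np.allclose(self.weights[mask], expected_w[mask], rtol=0,
                           atol=0):
            raise InvariantError("weights do not satisfy w = 1/(d~+1)")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.ids)}

    @classmethod
    def from_lengths(cls, ids, lengths, mask=None, q=DEFAULT_Q,
                     delta=DEFAULT_DELTA) -> "SimilarityNetwork":
        """Build a network directly from transformed edge lengths."""
        lengths = np.asarray(lengths, dtype=float)
        n = lengths.shape[0]
        if mask is None:
            mask = ~np.eye(n, dtype=bool)
        weights = np.zeros_like(lengths)
        off = np.asarray(mask, dtype=bool)
        weights[off] = 1.0 / (lengths[off] + 1.0)
        return cls(ids=tuple(ids), weights=weights, lengths=lengths,
                   mask=off, q=q, delta=delta)


def to_weights(
    dm: DistanceMatrix,
    q: float = DEFAULT_Q,
    delta: float = DEFAULT_DELTA,
    mask: np.ndarray | None = None,
) -> SimilarityNetwork:
    """Apply the d^q + delta transform and derive edge weights.

    0^q is defined as 0, so a zero sequence distance maps to length delta
    and weight 1/(1+delta), i.e. indistinguishable from 1 at double
    precision.
    """
    if q <= 0:
        raise ValueError("exponent q must be > 0")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    n = len(dm)
    lengths = np.power(dm.values, q) + delta
    np.fill_diagonal(lengths, 0.0)
    if mask is None:
        mask = ~np.eye(n, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool) & ~np.eye(n, dtype=bool)
    weights = np.zeros((n, n))
    weights[mask] = 1.0 / (lengths[mask] + 1.0)
    return SimilarityNetwork(ids=dm.ids, weights=weights, lengths=lengths,
                             mask=mask, q=q, delta=delta)


# ---------------------------------------------------------------------------
# shortest paths and components
# ---------------------------------------------------------------------------

def _edge_graph(net: SimilarityNetwork) -> csr_matrix:
    data = np.where(net.mask, net.lengths, 0.0)
    return csr_matrix(data)


def _components(net: SimilarityNetwork) -> np.ndarray:
    _, labels = connected_components(
        csr_matrix(net.mask.astype(int)), directed=False
    )
    return labels


def shortest_path_matrix(net: SimilarityNetwork) -> np.ndarray:
    """All-pairs shortest path lengths over present edges (inf across
    components)."""
    sp = dijkstra(_edge_graph(net), directed=False)
    np.fill_diagonal(sp, 0.0)
    return sp


# ---------------------------------------------------------------------------
# centrality measures
# ---------------------------------------------------------------------------

def weighted_degree(net: SimilarityNetwork) -> dict[str, float]:
    """C_WD(u) = sum of edge weights at u."""
    sums = net.weights.sum(axis=1)
    return {u: float(s) for u, s in zip(net.ids, sums)}


def closeness(net: SimilarityNetwork) -> dict[str, float]:
    """C_C(u) = (|V|-1) / sum of shortest-path lengths, per component.

    |V| is the size of u's connected component; an isolated node gets 0.
    """
    sp = shortest_path_matrix(net)
    comp = _components(net)
    values = {}
    for i, u in enumerate(net.ids):
        members = np.flatnonzero(comp == comp[i])
        if len(members) == 1:
            values[u] = 0.0
            continue
        total = sp[i, members].sum()
        values[u] = float((len(members) - 1) / total)
    return values


def _close(a: float, b: float, tol: float) -> bool:
    return abs(a - b) <= tol * max(a, b)


def _path_counts(net: SimilarityNetwork, sp: np.ndarray,
                 tol: float) -> np.ndarray:
    """counts[j, k] = number of shortest j→k paths (tolerance-tied).

    A predecessor of k on a shortest path from j must be tolerance-exact on
    total length AND strictly closer to j than k is: an edge whose length
    is below float resolution of the path total (a delta-scale edge out of
    a zero-distance core) cannot advance a shortest path, because
    mathematically it adds delta > 0.
    """
    n = len(net)
    counts = np.zeros((n, n))
    lengths = net.lengths
    mask = net.mask
    for j in range(n):
        order = np.argsort(sp[j], kind="stable")
        counts[j, j] = 1.0
        for k in order:
            if k == j or not np.isfinite(sp[j, k]):
                continue
            total = 0.0
            for v in np.flatnonzero(mask[k]):
                if sp[j, v] < sp[j, k] and _close(
                    sp[j, v] + lengths[v, k], sp[j, k], tol
                ):
                    total += counts[j, v]
            counts[j, k] = total
    return counts


def betweenness(
    net: SimilarityNetwork, tie_tol: float = DEFAULT_TIE_TOL
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Unnormalized node and edge betweenness over unordered pairs.

    For each pair j < k, every node u (j != u != k) receives
    g_jk(u)/g_jk and every present edge receives g_jk(e)/g_jk, where g
    counts shortest paths under the relative tie tolerance.
    """
    n = len(net)
    sp = shortest_path_matrix(net)
    counts = _path_counts(net, sp, tie_tol)
    node_bt = np.zeros(n)
    edge_index = [
        (a, b) for a in range(n) for b in range(a + 1, n) if net.mask[a, b]
    ]
    edge_bt = dict.fromkeys(edge_index, 0.0)
    for j in range(n):
        for k in range(j + 1, n):
            if not np.isfinite(sp[j, k]):
                continue
            g_jk = counts[j, k]
            if g_jk == 0:
                continue
            for u in range(n):
                if u == j or u == k:
                    continue
                if (
                    sp[j, u] < sp[j, k]
                    and sp[k, u] < sp[k, j]
                    and _close(sp[j, u] + sp[u, k], sp[j, k], tie_tol)
                ):
                    node_bt[u] += counts[j, u] * counts[u, k] / g_jk
            for (a, b) in edge_index:
                w_ab = net.lengths[a, b]
                through = 0.0
                # traversal a→b requires strict progress away from j
                if sp[j, a] < sp[j, b] and _close(
                    sp[j, a] + w_ab + sp[b, k], sp[j, k], tie_tol
                ):
                    through += counts[j, a] * counts[b, k]
                if sp[j, b] < sp[j, a] and _close(
                    sp[j, b] + w_ab + sp[a, k], sp[j, k], tie_tol
                ):
                    through += counts[j, b] * counts[a, k]
                if through:
                    edge_bt[(a, b)] += through / g_jk
    nodes = {u: float(v) for u, v in zip(net.ids, node_bt)}
    edges = {
        (net.ids[a], net.ids[b]): float(v) for (a, b), v in edge_bt.items()
    }
    return nodes, edges


def eigenvector_centrality(
    net: SimilarityNetwork,
    tol: float = 1e-12,
    max_iter: int = 10000,
) -> tuple[dict[str, float], float]:
    """Leading eigenpair of W by power iteration from the uniform vector.

    Returns the centrality vector (unit Euclidean norm, nonnegative) and
    the leading eigenvalue lambda.  Iteration runs on W + sigma*I with
    sigma = max row sum — a spectral shift that leaves eigenvectors
    untouched while keeping the convergence ratio away from 1 when W has
    large-magnitude negative eigenvalues; lambda is recovered as the
    Rayleigh quotient with W itself.

    On a disconnected network the leading eigenvalue is not unique; a
    warning is issued and each component is solved separately, the full
    vector then renormalized.
    """
    n = len(net)
    comp = _components(net)
    n_comp = comp.max() + 1 if n else 0
    if n_comp > 1:
        warnings.warn(
            "network is disconnected: eigenvector centrality computed "
            "component-wise (leading eigenvalue is degenerate)",
            RuntimeWarning,
            stacklevel=2,
        )
    x = np.zeros(n)
    lam_best = 0.0
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        if len(members) == 1:
            x[members[0]] = 1.0
            continue
        w = net.weights[np.ix_(members, members)]
        sigma = float(w.sum(axis=1).max())
        vec = np.full(len(members), 1.0 / np.sqrt(len(members)))
        converged = False
        for _ in range(max_iter):
            nxt = w @ vec + sigma * vec
            norm = np.linalg.norm(nxt)
            if norm == 0:
                vec = np.full_like(vec, 1.0 / np.sqrt(len(vec)))
                converged = True
                break
            nxt /= norm
            if np.max(np.abs(nxt - vec)) < tol:
                vec = nxt
                converged = True
                break
            vec = nxt
        if not converged:
            raise RuntimeError(
                f"power iteration failed to converge in {max_iter} iterations"
            )
        vec = np.abs(vec)  # Perron vector orientation
        lam = float(vec @ w @ vec)
        lam_best = max(lam_best, lam)
        x[members] = vec
    norm = np.linalg.norm(x)
    if norm > 0:
        x = x / norm
    return {u: float(v) for u, v in zip(net.ids, x)}, lam_best


# ---------------------------------------------------------------------------
# centrality graph exports
# ---------------------------------------------------------------------------

def _centrality_document(
    net: SimilarityNetwork,
    distances: np.ndarray,
    edge_role: str,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> GraphDocument:
    wd = weighted_degree(net)
    cc = closeness(net)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ev, lam = eigenvector_centrality(net)
    node_bt, edge_bt = betweenness(net, tie_tol=tie_tol)
    comp = _components(net)
    nodes = [
        {
            "id": u,
            "weighted_degree": wd[u],
            "closeness": cc[u],
            "betweenness": node_bt[u],
            "eigenvector": ev[u],
            "component": int(comp[i]),
        }
        for i, u in enumerate(net.ids)
    ]
    idx = net.index
    edges = []
    for (a, b), bt in sorted(edge_bt.items()):
        i, j = idx[a], idx[b]
        edges.append(
            {
                "source": a,
                "target": b,
                "distance": float(distances[i, j]),
                "weight": float(net.weights[i, j]),
                "betweenness": bt,
                "role": edge_role,
            }
        )
    doc = GraphDocument(nodes=nodes, edges=edges)
    return doc


def threshold_graph(
    dm: DistanceMatrix,
    threshold: float,
    q: float = DEFAULT_Q,
    delta: float = DEFAULT_DELTA,
    tie_tol: float = DEFAULT_TIE_TOL,
    recompute: str = "post",
) -> GraphDocument:
    """Similarity network keeping edges with d <= threshold.

    All nodes are retained.  With ``recompute="post"`` (default, matching
    the visual semantics of a thresholded view) centralities are computed
    on the thresholded graph per component; ``recompute="pre"`` attaches
    centralities of the full network instead.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if recompute not in ("post", "pre"):
        raise ValueError("recompute must be 'post' or 'pre'")
    n = len(dm)
    keep = (dm.values <= threshold) & ~np.eye(n, dtype=bool)
    net = to_weights(dm, q=q, delta=delta, mask=keep)
    if recompute == "post":
        return _centrality_document(net, dm.values, "plain", tie_tol)
    full = to_weights(dm, q=q, delta=delta)
    full_doc = _centrality_document(full, dm.values, "plain", tie_tol)
    node_attrs = {node["id"]: node for node in full_doc.nodes}
    thin = _centrality_document(net, dm.values, "plain", tie_tol)
    nodes = [dict(node_attrs[node["id"]]) for node in thin.nodes]
    return GraphDocument(nodes=nodes, edges=thin.edges)


def mst_centrality_graph(
    dm: DistanceMatrix,
    q: float = DEFAULT_Q,
    delta: float = DEFAULT_DELTA,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> GraphDocument:
    """Centrality graph computed on the minimum spanning tree.

    Node closeness/weighted-degree/eigenvector and edge betweenness are
    evaluated on the tree itself, so leaf nodes have betweenness 0 and the
    tree's hubs stand out.
    """
    n = len(dm)
    idx = dm.index
    mask = np.zeros((n, n), dtype=bool)
    for a, b, _ in mst_edges(dm):
        i, j = idx[a], idx[b]
        mask[i, j] = mask[j, i] = True
    net = to_weights(dm, q=q, delta=delta, mask=mask)
    return _centrality_document(net, dm.values, "tree", tie_tol)


# ---------------------------------------------------------------------------
# sklearn-style transformer
# ---------------------------------------------------------------------------

class DistanceWeightTransform(BaseEstimator, TransformerMixin):
    """Transform a square distance matrix into edge weights 1/(d^q+delta+1).

    Stateless; ``fit`` only validates parameters.  ``transform`` accepts a
    square ndarray or a :class:`DistanceMatrix` and returns the weight
    matrix as an ndarray (zero diagonal).
    """

    def __init__(self, q: float = DEFAULT_Q, delta: float = DEFAULT_DELTA):
        self.q = q
        self.delta = delta

    def fit(self, X=None, y=None):
        if self.q <= 0 or self.delta <= 0:
            raise ValueError("q and delta must be > 0")
        self.n_features_in_ = (
            len(X) if isinstance(X, DistanceMatrix)
            else (np.asarray(X).shape[0] if X is not None else 0)
        )
        return self

    def transform(self, X) -> np.ndarray:
        if not isinstance(X, DistanceMatrix):
            X = np.asarray(X, dtype=float)
            ids = tuple(f"u{i:03d}" for i in range(X.shape[0]))
            X = DistanceMatrix(ids=ids, values=X)
        return to_weights(X, q=self.q, delta=self.delta).weights
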