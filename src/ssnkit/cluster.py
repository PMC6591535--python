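"""Minimum-span clustering (MSC) of a distance matrix into nested levels.

MSC is a hierarchical clustering that needs no hyper-parameters and no
preset cluster count.  One round links every unit to its nearest neighbor
and takes connected components of the resulting undirected link graph as
clusters; the recursion then treats clusters as units with single-linkage
superdistances (minimum distance over cross pairs) and repeats.  Three
rounds give the sequence → cluster → family resolutions of a receptor
superfamily network.

All tie-breaks (nearest neighbors, spanning-tree edges, cluster numbering)
are lexicographic so outputs are identical across runs and platforms.

The per-level minimum spanning tree is the standard visualization backbone
of the similarity network; it is computed with a deterministic Kruskal in
which equal-distance edges are ordered by their (smaller id, larger id)
pair.

``find_core`` extracts a cluster's conservative core: the set of members
whose pairwise sequence distances are all exactly zero.  Zero-distance
components are reduced to cliques greedily (repeatedly dropping the member
with the most nonzero in-component pairs) because observed cores are
already cliques and exact maximum clique would be needless NP-hard
machinery.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .distance import DistanceMatrix
from .errors import InvariantError
from .io import AnnotationTable, GraphDocument

UNKNOWN_FAMILY = "unknown"
UNKNOWN_PREFIX = "Un"

_UNIT_KINDS = ("sequence", "cluster", "family")


@dataclass(frozen=True)
class Partition:
    """Disjoint clusters covering all units at one resolution level."""

    level: int
    clusters: tuple[tuple[str, ...], ...]
    unit_kind: str = "sequence"

    def __post_init__(self) -> None:
        canonical = tuple(
            sorted((tuple(sorted(c)) for c in self.clusters),
                   key=lambda c: c[0])
        )
        object.__setattr__(self, "clusters", canonical)
        if any(len(c) == 0 for c in canonical):
            raise InvariantError("empty cluster")
        flat = [u for c in canonical for u in c]
        if len(flat) != len(set(flat)):
            raise InvariantError("clusters are not disjoint")

    @property
    def units(self) -> tuple[str, ...]:
        return tuple(sorted(u for c in self.clusters for u in c))

    def labels_for(self, ids) -> np.ndarray:
        """Integer cluster labels aligned with ``ids`` (for e.g. ARI)."""
        lookup = {u: k for k, c in enumerate(self.clusters) for u in c}
        return np.array([lookup[i] for i in ids], dtype=int)


@dataclass(frozen=True)
class Hierarchy:
    """Nested partitions with per-level superdistance matrices.

    ``superdistances[k]`` is the single-linkage distance matrix over the
    clusters of ``levels[k]``; each cluster-unit is named by its
    lexicographically smallest member.
    """

    levels: tuple[Partition, ...]
    superdistances: tuple[DistanceMatrix, ...]

    def __post_init__(self) -> None:
        if not self.levels:
            raise InvariantError("hierarchy needs at least one level")
        for low, high in zip(self.levels, self.levels[1:]):
            fine = {frozenset(c) for c in low.clusters}
            for coarse in high.clusters:
                members = set(coarse)
                parts = [c for c in fine if c <= members]
                union = set().union(*parts) if parts else set()
                if union != members:
                    raise InvariantError(
                        "coarser cluster is not a union of finer clusters"
                    )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def to_json(self) -> str:
        payload = {
            "levels": [
                {
                    "level": p.level,
                    "unit_kind": p.unit_kind,
                    "clusters": [list(c) for c in p.clusters],
                }
                for p in self.levels
            ],
            "superdistances": [
                {
                    "ids": list(dm.ids),
                    "edges": [
                        [dm.ids[i], dm.ids[j], f"{dm.values[i, j]:.17e}"]
                        for i in range(len(dm.ids))
                        for j in range(i + 1, len(dm.ids))
                    ],
                }
                for dm in self.superdistances
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "Hierarchy":
        payload = json.loads(text)
        levels = tuple(
            Partition(
                level=p["level"],
                clusters=tuple(tuple(c) for c in p["clusters"]),
                unit_kind=p["unit_kind"],
            )
            for p in payload["levels"]
        )
        supers = []
        for entry in payload["superdistances"]:
            ids = tuple(entry["ids"])
            index = {name: i for i, name in enumerate(ids)}
            values = np.zeros((len(ids), len(ids)))
            for a, b, d in entry["edges"]:
                values[index[a], index[b]] = values[index[b], index[a]] = float(d)
            supers.append(DistanceMatrix(ids=ids, values=values))
        return cls(levels=levels, superdistances=tuple(supers))


def _unit_kind(level: int) -> str:
    return _UNIT_KINDS[min(level - 1, 2)]


def nearest_neighbor_partition(dm: DistanceMatrix, level: int = 1) -> Partition:
    """One MSC round: link each unit to its nearest neighbor, take components.

    Distance ties break to the lexicographically smallest neighbor id.  A
    single unit yields a single singleton cluster.
    """
    n = len(dm)
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return Partition(level=level, clusters=((dm.ids[0],),),
                         unit_kind=_unit_kind(level))
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    values = dm.values
    for i in range(n):
        row = values[i].copy()
        row[i] = np.inf
        d_min = row.min()
        candidates = [dm.ids[j] for j in range(n)
                      if j != i and row[j] == d_min]
        nn = min(candidates)
        union(i, dm.index[nn])
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(dm.ids[i])
    return Partition(
        level=level,
        clusters=tuple(tuple(sorted(g)) for g in groups.values()),
        unit_kind=_unit_kind(level),
    )


def inter_cluster_distance(dm: DistanceMatrix, a, b) -> float:
    """Single-linkage distance: minimum over cross pairs of two id sets."""
    a, b = set(a), set(b)
    if a & b:
        raise ValueError("clusters overlap")
    if not a or not b:
        raise ValueError("clusters must be non-empty")
    idx = dm.index
    rows = [idx[x] for x in a]
    cols = [idx[y] for y in b]
    return float(dm.values[np.ix_(rows, cols)].min())


def _superdistance_matrix(dm: DistanceMatrix, partition: Partition) -> DistanceMatrix:
    """Single-linkage matrix over a partition's clusters.

    Each cluster-unit is named by its lexicographically smallest member so
    higher-level tie-breaks stay deterministic.
    """
    clusters = partition.clusters
    idx = dm.index
    reps = tuple(c[0] for c in clusters)
    k = len(clusters)
    values = np.zeros((k, k))
    member_idx = [np.array([idx[u] for u in c]) for c in clusters]
    for i in range(k):
        for j in range(i + 1, k):
            d = dm.values[np.ix_(member_idx[i], member_idx[j])].min()
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=reps, values=values, meta=dm.meta)


def build_hierarchy(dm: DistanceMatrix, max_levels: int = 3) -> Hierarchy:
    """Recursive MSC: cluster, collapse to superdistances, repeat.

    Stops after ``max_levels`` rounds or as soon as a level contains a
    single cluster.  Level k+1 clusters are exact unions of level k
    clusters by construction.
    """
    if max_levels < 1:
        raise ValueError("max_levels must be >= 1")
    levels: list[Partition] = []
    supers: list[DistanceMatrix] = []
    # membership of each current unit id, expanded to sequence ids
    expansion: dict[str, tuple[str, ...]] = {i: (i,) for i in dm.ids}
    current = dm
    for level in range(1, max_levels + 1):
        unit_partition = nearest_neighbor_partition(current, level=level)
        seq_clusters = tuple(
            tuple(sorted(s for u in cluster for s in expansion[u]))
            for cluster in unit_partition.clusters
        )
        partition = Partition(level=level, clusters=seq_clusters,
                              unit_kind=_unit_kind(level))
        levels.append(partition)
        super_dm = _superdistance_matrix(current, unit_partition)
        supers.append(super_dm)
        if len(partition.clusters) == 1:
            break
        expansion = {
            rep: seq_cluster
            for rep, seq_cluster in zip(
                (c[0] for c in unit_partition.clusters), seq_clusters
            )
        }
        current = super_dm
    return Hierarchy(levels=tuple(levels), superdistances=tuple(supers))


# ---------------------------------------------------------------------------
# minimum spanning tree
# ---------------------------------------------------------------------------

def mst_edges(dm: DistanceMatrix) -> list[tuple[str, str, float]]:
    """Deterministic Kruskal MST edges over the complete distance graph.

    Equal-weight edges are taken in lexicographic (smaller id, larger id)
    order, which makes the tree unique and reproducible.
    """
    n = len(dm)
    if n <= 1:
        return []
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = dm.ids[i], dm.ids[j]
            if b < a:
                a, b = b, a
            edges.append((float(dm.values[i, j]), a, b))
    edges.sort()
    parent = {u: u for u in dm.ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = []
    for d, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
            tree.append((a, b, d))
            if len(tree) == n - 1:
                break
    return tree


def minimum_spanning_tree(dm: DistanceMatrix) -> GraphDocument:
    """MST as a graph document; edges carry the distance and role 'tree'."""
    nodes = [{"id": u} for u in dm.ids]
    edges = [
        {"source": a, "target": b, "distance": d, "role": "tree"}
        for a, b, d in mst_edges(dm)
    ]
    return GraphDocument(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# conservative cores
# ---------------------------------------------------------------------------

def find_core(dm: DistanceMatrix, cluster) -> tuple[str, ...]:
    """Largest all-pairs-zero subset of a cluster (the conservative core).

    Connected components of the zero-distance edge graph are each reduced
    to a fully-zero clique by greedily removing the member with the most
    nonzero in-component pairs (ties remove the lexicographically largest
    id); the largest resulting clique with >= 2 members wins, ties going to
    the clique holding the smallest id.  Returns an empty tuple when the
    cluster has no zero-distance pair.
    """
    members = sorted(set(cluster))
    if not members:
        raise ValueError("empty cluster")
    idx = dm.index
    order = [idx[m] for m in members]
    sub = dm.values[np.ix_(order, order)]
    m = len(members)
    # components of the zero-distance graph
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    any_zero = False
    for i in range(m):
        for j in range(i + 1, m):
            if sub[i, j] == 0:
                any_zero = True
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    if not any_zero:
        return ()
    components: dict[int, list[int]] = {}
    for i in range(m):
        components.setdefault(find(i), []).append(i)
    cliques = []
    for comp in components.values():
        if len(comp) < 2:
            continue
        keep = sorted(comp)
        while True:
            nonzero_counts = {
                i: sum(1 for j in keep if j != i and sub[i, j] != 0)
                for i in keep
            }
            worst = max(nonzero_counts.values())
            if worst == 0:
                break
            # deterministic removal: largest id among the worst offenders
            victim = max(
                (i for i in keep if nonzero_counts[i] == worst),
                key=lambda i: members[i],
            )
            keep.remove(victim)
            if len(keep) < 2:
                keep = []
                break
        if len(keep) >= 2:
            cliques.append(tuple(members[i] for i in keep))
    if not cliques:
        return ()
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques[0]


# ---------------------------------------------------------------------------
# naming and annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterLabel:
    """Receptor-group prefix plus a three-digit rank, e.g. ``Pe001``."""

    prefix: str
    index: int

    def __post_init__(self) -> None:
        if not re.match(r"^[A-Za-z0-9]{2,3}$", self.prefix):
            raise InvariantError(f"bad prefix {self.prefix!r}")
        if self.index < 1:
            raise InvariantError("label index must be >= 1")

    @property
    def text(self) -> str:
        return f"{self.prefix}{self.index:03d}"

    def __str__(self) -> str:
        return self.text


def _majority(values: list[str]) -> str:
    counts: dict[str, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def name_clusters(
    partition: Partition, annotations: AnnotationTable
) -> dict[tuple[str, ...], ClusterLabel]:
    """Label clusters ``<prefix><NNN>`` by majority receptor-group prefix.

    Within a prefix, clusters are numbered 001, 002, ... by decreasing
    member count (the largest cluster of a family gets 001); equal-size
    ties go first to the cluster holding the smallest id.  Unannotated
    members count toward the ``Un`` (unknown) prefix.
    """
    by_prefix: dict[str, list[tuple[str, ...]]] = {}
    for cluster in partition.clusters:
        prefixes = [
            (annotations.get(u).prefix if annotations.get(u) else UNKNOWN_PREFIX)
            for u in cluster
        ]
        by_prefix.setdefault(_majority(prefixes), []).append(cluster)
    labels: dict[tuple[str, ...], ClusterLabel] = {}
    for prefix, clusters in by_prefix.items():
        ranked = sorted(clusters, key=lambda c: (-len(c), c[0]))
        for rank, cluster in enumerate(ranked, start=1):
            labels[cluster] = ClusterLabel(prefix=prefix, index=rank)
    return labels


def annotate_partition(
    partition: Partition, annotations: AnnotationTable
) -> dict[tuple[str, ...], dict[str, str]]:
    """Per-cluster majority family and class labels.

    Ties break to the lexicographically smallest label; members without an
    annotation count as ``unknown``.
    """
    result = {}
    for cluster in partition.clusters:
        rows = [annotations.get(u) for u in cluster]
        families = [r.family if r else UNKNOWN_FAMILY for r in rows]
        classes = [r.class_label if r else UNKNOWN_FAMILY for r in rows]
        result[cluster] = {
            "family": _majority(families),
            "class": _majority(classes),
        }
    return result


def cluster_graph(
    dm: DistanceMatrix, cluster, core: tuple[str, ...] | None = None
) -> GraphDocument:
    """First-level diagram of one cluster: its MST with core annotation.

    Core membership is flagged on nodes; the edge roles encode the diagram
    arrows: a zero-distance edge between core members is ``core-shortest``,
    any other tree edge is ``toward-core`` when the cluster has a core
    (every tree path leads into it) and plain ``tree`` otherwise.
    """
    members = sorted(set(cluster))
    sub = dm.subset(members)
    if core is None:
        core = find_core(dm, members)
    core_set = set(core)
    nodes = [{"id": u, "in_core": u in core_set} for u in members]
    edges = []
    for a, b, d in mst_edges(sub):
        if a in core_set and b in core_set and d == 0:
            role = "core-shortest"
        elif core_set:
            role = "toward-core"
        else:
            role = "tree"
        edges.append({"source": a, "target": b, "distance": d, "role": role})
    return GraphDocument(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class MinSpanClustering(BaseEstimator, ClusterMixin):
    """Minimum-span clustering over a precomputed distance matrix.

    Parameters
    ----------
    max_levels : int, default 3
        Maximum number of nested resolution levels; the recursion also
        stops as soon as everything merges into one cluster.

    Attributes
    ----------
    ids_ : tuple of str
        Unit names, taken from the input or synthesized as ``u000``...
    hierarchy_ : Hierarchy
        All levels with superdistance matrices.
    labels_ : ndarray of int
        Level-1 cluster labels aligned with ``ids_``.
    n_levels_ : int
    """

    def __init__(self, max_levels: int = 3):
        self.max_levels = max_levels

    def fit(self, X, y=None):
        if isinstance(X, DistanceMatrix):
            dm = X
        else:
            X = np.asarray(X, dtype=float)
            ids = tuple(f"u{i:03d}" for i in range(X.shape[0]))
            dm = DistanceMatrix(ids=ids, values=X)
        self.ids_ = dm.ids
        self.hierarchy_ = build_hierarchy(dm, max_levels=self.max_levels)
        self.labels_ = self.hierarchy_.levels[0].labels_for(self.ids_)
        self.n_levels_ = self.hierarchy_.n_levels
        return self

    def level_labels(self, level: int) -> np.ndarray:
        """Integer labels for a 1-based resolution level."""
        return self.hierarchy_.levels[level - 1].labels_for(self.ids_)
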