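"""Seeded synthetic inputs with planted structure.

The generators emulate, at desk scale, the two regimes a receptor
similarity network exhibits: tight clusters whose members may form an
exact zero-distance conservative core, and looser multi-level grouping
with distances separated by many orders of magnitude between levels.
All sampling is log-uniform — E-value distances live on the log scale,
and uniform sampling would collapse the structure into the largest
decade.

Recoverability by design.  Minimum-span clustering links every unit to
its nearest neighbor, so a planted cluster is recovered exactly only if
its internal nearest-neighbor link graph is connected.  The generator
guarantees this by planting hub-star structure: within every cluster (and
every group of clusters at coarser levels) distances to a designated hub
unit are drawn from the lower half of the level's log10 range and all
other internal pairs from the upper half, which makes the hub every
member's nearest neighbor.  Planted cluster/group sizes must be >= 2 for
the guarantee to hold (a singleton necessarily links outward).

All generators are bit-reproducible for a fixed (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import Hierarchy, Partition, _superdistance_matrix, _unit_kind
from .distance import DistanceMatrix
from .io import EvalueTable


@dataclass(frozen=True)
class PlantedSpec:
    """Planted multi-level cluster structure.

    ``level_sizes`` nests inward-out: ``level_sizes[0]`` are the fine
    cluster sizes (in sequences), ``level_sizes[1]`` groups those clusters
    (counts of consecutive clusters per group), and so on.  E.g.
    ``[[2, 2, 2], [2, 1]]`` plants three fine pairs grouped 2 + 1.

    ``log10_ranges`` gives one (lo, hi) log10-distance range per depth,
    tightest first: ``log10_ranges[0]`` for intra-cluster pairs,
    ``log10_ranges[1]`` for cluster pairs inside a group, ..., and a final
    range for pairs in different top-level groups.  Ranges must be
    strictly ordered (deeper level ⇒ smaller distances).

    ``zero_core_fraction`` of each fine cluster (rounded up) gets exact
    zero pairwise distances — literal zeros, not tiny floats, since the
    conservative-core definition requires them.
    """

    level_sizes: tuple[tuple[int, ...], ...]
    log10_ranges: tuple[tuple[float, float], ...]
    zero_core_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(tuple(int(s) for s in lvl) for lvl in self.level_sizes)
        ranges = tuple(
            (float(lo), float(hi)) for lo, hi in self.log10_ranges
        )
        object.__setattr__(self, "level_sizes", sizes)
        object.__setattr__(self, "log10_ranges", ranges)
        if not sizes or not sizes[0]:
            raise ValueError("need at least one fine cluster")
        for lvl in sizes:
            if any(s < 1 for s in lvl):
                raise ValueError("cluster sizes must be >= 1")
        for k, lvl in enumerate(sizes[1:], start=1):
            if sum(lvl) != len(sizes[k - 1]):
                raise ValueError(
                    f"level {k} group counts must sum to the number of "
                    f"level {k - 1} units"
                )
        if len(ranges) != len(sizes) + 1:
            raise ValueError(
                "need one log10 range per depth: "
                f"{len(sizes) + 1} expected, got {len(ranges)}"
            )
        for lo, hi in ranges:
            if not lo < hi:
                raise ValueError("each log10 range needs lo < hi")
        for (_, hi), (lo, _) in zip(ranges[:-1], ranges[1:]):
            if not hi < lo:
                raise ValueError(
                    "overlapping ranges: deeper levels must have strictly "
                    "smaller distances"
                )
        if not 0.0 <= self.zero_core_fraction <= 1.0:
            raise ValueError("zero_core_fraction must be in [0, 1]")

    @property
    def n_sequences(self) -> int:
        return sum(self.level_sizes[0])


def _grouping(counts, n_units: int) -> list[list[int]]:
    """Split unit indices 0..n-1 into consecutive groups of given counts."""
    groups, start = [], 0
    for c in counts:
        groups.append(list(range(start, start + c)))
        start += c
    assert start == n_units
    return groups


def _sample_log_uniform(rng, lo: float, hi: float) -> float:
    return float(10.0 ** rng.uniform(lo, hi))


def planted_cluster_matrix(
    spec: PlantedSpec,
) -> tuple[DistanceMatrix, Hierarchy]:
    """Distance matrix with planted hierarchy, plus the ground truth.

    The truth hierarchy lists the fine partition, every grouping level,
    and — when the top level still has more than one group — a final
    all-in-one level (all cross distances are finite, so clustering
    ultimately merges everything).
    """
    rng = np.random.default_rng(spec.seed)
    fine_sizes = spec.level_sizes[0]
    n = spec.n_sequences
    ids = tuple(f"s{i:03d}" for i in range(n))
    # members of each fine cluster
    fine: list[list[int]] = []
    start = 0
    for size in fine_sizes:
        fine.append(list(range(start, start + size)))
        start += size

    values = np.zeros((n, n))

    def put(i: int, j: int, d: float) -> None:
        values[i, j] = values[j, i] = d

    # --- intra-cluster distances (depth 0), hub-star with optional core
    lo0, hi0 = spec.log10_ranges[0]
    mid0 = (lo0 + hi0) / 2.0
    for members in fine:
        core_size = int(np.ceil(spec.zero_core_fraction * len(members)))
        core = set(members[:core_size]) if core_size >= 2 else set()
        hub = members[0]
        for a_pos, a in enumerate(members):
            for b in members[a_pos + 1:]:
                if a in core and b in core:
                    put(a, b, 0.0)
                elif hub in (a, b):
                    put(a, b, _sample_log_uniform(rng, lo0, mid0))
                else:
                    put(a, b, _sample_log_uniform(rng, mid0, hi0))

    # --- coarser levels: one hub-star distance per unit pair in a group
    # units at depth k are the level-k groups; start from fine clusters
    units: list[list[int]] = [list(m) for m in fine]  # sequence members
    grouping_levels = list(spec.level_sizes[1:])
    # implicit final level: everything in one group (if more than one unit)
    depth = 1
    group_partitions: list[list[list[int]]] = []
    while True:
        if depth - 1 < len(grouping_levels):
            counts = grouping_levels[depth - 1]
        elif len(units) > 1:
            counts = [len(units)]
        else:
            break
        groups = _grouping(counts, len(units))
        lo, hi = spec.log10_ranges[depth]
        mid = (lo + hi) / 2.0
        for group in groups:
            hub_unit = group[0]
            for a_pos, ua in enumerate(group):
                for ub in group[a_pos + 1:]:
                    span = (lo, mid) if hub_unit in (ua, ub) else (mid, hi)
                    d = _sample_log_uniform(rng, *span)
                    for i in units[ua]:
                        for j in units[ub]:
                            put(i, j, d)
        group_partitions.append(groups)
        units = [sorted(x for u in group for x in units[u])
                 for group in groups]
        if len(units) == 1:
            break
        depth += 1
        if depth >= len(spec.log10_ranges):
            break

    dm = DistanceMatrix(ids=ids, values=values, meta="synthetic")

    # --- ground truth hierarchy
    partitions = [
        Partition(
            level=1,
            clusters=tuple(tuple(ids[i] for i in m) for m in fine),
            unit_kind=_unit_kind(1),
        )
    ]
    members_by_unit = [list(m) for m in fine]
    for level, groups in enumerate(group_partitions, start=2):
        clusters = []
        new_units = []
        for group in groups:
            merged = sorted(x for u in group for x in members_by_unit[u])
            new_units.append(merged)
            clusters.append(tuple(ids[i] for i in merged))
        partitions.append(
            Partition(level=level, clusters=tuple(clusters),
                      unit_kind=_unit_kind(level))
        )
        members_by_unit = new_units
    supers = tuple(_superdistance_matrix(dm, p) for p in partitions)
    truth = Hierarchy(levels=tuple(partitions), superdistances=supers)
    return dm, truth


def planted_classification_set(
    n_pos: int,
    n_neg: int,
    pos_max: float = 1e-4,
    neg_min: float = 1e-2,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Minimum distances with a planted positive/negative margin.

    Positives are log10-uniform over the six decades below ``pos_max``
    (the spec of the open interval (0, pos_max] has no finite log range);
    negatives are log10-uniform in [``neg_min``, 10].  The margin
    ``pos_max < neg_min`` is required, so a threshold inside it separates
    the classes perfectly.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one positive and one negative")
    if not pos_max < neg_min:
        raise ValueError("margin violated: pos_max must be < neg_min")
    rng = np.random.default_rng(seed)
    lp = np.log10(pos_max)
    pos = 10.0 ** rng.uniform(lp - 6.0, lp, size=n_pos)
    neg = 10.0 ** rng.uniform(np.log10(neg_min), 1.0, size=n_neg)
    d = np.concatenate([pos, neg])
    labels = ["positive"] * n_pos + ["negative"] * n_neg
    return d, labels


def random_evalue_table(
    n: int, asymmetry: float = 0.0, seed: int = 0
) -> EvalueTable:
    """Directed E-value table with controlled direction asymmetry.

    Each unordered pair gets a base log10 E-value uniform in [-100, 1];
    the two directions are jittered apart by up to ``asymmetry`` decades.
    With ``asymmetry = 0`` the table is exactly symmetric, so the
    symmetrized distance equals the E-value itself.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if asymmetry < 0:
        raise ValueError("asymmetry must be >= 0")
    rng = np.random.default_rng(seed)
    ids = [f"s{i:03d}" for i in range(n)]
    entries: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            base = rng.uniform(-100.0, 1.0)
            jitter = rng.uniform(-asymmetry, asymmetry) / 2.0
            fwd = 10.0 ** (base + jitter)
            rev = fwd if asymmetry == 0 else 10.0 ** (base - jitter)
            entries[(ids[i], ids[j])] = fwd
            entries[(ids[j], ids[i])] = rev
    return EvalueTable(entries=entries, ids=list(ids))
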