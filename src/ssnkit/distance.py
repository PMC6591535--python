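"""Symmetrized sequence distances from directed pairwise E-values.

The distance between sequences *i* and *j* is the geometric mean of the two
directed BLAST E-values, d_ij = sqrt(E_ij * E_ji).  E-values measure the
expected number of chance alignments at a given score, so a small value in
*both* search directions is strong evidence of homology; the geometric mean
symmetrizes the evidence on the log scale where E-values live.

A direction missing from the report is replaced by a cap (default 10, the
conventional BLAST reporting ceiling) before the product: unreported
similarity means "no better than threshold evidence", which keeps the
matrix total and conservative.  An E-value of exactly 0 is kept as exact 0
— zero-distance cores of near-identical sequences depend on it.

The module also provides the query-to-base distance vector used by the
membership classifier and the NRMSD diagnostic that validates computing
query distances against a fixed base dataset rather than base + query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputFormatError, InvariantError
from .io import EvalueTable

DEFAULT_E_CAP = 10.0


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric zero-diagonal matrix of distances over named units."""

    ids: tuple[str, ...]
    values: np.ndarray
    meta: str = "synthetic"

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(ids)
        if len(set(ids)) != n:
            raise InvariantError("duplicate unit ids")
        if values.shape != (n, n):
            raise InvariantError(
                f"matrix shape {values.shape} does not match {n} ids"
            )
        if not np.all(np.isfinite(values)):
            raise InvariantError("non-finite distance entries")
        if np.any(values < 0):
            raise InvariantError("negative distance entries")
        if not np.array_equal(values, values.T):
            raise InvariantError("distance matrix is not symmetric")
        if np.any(np.diag(values) != 0):
            raise InvariantError("nonzero diagonal")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        idx = self.index
        return float(self.values[idx[a], idx[b]])

    def subset(self, ids) -> "DistanceMatrix":
        idx = self.index
        order = [idx[i] for i in ids]
        return DistanceMatrix(
            ids=tuple(ids), values=self.values[np.ix_(order, order)],
            meta=self.meta,
        )


def geometric_mean_pair(a: float, b: float) -> float:
    """sqrt(a*b) computed without underflow for E-value-scale magnitudes.

    ``sqrt(a)*sqrt(b)`` keeps intermediates in range (1e-156 squared would
    underflow to 0 and silently create a spurious zero distance).  Equal
    inputs short-circuit so sqrt(E*E) == E exactly.
    """
    if a == b:
        return float(a)
    if a == 0.0 or b == 0.0:
        return 0.0
    return math.sqrt(a) * math.sqrt(b)


def symmetrize(
    ev: EvalueTable, e_cap: float = DEFAULT_E_CAP, meta: str = "blastp"
) -> DistanceMatrix:
    """Build the symmetrized distance matrix d_ij = sqrt(E_ij * E_ji).

    A missing direction is replaced by ``e_cap`` before the product; the
    diagonal is forced to 0 regardless of self-hits.  PSI-BLAST distances
    use this function unchanged on a PSI-BLAST-derived table
    (``meta="psiblast"``).
    """
    if e_cap <= 0:
        raise ValueError("e_cap must be > 0")
    ids = tuple(ev.ids)
    n = len(ids)
    if n < 2:
        raise InputFormatError("need at least 2 sequence ids to symmetrize")
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            e_ij = ev.get(ids[i], ids[j])
            e_ji = ev.get(ids[j], ids[i])
            d = geometric_mean_pair(
                e_ij if e_ij is not None else e_cap,
                e_ji if e_ji is not None else e_cap,
            )
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=ids, values=values, meta=meta)


@dataclass(frozen=True)
class QueryDistanceVector:
    """Distances from one query sequence to every base sequence."""

    query_id: str
    base_ids: tuple[str, ...]
    distances: tuple[float, ...]
    d_min: float = field(init=False)
    nearest: str = field(init=False)

    def __post_init__(self) -> None:
        if len(self.base_ids) != len(self.distances):
            raise InvariantError("base ids and distances differ in length")
        if not self.base_ids:
            raise InvariantError("empty base set")
        d = np.asarray(self.distances, dtype=float)
        d_min = float(d.min())
        # ties on the minimum break to the lexicographically smallest base id
        nearest = min(
            b for b, x in zip(self.base_ids, self.distances) if x == d_min
        )
        object.__setattr__(self, "d_min", d_min)
        object.__setattr__(self, "nearest", nearest)


def query_distances(
    hits: EvalueTable,
    query_id: str,
    base_ids,
    e_cap: float = DEFAULT_E_CAP,
) -> QueryDistanceVector:
    """Distance from one query to every base sequence.

    ``hits`` holds the directed E-values of the query against the base set
    (either direction may be missing; missing pairs fall back to
    sqrt(e_cap * e_cap) = e_cap).
    """
    if e_cap <= 0:
        raise ValueError("e_cap must be > 0")
    base_ids = tuple(base_ids)
    if not base_ids:
        raise ValueError("base_ids must be non-empty")
    distances = []
    for b in base_ids:
        e_qb = hits.get(query_id, b)
        e_bq = hits.get(b, query_id)
        distances.append(
            geometric_mean_pair(
                e_qb if e_qb is not None else e_cap,
                e_bq if e_bq is not None else e_cap,
            )
        )
    return QueryDistanceVector(
        query_id=query_id, base_ids=base_ids, distances=tuple(distances)
    )


def nrmsd(d_base, d_base_query) -> float:
    """Normalized root mean square deviation between two distance vectors.

    NRMSD = sqrt(mean_i (1 - d_i^b / d_i^{b+q})^2), pairing distances
    computed against the base dataset with distances computed against the
    base + query dataset.  A 0/0 pair is a perfect agreement (ratio 1,
    contribution 0); a zero base+query distance against a nonzero base
    distance leaves the ratio undefined and raises ``ValueError``.
    """
    d_b = np.asarray(d_base, dtype=float)
    d_bq = np.asarray(d_base_query, dtype=float)
    if d_b.shape != d_bq.shape or d_b.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if d_b.size == 0:
        raise ValueError("empty input")
    if np.any(d_b < 0) or np.any(d_bq < 0):
        raise ValueError("distances must be nonnegative")
    undefined = (d_bq == 0) & (d_b != 0)
    if np.any(undefined):
        raise ValueError(
            "d_base_query == 0 with d_base != 0: ratio undefined"
        )
    ratio = np.ones_like(d_b)
    ok = d_bq > 0
    ratio[ok] = d_b[ok] / d_bq[ok]
    return float(np.sqrt(np.mean((1.0 - ratio) ** 2)))
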