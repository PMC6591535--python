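"""Shared fixtures: tiny distance matrices and random networks."""

from __future__ import annotations

import numpy as np
import pytest

from ssnkit.centrality import SimilarityNetwork
from ssnkit.distance import DistanceMatrix


def make_distance_matrix(ids, pairs, default=1.0) -> DistanceMatrix:
    """Build a DistanceMatrix from {(a, b): d} with a default elsewhere."""
    ids = tuple(ids)
    n = len(ids)
    index = {name: i for i, name in enumerate(ids)}
    values = np.full((n, n), float(default))
    np.fill_diagonal(values, 0.0)
    for (a, b), d in pairs.items():
        values[index[a], index[b]] = values[index[b], index[a]] = float(d)
    return DistanceMatrix(ids=ids, values=values)


def random_connected_network(rng, n_max=6) -> SimilarityNetwork:
    """Random connected weighted graph with generic (tie-free) lengths."""
    n = int(rng.integers(2, n_max + 1))
    lengths = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    # random spanning tree first to guarantee connectivity
    order = rng.permutation(n)
    for pos in range(1, n):
        a, b = order[pos], order[int(rng.integers(0, pos))]
        mask[a, b] = mask[b, a] = True
    extra = rng.random((n, n)) < 0.4
    mask |= np.triu(extra, 1) | np.triu(extra, 1).T
    np.fill_diagonal(mask, False)
    vals = rng.uniform(0.05, 2.0, size=(n, n))
    vals = np.triu(vals, 1)
    lengths = vals + vals.T
    lengths[~mask] = 0.0
    ids = tuple(f"n{i}" for i in range(n))
    return SimilarityNetwork.from_lengths(ids, lengths, mask=mask)


def random_distance_matrix(rng, n) -> DistanceMatrix:
    """Dense random matrix with log-uniform E-value-scale distances."""
    log10 = rng.uniform(-120.0, 0.0, size=(n, n))
    vals = 10.0 ** np.triu(log10, 1)
    vals = np.where(np.triu(np.ones((n, n)), 1) > 0, vals, 0.0)
    vals = vals + vals.T
    ids = tuple(f"s{i:02d}" for i in range(n))
    return DistanceMatrix(ids=ids, values=vals)


@pytest.fixture
def dm_factory():
    return make_distance_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
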