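import dataclasses

import numpy as np
import pytest

from sgfc.core import euclidean_distances
from sgfc.matrices import FunctionalConnectome, StructuralConnectome
from sgfc.regions import RegionSet
from sgfc.synth import SynthParams, generate_fc, generate_regions, generate_sc


def tiny_instance(seed: int, n: int = 12, density: float = 0.3):
    """Small dense instance: regions, SC, FC, distances.

    Planted edges are disabled (tiny sets rarely have eligible
    long-range unconnected pairs).
    """
    params = SynthParams(
        n_regions=max(n, 8),
        sc_density_target=density,
        planted_edge_count=0,
        seed=seed,
    )
    regions = generate_regions(params.n_regions, seed)
    sc = generate_sc(regions, params)
    if sc.n_edges < 5:  # ensure a usable reference distribution
        params = dataclasses.replace(params, sc_density_target=min(0.6, 2 * density))
        sc = generate_sc(regions, params)
    fc, _ = generate_fc(regions, sc, params)
    return regions, sc, fc, euclidean_distances(regions)


@pytest.fixture
def small_instance():
    return tiny_instance(seed=7, n=16)


@pytest.fixture
def medium_instance():
    """200-node instance at the default study conditions."""
    params = SynthParams(seed=11)
    regions = generate_regions(params.n_regions, params.seed)
    sc = generate_sc(regions, params)
    fc, planted = generate_fc(regions, sc, params)
    return regions, sc, fc, planted, euclidean_distances(regions)


def hand_regions(centroids, hemisphere=None):
    centroids = np.asarray(centroids, float)
    n = len(centroids)
    if hemisphere is None:
        hemisphere = np.array(["left"] * n, dtype=object)
    return RegionSet(
        region_id=np.arange(n),
        centroids=centroids,
        hemisphere=np.asarray(hemisphere, dtype=object),
    )


def sym(mat):
    m = np.asarray(mat, float)
    return (m + m.T) / 2.0


def sc_from_edges(n, edges, weight=1.0):
    w = np.zeros((n, n))
    for e in edges:
        i, j = e[0], e[1]
        wt = e[2] if len(e) > 2 else weight
        w[i, j] = w[j, i] = wt
    return StructuralConnectome(weights=w)


def fc_from_upper(n, entries):
    """entries: dict {(i, j): value}; rest zero."""
    w = np.zeros((n, n))
    for (i, j), v in entries.items():
        w[i, j] = w[j, i] = v
    np.fill_diagonal(w, 1.0)
    return FunctionalConnectome(weights=w)
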