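"""Shared fixtures: tiny hand-built graphs and an independent scoring oracle."""

from __future__ import annotations

import numpy as np
import pytest

from phenotether.net_io import AnnotationSet, PhenotypeScheme, WeightedNetwork


def brute_force_potential(edge_weights, labels, query, seeds, K):
    """Independent tethering-potential oracle.

    Works directly on a ``{frozenset({a, b}): weight}`` dict and a
    ``{protein: set of categories}`` dict, summing w(query, s) into every
    category of every seed s != query. Deliberately avoids the package's
    graph container and neighbor iteration.
    """
    F = [0] * K
    for s in seeds:
        if s == query:
            continue
        w = edge_weights.get(frozenset((query, s)), 0)
        if w:
            for j in labels[s]:
                F[j - 1] += w
    return F


def random_instance(rng: np.random.Generator, max_nodes: int = 30):
    """A random labeled weighted graph plus its raw edge/label dicts."""
    n = int(rng.integers(2, max_nodes + 1))
    K = int(rng.integers(2, 7))
    names = [f"N{i:02d}" for i in range(n)]
    edge_weights = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                edge_weights[frozenset((names[i], names[j]))] = int(rng.integers(1, 1000))
    labels = {
        p: set(rng.choice(K, size=int(rng.integers(1, K + 1)), replace=False) + 1)
        for p in names
    }
    net = WeightedNetwork.from_edges(
        (min(pair), max(pair), w) for pair, w in edge_weights.items()
    )
    scheme = PhenotypeScheme.generic(K)
    annotations = AnnotationSet(labels, scheme)
    return net, annotations, scheme, edge_weights, labels, names


@pytest.fixture
def oracle():
    return brute_force_potential


@pytest.fixture
def scheme3():
    return PhenotypeScheme(("alpha", "beta", "gamma"))


@pytest.fixture
def path_graph(scheme3):
    """3-node path A(cat 1) - B(cat 2) - C(cat 1) with equal weights."""
    net = WeightedNetwork.from_edges([("A", "B", 500), ("B", "C", 500)])
    ann = AnnotationSet({"A": {1}, "B": {2}, "C": {1}}, scheme3)
    return net, ann, scheme3
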