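"""Planted-label synthetic data: networks, annotations and membership tables.

The generator emulates the statistical structure the tethering-potential
method relies on — interacting proteins tend to share phenotypes. Nodes
receive hidden category labels; each unordered pair is connected with
probability ``p_in`` when the two nodes share at least one label and
``p_out`` otherwise (a multi-label planted-partition model). Edge weights
are drawn uniformly from the confidence band of the real data (900-999 by
default). A ``multi_label_rate`` fraction of nodes gains a second random
label, connecting them to both label communities (a minimal model of
pleiotropy), and an ``unlabeled_fraction`` of nodes has its labels
stripped to serve as prediction targets.

Membership tables are block-structured: each category owns a block of
synthetic "complexes" its proteins join, with a configurable probability
of also joining a complex of another category (controlling how separable
the phenotypes look to the cosine-similarity analysis).

The generator makes no attempt to match the degree distribution of a real
interactome; it provides controlled assortativity, not realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .net_io import (
    AnnotationSet,
    MembershipTable,
    PhenotypeScheme,
    WeightedNetwork,
    write_annotations,
    write_edge_list,
    write_membership,
)

__all__ = ["SyntheticConfig", "generate", "write_fixture"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-label generator.

    Defaults mirror the study conditions of the yeast analysis: K = 11
    categories, a mean of about 1.7 phenotypes per annotated protein
    (``1 + multi_label_rate``), and edge confidences in the STRING
    "highest confidence" band 900-999. ``n_per_category`` is kept small
    (30) so a full jackknife over the synthetic seed set runs in seconds.
    """

    K: int = 11
    n_per_category: int = 30
    p_in: float = 0.3
    p_out: float = 0.01
    weight_range: tuple[int, int] = (900, 999)
    multi_label_rate: float = 0.7
    unlabeled_fraction: float = 0.1
    complexes_per_category: int = 5
    membership_overlap: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.n_per_category < 2:
            raise ValueError("n_per_category must be >= 2")
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        lo, hi = self.weight_range
        if not 0 <= lo <= hi <= 999:
            raise ValueError("weight_range must lie within 0..999")
        for name in ("multi_label_rate", "unlabeled_fraction", "membership_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.complexes_per_category < 1:
            raise ValueError("complexes_per_category must be >= 1")

    @property
    def n_nodes(self) -> int:
        return self.K * self.n_per_category

    def scheme(self) -> PhenotypeScheme:
        return PhenotypeScheme.generic(self.K)


def generate(
    config: SyntheticConfig,
) -> tuple[WeightedNetwork, AnnotationSet, MembershipTable]:
    """Draw one synthetic (network, annotations, membership) triple.

    Bit-reproducible for a fixed ``config.seed``. Stripped (unlabeled)
    nodes keep the edges their hidden labels produced but are absent from
    the annotation set and the membership table — they are the prediction
    targets. Isolated nodes can occur at low edge probabilities; they stay
    in the node universe only if they retained at least one edge.
    """
    rng = np.random.default_rng(config.seed)
    n, K = config.n_nodes, config.K
    names = [f"S{c + 1:02d}_{i:03d}" for c in range(K) for i in range(config.n_per_category)]

    # hidden multi-label assignment: base label by block, optional second label
    labels = np.zeros((n, K), dtype=bool)
    base = np.repeat(np.arange(K), config.n_per_category)
    labels[np.arange(n), base] = True
    extra_mask = rng.random(n) < config.multi_label_rate
    second = (base + rng.integers(1, K, size=n)) % K  # uniform over the other K-1
    labels[np.arange(n)[extra_mask], second[extra_mask]] = True

    # planted-partition edges with confidence-band weights
    share = (labels.astype(np.int8) @ labels.T.astype(np.int8)) > 0
    prob = np.where(share, config.p_in, config.p_out)
    iu, ju = np.triu_indices(n, k=1)
    hit = rng.random(len(iu)) < prob[iu, ju]
    lo, hi = config.weight_range
    weights = rng.integers(lo, hi + 1, size=int(hit.sum()))
    net = WeightedNetwork.from_edges(
        (names[i], names[j], int(w)) for i, j, w in zip(iu[hit], ju[hit], weights)
    )

    # strip a fraction of nodes: they become unlabeled prediction targets
    n_strip = int(round(config.unlabeled_fraction * n))
    stripped = set(rng.choice(n, size=n_strip, replace=False).tolist())

    ann = {
        names[v]: {int(c) + 1 for c in np.flatnonzero(labels[v])}
        for v in range(n)
        if v not in stripped
    }
    scheme = config.scheme()
    annotations = AnnotationSet(ann, scheme)

    # block membership: each category owns a complex block; proteins join
    # 1-2 complexes per own label, plus (with prob. membership_overlap) one
    # complex of a random other category
    features = [
        f"CPX{c + 1:02d}_{k + 1}" for c in range(K) for k in range(config.complexes_per_category)
    ]
    cpc = config.complexes_per_category
    membership: dict[str, frozenset[str]] = {}
    for v in range(n):
        if v in stripped:
            continue
        feats: set[str] = set()
        for c in np.flatnonzero(labels[v]):
            n_join = 1 + int(rng.random() < 0.5)
            for k in rng.choice(cpc, size=min(n_join, cpc), replace=False):
                feats.add(features[int(c) * cpc + int(k)])
        if rng.random() < config.membership_overlap:
            other = int((base[v] + rng.integers(1, K)) % K)
            feats.add(features[other * cpc + int(rng.integers(cpc))])
        membership[names[v]] = frozenset(feats)
    table = MembershipTable(membership, feature_universe=tuple(features))

    return net, annotations, table


def write_fixture(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate one triple and write it in the TSV dialects the readers consume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    net, ann, mem = generate(config)
    paths = {
        "network": out_dir / "network.tsv",
        "annotations": out_dir / "annotations.tsv",
        "membership": out_dir / "membership.tsv",
        "scheme": out_dir / "scheme.tsv",
    }
    write_edge_list(net, paths["network"])
    write_annotations(ann, paths["annotations"])
    write_membership(mem, paths["membership"])
    scheme = config.scheme()
    with open(paths["scheme"], "w", encoding="utf-8") as fh:
        for i in scheme.indices:
            fh.write(f"{i}\t{scheme.label(i)}\n")
    return paths
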