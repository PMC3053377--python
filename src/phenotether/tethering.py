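"""Tethering-potential scoring and ranked phenotype prediction.

The score of a query protein q for phenotype category j is the sum of
interaction confidences between q and the seed proteins annotated with j:

    F_j(q) = sum_{s in seeds, j in labels(s)} w(q, s)

with w(q, s) = 0 when q and s do not interact and w(q, q) = 0 (a protein
never votes for itself). Categories are then ranked by descending F_j; runs
of equal scores are ordered uniformly at random by an explicit, seedable
random generator so that ties carry no hidden ordering bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .net_io import AnnotationSet, PhenotypeScheme, WeightedNetwork, seed_set

__all__ = [
    "ScoreVector",
    "RankedPrediction",
    "interaction_weights",
    "tethering_potential",
    "top_category",
    "rank_prediction",
    "predict_unlabeled",
    "write_predictions",
]


@dataclass(frozen=True)
class ScoreVector:
    """The K tethering potentials of one query protein.

    ``scores[j-1]`` is F_j on the raw summed-confidence scale (integers for
    0-999 confidence inputs). ``query_in_network`` is False when the query
    is not a node of the network, in which case all scores are zero.
    """

    query: str
    scores: np.ndarray
    query_in_network: bool = True

    @property
    def K(self) -> int:
        return len(self.scores)

    @property
    def all_zero(self) -> bool:
        return not np.any(self.scores)


@dataclass(frozen=True)
class RankedPrediction:
    """Phenotype categories of one query sorted by descending tethering potential.

    ``order`` is a permutation of 1..K; ``sorted_scores`` the scores in that
    order (non-increasing); ``tie_groups`` partitions the 1-based ranks into
    maximal runs of equal score, recording where the ordering was decided by
    the tie-breaking RNG rather than the data. ``all_zero`` marks queries
    with no annotated interaction partner at all — their entire ranking is a
    single random tie group.
    """

    query: str
    order: tuple[int, ...]
    sorted_scores: np.ndarray
    tie_groups: tuple[tuple[int, ...], ...]
    all_zero: bool

    @property
    def K(self) -> int:
        return len(self.order)

    def top(self, r: int = 1) -> tuple[int, ...]:
        """The first ``r`` ranked category indices."""
        return self.order[:r]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def interaction_weights(
    network: WeightedNetwork, query: str, seeds: Iterable[str]
) -> np.ndarray:
    """Vector of edge confidences between the query and each seed protein.

    Entry k is w(query, seed_k): 0 when there is no edge, and 0 when the
    seed is the query itself (no self-interaction).
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed list must be nonempty")
    if query not in network:
        return np.zeros(len(seeds), dtype=np.int64)
    return np.array([network.weight(query, s) for s in seeds], dtype=np.int64)


def tethering_potential(
    network: WeightedNetwork,
    query: str,
    annotations: AnnotationSet,
    seeds: Iterable[str],
    scheme: PhenotypeScheme,
) -> ScoreVector:
    """Compute the K-vector of tethering potentials F_j for one query.

    Only seeds adjacent to the query contribute; each contributes its edge
    confidence to every category it is annotated with. The query itself
    never contributes, even if listed among the seeds.
    """
    seed_pool = set(seeds)
    missing = [s for s in seed_pool if s not in annotations]
    if missing:
        raise ValueError(f"seeds without annotation: {sorted(missing)[:5]}")
    scores = np.zeros(scheme.K, dtype=np.int64)
    in_network = query in network
    if in_network:
        for nbr in network.neighbors(query):
            if nbr == query or nbr not in seed_pool:
                continue
            w = network.weight(query, nbr)
            for j in annotations[nbr]:
                scores[j - 1] += w
    return ScoreVector(query=query, scores=scores, query_in_network=in_network)


def top_category(
    scores: ScoreVector, rng: np.random.Generator | int | None = None
) -> int | None:
    """Category index with the maximal tethering potential, or None.

    Returns ``None`` ("unpredictable") when every score is zero. A tie at
    the maximum is resolved by the same randomized policy as
    :func:`rank_prediction`: the first member of the shuffled tie group.
    """
    if scores.all_zero:
        return None
    return rank_prediction(scores, rng).order[0]


def rank_prediction(
    scores: ScoreVector, rng: np.random.Generator | int | None = None
) -> RankedPrediction:
    """Sort the categories by descending score, randomizing equal-score runs.

    A uniformly random permutation of the categories is drawn first and a
    stable descending sort applied on top of it, so each maximal run of
    tied scores ends up in uniformly random order. With no ties the result
    is independent of the RNG.
    """
    rng = _as_rng(rng)
    s = scores.scores
    perm = rng.permutation(scores.K)
    sorted_idx = perm[np.argsort(-s[perm], kind="stable")]
    order = tuple(int(i) + 1 for i in sorted_idx)
    sorted_scores = s[sorted_idx]

    tie_groups: list[tuple[int, ...]] = []
    start = 0
    for i in range(1, scores.K + 1):
        if i == scores.K or sorted_scores[i] != sorted_scores[start]:
            tie_groups.append(tuple(range(start + 1, i + 1)))
            start = i
    return RankedPrediction(
        query=scores.query,
        order=order,
        sorted_scores=sorted_scores,
        tie_groups=tuple(tie_groups),
        all_zero=scores.all_zero,
    )


def predict_unlabeled(
    network: WeightedNetwork,
    annotations: AnnotationSet,
    scheme: PhenotypeScheme,
    rng: np.random.Generator | int | None = None,
) -> dict[str, RankedPrediction]:
    """Ranked phenotype predictions for every network node without annotation.

    The full seed set (annotated network nodes) votes for each unlabeled
    node; in the yeast network this scores the 2,942 proteins that carry
    no phenotype annotation of their own.
    """
    rng = _as_rng(rng)
    seeds = seed_set(annotations, network)
    out: dict[str, RankedPrediction] = {}
    for node in sorted(network.nodes):
        if node in annotations:
            continue
        sv = tethering_potential(network, node, annotations, seeds, scheme)
        out[node] = rank_prediction(sv, rng)
    return out


def write_predictions(
    predictions: Mapping[str, RankedPrediction],
    scheme: PhenotypeScheme,
    path: str | Path,
) -> None:
    """Write ranked predictions as a TSV, one row per (protein, rank)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein\trank\tcategory_index\tcategory_label\tscore\tall_zero\n")
        for protein in sorted(predictions):
            pred = predictions[protein]
            for rank, (cat, score) in enumerate(zip(pred.order, pred.sorted_scores), 1):
                fh.write(
                    f"{protein}\t{rank}\t{cat}\t{scheme.label(cat)}\t"
                    f"{int(score)}\t{pred.all_zero}\n"
                )
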