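"""Re-prediction of a query's phenotypes after inactivating an interacting protein.

Inactivation is modelled as deleting the chosen protein — node and all
incident edges — from the network, then re-scoring the query against the
remaining seed proteins. Because the tethering potential is strictly
one-hop, only removal of a direct neighbor of the query can change its
ranking. In both the intact and the broken condition the query's own
annotation is withheld (the same leave-one-out condition used in the
jackknife), so the baseline column of a knockout table is directly
comparable with jackknife output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .net_io import AnnotationSet, PhenotypeScheme, WeightedNetwork, seed_set
from .tethering import RankedPrediction, _as_rng, rank_prediction, tethering_potential

__all__ = ["KnockoutResult", "inactivate_and_predict", "write_knockout_results"]


@dataclass(frozen=True)
class KnockoutResult:
    """Before/after rankings for one (query, removed) pair."""

    query: str
    removed: str
    baseline: RankedPrediction  # intact network
    knockout: RankedPrediction  # removed node deleted

    @property
    def baseline_top(self) -> int:
        return self.baseline.order[0]

    @property
    def knockout_top(self) -> int:
        return self.knockout.order[0]

    @property
    def top_changed(self) -> bool:
        return self.baseline_top != self.knockout_top


def inactivate_and_predict(
    network: WeightedNetwork,
    annotations: AnnotationSet,
    scheme: PhenotypeScheme,
    query: str,
    removed: str,
    rng: np.random.Generator | int | None = None,
) -> KnockoutResult:
    """Score ``query`` on the intact network and with ``removed`` deleted.

    ``removed`` must be a network node distinct from the query. If the
    query becomes isolated from all seeds, its knockout prediction is an
    all-zero (fully random-order) ranking.
    """
    if removed not in network:
        raise ValueError(f"{removed!r} is not a node of the network")
    if query == removed:
        raise ValueError("query and removed protein must differ")
    rng = _as_rng(rng)

    voters = set(seed_set(annotations, network)) - {query}
    sv_base = tethering_potential(network, query, annotations, voters, scheme)
    baseline = rank_prediction(sv_base, rng)

    broken = network.copy()
    broken.remove_node(removed)
    voters_ko = set(seed_set(annotations, broken)) - {query}
    sv_ko = tethering_potential(broken, query, annotations, voters_ko, scheme)
    knockout = rank_prediction(sv_ko, rng)
    return KnockoutResult(query=query, removed=removed, baseline=baseline, knockout=knockout)


def write_knockout_results(
    results: Iterable[KnockoutResult], scheme: PhenotypeScheme, path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "query\tremoved\tbaseline_top_index\tbaseline_top_label\t"
            "knockout_top_index\tknockout_top_label\ttop_changed\n"
        )
        for r in results:
            fh.write(
                f"{r.query}\t{r.removed}\t{r.baseline_top}\t"
                f"{scheme.label(r.baseline_top)}\t{r.knockout_top}\t"
                f"{scheme.label(r.knockout_top)}\t{r.top_changed}\n"
            )
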