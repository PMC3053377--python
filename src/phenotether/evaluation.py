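"""Leave-one-out (jackknife) cross-validation and ranking-quality statistics.

Each seed protein is in turn treated as an unannotated query: its own
phenotype labels are withheld and the remaining seed proteins vote through
their interaction confidences. Three statistics summarise the resulting
rankings over the N seed proteins:

* the i-th order accuracy A_i — the percentage of proteins whose rank-i
  category is among their true phenotypes;
* the mean phenotype count M — the average size of the true label sets;
* the inclusion likelihood L(r) — the percentage of proteins whose entire
  true label set lies within the top r ranked categories.

Because every true label occupies exactly one rank in a full permutation,
the order accuracies always satisfy sum_i A_i = 100 * M; a useful ranking
concentrates that mass at the low orders. The comparison point is a random
guess, which succeeds with probability M/K per draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .net_io import AnnotationSet, PhenotypeScheme, WeightedNetwork, seed_set
from .tethering import RankedPrediction, _as_rng, rank_prediction, tethering_potential

__all__ = [
    "EvaluationReport",
    "jackknife",
    "order_accuracies",
    "mean_phenotype_count",
    "random_baseline",
    "inclusion_likelihood",
    "evaluate",
]


def jackknife(
    network: WeightedNetwork,
    annotations: AnnotationSet,
    scheme: PhenotypeScheme,
    rng: np.random.Generator | int | None = None,
) -> dict[str, RankedPrediction]:
    """One ranked prediction per seed protein, with that protein left out.

    The query's own annotations are removed from the voter pool; its node
    and edges stay in the network. (Since a protein's self-interaction
    weight is zero this coincides with scoring against the full seed set,
    but the exclusion is made explicit here.)
    """
    rng = _as_rng(rng)
    seeds = seed_set(annotations, network)
    if not seeds:
        raise ValueError("seed set is empty")
    seed_pool = set(seeds)
    out: dict[str, RankedPrediction] = {}
    for query in seeds:
        voters = seed_pool - {query}
        sv = tethering_potential(network, query, annotations, voters, scheme)
        out[query] = rank_prediction(sv, rng)
    return out


def order_accuracies(
    predictions: Mapping[str, RankedPrediction], annotations: AnnotationSet
) -> np.ndarray:
    """A_i for i = 1..K, as percentages of the N predicted proteins."""
    if not predictions:
        raise ValueError("empty prediction map")
    K = next(iter(predictions.values())).K
    hits = np.zeros(K, dtype=np.int64)
    for protein, pred in predictions.items():
        truth = annotations[protein]
        for rank, cat in enumerate(pred.order):
            if cat in truth:
                hits[rank] += 1
    return 100.0 * hits / len(predictions)


def mean_phenotype_count(annotations: AnnotationSet, proteins: Sequence[str]) -> float:
    """Arithmetic mean of the true label-set sizes over the given proteins."""
    if not proteins:
        raise ValueError("empty protein list")
    return float(np.mean([len(annotations[p]) for p in proteins]))


def random_baseline(mean_count: float, K: int) -> float:
    """Success chance (%) of a single random phenotype guess: 100 * M / K."""
    if not 0 < mean_count <= K:
        raise ValueError("mean phenotype count must lie in (0, K]")
    return 100.0 * mean_count / K


def inclusion_likelihood(
    predictions: Mapping[str, RankedPrediction],
    annotations: AnnotationSet,
    r: int,
) -> float:
    """L(r): percentage of proteins whose whole label set is in the top r ranks."""
    if not predictions:
        raise ValueError("empty prediction map")
    K = next(iter(predictions.values())).K
    if not 1 <= r <= K:
        raise ValueError(f"r must lie in 1..{K}")
    n_included = sum(
        annotations[p] <= set(pred.top(r)) for p, pred in predictions.items()
    )
    return 100.0 * n_included / len(predictions)


@dataclass(frozen=True)
class EvaluationReport:
    """Bundle of jackknife statistics over one seed set."""

    order_accuracies: np.ndarray  # A_i (%), length K
    mean_phenotype_count: float  # M, phenotypes per protein
    inclusion_likelihood: dict[int, float]  # r -> L(r) (%)
    random_baseline: float  # 100 * M / K (%)
    n_proteins: int  # N
    seed: int | None = None  # tie-breaking RNG seed, for the record
    n_repeats: int = 1

    @property
    def K(self) -> int:
        return len(self.order_accuracies)

    def summary(self, scheme: PhenotypeScheme | None = None) -> str:
        """Human-readable report, percentages at 3 significant figures."""
        lines = [
            f"Jackknife evaluation over N = {self.n_proteins} seed proteins "
            f"(K = {self.K} categories)",
            f"mean phenotypes per protein  M = {self.mean_phenotype_count:.3g}",
            f"random-guess baseline        {self.random_baseline:.3g}%",
            "",
            "order i    A_i (%)",
        ]
        for i, a in enumerate(self.order_accuracies, 1):
            lines.append(f"{i:>7}    {a:.3g}")
        lines.append("")
        for r in sorted(self.inclusion_likelihood):
            lines.append(f"L({r}) = {self.inclusion_likelihood[r]:.3g}%")
        if self.seed is not None:
            lines.append(f"tie-break seed: {self.seed} ({self.n_repeats} pass(es))")
        return "\n".join(lines)

    def write_tsv(self, path: str | Path) -> None:
        """One row per order i, plus a key-value block of the scalars."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("order\taccuracy_pct\n")
            for i, a in enumerate(self.order_accuracies, 1):
                fh.write(f"{i}\t{a:.6g}\n")

    def write_summary_kv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"n_proteins\t{self.n_proteins}\n")
            fh.write(f"mean_phenotype_count\t{self.mean_phenotype_count:.6g}\n")
            fh.write(f"random_baseline_pct\t{self.random_baseline:.6g}\n")
            for r in sorted(self.inclusion_likelihood):
                fh.write(f"L({r})_pct\t{self.inclusion_likelihood[r]:.6g}\n")
            fh.write(f"seed\t{self.seed}\n")
            fh.write(f"n_repeats\t{self.n_repeats}\n")


def evaluate(
    network: WeightedNetwork,
    annotations: AnnotationSet,
    scheme: PhenotypeScheme,
    rng: int | None = 0,
    r_values: Iterable[int] = (1, 2, 3),
    n_repeats: int = 1,
) -> EvaluationReport:
    """Run the jackknife once (or ``n_repeats`` times) and derive all statistics.

    The tie-breaking randomness makes A_i and L(r) weakly stochastic;
    ``n_repeats > 1`` averages the percentages over independent tie-break
    passes of the same leave-one-out protocol.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    base_seed = rng
    gen = _as_rng(rng)
    r_values = sorted(set(int(r) for r in r_values))

    acc = np.zeros(scheme.K)
    incl = dict.fromkeys(r_values, 0.0)
    seeds = None
    for _ in range(n_repeats):
        preds = jackknife(network, annotations, scheme, gen)
        if seeds is None:
            seeds = sorted(preds)
        acc += order_accuracies(preds, annotations)
        for r in r_values:
            incl[r] += inclusion_likelihood(preds, annotations, r)
    acc /= n_repeats
    incl = {r: v / n_repeats for r, v in incl.items()}

    m = mean_phenotype_count(annotations, seeds)
    return EvaluationReport(
        order_accuracies=acc,
        mean_phenotype_count=m,
        inclusion_likelihood=incl,
        random_baseline=random_baseline(m, scheme.K),
        n_proteins=len(seeds),
        seed=base_seed if isinstance(base_seed, int) else None,
        n_repeats=n_repeats,
    )
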