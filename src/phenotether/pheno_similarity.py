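"""Phenotype separability from complex/pathway membership.

Rationale for network-based phenotype transfer: physically interacting
proteins share complexes and functionally interacting proteins share
pathways, so if distinct phenotypes occupy distinct complex/pathway
neighbourhoods they can be told apart through the interaction network.

To quantify this, each phenotype category is represented by a count vector
over the feature universe (complexes or pathways): the component-wise sum
of the binary membership indicator vectors of its single-phenotype
proteins. Pairwise cosine similarity of these vectors then measures how
confusable two phenotypes are; pairs above a threshold (0.5 by convention)
are considered hard to discriminate from membership alone. Cosine
similarity is invariant to positive rescaling, so summing indicators is
equivalent to averaging them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .net_io import AnnotationSet, MembershipTable, PhenotypeScheme

__all__ = [
    "PhenotypeVector",
    "SimilarityMatrix",
    "SimilaritySummary",
    "UndefinedSimilarityError",
    "single_phenotype_proteins",
    "phenotype_vector",
    "cosine_similarity",
    "similarity_profile",
]


class UndefinedSimilarityError(ValueError):
    """Cosine similarity is undefined against an all-zero vector."""


@dataclass(frozen=True)
class PhenotypeVector:
    """Per-complex (or per-pathway) protein counts for one phenotype category."""

    category: int
    counts: np.ndarray  # length = |feature universe|, entries >= 0
    n_proteins: int  # single-phenotype proteins aggregated

    @property
    def is_zero(self) -> bool:
        return not np.any(self.counts)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise cosine similarities over the categories with
    nonzero membership vectors (unit diagonal)."""

    values: np.ndarray  # K' x K', in [0, 1]
    categories: tuple[int, ...]  # the K' retained category indices

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def pair_values(self) -> list[tuple[int, int, float]]:
        """The K'(K'-1)/2 upper-triangle entries as (cat_a, cat_b, similarity)."""
        out = []
        for i in range(self.n_categories):
            for j in range(i + 1, self.n_categories):
                out.append(
                    (self.categories[i], self.categories[j], float(self.values[i, j]))
                )
        return out

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("category\t" + "\t".join(str(c) for c in self.categories) + "\n")
            for i, c in enumerate(self.categories):
                row = "\t".join(f"{v:.6g}" for v in self.values[i])
                fh.write(f"{c}\t{row}\n")


@dataclass(frozen=True)
class SimilaritySummary:
    """Numeric distribution of the pairwise similarities."""

    bin_edges: np.ndarray
    bin_counts: np.ndarray
    n_pairs: int
    n_below_threshold: int
    threshold: float

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("bin_lower_edge\tcount\n")
            for lo, c in zip(self.bin_edges[:-1], self.bin_counts):
                fh.write(f"{lo:.6g}\t{int(c)}\n")


def single_phenotype_proteins(annotations: AnnotationSet) -> list[str]:
    """Proteins annotated with exactly one phenotype category."""
    return [p for p in annotations.proteins if len(annotations[p]) == 1]


def phenotype_vector(
    category: int,
    proteins: Sequence[str],
    annotations: AnnotationSet,
    membership: MembershipTable,
) -> PhenotypeVector:
    """Aggregate the binary membership indicators of a category's proteins.

    ``proteins`` must be single-phenotype; those labeled with ``category``
    contribute their 0/1 indicator vector over the feature universe.
    Proteins explicitly flagged "no annotation" (or absent from the
    membership table) contribute a zero vector. A category with no
    contributing membership yields an all-zero vector.
    """
    multi = [p for p in proteins if len(annotations[p]) != 1]
    if multi:
        raise ValueError(f"not single-phenotype: {multi[:5]}")
    index = {f: i for i, f in enumerate(membership.feature_universe)}
    counts = np.zeros(len(index), dtype=np.int64)
    n = 0
    for p in proteins:
        if category not in annotations[p]:
            continue
        n += 1
        for f in membership.features_of(p):
            counts[index[f]] += 1
    return PhenotypeVector(category=category, counts=counts, n_proteins=n)


def cosine_similarity(u, v) -> float:
    """Inner product over the product of Euclidean norms; in [0, 1] for
    non-negative vectors. Raises :class:`UndefinedSimilarityError` on a
    zero vector."""
    a = np.asarray(u.counts if isinstance(u, PhenotypeVector) else u, dtype=float)
    b = np.asarray(v.counts if isinstance(v, PhenotypeVector) else v, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def similarity_profile(
    annotations: AnnotationSet,
    membership: MembershipTable,
    scheme: PhenotypeScheme,
    threshold: float = 0.5,
    n_bins: int = 10,
    restrict_to: Sequence[str] | None = None,
) -> tuple[SimilarityMatrix, SimilaritySummary]:
    """Pairwise phenotype similarities and their numeric distribution.

    Phenotype vectors are built from all single-phenotype proteins of the
    annotation set (optionally restricted, e.g. to the seed set).
    Categories whose vector is all zero — no complex/pathway annotation at
    all — are dropped from the matrix rather than reported as NaN rows.
    """
    proteins = single_phenotype_proteins(annotations)
    if restrict_to is not None:
        keep = set(restrict_to)
        proteins = [p for p in proteins if p in keep]
    vectors = [
        phenotype_vector(c, proteins, annotations, membership) for c in scheme.indices
    ]
    nonzero = [v for v in vectors if not v.is_zero]
    if len(nonzero) < 2:
        raise ValueError(
            f"need at least 2 categories with nonzero membership vectors, "
            f"got {len(nonzero)}"
        )
    kept = tuple(v.category for v in nonzero)
    Kp = len(kept)
    values = np.eye(Kp)
    for i in range(Kp):
        for j in range(i + 1, Kp):
            values[i, j] = values[j, i] = cosine_similarity(nonzero[i], nonzero[j])
    matrix = SimilarityMatrix(values=values, categories=kept)

    pair_vals = np.array([v for _, _, v in matrix.pair_values()])
    counts, edges = np.histogram(pair_vals, bins=n_bins, range=(0.0, 1.0))
    summary = SimilaritySummary(
        bin_edges=edges,
        bin_counts=counts,
        n_pairs=len(pair_vals),
        n_below_threshold=int(np.sum(pair_vals < threshold)),
        threshold=threshold,
    )
    return matrix, summary
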