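"""Budding-yeast phenotype scheme and two published example neighborhoods.

The CYGD phenotype catalogue groups *Saccharomyces cerevisiae* mutant
phenotypes into 11 categories; :func:`yeast_scheme` is the canonical
ordered registry used by the yeast analyses.

Two small seed-protein neighborhoods with published STRING confidences are
shipped as in-code data for documentation and regression testing:

* YBR039W (ATP synthase subunit 4) and its eight F0/F1 ATP synthase
  complex partners, all sharing the auxotrophies / carbon and nitrogen
  utilization defects phenotype;
* YDL028C and its eleven mitotic cell-cycle (sce04111) pathway partners,
  dominated by the cell cycle defects phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

from .net_io import AnnotationSet, MembershipTable, PhenotypeScheme, WeightedNetwork

__all__ = [
    "YEAST_PHENOTYPES",
    "yeast_scheme",
    "WorkedExample",
    "ybr039w_neighborhood",
    "ydl028c_neighborhood",
]

#: The 11 CYGD phenotype categories, in canonical order (index = position + 1).
YEAST_PHENOTYPES: tuple[str, ...] = (
    "Conditional phenotypes",
    "Cell cycle defects",
    "Mating and sporulation defects",
    "Auxotrophies, carbon and nitrogen utilization defects",
    "Cell morphology and organelle mutants",
    "Stress response defects",
    "Carbohydrate and lipid biosynthesis defects",
    "Nucleic acid metabolism defects",
    "Sensitivity to amino acid analogs and other drugs",
    "Sensitivity to antibiotics",
    "Sensitivity to immunosuppressants",
)


def yeast_scheme() -> PhenotypeScheme:
    """The 11-category budding-yeast phenotype scheme."""
    return PhenotypeScheme(YEAST_PHENOTYPES)


@dataclass(frozen=True)
class WorkedExample:
    """A query protein with its annotated neighborhood, ready to score."""

    query: str
    network: WeightedNetwork
    annotations: AnnotationSet
    membership: MembershipTable
    scheme: PhenotypeScheme


# neighbor -> (phenotype category indices, STRING confidence, complex IDs)
_YBR039W_NEIGHBORS: dict[str, tuple[frozenset[int], int, frozenset[str]]] = {
    "YBL099W": (frozenset({4}), 999, frozenset({"ATP synthase complex V"})),
    "YDL004W": (frozenset({4}), 999, frozenset({"ATP synthase complex V"})),
    "YDR298C": (frozenset({4}), 999, frozenset({"ATP synthase complex V", "Ho complex"})),
    "YLR295C": (frozenset({4}), 917, frozenset({"ATP synthase complex V"})),
    "YML081C-A": (frozenset({4, 5}), 934, frozenset({"ATP synthase complex V"})),
    "YPL078C": (frozenset({4}), 999, frozenset({"ATP synthase complex V", "Ho complex"})),
    "YPL271W": (frozenset({4}), 997, frozenset({"ATP synthase complex V"})),
    "YPR024W": (frozenset({4, 5, 1}), 986, frozenset({"Yme1 protease complex"})),
}

# neighbor -> (phenotype category indices, STRING confidence, KEGG pathway IDs)
_YDL028C_NEIGHBORS: dict[str, tuple[frozenset[int], int, frozenset[str]]] = {
    "YBL084C": (frozenset({2, 8}), 929, frozenset({"sce04111", "sce04113", "sce04120"})),
    "YDR168W": (frozenset({2}), 999, frozenset()),
    "YGL116W": (frozenset({2}), 956, frozenset({"sce04111", "sce04113", "sce04120"})),
    "YGR113W": (frozenset({2, 5}), 999, frozenset({"sce04111"})),
    "YGR188C": (frozenset({5}), 999, frozenset({"sce04111", "sce04113"})),
    "YIL106W": (frozenset({2, 5}), 988, frozenset({"sce04111"})),
    "YKL022C": (frozenset({2, 1}), 929, frozenset({"sce04111", "sce04113", "sce04120"})),
    "YKL042W": (frozenset({2}), 990, frozenset()),
    "YMR055C": (frozenset({2}), 984, frozenset({"sce04111"})),
    "YOR026W": (frozenset({2, 1}), 978, frozenset({"sce04111"})),
    "YPL209C": (frozenset({2, 5, 1}), 984, frozenset()),
}


def _build(
    query: str,
    query_labels: frozenset[int],
    query_features: frozenset[str],
    neighbors: dict[str, tuple[frozenset[int], int, frozenset[str]]],
) -> WorkedExample:
    scheme = yeast_scheme()
    net = WeightedNetwork.from_edges(
        (query, nbr, w) for nbr, (_, w, _) in neighbors.items()
    )
    labels = {nbr: cats for nbr, (cats, _, _) in neighbors.items()}
    labels[query] = query_labels
    membership = {nbr: feats for nbr, (_, _, feats) in neighbors.items()}
    membership[query] = query_features
    return WorkedExample(
        query=query,
        network=net,
        annotations=AnnotationSet(labels, scheme),
        membership=MembershipTable(membership),
        scheme=scheme,
    )


def ybr039w_neighborhood() -> WorkedExample:
    """YBR039W and its eight ATP-synthase seed neighbors (complex data)."""
    return _build(
        "YBR039W",
        frozenset({4}),
        frozenset({"ATP synthase complex V"}),
        _YBR039W_NEIGHBORS,
    )


def ydl028c_neighborhood() -> WorkedExample:
    """YDL028C and its eleven cell-cycle seed neighbors (pathway data)."""
    return _build(
        "YDL028C",
        frozenset({2, 5}),
        frozenset({"sce04111"}),
        _YDL028C_NEIGHBORS,
    )
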