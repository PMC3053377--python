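"""Domain types and I/O for networks, phenotype annotations and membership tables.

The package works on three plain-text inputs:

* a weighted, undirected protein interaction network given as an edge list
  (``protein_a  protein_b  combined_score``) with integer confidence scores
  on the STRING 0-999 scale;
* a phenotype annotation table mapping each protein to one or more
  category indices of a :class:`PhenotypeScheme`;
* optional complex / pathway membership tables mapping proteins to
  feature identifiers.

All identifiers are opaque, case-sensitive strings (systematic ORF names
such as ``YBR039W`` in the yeast data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "PhenotypeScheme",
    "WeightedNetwork",
    "AnnotationSet",
    "MembershipTable",
    "EdgeListParseError",
    "AnnotationError",
    "NO_ANNOTATION_TOKEN",
    "read_edge_list",
    "write_edge_list",
    "read_annotations",
    "write_annotations",
    "read_membership",
    "write_membership",
    "seed_set",
]

#: Literal token marking a protein that is explicitly known to lack
#: complex/pathway annotation (as opposed to being absent from the table).
NO_ANNOTATION_TOKEN = "no annotation"


class EdgeListParseError(ValueError):
    """A malformed row in an edge-list file (reports the 1-based line number)."""


class AnnotationError(ValueError):
    """An annotation row references an invalid phenotype category."""


@dataclass(frozen=True)
class PhenotypeScheme:
    """Ordered registry of the K phenotype categories.

    Categories are addressed by 1-based index throughout the package, so
    ``scheme.label(1)`` is the first category. Labels must be unique and
    K must be at least 2.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("a phenotype scheme needs at least 2 categories")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("phenotype category labels must be unique")

    @property
    def K(self) -> int:
        return len(self.labels)

    @property
    def indices(self) -> range:
        """The valid category indices, 1..K."""
        return range(1, self.K + 1)

    def label(self, index: int) -> str:
        if not 1 <= index <= self.K:
            raise IndexError(f"category index {index} outside 1..{self.K}")
        return self.labels[index - 1]

    def index_of(self, label: str) -> int:
        return self.labels.index(label) + 1

    @classmethod
    def generic(cls, K: int) -> "PhenotypeScheme":
        """A placeholder scheme ``phenotype_01 .. phenotype_K`` for synthetic data."""
        return cls(tuple(f"phenotype_{i:02d}" for i in range(1, K + 1)))


class WeightedNetwork:
    """Undirected protein interaction network with integer edge confidences.

    Thin wrapper around :class:`networkx.Graph` enforcing the package's
    invariants: no self-loops, one stored edge per unordered pair,
    symmetric weight lookup, and (when built through :func:`read_edge_list`)
    all weights at or above the configured confidence cutoff.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, int]]) -> "WeightedNetwork":
        """Build a network from ``(a, b, weight)`` triples.

        Self-loops are dropped; duplicate/reciprocal pairs keep the
        maximum weight.
        """
        net = cls()
        for a, b, w in edges:
            net.add_edge(a, b, w)
        return net

    def add_edge(self, a: str, b: str, weight: int) -> None:
        if a == b:  # self-interactions carry no information here
            return
        if self._g.has_edge(a, b):
            weight = max(weight, self._g[a][b]["weight"])
        self._g.add_edge(a, b, weight=weight)

    def weight(self, a: str, b: str) -> int:
        """Edge confidence between ``a`` and ``b``; 0 if absent or ``a == b``."""
        if a == b or not self._g.has_edge(a, b):
            return 0
        return self._g[a][b]["weight"]

    def neighbors(self, node: str) -> Iterator[str]:
        return iter(self._g[node]) if node in self._g else iter(())

    def remove_node(self, node: str) -> None:
        self._g.remove_node(node)

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(self._g.copy())

    def edges(self) -> Iterator[tuple[str, str, int]]:
        for a, b, data in self._g.edges(data=True):
            yield a, b, data["weight"]

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __repr__(self) -> str:
        return f"WeightedNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


class AnnotationSet:
    """Mapping from protein ID to a non-empty set of phenotype category indices."""

    def __init__(self, labels: Mapping[str, Iterable[int]], scheme: PhenotypeScheme):
        self.scheme = scheme
        self._labels: dict[str, frozenset[int]] = {}
        for protein, cats in labels.items():
            cats = frozenset(int(c) for c in cats)
            if not cats:
                raise AnnotationError(f"protein {protein!r} has an empty label set")
            bad = [c for c in cats if not 1 <= c <= scheme.K]
            if bad:
                raise AnnotationError(
                    f"protein {protein!r}: category indices {sorted(bad)} "
                    f"outside 1..{scheme.K}"
                )
            self._labels[protein] = cats

    @property
    def proteins(self) -> list[str]:
        return sorted(self._labels)

    def __getitem__(self, protein: str) -> frozenset[int]:
        return self._labels[protein]

    def __contains__(self, protein: str) -> bool:
        return protein in self._labels

    def __len__(self) -> int:
        return len(self._labels)

    def items(self) -> Iterator[tuple[str, frozenset[int]]]:
        return iter(self._labels.items())

    def category_counts(self) -> dict[int, int]:
        """Number of annotated proteins per category (a protein with several
        phenotypes counts once in each)."""
        counts = dict.fromkeys(self.scheme.indices, 0)
        for cats in self._labels.values():
            for c in cats:
                counts[c] += 1
        return counts

    def __repr__(self) -> str:
        return f"AnnotationSet({len(self)} proteins, K={self.scheme.K})"


@dataclass
class MembershipTable:
    """Protein -> complex/pathway membership.

    ``membership`` maps each protein to its feature set.  Proteins present
    with an empty set were explicitly marked with the literal token
    ``"no annotation"`` in the source file — they are known to lack
    annotation, which is distinct from being absent from the table.
    """

    membership: dict[str, frozenset[str]]
    feature_universe: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        referenced = set().union(*self.membership.values()) if self.membership else set()
        if not self.feature_universe:
            self.feature_universe = tuple(sorted(referenced))
        elif not referenced <= set(self.feature_universe):
            missing = sorted(referenced - set(self.feature_universe))
            raise ValueError(f"features outside the universe: {missing[:5]}")

    def features_of(self, protein: str) -> frozenset[str]:
        return self.membership.get(protein, frozenset())

    @property
    def n_features(self) -> int:
        return len(self.feature_universe)


def _open_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def read_edge_list(
    path: str | Path,
    min_weight: int = 900,
    columns: tuple[int, int, int] = (0, 1, 2),
) -> WeightedNetwork:
    """Read a whitespace/tab-delimited edge list into a :class:`WeightedNetwork`.

    Parameters
    ----------
    path:
        File with at least three columns: protein_a, protein_b and an
        integer confidence score. A single header line is auto-detected by
        a non-numeric score field and skipped.
    min_weight:
        Inclusive confidence cutoff; only edges with score >= ``min_weight``
        are kept (the yeast analyses use the STRING "highest confidence"
        cutoff of 900).
    columns:
        0-based positions of the protein_a / protein_b / score columns,
        for files with extra columns.

    Rows defining self-loops are dropped, and duplicate or reciprocal rows
    for the same unordered pair are collapsed keeping the maximum weight.
    The node set consists exactly of the endpoints of retained edges.
    """
    if min_weight < 0:
        raise ValueError("min_weight must be >= 0")
    ca, cb, cw = columns
    need = max(columns) + 1
    net = WeightedNetwork()
    first_data_line = True
    for lineno, fields in _open_lines(path):
        if len(fields) < need:
            raise EdgeListParseError(
                f"{path}:{lineno}: expected at least {need} columns, got {len(fields)}"
            )
        try:
            w = int(float(fields[cw]))
        except ValueError:
            if first_data_line:  # header row: non-numeric score field
                first_data_line = False
                continue
            raise EdgeListParseError(
                f"{path}:{lineno}: non-numeric score field {fields[cw]!r}"
            ) from None
        first_data_line = False
        if w >= min_weight:
            net.add_edge(fields[ca], fields[cb], w)
    if net.n_edges == 0:
        warnings.warn(f"no edges retained from {path} at cutoff {min_weight}")
    return net


def write_edge_list(net: WeightedNetwork, path: str | Path, header: bool = True) -> None:
    """Write a network as a 3-column TSV readable by :func:`read_edge_list`."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("protein_a\tprotein_b\tcombined_score\n")
        for a, b, w in sorted(net.edges()):
            fh.write(f"{a}\t{b}\t{w}\n")


def read_annotations(path: str | Path, scheme: PhenotypeScheme) -> AnnotationSet:
    """Read a two-column TSV of protein -> comma-separated category indices.

    Duplicate protein rows are merged by union of their label sets (with a
    warning); an index outside 1..K raises :class:`AnnotationError`.
    """
    labels: dict[str, set[int]] = {}
    for lineno, fields in _open_lines(path):
        if len(fields) < 2:
            raise AnnotationError(f"{path}:{lineno}: expected 2 columns")
        protein, cats_field = fields[0], fields[1]
        try:
            cats = {int(tok) for tok in cats_field.replace(";", ",").split(",") if tok.strip()}
        except ValueError:
            raise AnnotationError(
                f"{path}:{lineno}: non-integer category in {cats_field!r}"
            ) from None
        if not cats:
            raise AnnotationError(f"{path}:{lineno}: empty category list")
        if protein in labels:
            warnings.warn(f"{path}:{lineno}: duplicate row for {protein}; merging labels")
            labels[protein] |= cats
        else:
            labels[protein] = cats
    return AnnotationSet(labels, scheme)


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for protein in annotations.proteins:
            cats = ",".join(str(c) for c in sorted(annotations[protein]))
            fh.write(f"{protein}\t{cats}\n")


def read_membership(path: str | Path) -> MembershipTable:
    """Read a two-column TSV of protein -> comma-separated feature IDs.

    The literal value ``"no annotation"`` in column 2 marks a protein
    explicitly known to lack membership; it is stored with an empty set.
    """
    membership: dict[str, frozenset[str]] = {}
    for lineno, fields in _open_lines(path):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        protein, feats_field = fields[0], fields[1]
        if feats_field.strip() == NO_ANNOTATION_TOKEN:
            feats: frozenset[str] = frozenset()
        else:
            feats = frozenset(
                tok.strip() for tok in feats_field.replace(";", ",").split(",") if tok.strip()
            )
        membership[protein] = membership.get(protein, frozenset()) | feats
    if not membership:
        warnings.warn(f"empty membership table {path}")
    return MembershipTable(membership)


def write_membership(table: MembershipTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for protein in sorted(table.membership):
            feats = table.membership[protein]
            value = ",".join(sorted(feats)) if feats else NO_ANNOTATION_TOKEN
            fh.write(f"{protein}\t{value}\n")


def seed_set(annotations: AnnotationSet, network: WeightedNetwork) -> list[str]:
    """Annotated proteins that are nodes of the network, lexicographically sorted.

    These are the "seed proteins" whose phenotype labels drive every
    prediction; in the yeast data 1,267 of the 1,460 annotated proteins
    map onto the interaction network.
    """
    return sorted(p for p in annotations.proteins if p in network)
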