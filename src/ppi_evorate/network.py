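"""PPI network ingestion and local-topology features.

The network is a simple undirected graph of proteins: self-interactions are
dropped and duplicate (or reversed-duplicate) edges collapse to one. Two
per-protein features live here — the degree *v* and the clustering
coefficient 2l / (v(v-1)), where *l* counts interactions among the protein's
*v* neighbours — together with the sparse-part / dense-part (SP/DP)
classification against a mean-coefficient cutoff.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Literal, Mapping, Optional, Union

import networkx as nx

logger = logging.getLogger(__name__)

Dialect = Literal["two-column-tsv", "mitab-lite"]

SP = "SP"
DP = "DP"
UNCLASSIFIED = "unclassified"


class EdgeListParseError(ValueError):
    """A row of the edge list could not be parsed (names the line number)."""


@dataclass
class InteractionNetwork:
    """Simple undirected protein-protein interaction graph.

    Wraps a :class:`networkx.Graph` whose nodes are opaque protein-ID
    strings.  Invariants: no self-loops, each unordered pair at most once,
    every edge endpoint is a node.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def proteins(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    @property
    def n_proteins(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, protein: str) -> bool:
        return protein in self.graph

    def add_edge(self, a: str, b: str) -> bool:
        """Add an undirected edge; returns False for a self-loop or duplicate."""
        if a == b:
            return False
        if self.graph.has_edge(a, b):
            return False
        self.graph.add_edge(a, b)
        return True

    def add_protein(self, p: str) -> None:
        self.graph.add_node(p)

    def degree(self, p: str) -> int:
        """Number of distinct interaction partners of ``p``."""
        if p not in self.graph:
            raise KeyError(f"protein {p!r} is not in the network")
        return self.graph.degree[p]

    def neighbors(self, p: str) -> set[str]:
        if p not in self.graph:
            raise KeyError(f"protein {p!r} is not in the network")
        return set(self.graph.neighbors(p))

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "InteractionNetwork":
        net = cls()
        for a, b in edges:
            net.add_edge(a, b)
        return net


@dataclass(frozen=True)
class DensityLabel:
    """SP/DP classification of one protein by clustering coefficient."""

    protein: str
    clustering_coefficient: Optional[float]
    label: str  # SP, DP or unclassified

    def __post_init__(self) -> None:
        if (self.clustering_coefficient is None) != (self.label == UNCLASSIFIED):
            raise ValueError(
                "label must be 'unclassified' exactly when the coefficient is missing"
            )


@dataclass
class ReadReport:
    """Bookkeeping from edge-list ingestion."""

    rows_read: int = 0
    self_loops_dropped: int = 0
    duplicates_collapsed: int = 0
    filtered_out: int = 0


def read_edge_list(
    source: Union[str, Path, IO[str]],
    dialect: Dialect = "two-column-tsv",
    id_filter: Optional[str] = None,
) -> tuple[InteractionNetwork, ReadReport]:
    """Read an undirected edge list into an :class:`InteractionNetwork`.

    Parameters
    ----------
    source:
        Path or open text handle. Rows are tab-separated; a header row whose
        first field does not look like data (``id_a``/``#``-prefixed) is
        skipped automatically.
    dialect:
        ``"two-column-tsv"`` expects exactly the two ID columns first;
        ``"mitab-lite"`` takes the first two columns as IDs and ignores any
        trailing metadata columns.
    id_filter:
        Optional regex; rows where either ID does not match are dropped
        (stand-in for the intra-species screen applied to mixed-species
        interaction databases).

    Returns the network plus a :class:`ReadReport` of dropped rows.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as handle:
            return read_edge_list(handle, dialect=dialect, id_filter=id_filter)

    pattern = re.compile(id_filter) if id_filter else None
    net = InteractionNetwork()
    report = ReadReport()
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2 and dialect == "two-column-tsv":
            # tolerate whitespace-separated two-column files
            fields = line.split()
        if len(fields) < 2:
            raise EdgeListParseError(
                f"line {lineno}: expected at least two ID fields, got {len(fields)}"
            )
        a, b = fields[0].strip(), fields[1].strip()
        if lineno == 1 and {a.lower(), b.lower()} & {"id_a", "id_b", "protein_a", "protein_b"}:
            continue  # header
        if not a or not b:
            raise EdgeListParseError(f"line {lineno}: empty protein ID")
        report.rows_read += 1
        if pattern is not None and not (pattern.search(a) and pattern.search(b)):
            report.filtered_out += 1
            continue
        if a == b:
            report.self_loops_dropped += 1
            continue
        if not net.add_edge(a, b):
            report.duplicates_collapsed += 1
    logger.info(
        "edge list: %d rows, %d self-loops dropped, %d duplicates collapsed, %d filtered",
        report.rows_read,
        report.self_loops_dropped,
        report.duplicates_collapsed,
        report.filtered_out,
    )
    return net, report


def clustering_coefficient(net: InteractionNetwork, p: str) -> Optional[float]:
    """Clustering coefficient 2l / (v(v-1)) of protein ``p``.

    ``v`` is the degree and ``l`` the number of interactions among the
    protein's neighbours.  Proteins with fewer than two partners have no
    defined coefficient and return ``None``; they are excluded from the
    SP/DP classification because a single connection carries no neighbour-
    pair information and would bias the cutoff.
    """
    if p not in net.graph:
        raise KeyError(f"protein {p!r} is not in the network")
    if net.graph.degree[p] < 2:
        return None
    return float(nx.clustering(net.graph, p))


def all_clustering_coefficients(net: InteractionNetwork) -> dict[str, Optional[float]]:
    """Coefficient for every protein; ``None`` where degree < 2."""
    cc = nx.clustering(net.graph)
    return {
        p: (float(cc[p]) if net.graph.degree[p] >= 2 else None) for p in net.graph.nodes
    }


def classify_density(
    coefficients: Mapping[str, Optional[float]],
    cutoff: Union[float, Literal["mean"]] = "mean",
) -> list[DensityLabel]:
    """Label proteins dense-part (DP) or sparse-part (SP) by clustering coefficient.

    ``cutoff="mean"`` uses the arithmetic mean over the defined coefficients.
    A coefficient at or above the cutoff gives DP, below gives SP; missing
    coefficients (degree < 2) stay unclassified and are excluded from the
    mean.
    """
    defined = [c for c in coefficients.values() if c is not None]
    if cutoff == "mean":
        if not defined:
            raise ValueError("cannot take the mean cutoff: no defined coefficients")
        threshold = sum(defined) / len(defined)
    else:
        threshold = float(cutoff)
    labels = []
    for protein, coeff in coefficients.items():
        if coeff is None:
            labels.append(DensityLabel(protein, None, UNCLASSIFIED))
        elif coeff >= threshold:
            labels.append(DensityLabel(protein, coeff, DP))
        else:
            labels.append(DensityLabel(protein, coeff, SP))
    return labels
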