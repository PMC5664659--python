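"""Degree centrality on the composite network and candidate-chemical scoring.

Degree centrality here is the plain link count: the number of DISTINCT
neighbors a gene has in the composite network (an edge supported by several
evidence categories still counts once).  A candidate chemical's priority score
is the sum of the degree centralities of the network genes it interacts with —
chemicals touching many well-connected (hub) genes score highest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .integration import ChemicalGeneTable, GeneSet, intersect
from .netcombine import CompositeNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CentralityMap",
    "CandidateRow",
    "CandidateScoreTable",
    "degree_centrality",
    "score_chemical",
    "screen_candidates",
]


@dataclass
class CentralityMap:
    """Distinct-neighbor degree per gene of a source network."""

    degrees: dict[str, int]
    network_ref: str = "composite"

    def __getitem__(self, gene: str) -> int:
        return self.degrees[gene]

    def get(self, gene: str, default: int = 0) -> int:
        return self.degrees.get(gene, default)

    def top(self, k: int) -> list[tuple[str, int]]:
        """The ``k`` most central genes (descending degree, ties by symbol)."""
        ranked = sorted(self.degrees.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:k]


@dataclass(frozen=True)
class CandidateRow:
    chemical: str
    cas: str
    score: int
    interacting_genes: GeneSet


@dataclass
class CandidateScoreTable:
    """Ranked candidate chemicals: descending score, ties by chemical name."""

    rows: list[CandidateRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rows = sorted(self.rows, key=lambda r: (-r.score, r.chemical))

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def top_chemical(self) -> str | None:
        return self.rows[0].chemical if self.rows else None

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tscore\tchemical\tcas\tinteracting_genes\n")
            for rank, row in enumerate(self.rows, start=1):
                genes = ";".join(row.interacting_genes)
                fh.write(f"{rank}\t{row.score}\t{row.chemical}\t{row.cas}\t{genes}\n")


def degree_centrality(net: CompositeNetwork) -> CentralityMap:
    """Number of distinct neighbors per node; isolated nodes get 0."""
    degrees = {gene: int(net.graph.degree(gene)) for gene in net.nodes}
    return CentralityMap(degrees=degrees)


def score_chemical(genes: Iterable[str], centrality: CentralityMap) -> int:
    """Sum of degree centralities over the chemical's interacting genes.

    Genes absent from the network contribute 0 (and are logged): the printed
    candidate tables in this workflow list only network genes per chemical,
    implying restriction to the network.  Duplicate listings count once.
    """
    unique = dict.fromkeys(genes)
    absent = [g for g in unique if g not in centrality.degrees]
    if absent:
        logger.info("genes not in network contribute 0: %s", ", ".join(absent))
    return sum(centrality.get(g, 0) for g in unique)


def screen_candidates(
    candidates: ChemicalGeneTable,
    centrality: CentralityMap,
    query_genes: GeneSet,
) -> CandidateScoreTable:
    """Score and rank candidate chemicals against the query gene network.

    ``candidates`` should already be category-filtered and seed-excluded.  A
    candidate appears iff its gene set intersects ``query_genes``; its
    ``interacting_genes`` column is that intersection and its score is the sum
    of those genes' degrees.
    """
    rows = []
    for chem in candidates.chemicals:
        overlap = intersect(candidates.index[chem], query_genes)
        if len(overlap) == 0:
            continue
        rows.append(
            CandidateRow(
                chemical=chem,
                cas=candidates.cas_of(chem),
                score=score_chemical(overlap, centrality),
                interacting_genes=overlap,
            )
        )
    return CandidateScoreTable(rows)
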