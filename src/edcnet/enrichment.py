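"""Over-representation analysis with kappa-based functional grouping.

Given a query gene list and a term-annotation collection (GO/KEGG-style gene
sets in GMT format), each term is tested for over-representation with the
one-sided upper-tail hypergeometric test, p-values are optionally adjusted for
multiple testing, and significant terms are grouped by the Cohen's-kappa
agreement of their gene memberships: terms whose membership vectors agree with
kappa ≥ 0.4 (the conventional cut-off of ClueGO-style analyses) are linked,
groups are the connected components of that term graph, and each group is
labelled by its most significant member term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .integration import FormatError, GeneSet, intersect

logger = logging.getLogger(__name__)

__all__ = [
    "Term",
    "AnnotationCollection",
    "TermRecord",
    "TermGroup",
    "EnrichmentResult",
    "parse_gmt",
    "write_gmt",
    "hypergeom_p",
    "adjust_pvalues",
    "kappa",
    "enrich_and_group",
]


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    source: str  # e.g. "KEGG", "GO-biological-process", "other"
    genes: GeneSet


@dataclass
class AnnotationCollection:
    """Term gene sets plus the annotation universe (background gene list)."""

    terms: dict[str, Term]
    universe: GeneSet

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for term in self.terms.values():
            stray = [g for g in term.genes if g not in uni]
            if stray:
                raise ValueError(
                    f"term {term.term_id}: genes outside the universe: {', '.join(stray)}"
                )

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class TermRecord:
    term_id: str
    source: str
    p_value: float
    adjusted_p: float
    overlap: GeneSet


@dataclass(frozen=True)
class TermGroup:
    members: tuple[str, ...]
    representative: str


@dataclass
class EnrichmentResult:
    records: list[TermRecord]
    groups: list[TermGroup]

    @property
    def significant_ids(self) -> tuple[str, ...]:
        return tuple(tid for group in self.groups for tid in group.members)

    def to_tsv(self, path: str | Path) -> None:
        group_of = {}
        rep = set()
        for gi, group in enumerate(self.groups, start=1):
            rep.add(group.representative)
            for tid in group.members:
                group_of[tid] = gi
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term_id\tsource\tp\tadjusted_p\toverlap_genes\tgroup_id\tis_representative\n")
            for rec in sorted(self.records, key=lambda r: (r.p_value, r.term_id)):
                genes = ";".join(rec.overlap)
                gid = group_of.get(rec.term_id, "")
                is_rep = "yes" if rec.term_id in rep else ("no" if gid else "")
                fh.write(
                    f"{rec.term_id}\t{rec.source}\t{rec.p_value:.6g}\t"
                    f"{rec.adjusted_p:.6g}\t{genes}\t{gid}\t{is_rep}\n"
                )


def parse_gmt(path: str | Path, universe: GeneSet | None = None) -> AnnotationCollection:
    """Parse a Broad-dialect GMT file: ``term_id TAB description TAB gene...``.

    The description field may carry an optional ``source|name`` prefix (as
    written by :func:`write_gmt`); otherwise the source is "other".  Unless an
    explicit ``universe`` is given, it defaults to the union of all term genes.
    """
    terms: dict[str, Term] = {}
    all_genes: list[str] = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        term_id, desc = fields[0].strip(), fields[1].strip()
        source, name = "other", desc
        if "|" in desc:
            maybe_source, _, rest = desc.partition("|")
            if maybe_source in ("KEGG", "GO-biological-process", "other"):
                source, name = maybe_source, rest
        genes = GeneSet([g for g in fields[2:] if g.strip()], provenance=term_id)
        if term_id in terms:
            raise FormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
        terms[term_id] = Term(term_id=term_id, name=name, source=source, genes=genes)
        all_genes.extend(genes)
    if universe is None:
        universe = GeneSet(all_genes, provenance="annotation universe")
    return AnnotationCollection(terms=terms, universe=universe)


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid in collection.terms:
            term = collection.terms[tid]
            genes = "\t".join(term.genes)
            fh.write(f"{term.term_id}\t{term.source}|{term.name}\t{genes}\n")


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X ≥ k).

    ``X`` counts annotated genes in a draw of ``n`` query genes from a
    universe of ``N`` genes of which ``K`` carry the annotation.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 ≤ K ≤ N and 0 ≤ n ≤ N; got k={k}, K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 ≤ k ≤ min(K, n); got k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def adjust_pvalues(
    ps: Sequence[float],
    method: Literal["benjamini-hochberg", "bonferroni", "none"] = "benjamini-hochberg",
) -> list[float]:
    """Multiple-testing adjustment, order-aligned with the input."""
    if any(not (0.0 <= p <= 1.0) for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    if len(ps) == 0 or method == "none":
        return list(ps)
    mapped = {"benjamini-hochberg": "fdr_bh", "bonferroni": "bonferroni"}
    try:
        sm_method = mapped[method]
    except KeyError:
        raise ValueError(f"unknown adjustment method: {method!r}") from None
    return [float(p) for p in multipletests(list(ps), method=sm_method)[1]]


def kappa(term_a: GeneSet, term_b: GeneSet, universe: GeneSet) -> float:
    """Cohen's kappa of two terms' binary gene-membership vectors.

    Each gene of the universe is classified as in/out of each term; kappa is
    the chance-corrected agreement of the two classifications.  Symmetric;
    1.0 for identical terms, 0.0 at chance agreement.
    """
    if len(universe) < 1:
        raise ValueError("universe must be non-empty")
    uni = set(universe)
    a, b = set(term_a), set(term_b)
    if not a <= uni or not b <= uni:
        raise ValueError("terms must be subsets of the universe")
    N = len(uni)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = N - n11 - n10 - n01
    po = (n11 + n00) / N
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / (N * N)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def enrich_and_group(
    genes: GeneSet,
    ann: AnnotationCollection,
    p_threshold: float = 0.05,
    kappa_threshold: float = 0.4,
    correction: Literal["benjamini-hochberg", "bonferroni", "none"] = "benjamini-hochberg",
    filter_on: Literal["raw", "adjusted"] = "raw",
) -> EnrichmentResult:
    """Hypergeometric over-representation plus kappa grouping.

    Per term: k = \\|query ∩ term\\|, K = \\|term\\|, n = \\|query ∩ universe\\|,
    N = \\|universe\\|.  Terms passing the significance filter (raw p by
    default, mirroring the p < 0.05 convention; adjusted p via ``filter_on``)
    are linked when pairwise kappa ≥ ``kappa_threshold``; groups are the
    connected components, each represented by its smallest-p member
    (ties broken by lexicographic term id).
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError("p_threshold must be in (0, 1]")
    if not (-1.0 <= kappa_threshold <= 1.0):
        raise ValueError("kappa_threshold must be in [-1, 1]")
    query = intersect(genes, ann.universe)
    if len(genes) and len(query) == 0:
        logger.warning("query genes share no symbols with the annotation universe")
        return EnrichmentResult(records=[], groups=[])

    term_ids = sorted(ann.terms)
    N, n = len(ann.universe), len(query)
    ps = []
    overlaps = {}
    for tid in term_ids:
        term = ann.terms[tid]
        overlap = intersect(query, term.genes)
        overlaps[tid] = overlap
        ps.append(hypergeom_p(len(overlap), len(term.genes), n, N))
    adj = adjust_pvalues(ps, method=correction)
    records = [
        TermRecord(
            term_id=tid,
            source=ann.terms[tid].source,
            p_value=p,
            adjusted_p=max(p, q),
            overlap=overlaps[tid],
        )
        for tid, p, q in zip(term_ids, ps, adj)
    ]

    crit = {"raw": lambda r: r.p_value, "adjusted": lambda r: r.adjusted_p}[filter_on]
    significant = [r for r in records if crit(r) < p_threshold]
    term_graph = nx.Graph()
    term_graph.add_nodes_from(r.term_id for r in significant)
    for i, ra in enumerate(significant):
        for rb in significant[i + 1 :]:
            if kappa(ann.terms[ra.term_id].genes, ann.terms[rb.term_id].genes, ann.universe) >= kappa_threshold:
                term_graph.add_edge(ra.term_id, rb.term_id)

    p_of = {r.term_id: r.p_value for r in records}
    groups = []
    for component in nx.connected_components(term_graph):
        members = tuple(sorted(component))
        representative = min(members, key=lambda tid: (p_of[tid], tid))
        groups.append(TermGroup(members=members, representative=representative))
    groups.sort(key=lambda g: (p_of[g.representative], g.representative))
    return EnrichmentResult(records=records, groups=groups)
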