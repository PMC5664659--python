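"""Gene-set integration: parsing chemical–gene tables, disease gene lists and
chemical category lists, and the set algebra that defines the common-gene query set.

The toxicogenomics workflow this package implements starts from three tabular
resources: a curated chemical–gene interaction table (CTD-style export, one row
per interaction), a disease mutated-gene list (COSMIC-browser-style, one symbol
per line) and a chemical category membership list (TEDX-style, e.g. the
"PCP/Cosmetic ingredient" category).  This module turns them into normalized
in-memory objects and computes the unions, intersections and Venn counts that
produce the query gene set for the downstream network analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "ChemicalGeneTable",
    "CategoryList",
    "InvalidSymbolError",
    "FormatError",
    "normalize_symbol",
    "normalize_chemical_name",
    "parse_chemical_gene_table",
    "parse_gene_list",
    "union_genes",
    "intersect",
    "venn_counts",
    "filter_by_category",
]


class InvalidSymbolError(ValueError):
    """Raised for empty or whitespace-only gene symbols."""


class FormatError(ValueError):
    """Raised when an input file does not match the documented dialect."""


def normalize_symbol(raw: str) -> str:
    """Normalize a gene symbol: strip whitespace, uppercase.

    Pure function; the only identifier mapping performed anywhere in the
    package (no Entrez/Ensembl translation).

    Raises
    ------
    InvalidSymbolError
        If ``raw`` is empty after stripping.
    """
    sym = raw.strip().upper()
    if not sym:
        raise InvalidSymbolError(f"empty gene symbol: {raw!r}")
    return sym


def normalize_chemical_name(raw: str) -> str:
    """Case-fold and whitespace-normalize a chemical name for matching."""
    return " ".join(raw.split()).casefold()


class GeneSet:
    """Ordered collection of unique, normalized gene symbols.

    Symbols are uppercased and deduplicated; iteration order is the insertion
    order of first occurrence, which keeps every downstream ranking and report
    deterministic.
    """

    __slots__ = ("_symbols", "provenance")

    def __init__(self, symbols: Iterable[str] = (), provenance: str = ""):
        seen: dict[str, None] = {}
        for raw in symbols:
            seen.setdefault(normalize_symbol(raw), None)
        self._symbols: tuple[str, ...] = tuple(seen)
        self.provenance = provenance

    @property
    def symbols(self) -> tuple[str, ...]:
        return self._symbols

    def __iter__(self) -> Iterator[str]:
        return iter(self._symbols)

    def __len__(self) -> int:
        return len(self._symbols)

    def __contains__(self, symbol: object) -> bool:
        return symbol in set(self._symbols)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, GeneSet):
            return self._symbols == other._symbols
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._symbols)

    def __repr__(self) -> str:
        label = f" {self.provenance!r}" if self.provenance else ""
        return f"GeneSet({len(self)} genes{label})"

    def union(self, other: "GeneSet", provenance: str = "") -> "GeneSet":
        return GeneSet(list(self) + list(other), provenance=provenance)

    def to_file(self, path: str | Path) -> None:
        """Write one symbol per line (the plain gene-list dialect)."""
        Path(path).write_text("".join(f"{s}\n" for s in self), encoding="utf-8")


@dataclass(frozen=True)
class ChemicalGeneRecord:
    chemical: str
    cas: str
    gene: str
    organism: str
    context: str


REQUIRED_COLUMNS = ("chemical", "cas", "gene", "organism")


@dataclass
class ChemicalGeneTable:
    """Chemical → interacting GeneSet mapping with per-row metadata.

    ``index`` is exactly the per-chemical deduplicated gene sets of ``records``;
    it is rebuilt on construction so the invariant cannot drift.
    """

    records: list[ChemicalGeneRecord] = field(default_factory=list)
    index: dict[str, GeneSet] = field(init=False, default_factory=dict)
    cas_index: dict[str, str] = field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        per_chem: dict[str, list[str]] = {}
        n_dup = 0
        deduped: list[ChemicalGeneRecord] = []
        seen_pairs: set[tuple[str, str, str]] = set()
        for rec in self.records:
            key = (rec.chemical, rec.gene, rec.organism)
            if key in seen_pairs:
                n_dup += 1
                continue
            seen_pairs.add(key)
            deduped.append(rec)
            per_chem.setdefault(rec.chemical, []).append(rec.gene)
            if rec.cas:
                self.cas_index.setdefault(rec.chemical, rec.cas)
        if n_dup:
            # CTD exports list one row per interaction type; collapse quietly.
            logger.info("collapsed %d duplicate (chemical, gene) rows", n_dup)
        self.records = deduped
        self.index = {
            chem: GeneSet(genes, provenance=f"{chem} interacting genes")
            for chem, genes in per_chem.items()
        }

    @property
    def chemicals(self) -> tuple[str, ...]:
        return tuple(self.index)

    def __len__(self) -> int:
        return len(self.index)

    def cas_of(self, chemical: str) -> str:
        return self.cas_index.get(chemical, "")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(r.chemical, r.cas, r.gene, r.organism, r.context) for r in self.records],
            columns=["chemical", "cas", "gene", "organism", "context"],
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class CategoryList:
    """A named chemical category (e.g. a "PCP/Cosmetic ingredient" list).

    Membership is matched on normalized chemical name, with the CAS registry
    number as the tie-breaking identity when names differ between sources.
    """

    category_name: str
    chemicals: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        names = [normalize_chemical_name(n) for n, _ in self.chemicals]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate chemical names in category {self.category_name!r}")

    @property
    def names(self) -> set[str]:
        return {normalize_chemical_name(n) for n, _ in self.chemicals}

    @property
    def cas_numbers(self) -> set[str]:
        return {cas for _, cas in self.chemicals if cas}

    def __contains__(self, item: tuple[str, str]) -> bool:
        name, cas = item
        if cas and cas in self.cas_numbers:
            return True
        return normalize_chemical_name(name) in self.names

    @classmethod
    def from_tsv(cls, path: str | Path, category: str | None = None) -> "CategoryList":
        """Read a category TSV with columns ``category``, ``chemical``, ``cas``."""
        df = _read_tsv(path, required=("category", "chemical"))
        if category is not None:
            df = df[df["category"] == category]
            name = category
        else:
            names = df["category"].unique()
            if len(names) > 1:
                raise FormatError(
                    f"{path}: multiple categories present ({list(names)}); pass category="
                )
            name = names[0] if len(names) else "empty"
        cas = df["cas"] if "cas" in df.columns else [""] * len(df)
        return cls(str(name), set(zip(df["chemical"].astype(str), (str(c) for c in cas))))


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def parse_chemical_gene_table(
    path: str | Path, organism_filter: str | None = "Homo sapiens"
) -> ChemicalGeneTable:
    """Parse a chemical–gene interaction TSV.

    Columns ``chemical``, ``cas``, ``gene``, ``organism`` are required
    (``context`` optional).  Rows are restricted to ``organism_filter`` by
    exact string match after whitespace normalization (pass ``None`` to keep
    all organisms); gene symbols are normalized and per-chemical sets
    deduplicated.
    """
    df = _read_tsv(path, required=REQUIRED_COLUMNS)
    records = []
    for row in df.itertuples(index=False):
        organism = " ".join(str(row.organism).split())
        if organism_filter is not None and organism != " ".join(organism_filter.split()):
            continue
        records.append(
            ChemicalGeneRecord(
                chemical=str(row.chemical).strip(),
                cas=str(row.cas).strip(),
                gene=normalize_symbol(str(row.gene)),
                organism=organism,
                context=str(getattr(row, "context", "")).strip(),
            )
        )
    return ChemicalGeneTable(records)


def parse_gene_list(path: str | Path, provenance: str = "") -> GeneSet:
    """Read a plain gene list: one symbol per line, ``#`` comments allowed."""
    symbols = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    return GeneSet(symbols, provenance=provenance or str(path))


def union_genes(table: ChemicalGeneTable, chemicals: Sequence[str]) -> GeneSet:
    """Deduplicated union of the named chemicals' gene sets.

    Raises
    ------
    KeyError
        Listing every requested chemical absent from the table.
    """
    missing = [c for c in chemicals if c not in table.index]
    if missing:
        raise KeyError(f"chemicals not in table: {', '.join(missing)}")
    symbols: list[str] = []
    for chem in chemicals:
        symbols.extend(table.index[chem])
    return GeneSet(symbols, provenance=f"union of {len(chemicals)} chemicals")


def intersect(a: GeneSet, b: GeneSet) -> GeneSet:
    """Symbols present in both sets, in ``a``'s order."""
    b_set = set(b)
    return GeneSet(
        [s for s in a if s in b_set],
        provenance=f"({a.provenance}) ∩ ({b.provenance})" if a.provenance or b.provenance else "",
    )


def venn_counts(a: GeneSet, b: GeneSet) -> tuple[int, int, int]:
    """Two-set Venn partition sizes ``(only_a, common, only_b)``."""
    common = len(intersect(a, b))
    return len(a) - common, common, len(b) - common


def filter_by_category(
    table: ChemicalGeneTable,
    category: CategoryList,
    exclude: Iterable[str] = (),
) -> ChemicalGeneTable:
    """Retain chemicals that belong to ``category`` and are not in ``exclude``.

    This implements the candidate-selection step: keep the category's members
    (e.g. PCP/cosmetic ingredients) while dropping the seed chemicals that
    defined the query set.  Matching is on normalized name with CAS number as
    fallback identity.
    """
    excluded = {normalize_chemical_name(c) for c in exclude}
    keep = {
        chem
        for chem in table.index
        if (chem, table.cas_of(chem)) in category
        and normalize_chemical_name(chem) not in excluded
    }
    return ChemicalGeneTable([r for r in table.records if r.chemical in keep])
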