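"""Composite functional-association network and label-propagation prediction.

The network stage mirrors the two-part algorithm family popularized by
GeneMANIA: (i) a linear-regression step that combines multiple
evidence-specific association networks (co-expression, physical interaction,
pathway, ...) into a single weighted composite network, and (ii) a
Gaussian-field label-propagation step that diffuses the query genes' labels
over the composite network to rank every other gene by its association with
the query set.

Layer combination
-----------------
Per-layer weights are fit by ridge-regularized non-negative least squares of a
seed co-membership target on the per-layer adjacency entries: for every
unordered node pair the target is 1 when both nodes are query (seed) genes and
0 otherwise, so layers whose edges concentrate inside the query set receive
larger weights.  An unpenalized intercept column absorbs the target's baseline
and is discarded; the non-negative layer weights are renormalized to sum to 1.
Degenerate fits (all-zero solution, or fewer than two seeds) fall back to
equal weights.

Label propagation
-----------------
Seeds get label bias +1 and non-seeds the negative background bias
−(|seeds|/|nodes|); scores solve the Gaussian-field linear system

    (I + λ · L_sym) f = y

with L_sym the symmetric normalized graph Laplacian.  The solution is
deterministic; ranking ties are broken by ascending gene symbol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import nnls

from .integration import FormatError, GeneSet, normalize_symbol, _read_tsv

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "CATEGORY_CODES",
    "NetworkLayer",
    "CompositeNetwork",
    "PropagationResult",
    "load_layers",
    "fit_layer_weights",
    "build_composite",
    "propagate",
    "top_predicted",
]

# The seven evidence categories: the six classic ones plus "pathway".
CATEGORIES = (
    "co-expression",
    "physical-interaction",
    "pathway",
    "predicted",
    "co-localization",
    "shared-protein-domains",
    "genetic-interaction",
)
CATEGORY_CODES = {str(i + 1): cat for i, cat in enumerate(CATEGORIES)}


def _canonical_category(raw: str) -> str:
    label = raw.strip().lower().replace("_", "-").replace(" ", "-")
    if label in CATEGORY_CODES:  # numeric code 1-7
        return CATEGORY_CODES[label]
    if label in CATEGORIES:
        return label
    raise FormatError(f"unknown network category: {raw!r} (expected one of {CATEGORIES} or codes 1-7)")


@dataclass
class NetworkLayer:
    """One evidence layer: a named weighted undirected edge list.

    Edges are stored with endpoints ordered lexicographically; self-loops are
    dropped and duplicate pairs merged by maximum weight.
    """

    name: str
    category: str
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.category = _canonical_category(self.category)
        clean: dict[tuple[str, str], float] = {}
        for (a, b), w in self.edges.items():
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                logger.warning("layer %s: dropping self-loop on %s", self.name, a)
                continue
            if w < 0:
                raise ValueError(f"layer {self.name}: negative edge weight {w} on ({a}, {b})")
            key = (a, b) if a < b else (b, a)
            clean[key] = max(clean.get(key, 0.0), float(w))
        self.edges = clean

    @property
    def nodes(self) -> tuple[str, ...]:
        seen = sorted({g for pair in self.edges for g in pair})
        return tuple(seen)

    def adjacency(self, nodelist: Sequence[str]) -> np.ndarray:
        idx = {g: i for i, g in enumerate(nodelist)}
        W = np.zeros((len(nodelist), len(nodelist)))
        for (a, b), w in self.edges.items():
            if a in idx and b in idx:
                W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
        return W


@dataclass
class CompositeNetwork:
    """Weighted merge of evidence layers.

    ``graph`` is an undirected networkx graph whose edge attributes carry the
    combined ``weight`` (Σ layer_weight × layer edge weight) and the union of
    evidence ``categories`` supporting the pair.  ``layer_weights`` sum to 1.
    """

    graph: nx.Graph
    layer_weights: dict[str, float]

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    def adjacency(self, u: str, v: str) -> float:
        data = self.graph.get_edge_data(u, v)
        return float(data["weight"]) if data else 0.0

    def categories(self, u: str, v: str) -> set[str]:
        data = self.graph.get_edge_data(u, v)
        return set(data["categories"]) if data else set()

    def to_tsv(self, path: str | Path, weights_path: str | Path | None = None) -> None:
        """Export edges in the layer TSV dialect, plus a layer-weight sidecar."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tlayer_name\tcategory\tweight\n")
            for a, b in sorted(tuple(sorted(e)) for e in self.graph.edges):
                data = self.graph[a][b]
                cats = ";".join(sorted(data["categories"]))
                fh.write(f"{a}\t{b}\tcomposite\t{cats}\t{data['weight']:.6g}\n")
        if weights_path is not None:
            with open(weights_path, "w", encoding="utf-8") as fh:
                fh.write("layer_name\tweight\n")
                for name in sorted(self.layer_weights):
                    fh.write(f"{name}\t{self.layer_weights[name]:.6g}\n")


@dataclass
class PropagationResult:
    """Gene scores from label propagation, with a deterministic ranking."""

    scores: dict[str, float]
    seed_genes: GeneSet
    ranking: list[str]  # non-seed genes, descending score, ties by symbol

    def score_of(self, gene: str) -> float:
        return self.scores[gene]


def load_layers(path: str | Path) -> list[NetworkLayer]:
    """Read evidence layers from a TSV with columns
    ``source``, ``target``, ``layer_name``, ``category``, ``weight``.

    Categories may be labels or the numeric codes 1–7.  One layer is produced
    per distinct ``layer_name``, in first-appearance order.
    """
    df = _read_tsv(path, required=("source", "target", "layer_name", "category", "weight"))
    grouped: dict[str, tuple[str, list[tuple[str, str, float]]]] = {}
    for row in df.itertuples(index=False):
        name = str(row.layer_name)
        cat = _canonical_category(str(row.category))
        weight = float(row.weight)
        if weight < 0:
            raise ValueError(
                f"{path}: negative edge weight {weight} on ({row.source}, {row.target})"
            )
        if name in grouped and grouped[name][0] != cat:
            raise FormatError(f"layer {name!r} has inconsistent categories")
        grouped.setdefault(name, (cat, []))[1].append((str(row.source), str(row.target), weight))
    layers = []
    for name, (cat, rows) in grouped.items():
        edges: dict[tuple[str, str], float] = {}
        for a, b, w in rows:
            edges[(a, b)] = max(edges.get((a, b), 0.0), w)  # merge handled again in __post_init__
        layers.append(NetworkLayer(name=name, category=cat, edges=edges))
    return layers


def fit_layer_weights(
    layers: Sequence[NetworkLayer],
    seeds: GeneSet,
    ridge: float = 1.0,
) -> dict[str, float]:
    """Fit non-negative per-layer combination weights (summing to 1).

    Solves ``min ||[1, A] [b; w] − y||² + ridge·||w||²`` with ``w ≥ 0`` where
    each row of ``A`` holds one unordered node pair's adjacency in every layer
    and ``y`` is 1 for seed–seed pairs, else 0.  The intercept ``b`` is not
    penalized and is discarded.
    """
    if not layers:
        raise ValueError("at least one network layer is required")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    names = [layer.name for layer in layers]
    if len(set(names)) != len(names):
        raise ValueError("layer names must be unique")
    equal = {name: 1.0 / len(layers) for name in names}
    nodes = sorted({g for layer in layers for g in layer.nodes})
    node_set = set(nodes)
    seed_list = [s for s in seeds if s in node_set]
    missing = [s for s in seeds if s not in node_set]
    if missing:
        raise KeyError(f"seed genes absent from all layers: {', '.join(missing)}")
    if len(seed_list) < 2 or len(layers) == 1:
        return equal

    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    A = np.column_stack(
        [np.ones(iu.size)] + [layer.adjacency(nodes)[iu, ju] for layer in layers]
    )
    is_seed = np.isin(nodes, seed_list)
    y = (is_seed[iu] & is_seed[ju]).astype(float)

    # Ridge on layer columns only, via row augmentation; nnls handles the
    # clip-to-zero-and-refit-on-support active-set logic internally.
    if ridge > 0:
        aug = np.zeros((len(layers), len(layers) + 1))
        aug[:, 1:] = np.sqrt(ridge) * np.eye(len(layers))
        A = np.vstack([A, aug])
        y = np.concatenate([y, np.zeros(len(layers))])
    coef, _ = nnls(A, y)
    w = coef[1:]
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        logger.warning("degenerate layer-weight fit; falling back to equal weights")
        return equal
    return {name: float(wi / total) for name, wi in zip(names, w)}


def build_composite(
    layers: Sequence[NetworkLayer], weights: Mapping[str, float]
) -> CompositeNetwork:
    """Weighted-sum merge of layers into a single composite network.

    ``weights`` must be keyed exactly by the layer names, be non-negative and
    have positive sum; they are renormalized to sum to 1.  Edge categories are
    unioned per node pair; every layer node appears in the composite even if
    isolated after weighting.
    """
    names = {layer.name for layer in layers}
    if set(weights) != names:
        raise ValueError(
            f"weights keys {sorted(weights)} do not match layer names {sorted(names)}"
        )
    if any(w < 0 for w in weights.values()):
        raise ValueError("layer weights must be non-negative")
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("layer weights must have positive sum")
    norm = {k: v / total for k, v in weights.items()}

    graph = nx.Graph()
    for layer in layers:
        graph.add_nodes_from(layer.nodes)
        lw = norm[layer.name]
        for (a, b), w in layer.edges.items():
            contrib = lw * w
            if graph.has_edge(a, b):
                graph[a][b]["weight"] += contrib
                graph[a][b]["categories"].add(layer.category)
            else:
                graph.add_edge(a, b, weight=contrib, categories={layer.category})
    # An all-zero combined weight carries no evidence under the weighting.
    zero = [(a, b) for a, b, d in graph.edges(data=True) if d["weight"] <= 0]
    graph.remove_edges_from(zero)
    return CompositeNetwork(graph=graph, layer_weights=norm)


def _as_composite(net: CompositeNetwork | NetworkLayer) -> CompositeNetwork:
    if isinstance(net, NetworkLayer):
        return build_composite([net], {net.name: 1.0})
    return net


def propagate(
    net: CompositeNetwork | NetworkLayer,
    seeds: GeneSet,
    regularization: float = 1.0,
) -> PropagationResult:
    """Gaussian-field label propagation over the composite network.

    Solves ``(I + λ L_sym) f = y`` with seed bias +1 and non-seed bias
    −(|seeds|/|nodes|).  Nodes with no edges keep their bias shrunk by
    1/(1+λ).  Deterministic for fixed input.
    """
    net = _as_composite(net)
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    if len(seeds) == 0:
        raise ValueError("seeds must be non-empty")
    nodes = list(net.nodes)
    node_set = set(nodes)
    missing = [s for s in seeds if s not in node_set]
    if missing:
        raise KeyError(f"seed genes not in network: {', '.join(missing)}")

    n = len(nodes)
    W = nx.to_numpy_array(net.graph, nodelist=nodes, weight="weight")
    deg = W.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    L_sym = np.eye(n) - dinv_sqrt[:, None] * W * dinv_sqrt[None, :]
    # Isolated nodes: L_sym row reduces to the identity row, so f = y/(1+λ).
    L_sym[deg == 0] = 0.0
    L_sym[:, deg == 0] = 0.0
    np.fill_diagonal(L_sym, np.where(deg > 0, np.diag(L_sym), 1.0))

    is_seed = np.isin(nodes, list(seeds))
    y = np.where(is_seed, 1.0, -len(seeds) / n)
    f = np.linalg.solve(np.eye(n) + regularization * L_sym, y)
    if not np.all(np.isfinite(f)):
        raise ArithmeticError("propagation produced non-finite scores")

    scores = {g: float(fi) for g, fi in zip(nodes, f)}
    ranking = sorted(
        (g for g, s in zip(nodes, is_seed) if not s),
        key=lambda g: (-scores[g], g),
    )
    return PropagationResult(
        scores=scores,
        seed_genes=GeneSet(list(seeds), provenance=seeds.provenance),
        ranking=ranking,
    )


def top_predicted(result: PropagationResult, k: int = 20) -> GeneSet:
    """The ``k`` highest-scoring non-seed genes, in ranking order."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return GeneSet(result.ranking[:k], provenance=f"top {k} predicted genes")
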