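"""Synthetic test-bed generator with planted ground truth.

Every pipeline stage consumes tabular inputs that in a real analysis come from
curated databases (chemical–gene interactions, disease mutated-gene lists,
chemical category lists, evidence-layer networks, GO/KEGG-style annotations).
This module writes a complete, self-consistent bundle of such files with
*planted* structure, so each stage can be validated against known truth
without any download:

- the seed chemicals' gene union overlaps the disease gene list in exactly
  ``overlap_size`` genes (the planted common set);
- a ``module_size``-gene module inside the common set is densely connected in
  the *signal* network layers, while *noise* layers are Erdős–Rényi;
- one annotation term is planted to contain ``planted_term_overlap`` of the
  query genes, against background terms drawn at chance;
- one candidate chemical interacts with the highest-degree module hubs and is
  therefore the planted top-scoring candidate.

Gene names are synthetic ("G0001", ...) to keep simulations visually distinct
from the packaged verbatim fixtures of the printed tables, which carry real
symbols.  All randomness flows from ``random_seed`` through one generator
instance; the emitted bundle is byte-identical for identical seeds.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .centrality import degree_centrality, score_chemical
from .integration import GeneSet
from .netcombine import CATEGORIES, NetworkLayer, build_composite

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticBundle",
    "generate",
    "make_layer_pair",
    "table_fixtures",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = (
    "table1_chemical_gene.tsv",
    "table2_network_layers.tsv",
    "table3_candidates.tsv",
)

PCP_CATEGORY = "PCP/Cosmetic ingredient"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic bundle.

    Defaults mirror the scale of the motivating analysis: 4 seed chemicals
    whose 229-gene union overlaps a 669-gene disease list in 27 genes, a
    60-node network with a 15-gene planted module of which 8 genes are used
    as propagation seeds, and 20 annotation terms with one planted term
    covering 12 query genes.
    """

    n_genes: int = 1000
    n_chemicals: int = 10
    n_seed_chemicals: int = 4
    overlap_size: int = 27
    module_size: int = 15
    n_layers: int = 4
    noise_edge_prob: float = 0.05
    within_module_edge_prob: float = 0.9
    n_terms: int = 20
    planted_term_overlap: int = 12
    random_seed: int = 0
    # Scale parameters of the emulated resources.
    seed_union_size: int = 229
    disease_list_size: int = 669
    n_network_nodes: int = 60
    n_propagation_seeds: int = 8

    def __post_init__(self) -> None:
        for name in ("noise_edge_prob", "within_module_edge_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        checks = [
            (self.overlap_size <= self.seed_union_size, "overlap_size ≤ seed_union_size"),
            (self.module_size <= self.overlap_size, "module_size ≤ overlap_size"),
            (self.overlap_size <= self.disease_list_size, "overlap_size ≤ disease_list_size"),
            (
                self.seed_union_size + self.disease_list_size - self.overlap_size
                <= self.n_genes,
                "union + disease list must fit in n_genes",
            ),
            (self.n_seed_chemicals >= 1, "need at least one seed chemical"),
            (self.n_seed_chemicals < self.n_chemicals, "need at least one candidate chemical"),
            (self.n_seed_chemicals <= self.seed_union_size, "more seed chemicals than genes"),
            (self.module_size <= self.n_network_nodes, "module_size ≤ n_network_nodes"),
            (self.n_network_nodes >= self.overlap_size + 1, "network must hold the common set"),
            (0 < self.n_propagation_seeds <= self.module_size, "propagation seeds ⊆ module"),
            (self.planted_term_overlap <= self.overlap_size, "planted_term_overlap ≤ overlap_size"),
            (self.n_layers >= 2, "need a signal and a noise layer"),
            (self.n_terms >= 1, "need at least one term"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"infeasible synthetic config: {msg}")


@dataclass
class SyntheticTruth:
    """The planted structure, re-derivable by parsing the emitted bundle."""

    planted_common: GeneSet
    planted_module: GeneSet
    planted_terms: tuple[str, ...]
    expected_top_candidate: str
    layer_roles: dict[str, str]  # layer name -> "signal" | "noise"
    propagation_seeds: GeneSet  # module genes used as seeds in recovery tests
    held_out_module: GeneSet  # module genes NOT seeded (the recovery targets)
    seed_chemicals: tuple[str, ...]


@dataclass
class SyntheticBundle:
    """Paths of the emitted files."""

    chemical_gene_tsv: Path
    disease_genes_txt: Path
    category_tsv: Path
    layers_tsv: Path
    annotations_gmt: Path
    manifest_json: Path


def _cas(i: int) -> str:
    return f"{100000 + i}-{i % 90 + 10:02d}-{i % 10}"


def _build_layer(
    rng: np.random.Generator,
    nodes: list[str],
    module: list[str],
    role: str,
    config: SyntheticConfig,
    name: str,
    category: str,
) -> NetworkLayer:
    """One evidence layer under the generator's noise model.

    Noise layers are Erdős–Rényi with edge probability ``noise_edge_prob`` and
    uniform (0, 1] weights; signal layers additionally connect module pairs
    with probability ``within_module_edge_prob`` at weight 1.
    """
    node_arr = np.array(nodes)
    iu, ju = np.triu_indices(len(nodes), k=1)
    keep = rng.random(iu.size) < config.noise_edge_prob
    weights = rng.uniform(0.0, 1.0, size=iu.size)
    edges: dict[tuple[str, str], float] = {}
    for a, b, w in zip(node_arr[iu[keep]], node_arr[ju[keep]], weights[keep]):
        edges[(str(a), str(b))] = float(np.nextafter(w, 1.0)) if w == 0 else float(w)
    if role == "signal":
        in_module = np.isin(node_arr, module)
        module_pair = in_module[iu] & in_module[ju]
        add = (rng.random(iu.size) < config.within_module_edge_prob) & module_pair
        for a, b in zip(node_arr[iu[add]], node_arr[ju[add]]):
            edges[(str(a), str(b))] = 1.0
    return NetworkLayer(name=name, category=category, edges=edges)


def make_layer_pair(
    config: SyntheticConfig, seed: int
) -> tuple[NetworkLayer, NetworkLayer, GeneSet]:
    """One signal layer and one Erdős–Rényi noise layer over the same nodes.

    A minimal instance of the generator's network model, for replicate-based
    checks of the layer-weight fitting: returns ``(signal, noise, module)``
    where ``module`` is the planted dense gene set of the signal layer.
    """
    rng = np.random.default_rng(seed)
    width = max(4, len(str(config.n_genes)))
    nodes = [f"G{i + 1:0{width}d}" for i in range(config.n_network_nodes)]
    module = nodes[: config.module_size]
    signal = _build_layer(rng, nodes, module, "signal", config, "signal", CATEGORIES[0])
    noise = _build_layer(rng, nodes, module, "noise", config, "noise", CATEGORIES[1])
    return signal, noise, GeneSet(module, provenance="planted module")


def generate(config: SyntheticConfig, outdir: str | Path) -> tuple[SyntheticBundle, SyntheticTruth]:
    """Write the synthetic bundle into ``outdir`` and return paths + truth."""
    rng = np.random.default_rng(config.random_seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    perm = [genes[i] for i in rng.permutation(config.n_genes)]

    common = perm[: config.overlap_size]
    pos = config.overlap_size
    seed_only = perm[pos : pos + config.seed_union_size - config.overlap_size]
    pos += len(seed_only)
    disease_only = perm[pos : pos + config.disease_list_size - config.overlap_size]
    pos += len(disease_only)
    background = perm[pos:]

    module = common[: config.module_size]
    prop_seeds = module[: config.n_propagation_seeds]
    held_out = module[config.n_propagation_seeds :]

    # ---- network layers: first half signal (module-dense), rest pure noise
    n_extra = config.n_network_nodes - config.overlap_size
    network_nodes = common + background[:n_extra]
    n_signal = max(1, config.n_layers // 2)
    layers: list[NetworkLayer] = []
    roles: dict[str, str] = {}
    for li in range(config.n_layers):
        role = "signal" if li < n_signal else "noise"
        category = CATEGORIES[li % len(CATEGORIES)]
        name = f"layer{li + 1:02d}_{role}"
        layers.append(
            _build_layer(rng, network_nodes, module, role, config, name, category)
        )
        roles[name] = role

    # ---- chemicals: seed chemicals partition/cover the planted union
    union_genes_list = common + seed_only
    seed_chems = [f"SEED_CHEM_{i + 1:02d}" for i in range(config.n_seed_chemicals)]
    membership: dict[str, list[str]] = {c: [] for c in seed_chems}
    for g in union_genes_list:
        owner = seed_chems[int(rng.integers(config.n_seed_chemicals))]
        membership[owner].append(g)
        for chem in seed_chems:
            if chem != owner and rng.random() < 0.2:
                membership[chem].append(g)
    for chem in seed_chems:  # every seed chemical interacts with something
        if not membership[chem]:
            membership[chem].append(union_genes_list[0])

    # Candidate chemicals: the planted winner touches the top-degree hubs of
    # the query network; the rest touch a couple of low-degree query genes.
    composite = build_composite(layers, {l.name: 1.0 / len(layers) for l in layers})
    cent = degree_centrality(composite)
    by_degree = sorted(common, key=lambda g: (-cent.get(g), g))
    n_cand = config.n_chemicals - config.n_seed_chemicals
    cand_chems = [f"CAND_CHEM_{i + 1:02d}" for i in range(n_cand)]
    winner = cand_chems[0]
    low_pool = by_degree[len(by_degree) // 2 :]
    membership[winner] = list(by_degree[:5])
    for chem in cand_chems[1:]:
        n_query = int(rng.integers(1, 3))
        picks = [low_pool[int(i)] for i in rng.choice(len(low_pool), size=n_query, replace=False)]
        extras_pool = background[n_extra:]
        extras = [extras_pool[int(i)] for i in rng.choice(len(extras_pool), size=2, replace=False)]
        membership[chem] = picks + extras
    # Guarantee a strict winner under the planted degrees.
    query = GeneSet(common, provenance="planted common genes")
    others_best = max(
        (score_chemical([g for g in membership[c] if g in set(common)], cent) for c in cand_chems[1:]),
        default=0,
    )
    reserve = [g for g in by_degree[5:] if g not in membership[winner]]
    while score_chemical(membership[winner], cent) <= others_best and reserve:
        membership[winner].append(reserve.pop(0))

    chem_cas = {c: _cas(i) for i, c in enumerate(seed_chems + cand_chems)}

    # ---- emit files (deterministic ordering throughout)
    bundle = SyntheticBundle(
        chemical_gene_tsv=outdir / "chemical_gene.tsv",
        disease_genes_txt=outdir / "disease_genes.txt",
        category_tsv=outdir / "category.tsv",
        layers_tsv=outdir / "layers.tsv",
        annotations_gmt=outdir / "annotations.gmt",
        manifest_json=outdir / "manifest.json",
    )

    with open(bundle.chemical_gene_tsv, "w", encoding="utf-8") as fh:
        fh.write("chemical\tcas\tgene\torganism\tcontext\n")
        for chem in seed_chems + cand_chems:
            for g in membership[chem]:
                fh.write(f"{chem}\t{chem_cas[chem]}\t{g}\tHomo sapiens\tsynthetic\n")

    with open(bundle.disease_genes_txt, "w", encoding="utf-8") as fh:
        fh.write("# synthetic disease mutated-gene list\n")
        for g in common + disease_only:
            fh.write(g + "\n")

    with open(bundle.category_tsv, "w", encoding="utf-8") as fh:
        fh.write("category\tchemical\tcas\n")
        for chem in seed_chems + cand_chems:
            fh.write(f"{PCP_CATEGORY}\t{chem}\t{chem_cas[chem]}\n")

    with open(bundle.layers_tsv, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tlayer_name\tcategory\tweight\n")
        for layer in layers:
            for (a, b) in sorted(layer.edges):
                fh.write(f"{a}\t{b}\t{layer.name}\t{layer.category}\t{layer.edges[(a, b)]:.6f}\n")

    # ---- annotations: one planted term over query genes, rest at chance
    planted_id = "T001"
    term_pool = common + background[: max(200, n_extra)]
    with open(bundle.annotations_gmt, "w", encoding="utf-8") as fh:
        planted = module[: config.planted_term_overlap] + common[config.module_size :][
            : max(0, config.planted_term_overlap - config.module_size)
        ]
        fillers = [background[n_extra + i] for i in range(8)]
        fh.write(planted_id + "\tKEGG|planted pathway\t" + "\t".join(planted + fillers) + "\n")
        for ti in range(1, config.n_terms):
            tid = f"T{ti + 1:03d}"
            size = int(rng.integers(10, 41))
            members = [term_pool[int(i)] for i in rng.choice(len(term_pool), size=size, replace=False)]
            fh.write(tid + "\tGO-biological-process|background term\t" + "\t".join(members) + "\n")

    truth = SyntheticTruth(
        planted_common=GeneSet(common, provenance="planted common genes"),
        planted_module=GeneSet(module, provenance="planted network module"),
        planted_terms=(planted_id,),
        expected_top_candidate=winner,
        layer_roles=roles,
        propagation_seeds=GeneSet(prop_seeds, provenance="planted propagation seeds"),
        held_out_module=GeneSet(held_out, provenance="held-out module genes"),
        seed_chemicals=tuple(seed_chems),
    )
    manifest = {
        "config": dataclasses.asdict(config),
        "truth": {
            "planted_common": list(truth.planted_common),
            "planted_module": list(truth.planted_module),
            "planted_terms": list(truth.planted_terms),
            "expected_top_candidate": truth.expected_top_candidate,
            "layer_roles": truth.layer_roles,
            "propagation_seeds": list(truth.propagation_seeds),
            "held_out_module": list(truth.held_out_module),
            "seed_chemicals": list(truth.seed_chemicals),
        },
    }
    bundle.manifest_json.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return bundle, truth


def table_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Copy the packaged verbatim fixtures of the printed reference tables.

    ``table1_chemical_gene.tsv`` — the four seed chemicals and their curated
    interacting genes (sets of 5, 115, 20 and 134 symbols; union 229);
    ``table2_network_layers.tsv`` — the printed top-centrality rows as a
    symmetrized, category-coded edge list; ``table3_candidates.tsv`` — the
    printed top-five candidate chemicals with scores.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    for name in FIXTURE_NAMES:
        target = outdir / name
        with resources.as_file(resources.files("edcnet.data") / name) as src:
            shutil.copyfile(src, target)
        out[name] = target
    return out


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture (read-only use)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    with resources.as_file(resources.files("edcnet.data") / name) as p:
        return Path(p)
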