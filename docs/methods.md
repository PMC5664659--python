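# Methods

## The workflow and its assumptions

`edcnet` links a set of *seed chemicals* to a disease through shared gene
interactions, then uses a gene network to (a) find the most central genes of
the shared set, (b) predict further associated genes, and (c) prioritize
additional *candidate chemicals*. The underlying assumptions are the usual
ones of guilt-by-association analysis:

- curated chemical–gene interaction rows are treated as binary membership
  (any interaction type counts; duplicate rows per interaction type are
  collapsed), restricted to one organism (default `Homo sapiens`, exact
  string match after whitespace normalization);
- genes are identified by symbol only, normalized to uppercase; no
  Entrez/Ensembl mapping is attempted, so symbol drift between resources is
  the user's responsibility;
- a gene relevant to the disease mechanism is assumed to be *near* the
  common genes in a functional association network, which justifies label
  propagation as the prediction principle;
- a chemical's disease relevance is assumed to scale with how central its
  interacting genes are, which justifies the summed-degree score.

## Layer combination

Evidence layers (co-expression, physical interaction, pathway, predicted,
co-localization, shared protein domains, genetic interaction — labels or
numeric codes 1–7 in the edge TSV) are merged as a convex combination
`W* = Σ α_l W_l`. The weights solve a non-negative least-squares regression
of the seed co-membership indicator on per-layer adjacency over all
unordered node pairs, with an unpenalized intercept and an L2 penalty
`ρ‖α‖²` (default `ρ = 1.0`):

- the intercept absorbs the baseline co-membership rate so that layers are
  rewarded for *contrast* between seed–seed pairs and other pairs, not for
  overall density;
- the NNLS active-set solution implements the clip-negative-and-refit
  behaviour exactly;
- degenerate cases (a single layer, fewer than two seeds inside the layers,
  or an all-zero solution) fall back to equal weights;
- fitted weights are renormalized to sum to 1, so `ρ` only shapes the
  relative allocation.

Within a layer, edges are undirected, self-loops are dropped, and duplicate
pairs merge by maximum weight. In the composite, an edge's evidence
categories are the union over contributing layers; combined weights of zero
are removed.

## Label propagation

Scores solve `(I + λ L_sym) f = y` with the symmetric normalized Laplacian
and bias `y = +1` on seeds, `−|S|/n` on non-seeds (the standard
negative-prior convention for this algorithm family: the negative mass keeps
the solution centred so that unrelated components score below zero).
`λ > 0` (default 1.0) controls smoothing. Numerical notes:

- the system is symmetric positive definite for every `λ > 0`; a dense
  direct solve is used (the package targets networks of tens to a few
  thousand nodes);
- nodes with zero degree have no Laplacian coupling; their score is exactly
  `y_i / (1 + λ)`;
- propagation cannot cross connected components, so seeds rank their own
  component above others — asserted as a unit test;
- the spread of non-seed scores is ~0 as `λ → 0` (scores approach the bias
  vector), peaks at moderate `λ`, and decays monotonically in the
  strong-smoothing regime; the regression test asserts the decay for
  `λ ≥ 2`;
- ranking ties (e.g. automorphic leaves of a star) are broken by ascending
  gene symbol, making all outputs byte-reproducible.

The default prediction size is `k = 20` non-seed genes, matching the
workflow's conventional report size; `k` is a config field.

## Degree centrality and the candidate score

Degree centrality is the number of *distinct* neighbors in the composite
network — an edge supported by four evidence categories counts once. This is
forced by the reference table the fixture encodes, where the top gene lists
13 interacting genes (several multi-category) and has printed centrality 13.
The candidate score is the plain integer sum of the degrees of the
candidate's query-gene interactions; genes absent from the network
contribute 0 (logged, not an error), and no normalization by gene-set size
is applied. Candidates whose gene sets do not intersect the query set are
omitted. Rows sort by descending score, then chemical name.

## Enrichment and kappa grouping

Per term: one-sided upper-tail hypergeometric p-value with
`k = |query ∩ term|`, `K = |term|`, `n = |query ∩ universe|`,
`N = |universe|`. The universe defaults to the union of all term genes in
the GMT; an explicit background can be supplied. The significance filter
defaults to **raw** `p < 0.05` — the convention of the kappa-grouping
visualization tools this stage mirrors — with Benjamini–Hochberg or
Bonferroni filtering available via `filter_on: adjusted`. Adjusted p-values
are reported in every output regardless of the filter.

Significant terms are linked when the Cohen's kappa of their binary
membership vectors over the universe is ≥ 0.4 (configurable); groups are
the connected components of this term graph. This is a deterministic,
order-independent approximation of the iterative leading-group merge used
by interactive tools; components, unlike iterative merging, cannot depend
on term input order. Each group's representative is its smallest-p member,
ties broken by lexicographic term id. Kappa edge cases: if expected
agreement is 1 (both terms empty or both equal to the universe), kappa is
defined as 1 for identical terms and 0 otherwise.

## Synthetic data: what it emulates and what it does not

The generator emits a full input bundle (chemical–gene TSV, disease gene
list, category TSV, layer TSV, GMT, JSON manifest) with planted structure:

| parameter | default | meaning |
|---|---|---|
| `overlap_size` | 27 | genes common to the seed-chemical union and disease list |
| `seed_union_size` | 229 | union of the seed chemicals' gene sets |
| `disease_list_size` | 669 | disease mutated-gene list size |
| `n_seed_chemicals` / `n_chemicals` | 4 / 10 | seed and total chemicals |
| `n_network_nodes` | 60 | composite-network node count |
| `module_size` | 15 | planted dense module (subset of the common genes) |
| `n_propagation_seeds` | 8 | module genes seeded in recovery benchmarks |
| `n_layers` | 4 | evidence layers, first half signal / rest noise |
| `noise_edge_prob` | 0.05 | Erdős–Rényi edge probability (all layers) |
| `within_module_edge_prob` | 0.9 | extra module-pair edge probability (signal layers) |
| `n_terms` / `planted_term_overlap` | 20 / 12 | GMT terms; planted term's query-gene content |
| `random_seed` | 0 | single source of randomness |

The headline sizes (27/229/669, 60-node network, 15-gene module with 8
seeds, 20 predicted genes) mirror the scale of the motivating analysis; the
remaining values are fixed desk-scale choices: a 5% background edge density
with 90% within-module density gives a clearly assortative but not trivial
module, and 10 chemicals / 20 terms keep every screening table small enough
to inspect by eye. Noise layers are pure Erdős–Rényi with uniform (0, 1]
weights; signal layers add module edges at weight 1, the simplest contrast
that exercises the weight fitting. One candidate chemical is planted to
interact with the highest-degree module hubs (extended, deterministically,
until its score strictly exceeds every other candidate's), and one GMT term
is planted to contain `planted_term_overlap` common genes.

What passing on this bench does **not** show: real chemical–gene tables
have interaction-type structure, heavy-tailed per-chemical set sizes, and
symbol synonymy, none of which are simulated; real association layers are
weighted by profile similarity rather than uniform noise; and real GO/KEGG
annotations are hierarchical and strongly overlapping, so kappa groups on
real data are larger and less clean than on independent random terms.
Recovery rates here (AUROC ≈ 1, 50/50 signal-layer wins) characterize the
implementation's correctness under a favourable planted model, not expected
performance on curated databases.

## Verbatim reference fixtures

Three small TSV fixtures ship inside the package and encode the workflow's
printed reference tables: the four-chemical interaction table (gene sets of
5, 115, 20 and 134 symbols; union 229), the symmetrized top-centrality edge
list with per-edge evidence codes (degrees ESR1 13, TP53 12, NCOA1 12,
AKT1 11, BCL6 11), and the top-five candidate score table. Where running
text and the curated table disagree on a symbol, the table is taken as
authoritative. The top candidate row of the score table depends on degrees
of genes outside the five printed network rows, so it is checked for
internal consistency (score differences and an inferred AR degree of 10)
rather than recomputed.

## Known limitations

- Exact recovery of a specific historical 20-gene prediction is out of
  scope: it depends on a particular genome-scale network snapshot and
  weighting mode that a desk-scale composite cannot reproduce.
- Published enrichment p-values tied to specific GO/KEGG release dates are
  likewise not reproduction targets; enrichment is validated against
  exhaustive-enumeration oracles and planted terms instead.
- The dense linear-algebra path is O(n³) in network nodes; the package is
  not intended for genome-scale composites.
- Chemical identity uses (normalized name, CAS) with CAS precedence; no
  structure-based identity resolution is attempted.
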