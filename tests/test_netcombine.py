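"""Composite-network construction, layer weighting, and label propagation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edcnet.integration import FormatError, GeneSet
from edcnet.netcombine import (
    CATEGORIES,
    NetworkLayer,
    build_composite,
    fit_layer_weights,
    load_layers,
    propagate,
    top_predicted,
)


def layer(name, edges, category="co-expression"):
    return NetworkLayer(name=name, category=category, edges=dict(edges))


def path_layer(name="chain", genes=("A", "B", "C", "D"), w=1.0):
    return layer(name, {(a, b): w for a, b in zip(genes, genes[1:])})


class TestLoadLayers:
    def test_table2_has_all_seven_categories(self, table2_path):
        layers = load_layers(table2_path)
        assert {l.category for l in layers} >= set(CATEGORIES[:6])
        assert len({l.category for l in layers}) == 7

    def test_self_loop_dropped(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text(
            "source\ttarget\tlayer_name\tcategory\tweight\n"
            "A\tA\tL\t1\t0.5\nA\tB\tL\t1\t0.5\n"
        )
        (only,) = load_layers(p)
        assert only.edges == {("A", "B"): 0.5}

    def test_duplicate_edge_max_merge(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text(
            "source\ttarget\tlayer_name\tcategory\tweight\n"
            "A\tB\tL\t1\t0.2\nB\tA\tL\t1\t0.5\n"
        )
        (only,) = load_layers(p)
        assert only.edges == {("A", "B"): 0.5}

    def test_unknown_category_rejected(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("source\ttarget\tlayer_name\tcategory\tweight\nA\tB\tL\tbogus\t1\n")
        with pytest.raises(FormatError, match="bogus"):
            load_layers(p)

    def test_negative_weight_rejected(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("source\ttarget\tlayer_name\tcategory\tweight\nA\tB\tL\t1\t-1\n")
        with pytest.raises(ValueError):
            load_layers(p)


class TestFitLayerWeights:
    def test_single_layer_gets_weight_one(self):
        w = fit_layer_weights([path_layer()], GeneSet(["A", "B"]))
        assert w == {"chain": 1.0}

    def test_identical_layers_split_evenly(self):
        l1, l2 = path_layer("l1"), path_layer("l2")
        w = fit_layer_weights([l1, l2], GeneSet(["A", "B", "C"]))
        assert w["l1"] == pytest.approx(w["l2"])
        assert sum(w.values()) == pytest.approx(1.0)

    def test_empty_layer_list_rejected(self):
        with pytest.raises(ValueError):
            fit_layer_weights([], GeneSet(["A"]))

    def test_seed_outside_layers_rejected(self):
        with pytest.raises(KeyError):
            fit_layer_weights([path_layer()], GeneSet(["A", "ZZ"]))

    def test_single_seed_falls_back_to_equal(self):
        w = fit_layer_weights([path_layer("l1"), layer("l2", {("A", "C"): 1.0})], GeneSet(["A"]))
        assert w == {"l1": 0.5, "l2": 0.5}

    def test_signal_layer_outweighs_noise(self, bundle, truth):
        layers = load_layers(bundle.layers_tsv)
        w = fit_layer_weights(layers, truth.planted_module)
        signal = [w[n] for n, role in truth.layer_roles.items() if role == "signal"]
        noise = [w[n] for n, role in truth.layer_roles.items() if role == "noise"]
        assert min(signal) > max(noise)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_weights_nonnegative_and_normalized(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(12)]
        layers = []
        for li in range(3):
            edges = {}
            for i in range(12):
                for j in range(i + 1, 12):
                    if rng.random() < 0.3:
                        edges[(genes[i], genes[j])] = float(rng.random())
            edges.setdefault((genes[0], genes[1]), 0.5)
            layers.append(layer(f"l{li}", edges))
        w = fit_layer_weights(layers, GeneSet(genes[:4]))
        assert all(v >= 0 for v in w.values())
        assert sum(w.values()) == pytest.approx(1.0)


class TestBuildComposite:
    def test_single_layer_identity(self):
        l = path_layer()
        comp = build_composite([l], {"chain": 1.0})
        for (a, b), w in l.edges.items():
            assert comp.adjacency(a, b) == pytest.approx(w)

    def test_two_layer_arithmetic_and_category_union(self):
        l1 = layer("l1", {("A", "B"): 1.0}, "co-expression")
        l2 = layer("l2", {("A", "B"): 1.0}, "pathway")
        comp = build_composite([l1, l2], {"l1": 0.5, "l2": 0.5})
        assert comp.adjacency("A", "B") == pytest.approx(1.0)
        assert comp.categories("A", "B") == {"co-expression", "pathway"}

    def test_table2_esr1_ar_categories(self, table2_path):
        layers = load_layers(table2_path)
        comp = build_composite(layers, {l.name: 1.0 for l in layers})
        assert comp.categories("ESR1", "AR") == {
            "physical-interaction",
            "pathway",
            "co-localization",
            "shared-protein-domains",
        }

    def test_weight_key_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_composite([path_layer()], {"wrong": 1.0})

    def test_weights_renormalized(self):
        comp = build_composite([path_layer()], {"chain": 4.0})
        assert comp.layer_weights == {"chain": 1.0}


class TestPropagate:
    def test_seeds_stay_within_component(self):
        comp = build_composite(
            [layer("l", {("A", "B"): 1.0, ("B", "C"): 1.0, ("X", "Y"): 1.0})],
            {"l": 1.0},
        )
        res = propagate(comp, GeneSet(["A"]))
        comp1 = {"B", "C"}
        comp2 = {"X", "Y"}
        assert min(res.scores[g] for g in comp1) > max(res.scores[g] for g in comp2)

    def test_star_graph_leaves_tie_alphabetically(self):
        leaves = ["D", "B", "E", "C"]
        comp = build_composite(
            [layer("l", {("HUB", leaf): 1.0 for leaf in leaves})], {"l": 1.0}
        )
        res = propagate(comp, GeneSet(["HUB"]))
        leaf_scores = {res.scores[l] for l in leaves}
        assert len(leaf_scores) == 1  # symmetry: all leaves equal
        assert res.ranking == sorted(leaves)

    def test_small_instance_matches_dense_inverse(self):
        """On ≤6-node graphs, the solver must agree with brute-force inversion."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            genes = [f"N{i}" for i in range(n)]
            W = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.6), k=1)
            edges = {
                (genes[i], genes[j]): float(W[i, j])
                for i in range(n)
                for j in range(i + 1, n)
                if W[i, j] > 0
            }
            if not edges:
                continue
            comp = build_composite([layer("l", edges)], {"l": 1.0})
            nodes = list(comp.nodes)
            seeds = GeneSet([nodes[0]])
            lam = float(rng.uniform(0.1, 3.0))
            res = propagate(comp, seeds, regularization=lam)

            # independent dense oracle
            m = len(nodes)
            A = np.zeros((m, m))
            for (a, b), w in edges.items():
                i, j = nodes.index(a), nodes.index(b)
                A[i, j] = A[j, i] = w
            d = A.sum(1)
            dh = np.where(d > 0, 1 / np.sqrt(np.where(d > 0, d, 1)), 0.0)
            L = np.eye(m) - np.outer(dh, dh) * A
            L[d == 0] = 0
            L[:, d == 0] = 0
            for i in range(m):
                if d[i] == 0:
                    L[i, i] = 1.0
            y = np.array([1.0 if g in set(seeds) else -1 / m for g in nodes])
            expected = np.linalg.inv(np.eye(m) + lam * L) @ y
            got = np.array([res.scores[g] for g in nodes])
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_relabeling_invariance(self):
        edges = {("A", "B"): 0.7, ("B", "C"): 0.2, ("A", "D"): 1.0}
        comp = build_composite([layer("l", edges)], {"l": 1.0})
        res = propagate(comp, GeneSet(["A"]))
        relabel = {"A": "W", "B": "Z", "C": "Q", "D": "M"}
        edges2 = {(relabel[a], relabel[b]): w for (a, b), w in edges.items()}
        comp2 = build_composite([layer("l", edges2)], {"l": 1.0})
        res2 = propagate(comp2, GeneSet(["W"]))
        for g, g2 in relabel.items():
            assert res.scores[g] == pytest.approx(res2.scores[g2], abs=1e-12)

    def test_strong_regularization_shrinks_nonseed_spread(self):
        """In the strong-smoothing regime, increasing the regularization
        flattens the non-seed score profile (spread starts near zero at λ≈0,
        peaks, and then decays — so monotonicity is asserted past the peak)."""
        comp = build_composite(
            [layer("l", {("A", "B"): 1.0, ("B", "C"): 0.3, ("C", "D"): 0.8})], {"l": 1.0}
        )
        seeds = GeneSet(["A"])
        spreads = []
        for lam in (2.0, 4.0, 8.0, 16.0, 64.0):
            res = propagate(comp, seeds, regularization=lam)
            vals = [res.scores[g] for g in res.ranking]
            spreads.append(max(vals) - min(vals))
            assert all(np.isfinite(v) for v in res.scores.values())
        assert spreads == sorted(spreads, reverse=True)

    def test_layer_direct_equals_composite(self):
        l = path_layer()
        via_composite = propagate(build_composite([l], {"chain": 1.0}), GeneSet(["A"]))
        direct = propagate(l, GeneSet(["A"]))
        assert via_composite.scores == direct.scores

    def test_error_contracts(self):
        comp = build_composite([path_layer()], {"chain": 1.0})
        with pytest.raises(ValueError):
            propagate(comp, GeneSet([]))
        with pytest.raises(KeyError):
            propagate(comp, GeneSet(["ZZ"]))
        with pytest.raises(ValueError):
            propagate(comp, GeneSet(["A"]), regularization=0.0)


class TestTopPredicted:
    def test_boundaries(self):
        res = propagate(path_layer(), GeneSet(["A"]))
        assert len(top_predicted(res, 0)) == 0
        assert list(top_predicted(res, 100)) == res.ranking

    def test_planted_module_recovery(self, bundle, truth):
        """≥6 of the 7 held-out module genes in the top-7 predictions."""
        layers = load_layers(bundle.layers_tsv)
        weights = fit_layer_weights(layers, truth.propagation_seeds)
        comp = build_composite(layers, weights)
        res = propagate(comp, truth.propagation_seeds)
        held = set(truth.held_out_module)
        top = top_predicted(res, len(held))
        assert sum(g in held for g in top) >= len(held) - 1
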