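"""Three-step feature selection: filters, network construction, hub greedy."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutdx import (
    SelectionConfig,
    abundance_filter,
    build_cooccurrence_graph,
    hub_selection,
    ranksum_pvalue,
    select_features,
    wilcoxon_filter,
)


def _fam_frame(values: np.ndarray, prefix: str = "f") -> pd.DataFrame:
    return pd.DataFrame(
        values,
        index=[f"S{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{j}" for j in range(values.shape[1])],
    )


class TestAbundanceFilter:
    def test_strictly_above_floor(self):
        X = pd.DataFrame(
            {"at_floor": [1e-6, 0.0], "zero": [0.0, 0.0], "seen": [0.5, 0.0]},
            index=["S0", "S1"],
        )
        assert abundance_filter(X) == ["seen"]

    def test_single_high_sample_suffices(self):
        X = pd.DataFrame({"f": [0.0, 0.5, 0.0]}, index=["a", "b", "c"])
        assert abundance_filter(X) == ["f"]


def _enumerated_ranksum_p(x, y):
    """Independent oracle: full enumeration of group assignments.

    Uses midranks and the permutation definition of the two-sided p-value,
    with the null mean obtained from the enumeration itself.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    m = len(x)
    sums = np.array(
        [sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), m)]
    )
    w_obs = ranks[:m].sum()
    center = sums.mean()
    return float(np.mean(np.abs(sums - center) >= abs(w_obs - center) - 1e-12))


class TestRanksum:
    def test_separated_small_groups_exact(self):
        # 2 / C(10,5) of all rank assignments are at least this extreme
        p = ranksum_pvalue([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252)

    def test_constant_feature_is_uninformative(self):
        assert ranksum_pvalue([3.0] * 5, [3.0] * 6) == 1.0

    @pytest.mark.parametrize("with_ties", [False, True])
    def test_exact_path_matches_enumeration_oracle(self, with_ties):
        rng = np.random.default_rng(4)
        for m, n in [(2, 3), (4, 4), (5, 7), (8, 6)]:
            data = rng.normal(size=m + n)
            if with_ties:
                data = np.round(data, 0)
            p = ranksum_pvalue(data[:m], data[m:])
            assert p == pytest.approx(_enumerated_ranksum_p(data[:m], data[m:]))

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            ranksum_pvalue([1.0], [2.0, 3.0])

    def test_filter_exposes_pvalues_and_respects_alpha(self):
        rng = np.random.default_rng(7)
        null = rng.normal(size=(30, 10))
        signal = np.r_[rng.normal(0, 1, 15), rng.normal(4, 1, 15)]
        X = _fam_frame(np.c_[signal, null])
        groups = ["a"] * 15 + ["b"] * 15
        kept, pvalues = wilcoxon_filter(X, groups)
        assert list(pvalues.index) == list(X.columns)
        assert "f0" in kept
        assert all(pvalues[f] < 0.01 for f in kept)
        assert all(pvalues[f] >= 0.01 for f in X.columns if f not in kept)

    def test_filter_requires_two_groups_of_two(self):
        X = _fam_frame(np.ones((3, 2)))
        with pytest.raises(ValueError):
            wilcoxon_filter(X, ["a", "a", "b"])


class TestCooccurrenceGraph:
    def test_perfect_monotone_association(self):
        x = np.arange(10, dtype=float)
        X = _fam_frame(np.c_[x, x**2])
        g = build_cooccurrence_graph(X)
        assert g.has_edge("f0", "f1")
        assert g.edges["f0", "f1"]["rho"] == pytest.approx(1.0)

    def test_anticorrelated_pair_and_isolated_third(self):
        rng = np.random.default_rng(0)
        x = np.arange(12, dtype=float)
        z = rng.normal(size=12)
        X = _fam_frame(np.c_[x, -x, z])
        g = build_cooccurrence_graph(X)
        assert g.edges["f0", "f1"]["rho"] == pytest.approx(-1.0)
        assert g.degree("f2") == 0

    def test_independent_noise_rarely_validated(self):
        rng = np.random.default_rng(11)
        X = _fam_frame(rng.normal(size=(100, 2)))
        g = build_cooccurrence_graph(X)
        assert not g.has_edge("f0", "f1")

    def test_constant_feature_stays_isolated(self, caplog):
        X = _fam_frame(np.c_[np.arange(8.0), np.full(8, 0.3), np.arange(8.0) ** 2])
        with caplog.at_level("WARNING"):
            g = build_cooccurrence_graph(X)
        assert g.degree("f1") == 0
        assert "constant" in caplog.text

    def test_permutation_mode_agrees_on_strong_edge(self):
        x = np.arange(20, dtype=float)
        X = _fam_frame(np.c_[x, 2 * x + 1])
        cfg = SelectionConfig(edge_p_mode="permutation", n_permutations=199)
        g = build_cooccurrence_graph(X, cfg)
        assert g.has_edge("f0", "f1")


def _greedy_reference(nodes, edges, strong_r=0.4, min_nodes=3):
    """Independent brute-force greedy over explicit adjacency dicts."""
    adjacency = {v: {} for v in nodes}
    for u, v, rho in edges:
        adjacency[u][v] = rho
        adjacency[v][u] = rho
    remaining = set(nodes)
    selected = []
    while len(remaining) >= min_nodes:
        best, best_key = None, None
        for v in sorted(remaining):
            nbrs = [w for w in adjacency[v] if w in remaining]
            degree = len(nbrs)
            strength = math.fsum(abs(adjacency[v][w]) for w in sorted(nbrs))
            key = (-degree, -strength, v)
            if best_key is None or key < best_key:
                best, best_key = v, key
        drop = {
            w for w in adjacency[best]
            if w in remaining and abs(adjacency[best][w]) > strong_r
        }
        selected.append(best)
        remaining -= drop | {best}
    return selected


def _random_graph(rng: np.random.Generator) -> nx.Graph:
    n = int(rng.integers(3, 13))
    g = nx.Graph()
    g.add_nodes_from(f"n{i:02d}" for i in range(n))
    prob = rng.uniform(0.1, 0.6)
    nodes = sorted(g.nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < prob:
                g.add_edge(
                    nodes[i], nodes[j],
                    rho=float(rng.uniform(-1, 1)), p=float(rng.uniform(0, 0.049)),
                )
    return g


class TestHubSelection:
    def test_star_center_forced(self):
        g = nx.Graph()
        for leaf in "bcde":
            g.add_edge("a", leaf, rho=0.9, p=0.001)
        assert hub_selection(g) == ["a"]

    def test_below_min_nodes_selects_nothing(self):
        g = nx.Graph()
        g.add_edge("a", "b", rho=0.9, p=0.001)
        assert hub_selection(g) == []

    def test_edgeless_nodes_selected_one_per_iteration(self):
        g = nx.Graph()
        g.add_nodes_from("abcde")
        # degree-0 nodes remove only themselves; the last two stay unselected
        assert hub_selection(g) == ["a", "b", "c"]

    def test_weak_edges_do_not_remove_neighbors(self):
        g = nx.Graph()
        g.add_edge("a", "b", rho=0.3, p=0.01)
        g.add_edge("a", "c", rho=0.9, p=0.01)
        # a wins by degree, removes only c; b survives but then < min_nodes
        assert hub_selection(g) == ["a"]

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            g = _random_graph(rng)
            edges = [(u, v, d["rho"]) for u, v, d in g.edges(data=True)]
            assert hub_selection(g) == _greedy_reference(sorted(g.nodes), edges)


class TestSelectFeatures:
    def _planted_cohort(self):
        # planted markers differ a thousand-fold between groups but stay at
        # tiny absolute abundance, so closure barely perturbs the null
        # features and the survivors are exactly the planted set
        rng = np.random.default_rng(42)
        n = 40
        null = rng.lognormal(0.0, 1.0, (n, 15))
        groups = np.array(["A"] * 20 + ["B"] * 20)
        planted = np.where(
            groups[:, None] == "B",
            rng.lognormal(np.log(1e-3), 0.3, (n, 5)),
            rng.lognormal(np.log(1e-5), 0.3, (n, 5)),
        )
        X = np.c_[planted, null]
        X /= X.sum(axis=1, keepdims=True)
        columns = [f"P{i}" for i in range(5)] + [f"N{i}" for i in range(15)]
        frame = pd.DataFrame(X, index=[f"S{i}" for i in range(n)], columns=columns)
        return frame, groups

    def test_nesting_and_planted_recovery(self):
        frame, groups = self._planted_cohort()
        result = select_features(frame, groups)
        assert set(result.hubs) <= set(result.after_wilcoxon)
        assert set(result.after_wilcoxon) <= set(result.after_abundance)
        assert set(result.after_wilcoxon) == {f"P{i}" for i in range(5)}
        assert len(result.hubs) >= 1
        assert set(result.hubs) <= {f"P{i}" for i in range(5)}

    def test_empty_survivor_set_is_not_an_error(self):
        rng = np.random.default_rng(9)
        frame = _fam_frame(rng.normal(10, 0.1, size=(12, 4)))
        cfg = SelectionConfig(wilcoxon_alpha=1e-12)
        result = select_features(frame, ["a"] * 6 + ["b"] * 6, cfg)
        assert result.after_wilcoxon == []
        assert result.hubs == []

    def test_deterministic(self, tiny_separable):
        groups = tiny_separable.manifest.labels().values
        one = select_features(tiny_separable.fam.data, groups)
        two = select_features(tiny_separable.fam.data, groups)
        assert one.hubs == two.hubs
        assert one.after_wilcoxon == two.after_wilcoxon
        pd.testing.assert_series_equal(one.pvalues, two.pvalues)

    def test_selected_hubs_share_no_strong_edge(self, planted_markers):
        labels = planted_markers.manifest.labels().values
        result = select_features(planted_markers.fam.data, labels)
        for i, u in enumerate(result.hubs):
            for v in result.hubs[i + 1:]:
                if result.graph.has_edge(u, v):
                    assert abs(result.graph.edges[u, v]["rho"]) <= 0.4

    def test_json_and_edge_export(self, tmp_path):
        frame, groups = self._planted_cohort()
        result = select_features(frame, groups)
        result.write_json(tmp_path / "selection.json")
        result.write_edges(tmp_path / "edges.tsv")
        assert (tmp_path / "selection.json").stat().st_size > 0
        header = (tmp_path / "edges.tsv").read_text().splitlines()[0]
        assert header == "feature_i\tfeature_j\trho\tp"
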