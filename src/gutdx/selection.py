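"""Case-specific three-step feature selection.

Given a feature abundance matrix and a two-group contrast, features are
narrowed in three nested steps:

(i)   abundance filter — keep features whose relative abundance exceeds a
      detection floor (default 1e-6) in at least one sample;
(ii)  differential filter — keep features whose two-sided Wilcoxon
      rank-sum p-value falls below alpha (default 0.01);
(iii) redundancy collapse — build a co-occurrence network whose edges are
      statistically validated Spearman correlations (p < 0.05), then
      greedily pick the most intensively connected node per iteration,
      removing it together with its strongly correlated neighbors
      (|rho| > 0.4), until fewer than three nodes remain.

Step (iii) keeps one representative per correlated cluster of taxa, so the
final feature set is both discriminative and non-redundant.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .profiles import FeatureAbundanceMatrix

logger = logging.getLogger(__name__)


def _frame(fam) -> pd.DataFrame:
    if isinstance(fam, FeatureAbundanceMatrix):
        return fam.data
    return fam


@dataclass
class SelectionConfig:
    """Tunables for the three-step selection; defaults follow the method."""

    abundance_min: float = 1e-6
    wilcoxon_alpha: float = 0.01
    edge_alpha: float = 0.05
    strong_r: float = 0.4
    min_nodes: int = 3
    #: "analytic" = t-approximation Spearman p; "permutation" = empirical p
    edge_p_mode: str = "analytic"
    n_permutations: int = 999
    permutation_seed: int = 0
    #: both groups at or below this size -> exact rank-sum enumeration
    exact_max_n: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.abundance_min < 1):
            raise ValueError("abundance_min must lie in (0, 1)")
        for name in ("wilcoxon_alpha", "edge_alpha"):
            if not (0 < getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if not (0 < self.strong_r < 1):
            raise ValueError("strong_r must lie in (0, 1)")
        if self.min_nodes < 1:
            raise ValueError("min_nodes must be >= 1")
        if self.edge_p_mode not in ("analytic", "permutation"):
            raise ValueError("edge_p_mode must be 'analytic' or 'permutation'")


@dataclass
class SelectionResult:
    """Nested feature lists from the three steps plus diagnostics."""

    after_abundance: list[str]
    after_wilcoxon: list[str]
    hubs: list[str]
    pvalues: pd.Series
    graph: nx.Graph = field(repr=False, default_factory=nx.Graph)

    def to_dict(self) -> dict:
        return {
            "after_abundance": self.after_abundance,
            "after_wilcoxon": self.after_wilcoxon,
            "hubs": self.hubs,
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_edges(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("feature_i\tfeature_j\trho\tp\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['rho']!r}\t{d['p']!r}\n")


def abundance_filter(fam, cfg: SelectionConfig | None = None) -> list[str]:
    """Keep features seen above the detection floor in at least one sample."""
    cfg = cfg or SelectionConfig()
    X = _frame(fam)
    if X.empty:
        raise ValueError("empty abundance matrix")
    keep = X.max(axis=0) > cfg.abundance_min  # strictly greater
    return list(X.columns[keep])


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum p-values
# ---------------------------------------------------------------------------

def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by shift-DP over scaled midranks.

    Midranks are doubled so ties become integers; the two-sided p is the
    permutation probability of a rank sum at least as far from its mean as
    observed.  Exact for any tie pattern.
    """
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2.0 * stats.rankdata(pooled)).astype(np.int64)
    m, n = len(x), len(pooled)
    w_obs = int(ranks2[:m].sum())
    mean2 = m * (n + 1)  # E[2W] is integral
    dev = abs(w_obs - mean2)
    max_sum = int(ranks2.sum())
    # dp[k, s] = number of size-k subsets of the scaled ranks with sum s
    dp = np.zeros((m + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(m, 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum - r + 1]
    counts = dp[m]
    sums = np.arange(max_sum + 1)
    total = counts.sum()
    extreme = counts[np.abs(sums - mean2) >= dev].sum()
    return float(extreme / total)


def ranksum_pvalue(x, y, exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups are small (<= ``exact_max_n``),
    otherwise the tie-corrected, continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        return _exact_ranksum_p(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def wilcoxon_filter(
    fam, groups: Sequence, cfg: SelectionConfig | None = None
) -> tuple[list[str], pd.Series]:
    """Keep features with two-sided rank-sum p < alpha; expose all p-values."""
    cfg = cfg or SelectionConfig()
    X = _frame(fam)
    groups = np.asarray(groups)
    if len(groups) != len(X):
        raise ValueError("groups must align with abundance rows")
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(levels)}")
    a = X.values[groups == levels[0]]
    b = X.values[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")

    if len(a) <= cfg.exact_max_n and len(b) <= cfg.exact_max_n:
        pvals = np.array(
            [ranksum_pvalue(a[:, j], b[:, j], cfg.exact_max_n) for j in range(X.shape[1])]
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=True, axis=0,
            )
            pvals = np.asarray(res.pvalue, dtype=float)
        # constant features have zero rank variance -> undefined z; no
        # rank separation is possible, so p = 1
        constant = (X.values == X.values[0]).all(axis=0)
        pvals = np.where(np.isnan(pvals) | constant, 1.0, pvals)
    pvalues = pd.Series(pvals, index=X.columns, name="ranksum_p")
    kept = list(X.columns[pvals < cfg.wilcoxon_alpha])
    return kept, pvalues


# ---------------------------------------------------------------------------
# Co-occurrence network and hub extraction
# ---------------------------------------------------------------------------

def _spearman_matrices(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman rho (Pearson on midranks) and two-sided t-approx p.

    Constant columns yield NaN entries and stay isolated in the graph.
    """
    n = X.shape[0]
    ranks = stats.rankdata(X, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) == 1.0] = 0.0
    p[~np.isfinite(rho)] = np.nan
    return rho, p


def _permutation_edge_p(
    ranks: np.ndarray, i: int, j: int, rho_obs: float, n_perm: int,
    rng: np.random.Generator,
) -> float:
    ri = ranks[:, i]
    rj = ranks[:, j]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(rj)
        r = np.corrcoef(ri, perm)[0, 1]
        if abs(r) >= abs(rho_obs):
            hits += 1
    return (hits + 1) / (n_perm + 1)


def build_cooccurrence_graph(fam, cfg: SelectionConfig | None = None) -> nx.Graph:
    """Spearman co-occurrence network keeping only validated edges (p < alpha)."""
    cfg = cfg or SelectionConfig()
    X = _frame(fam)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features to build a network")
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples to build a network")
    features = list(X.columns)
    values = X.values
    constant = [f for f, col in zip(features, values.T) if np.all(col == col[0])]
    if constant:
        logger.warning(
            "constant features have undefined correlations and stay isolated: %s",
            constant[:10],
        )
    rho, p = _spearman_matrices(values)

    graph = nx.Graph()
    graph.add_nodes_from(features)
    if cfg.edge_p_mode == "permutation":
        ranks = stats.rankdata(values, axis=0)
        rng = np.random.default_rng(cfg.permutation_seed)
    for i in range(len(features)):
        for j in range(i + 1, len(features)):
            r = rho[i, j]
            if not np.isfinite(r):
                continue
            if cfg.edge_p_mode == "permutation":
                pv = _permutation_edge_p(ranks, i, j, r, cfg.n_permutations, rng)
            else:
                pv = p[i, j]
            if np.isfinite(pv) and pv < cfg.edge_alpha:
                graph.add_edge(features[i], features[j], rho=float(r), p=float(pv))
    return graph


def _node_strength(graph: nx.Graph, node) -> float:
    # fsum over id-sorted neighbors: summation-order independent, so the
    # tie-break is reproducible across implementations
    return math.fsum(
        abs(graph.edges[node, nbr]["rho"]) for nbr in sorted(graph.neighbors(node))
    )


def hub_selection(graph: nx.Graph, cfg: SelectionConfig | None = None) -> list[str]:
    """Iteratively extract the most intensively connected node.

    Each iteration picks the node of maximal degree (ties: larger sum of
    |rho| over validated incident edges, then lexicographically smaller id),
    removes it together with its strongly correlated neighbors
    (|rho| > strong_r), and repeats while at least ``min_nodes`` nodes
    remain.  Leftover nodes are not selected.  Degree-0 nodes are ordinary
    candidates: an uncorrelated but significant feature is kept, one per
    iteration.
    """
    cfg = cfg or SelectionConfig()
    g = graph.copy()
    hubs: list[str] = []
    while g.number_of_nodes() >= cfg.min_nodes:
        best = min(
            g.nodes,
            key=lambda v: (-g.degree(v), -_node_strength(g, v), v),
        )
        strong = [
            nbr for nbr in g.neighbors(best)
            if abs(g.edges[best, nbr]["rho"]) > cfg.strong_r
        ]
        hubs.append(best)
        g.remove_nodes_from([best, *strong])
    return hubs


def select_features(
    fam, groups: Sequence, cfg: SelectionConfig | None = None
) -> SelectionResult:
    """Run the three selection steps in order and record every stage."""
    cfg = cfg or SelectionConfig()
    X = _frame(fam)
    after_abundance = abundance_filter(X, cfg)
    if not after_abundance:
        empty = pd.Series(dtype=float, name="ranksum_p")
        return SelectionResult([], [], [], empty, nx.Graph())
    after_wilcoxon, pvalues = wilcoxon_filter(X[after_abundance], groups, cfg)
    if len(after_wilcoxon) >= 2 and X.shape[0] >= 4:
        graph = build_cooccurrence_graph(X[after_wilcoxon], cfg)
    else:
        graph = nx.Graph()
        graph.add_nodes_from(after_wilcoxon)
    hubs = hub_selection(graph, cfg)

    _check_invariants(X.columns, after_abundance, after_wilcoxon, hubs, graph, cfg)
    return SelectionResult(after_abundance, after_wilcoxon, hubs, pvalues, graph)


def _check_invariants(all_features, after_abundance, after_wilcoxon, hubs,
                      graph: nx.Graph, cfg: SelectionConfig) -> None:
    if not set(hubs) <= set(after_wilcoxon) <= set(after_abundance) <= set(all_features):
        raise RuntimeError("selection nesting invariant violated")
    for i, u in enumerate(hubs):
        for v in hubs[i + 1:]:
            if graph.has_edge(u, v) and abs(graph.edges[u, v]["rho"]) > cfg.strong_r:
                raise RuntimeError(
                    f"selected hubs {u!r} and {v!r} share a strong validated edge"
                )
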