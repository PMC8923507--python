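"""Protein–protein interaction network analysis stratified by disorder.

The network is an undirected, deduplicated edge set (self-loops allowed,
matching multi-validated interaction exports).  Node degree counts distinct
incident interactions — a self-loop contributes one, the "interactions"
semantics of interaction-database counting.  Disorder-stratified degree
distributions are compared with pairwise Wilcoxon rank-sum (Mann–Whitney)
tests under Bonferroni correction, and partner-class interaction
proportions quantify who interacts with whom.
"""

from __future__ import annotations

import warnings
from collections.abc import Collection, Mapping, Sequence
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PPINetwork",
    "GroupComparison",
    "read_edges",
    "node_degree",
    "rank_sum_test",
    "pairwise_group_comparison",
    "partner_proportions",
    "stress_subnetwork",
]

#: Exact Mann–Whitney enumeration is used when both samples are at most this
#: size and tie-free; otherwise the normal approximation with continuity
#: correction and midrank tie handling applies.
EXACT_MAX_N = 10


class PPINetwork:
    """Undirected deduplicated interaction network (self-loops allowed)."""

    def __init__(self, edges: Collection[tuple[str, str]] = (), nodes: Collection[str] = ()):
        self.graph = nx.Graph()
        self.graph.add_nodes_from(nodes)
        for a, b in edges:
            self.graph.add_edge(a, b)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self.graph


def read_edges(path, mv_only: bool = False) -> PPINetwork:
    """Read a two-column edge TSV (id_a, id_b, optional ``mv`` flag column).

    Unordered duplicates collapse to one edge; self-rows are retained as
    self-loops.  With ``mv_only`` and an ``mv`` column present, rows whose
    flag is falsy are dropped (and counted on the returned network as
    ``n_dropped_non_mv``).  Extra columns are ignored, so exported slices of
    wider interaction-database tables can be used directly.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        net = PPINetwork()
        net.n_dropped_non_mv = 0
        return net
    missing = {"id_a", "id_b"} - set(df.columns)
    if missing:
        raise ValueError(f"edge table {path}: missing columns {sorted(missing)}")
    dropped = 0
    if mv_only and "mv" in df.columns:
        flags = df["mv"].astype(str).str.strip().isin({"1", "true", "True"})
        dropped = int((~flags).sum())
        df = df[flags]
    bad = df.index[df["id_a"].isna() | df["id_b"].isna()]
    if len(bad):
        raise ValueError(f"edge table {path}: malformed row at line {int(bad[0]) + 2}")
    net = PPINetwork(zip(df["id_a"], df["id_b"]))
    net.n_dropped_non_mv = dropped
    return net


def node_degree(network: PPINetwork, node: str) -> int:
    """Number of distinct interactions incident to ``node`` (self-loop counts once)."""
    if node not in network:
        raise KeyError(f"unknown node: {node}")
    return sum(1 for _ in network.graph.edges(node))


def degree_series(network: PPINetwork, nodes: Sequence[str] | None = None) -> pd.Series:
    """Degrees for ``nodes`` (default all network nodes); absent nodes get 0."""
    if nodes is None:
        nodes = network.nodes
    return pd.Series(
        [node_degree(network, n) if n in network else 0 for n in nodes],
        index=list(nodes),
        name="degree",
    )


def rank_sum_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact null enumeration when both samples have at most ``EXACT_MAX_N``
    observations and there are no ties; otherwise the normal approximation
    with continuity correction and midrank tie correction.  Returns
    ``(U statistic of sample_a, two-sided p)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupComparison:
    """One pairwise group contrast with its Bonferroni-corrected p-value."""

    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_bonferroni: float
    significant: bool


def pairwise_group_comparison(
    values_by_class: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """All unordered pairwise rank-sum contrasts between the given classes.

    The Bonferroni multiplier is the number of pairs actually tested; empty
    classes are skipped with a warning.
    """
    nonempty = {g: np.asarray(v, dtype=float) for g, v in values_by_class.items() if len(v)}
    for g in values_by_class:
        if g not in nonempty:
            warnings.warn(f"class {g!r} is empty; its pairs are skipped", stacklevel=2)
    pairs = list(combinations(nonempty, 2))
    if len(nonempty) < 2:
        raise ValueError("pairwise_group_comparison needs at least two non-empty classes")
    m = len(pairs)
    out = []
    for ga, gb in pairs:
        stat, p = rank_sum_test(nonempty[ga], nonempty[gb])
        p_bonf = min(1.0, p * m)
        out.append(GroupComparison(ga, gb, stat, p, p_bonf, p_bonf < alpha))
    return out


def partner_proportions(
    network: PPINetwork,
    class_of: Mapping[str, str],
    default_category: str = "other",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partner-category interaction proportions per focal category.

    For each focal category, every edge incident to a node of that category
    contributes its partner endpoint's category once; a self-loop
    contributes the node's own category once.  Returns ``(proportions,
    counts)`` DataFrames indexed by focal category; proportion rows sum to 1
    for categories with at least one edge, and are all-zero (flagged by a
    zero row sum in ``counts``) otherwise.
    """
    cat = lambda n: class_of.get(n, default_category)  # noqa: E731
    categories = sorted(set(class_of.values()) | {default_category}
                        | {cat(n) for n in network.nodes})
    counts = pd.DataFrame(0, index=categories, columns=categories, dtype=int)
    for u, v in network.graph.edges:
        if u == v:
            counts.loc[cat(u), cat(u)] += 1
        else:
            counts.loc[cat(u), cat(v)] += 1
            counts.loc[cat(v), cat(u)] += 1
    totals = counts.sum(axis=1)
    props = counts.astype(float)
    nz = totals > 0
    props.loc[nz] = props.loc[nz].div(totals[nz], axis=0)
    return props, counts


def stress_subnetwork(
    network: PPINetwork,
    focal_ids: Collection[str],
    class_of: Mapping[str, str] | None = None,
    tf_flags: Mapping[str, bool] | None = None,
    pathway_counts: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Edges incident to the focal nodes, with partner labels.

    Each row carries the partner's disorder class and TF flag and the focal
    node's pathway count.  Focal ids absent from the network are returned in
    the second element (reported, not an error).
    """
    class_of = class_of or {}
    tf_flags = tf_flags or {}
    pathway_counts = pathway_counts or {}
    missing = sorted(set(focal_ids) - set(network.nodes))
    focal = [f for f in focal_ids if f in network]
    rows = []
    for f in focal:
        for u, v in network.graph.edges(f):
            partner = v if u == f else u
            rows.append(
                (
                    f,
                    partner,
                    class_of.get(partner, "unknown"),
                    bool(tf_flags.get(partner, False)),
                    int(pathway_counts.get(f, 0)),
                )
            )
    df = pd.DataFrame(
        rows,
        columns=["focal_id", "partner_id", "partner_class", "partner_is_tf", "focal_pathway_count"],
    )
    return df, missing


def write_comparisons(comparisons: Sequence[GroupComparison], path) -> None:
    with open(path, "w") as fh:
        fh.write("# pairwise Wilcoxon rank-sum contrasts; Bonferroni over pairs tested\n")
        pd.DataFrame(
            [
                (c.group_a, c.group_b, c.statistic, c.p_raw, c.p_bonferroni, c.significant)
                for c in comparisons
            ],
            columns=["group_a", "group_b", "statistic", "p_raw", "p_bonferroni", "significant"],
        ).to_csv(fh, sep="\t", index=False)


def write_subnetwork(df: pd.DataFrame, path_tsv, path_graphml=None) -> None:
    df.to_csv(path_tsv, sep="\t", index=False)
    if path_graphml is not None:
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.focal_id, row.partner_id)
            g.nodes[row.partner_id]["disorder_class"] = row.partner_class
            g.nodes[row.partner_id]["is_tf"] = bool(row.partner_is_tf)
        nx.write_graphml(g, path_graphml)
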