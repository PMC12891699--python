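"""Trait-labelled co-occurrence networks from OTU count tables.

Edges connect OTU pairs whose abundance profiles correlate (Pearson r on
per-sample relative abundances, two-sided p from the t transform with
n - 2 df; edge iff p < alpha and |r| > r_min, optionally BH-corrected).
Node centralities (degree, harmonic closeness, betweenness) are then
compared between producer-phenotype groups with Mann-Whitney U tests, the
question being whether cobamide producers sit at network hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LABELS = ("very_likely", "likely", "possible", "nonproducer", "unassigned")


@dataclass
class AbundanceTable:
    """OTU x sample count matrix with per-OTU phenotype labels."""

    counts: pd.DataFrame  # index = otu_ids, columns = sample_ids, ints >= 0
    labels: dict = field(default_factory=dict)  # otu_id -> label

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for otu in self.counts.index:
            self.labels.setdefault(otu, "unassigned")

    @property
    def otu_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @classmethod
    def from_tsv(cls, counts_tsv, labels_tsv=None) -> "AbundanceTable":
        """Read counts (first column ``otu_id``) and optional labels TSV
        (columns ``otu_id, label``)."""
        counts = pd.read_csv(counts_tsv, sep="\t", index_col="otu_id")
        labels = {}
        if labels_tsv is not None:
            ldf = pd.read_csv(labels_tsv, sep="\t", dtype=str)
            labels = dict(zip(ldf["otu_id"], ldf["label"]))
        return cls(counts=counts, labels=labels)

    def to_tsv(self, counts_tsv, labels_tsv=None) -> None:
        self.counts.to_csv(counts_tsv, sep="\t", index_label="otu_id")
        if labels_tsv is not None:
            pd.DataFrame(
                {"otu_id": self.otu_ids, "label": [self.labels[o] for o in self.otu_ids]}
            ).to_csv(labels_tsv, sep="\t", index=False)


@dataclass
class Network:
    """Co-occurrence graph with build parameters and skipped-pair notes."""

    graph: nx.Graph
    params: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_table(self) -> pd.DataFrame:
        rows = [
            {"otu_a": min(a, b), "otu_b": max(a, b), "r": d["r"], "p": d["p"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["otu_a", "otu_b", "r", "p"])
        return df.sort_values(["otu_a", "otu_b"]).reset_index(drop=True)


def filter_rare(table: AbundanceTable, min_total: int = 100) -> AbundanceTable:
    """Exclude rare OTUs: keep an OTU iff its read total across all samples
    is at least ``min_total`` (so a total of exactly 100 is kept). Samples
    are unchanged; idempotent."""
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= min_total].index
    if len(keep) == 0:
        logger.warning("filter_rare removed every OTU (min_total=%d)", min_total)
    kept = table.counts.loc[keep]
    return AbundanceTable(
        counts=kept, labels={o: table.labels[o] for o in kept.index}
    )


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson r via the t transform with n-2 df."""
    if n < 3:
        raise ValueError("need at least 3 samples")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def build_network(
    table: AbundanceTable,
    alpha: float = 0.05,
    r_min: float = 0.0,
    correction: str = "none",
    on_counts: bool = False,
) -> Network:
    """Build the co-occurrence graph from an OTU table.

    Counts are converted to per-sample relative abundances (unequal
    sequencing depth; pass ``on_counts=True`` to correlate raw counts).
    Every OTU pair is tested; an edge is kept iff p < alpha — after
    Benjamini-Hochberg across all tested pairs when ``correction='bh'`` —
    and |r| > r_min. Pairs where either vector has zero variance are
    skipped with a note. All OTUs enter the graph as nodes (labelled), so
    unconnected taxa report degree 0.

    Raises
    ------
    ValueError
        With fewer than 3 samples.
    """
    if correction not in ("none", "bh"):
        raise ValueError("correction must be 'none' or 'bh'")
    n_samples = len(table.sample_ids)
    if n_samples < 3:
        raise ValueError(f"need >= 3 samples to build a network, got {n_samples}")

    X = table.counts.to_numpy(dtype=float)
    if not on_counts:
        col_sums = X.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            X = np.where(col_sums > 0, X / col_sums, 0.0)

    otus = table.otu_ids
    sd = X.std(axis=1)
    variable = sd > 0
    notes = [
        f"zero_variance:{otus[i]}" for i in np.flatnonzero(~variable)
    ]

    graph = nx.Graph()
    for otu in otus:
        graph.add_node(otu, label=table.labels[otu])

    idx = np.flatnonzero(variable)
    pairs: list = []
    if len(idx) >= 2:
        corr = np.corrcoef(X[idx])
        for a_pos, b_pos in combinations(range(len(idx)), 2):
            r = float(np.clip(corr[a_pos, b_pos], -1.0, 1.0))
            p = pearson_pvalue(r, n_samples)
            pairs.append((otus[idx[a_pos]], otus[idx[b_pos]], r, p))

    if pairs:
        pvals = np.array([p for *_, p in pairs])
        p_eff = (
            stats.false_discovery_control(pvals, method="bh")
            if correction == "bh"
            else pvals
        )
        for (a, b, r, _), p in zip(pairs, p_eff):
            if p < alpha and abs(r) > r_min:
                graph.add_edge(a, b, r=r, p=float(p))

    return Network(
        graph=graph,
        params={
            "alpha": alpha,
            "r_min": r_min,
            "correction": correction,
            "on_counts": on_counts,
            "n_samples": n_samples,
        },
        notes=notes,
    )


def topology(net: Network) -> pd.DataFrame:
    """Per-node centrality table: degree, closeness, betweenness.

    Closeness is *harmonic* centrality normalized by (n - 1), finite on
    disconnected graphs; betweenness is on unweighted shortest paths,
    normalized. Deterministic. Empty network -> empty table.
    """
    g = net.graph
    nodes = sorted(g.nodes)
    if not nodes:
        return pd.DataFrame(
            columns=["otu_id", "label", "degree", "closeness", "betweenness"]
        ).set_index("otu_id")
    n = len(nodes)
    # harmonic centrality summed in sorted node order so results are
    # bit-identical across processes (set-order summation is not)
    harmonic = {}
    for v in nodes:
        dist = nx.single_source_shortest_path_length(g, v)
        harmonic[v] = sum(1.0 / d for _, d in sorted(dist.items()) if d > 0)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    return pd.DataFrame(
        {
            "otu_id": nodes,
            "label": [g.nodes[v].get("label", "unassigned") for v in nodes],
            "degree": [g.degree(v) for v in nodes],
            "closeness": [harmonic[v] / (n - 1) if n > 1 else 0.0 for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
        }
    ).set_index("otu_id")


def compare_groups(
    metrics: pd.DataFrame,
    labels: Optional[Mapping] = None,
    group_a: Iterable[str] = ("very_likely",),
    group_b: Iterable[str] = ("nonproducer",),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare centrality metrics between two phenotype groups.

    For each metric column, reports group medians, the two-sided
    Mann-Whitney U statistic and its p-value, flagging metrics with
    p < ``alpha``. ``labels`` defaults to the ``label`` column of the
    metrics table.

    Raises
    ------
    ValueError
        If either group has no members, naming the empty group.
    """
    group_a, group_b = set(group_a), set(group_b)
    if labels is None:
        if "label" not in metrics.columns:
            raise ValueError("no labels supplied and metrics lack a 'label' column")
        labels = metrics["label"].to_dict()
    in_a = [i for i in metrics.index if labels.get(i) in group_a]
    in_b = [i for i in metrics.index if labels.get(i) in group_b]
    if not in_a:
        raise ValueError(f"group_a {sorted(group_a)} has no members")
    if not in_b:
        raise ValueError(f"group_b {sorted(group_b)} has no members")

    rows = []
    metric_cols = [c for c in metrics.columns if c != "label"]
    for col in metric_cols:
        a = metrics.loc[in_a, col].to_numpy(dtype=float)
        b = metrics.loc[in_b, col].to_numpy(dtype=float)
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "metric": col,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "n_a": len(a),
                "n_b": len(b),
                "U": float(res.statistic),
                "p": float(res.pvalue),
                "significant": bool(res.pvalue < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("metric")
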