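"""Stage 3: trait-anchored co-expression network and the network-formation
tendency test.

The network's nodes are a chosen set of transcripts plus every trait column;
an edge joins two nodes when the two-tailed p-value of their Pearson
correlation across samples is at or below the edge threshold.  Clusters are
the connected components over nodes of degree >= 1 (an isolated node has not
"joined" the network).

The tendency test asks whether a candidate gene set forms a denser network
than equally sized sets of randomly drawn background genes: the candidate
network is built once, R control networks are built from random same-size
subsets of a background pool (traits included in every network so counts are
comparable), and the observed connected-node and edge counts are compared
against the control distribution.  The comparison uses a two-sided
predictive t-statistic, ``t = (obs - mean(controls)) / (sd * sqrt(1 + 1/R))``
with ``R - 1`` degrees of freedom, which treats the observed value as one
more draw and is therefore calibrated when the candidate set is exchangeable
with the controls; an empirical percentile p-value is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import (
    ExpressionMatrix,
    TraitTable,
    ValidationError,
    check_matched_samples,
    pairwise_correlations,
)

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionNetwork:
    """A thresholded correlation graph over transcript and trait nodes."""

    graph: nx.Graph
    alpha: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def transcript_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "transcript"]

    @property
    def trait_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "trait"]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def connected_nodes(self) -> list[str]:
        return [n for n, deg in self.graph.degree if deg >= 1]

    @property
    def n_connected_nodes(self) -> int:
        return len(self.connected_nodes)

    @property
    def clusters(self) -> list[frozenset[str]]:
        sub = self.graph.subgraph(self.connected_nodes)
        comps = [frozenset(c) for c in nx.connected_components(sub)]
        return sorted(comps, key=lambda c: (-len(c), sorted(c)[0]))

    def edge_class_counts(self) -> dict[str, int]:
        """Edges split into gene–gene, gene–trait and trait–trait classes."""
        counts = {"gene_gene": 0, "gene_trait": 0, "trait_trait": 0}
        kinds = nx.get_node_attributes(self.graph, "kind")
        for u, v in self.graph.edges:
            ks = sorted((kinds[u], kinds[v]))
            if ks == ["transcript", "transcript"]:
                counts["gene_gene"] += 1
            elif ks == ["trait", "trait"]:
                counts["trait_trait"] += 1
            else:
                counts["gene_trait"] += 1
        return counts

    def edge_list(self) -> pd.DataFrame:
        rows = [
            (u, v, d["r"], d["p"]) for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "r", "p"]).sort_values(
            ["node_a", "node_b"]
        ).reset_index(drop=True)

    def write(self, outdir: str | Path, stem: str = "network") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        el = self.edge_list()
        el["p"] = el["p"].map(lambda v: f"{v:.2E}")
        el.to_csv(outdir / f"{stem}_edges.tsv", sep="\t", index=False)
        nx.write_graphml(self.graph, outdir / f"{stem}.graphml")


def build_network(
    expr: ExpressionMatrix,
    traits: TraitTable,
    node_transcripts: Sequence[str],
    alpha: float = 0.05,
) -> CoexpressionNetwork:
    """Build the thresholded co-expression graph over the selected
    transcripts plus every trait column."""
    if not 0.0 < alpha <= 1.0:
        raise ValidationError(f"edge alpha {alpha} outside (0, 1]")
    samples = check_matched_samples(expr, traits)
    if len(samples) < 3:
        raise ValidationError("network construction requires at least 3 samples")
    missing = [t for t in node_transcripts if t not in expr.data.index]
    if missing:
        raise ValidationError(f"transcripts absent from expression matrix: {missing[:5]}")

    labels = list(node_transcripts) + list(traits.traits)
    kinds = ["transcript"] * len(node_transcripts) + ["trait"] * len(traits.traits)
    M = np.vstack(
        [
            expr.data.loc[list(node_transcripts), samples].to_numpy()
            if node_transcripts
            else np.empty((0, len(samples))),
            traits.data.loc[samples].to_numpy().T,
        ]
    )
    r, p = pairwise_correlations(M, M)

    g = nx.Graph()
    for lab, kind in zip(labels, kinds):
        g.add_node(lab, kind=kind)
    var0 = np.flatnonzero(np.isnan(np.diag(r)))
    for i in var0:
        logger.warning("node %s has zero variance; kept without edges", labels[i])
    n_nodes = len(labels)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            pij = p[i, j]
            if not np.isnan(pij) and pij <= alpha:
                g.add_edge(labels[i], labels[j], r=float(r[i, j]), p=float(pij))
    return CoexpressionNetwork(g, alpha)


@dataclass
class TendencyResult:
    """Observed candidate-network size vs R random background gene sets."""

    observed_nodes: int
    observed_edges: int
    control_node_counts: np.ndarray
    control_edge_counts: np.ndarray
    p_nodes: float
    p_edges: float
    p_nodes_empirical: float
    p_edges_empirical: float
    seed: int
    alpha_edge: float

    @property
    def R(self) -> int:
        return len(self.control_edge_counts)

    @property
    def control_node_mean(self) -> float:
        return float(np.mean(self.control_node_counts))

    @property
    def control_node_sd(self) -> float:
        return float(np.std(self.control_node_counts, ddof=1))

    @property
    def control_edge_mean(self) -> float:
        return float(np.mean(self.control_edge_counts))

    @property
    def control_edge_sd(self) -> float:
        return float(np.std(self.control_edge_counts, ddof=1))

    def to_dict(self) -> dict:
        return {
            "observed_nodes": self.observed_nodes,
            "observed_edges": self.observed_edges,
            "R": self.R,
            "control_node_mean": self.control_node_mean,
            "control_node_sd": self.control_node_sd,
            "control_edge_mean": self.control_edge_mean,
            "control_edge_sd": self.control_edge_sd,
            "control_node_counts": [int(x) for x in self.control_node_counts],
            "control_edge_counts": [int(x) for x in self.control_edge_counts],
            "p_nodes": self.p_nodes,
            "p_edges": self.p_edges,
            "p_nodes_empirical": self.p_nodes_empirical,
            "p_edges_empirical": self.p_edges_empirical,
            "seed": self.seed,
            "alpha_edge": self.alpha_edge,
        }


def _predictive_p(observed: float, controls: np.ndarray) -> float:
    """Two-sided p for the observed value being one more draw from the
    control distribution (prediction-interval t with R - 1 df)."""
    R = len(controls)
    mean = float(np.mean(controls))
    sd = float(np.std(controls, ddof=1))
    if sd == 0.0:
        return 1.0 if observed == mean else float(np.nextafter(0.0, 1.0))
    t = (observed - mean) / (sd * np.sqrt(1.0 + 1.0 / R))
    return float(2.0 * stats.t.sf(abs(t), R - 1))


def _empirical_p(observed: float, controls: np.ndarray) -> float:
    """One-sided add-one percentile in the direction of the deviation."""
    R = len(controls)
    if observed >= np.mean(controls):
        extreme = int(np.sum(controls >= observed))
    else:
        extreme = int(np.sum(controls <= observed))
    return (1 + extreme) / (R + 1)


def tendency_test(
    expr: ExpressionMatrix,
    traits: TraitTable,
    candidate_set: Sequence[str],
    background_pool: Sequence[str],
    R: int = 20,
    alpha_edge: float = 0.05,
    seed: int = 0,
) -> TendencyResult:
    """Compare the candidate set's network formation against R random
    equally sized background gene sets (see module docstring)."""
    if R < 2:
        raise ValidationError("tendency test needs at least R = 2 replications")
    cand = list(candidate_set)
    pool = list(background_pool)
    if set(cand) & set(pool):
        raise ValidationError("background pool must be disjoint from the candidate set")
    if len(pool) < len(cand):
        raise ValidationError(
            f"background pool ({len(pool)}) smaller than candidate set ({len(cand)})"
        )
    observed = build_network(expr, traits, cand, alpha_edge)
    rng = np.random.default_rng(seed)
    node_counts = np.empty(R, dtype=int)
    edge_counts = np.empty(R, dtype=int)
    for k in range(R):
        draw = list(rng.choice(pool, size=len(cand), replace=False))
        ctrl = build_network(expr, traits, draw, alpha_edge)
        node_counts[k] = ctrl.n_connected_nodes
        edge_counts[k] = ctrl.n_edges
    return TendencyResult(
        observed_nodes=observed.n_connected_nodes,
        observed_edges=observed.n_edges,
        control_node_counts=node_counts,
        control_edge_counts=edge_counts,
        p_nodes=_predictive_p(observed.n_connected_nodes, node_counts),
        p_edges=_predictive_p(observed.n_edges, edge_counts),
        p_nodes_empirical=_empirical_p(observed.n_connected_nodes, node_counts),
        p_edges_empirical=_empirical_p(observed.n_edges, edge_counts),
        seed=seed,
        alpha_edge=alpha_edge,
    )


def heatmap_export(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    groups: dict[str, str] | None = None,
    out: str | Path | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Plot-ready, row-clustered z-score matrix for the given transcripts.

    Rows are z-scored across samples (constant rows become zeros, with a
    warning) and ordered by average-linkage hierarchical clustering on the
    distance ``1 - r``.  ``groups`` optionally orders the sample columns by
    group label.  Returns the ordered matrix and the row order.
    """
    missing = [g for g in genes if g not in expr.data.index]
    if missing:
        raise ValidationError(f"transcripts absent from expression matrix: {missing[:5]}")
    sub = expr.data.loc[list(genes)]
    vals = sub.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0.0).ravel()
    for g in sub.index[flat]:
        logger.warning("transcript %s is constant; z-scores emitted as zeros", g)
    sd[sd == 0.0] = 1.0
    z = (vals - mu) / sd

    if len(genes) > 1:
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(z)
        r[np.isnan(r)] = 0.0
        np.fill_diagonal(r, 1.0)
        dist = np.clip(1.0 - r, 0.0, 2.0)
        link = hierarchy.linkage(squareform(dist, checks=False), method="average")
        order = [list(genes)[i] for i in hierarchy.leaves_list(link)]
    else:
        order = list(genes)

    zdf = pd.DataFrame(z, index=sub.index, columns=sub.columns).loc[order]
    if groups is not None:
        cols = sorted(zdf.columns, key=lambda s: (groups.get(s, ""), list(zdf.columns).index(s)))
        zdf = zdf[cols]
    if out is not None:
        zdf.to_csv(out, sep="\t", index_label="transcript_id")
    return zdf, order
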