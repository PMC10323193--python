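"""CrossBoruta gene-gene network inference and network summaries.

CrossBoruta runs all-relevant feature selection once per gene, with that
gene's expression as the regression target and all other genes as
candidate predictors.  A confirmed predictor j for target i is a directed
association i<-j; directed associations are merged into an undirected
importance-weighted graph, and every edge is annotated with the Spearman
rank correlation of its endpoint genes over the pooled samples.  Edge
color encodes the correlation: positive (significant rho > 0), negative
(significant rho < 0), or grey (association found by the trees but no
significant monotone correlation) — the last class is what makes the
procedure sensitive to non-linear coupling.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .boruta import CONFIRMED, BorutaConfig, boruta_run
from .quant import ExpressionMatrix

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
GREY = "grey"


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    degenerate: bool


def spearman(x: np.ndarray, y: np.ndarray) -> SpearmanResult:
    """Spearman rank correlation with mid-rank ties and t-approximation p.

    A constant input leaves the rank correlation undefined; by convention
    this returns rho=0, p=1 with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(0.0, 1.0, True)
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    if abs(rho) >= 1.0 - 1e-12:  # snap float error on perfect rankings
        return SpearmanResult(float(np.sign(rho)), 0.0, False)
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, float(p), False)


@dataclass
class GeneNetwork:
    """Undirected gene-gene graph with weighted, correlation-colored edges."""

    graph: nx.Graph
    pool_label: str = ""

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_by_color(self, color: str) -> list[tuple[str, str]]:
        return [
            (u, v) for u, v, c in self.graph.edges(data="color") if c == color
        ]

    def disconnected_genes(self) -> list[str]:
        return [n for n, d in self.graph.degree() if d == 0]

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_a": u,
                "gene_b": v,
                "weight": d["weight"],
                "weight_norm": d["weight_norm"],
                "rho": d["rho"],
                "rho_p": d["rho_p"],
                "color": d["color"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows,
            columns=["gene_a", "gene_b", "weight", "weight_norm",
                     "rho", "rho_p", "color"],
        )

    def node_frame(self) -> pd.DataFrame:
        deg = dict(self.graph.degree())
        return pd.DataFrame(
            {
                "gene": list(self.graph.nodes),
                "degree": [deg[n] for n in self.graph.nodes],
                "disconnected": [deg[n] == 0 for n in self.graph.nodes],
            }
        )

    def write_edge_list(self, path: str | Path) -> None:
        self.edge_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_node_table(self, path: str | Path) -> None:
        self.node_frame().to_csv(path, sep="\t", index=False)


@dataclass
class NetworkSummary:
    pool_label: str
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    n_grey: int
    disconnected_genes: list[str]
    homogeneity: float
    mean_abs_rho: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class NetworkComparison:
    """Per-metric contrast of network a minus network b."""

    delta_n_positive: int
    delta_n_negative: int
    delta_homogeneity: float
    jaccard: float
    disconnected_only_a: list[str]
    disconnected_only_b: list[str]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _edge_color(rho: float, p: float, degenerate: bool, alpha: float) -> str:
    if degenerate or p >= alpha or rho == 0:
        return GREY
    return POSITIVE if rho > 0 else NEGATIVE


def crossboruta(
    expr: ExpressionMatrix,
    cfg: BorutaConfig = BorutaConfig(),
    edge_rule: str = "union",
    edge_alpha: float = 0.05,
    pool_label: str = "",
) -> GeneNetwork:
    """Build the all-against-all feature-selection network.

    ``edge_rule='union'`` keeps an edge when either direction is
    Confirmed; ``'intersection'`` requires both.  Edge weight is the mean
    of the confirming directions' median importances, min-max normalized
    per network onto [0, 1] as ``weight_norm``.
    """
    if edge_rule not in ("union", "intersection"):
        raise ValueError(f"unknown edge_rule {edge_rule!r}")
    genes = expr.genes
    if len(genes) < 3:
        raise ValueError("need at least 3 genes")
    V = expr.values.to_numpy(dtype=float)
    if V.shape[0] < 5:
        raise ValueError("need at least 5 samples")

    ss = np.random.SeedSequence(cfg.seed)
    target_seeds = ss.generate_state(len(genes), dtype=np.uint32)

    # directed importance: directed[(i, j)] = median importance of
    # predictor j confirmed for target i
    directed: dict[tuple[int, int], float] = {}
    for i, gene in enumerate(genes):
        y = V[:, i]
        if np.ptp(y) == 0:
            logger.warning("%s: constant expression; left isolated", gene)
            continue
        others = [j for j in range(len(genes)) if j != i]
        X = V[:, others]
        # only Confirmed predictors become edges; with the default
        # leave_tentative resolution, features still undecided at the
        # iteration cap carry too little evidence for an edge
        sub_cfg = BorutaConfig(
            n_trees=cfg.n_trees,
            max_iterations=cfg.max_iterations,
            alpha=cfg.alpha,
            importance=cfg.importance,
            multiple_test=cfg.multiple_test,
            seed=int(target_seeds[i]),
            tentative_resolution=cfg.tentative_resolution,
        )
        res = boruta_run(X, y, sub_cfg)
        for k, j in enumerate(others):
            if res.decisions[k] == CONFIRMED:
                directed[(i, j)] = float(res.median_importance[k])

    g = nx.Graph()
    g.add_nodes_from(genes)
    for (i, j), w_ij in directed.items():
        if i > j:
            continue
        back = directed.get((j, i))
        if edge_rule == "intersection" and back is None:
            continue
        weight = w_ij if back is None else (w_ij + back) / 2.0
        sp = spearman(V[:, i], V[:, j])
        g.add_edge(
            genes[i], genes[j],
            weight=weight,
            rho=sp.rho,
            rho_p=sp.p,
            color=_edge_color(sp.rho, sp.p, sp.degenerate, edge_alpha),
        )
    # reverse-only pairs under the union rule
    if edge_rule == "union":
        for (i, j), w_ij in directed.items():
            if i < j or g.has_edge(genes[i], genes[j]):
                continue
            sp = spearman(V[:, i], V[:, j])
            g.add_edge(
                genes[j], genes[i],
                weight=w_ij,
                rho=sp.rho,
                rho_p=sp.p,
                color=_edge_color(sp.rho, sp.p, sp.degenerate, edge_alpha),
            )

    _normalize_weights(g)
    return GeneNetwork(graph=g, pool_label=pool_label)


def _normalize_weights(g: nx.Graph) -> None:
    weights = [d["weight"] for _, _, d in g.edges(data=True)]
    if not weights:
        return
    lo, hi = min(weights), max(weights)
    for _, _, d in g.edges(data=True):
        d["weight_norm"] = 1.0 if hi == lo else (d["weight"] - lo) / (hi - lo)


def summarize_network(net: GeneNetwork) -> NetworkSummary:
    """Edge-sign counts, degree-0 genes, and correlation homogeneity.

    Homogeneity is 1 minus the sample standard deviation of edge rho
    values (the maximum attainable s.d. for values in [-1, 1] is 1), so a
    network whose edges all carry similar correlations scores near 1.
    """
    g = net.graph
    rhos = np.array([d["rho"] for _, _, d in g.edges(data=True)])
    homogeneity = 1.0 if rhos.size < 2 else 1.0 - float(np.std(rhos, ddof=1))
    return NetworkSummary(
        pool_label=net.pool_label,
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_positive=len(net.edges_by_color(POSITIVE)),
        n_negative=len(net.edges_by_color(NEGATIVE)),
        n_grey=len(net.edges_by_color(GREY)),
        disconnected_genes=net.disconnected_genes(),
        homogeneity=homogeneity,
        mean_abs_rho=float(np.mean(np.abs(rhos))) if rhos.size else 0.0,
    )


def compare_networks(a: GeneNetwork, b: GeneNetwork) -> NetworkComparison:
    """Contrast two networks built over the same gene set (a minus b)."""
    if set(a.nodes) != set(b.nodes):
        diff = sorted(set(a.nodes) ^ set(b.nodes))
        raise ValueError(f"node sets differ; symmetric difference: {diff}")
    sa, sb = summarize_network(a), summarize_network(b)
    ea = {frozenset(e) for e in a.graph.edges}
    eb = {frozenset(e) for e in b.graph.edges}
    union = ea | eb
    jaccard = 1.0 if not union else len(ea & eb) / len(union)
    da, db = set(sa.disconnected_genes), set(sb.disconnected_genes)
    return NetworkComparison(
        delta_n_positive=sa.n_positive - sb.n_positive,
        delta_n_negative=sa.n_negative - sb.n_negative,
        delta_homogeneity=sa.homogeneity - sb.homogeneity,
        jaccard=jaccard,
        disconnected_only_a=sorted(da - db),
        disconnected_only_b=sorted(db - da),
    )


def write_summary_json(summary: NetworkSummary | NetworkComparison,
                       path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
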