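"""2-D network geometry by stress majorization (SMACOF).

Edge importance sets the target geometry: strongly associated genes
should sit close together, so an edge of normalized weight w gets target
length 1/(w + eps), non-adjacent pairs get the shortest-path distance
over those lengths, and disconnected components are pushed apart by a
fixed multiple of the finite diameter.  The embedding minimizes raw
stress sum_{i<j} (||x_i - x_j|| - d_ij)^2 by iterated Guttman transforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist, squareform

from .network import GeneNetwork, GREY, NEGATIVE, POSITIVE


@dataclass
class LayoutResult:
    nodes: list[str]
    coordinates: np.ndarray  # n x 2
    stress: float
    stress_history: np.ndarray
    iterations_run: int
    converged: bool

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.nodes,
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.frame().to_csv(path, index=False, float_format="%.6g")


def target_distances(
    net: GeneNetwork, eps: float = 0.05, pad_factor: float = 1.5
) -> tuple[list[str], np.ndarray]:
    """Importance-derived target distance matrix for the layout.

    Adjacent pairs: 1/(weight_norm + eps).  Other pairs within a
    component: graph shortest path over those edge lengths.  Pairs in
    different components: pad_factor times the largest finite distance.
    """
    nodes = net.nodes
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    index = {g: k for k, g in enumerate(nodes)}
    W = np.zeros((n, n))
    for u, v, d in net.graph.edges(data=True):
        length = 1.0 / (d["weight_norm"] + eps)
        W[index[u], index[v]] = W[index[v], index[u]] = length
    D = shortest_path(W, method="D", directed=False, unweighted=False)
    finite_off = D[np.isfinite(D) & (D > 0)]
    diameter = float(finite_off.max()) if finite_off.size else 1.0 / (1.0 + eps)
    D[~np.isfinite(D)] = pad_factor * diameter
    np.fill_diagonal(D, 0.0)
    return nodes, D


def _raw_stress(X: np.ndarray, D: np.ndarray) -> float:
    diff = squareform(pdist(X)) - D
    return float((diff[np.triu_indices_from(diff, k=1)] ** 2).sum())


def stress_majorization(
    D: np.ndarray,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    nodes: list[str] | None = None,
) -> LayoutResult:
    """Minimize raw stress by the Guttman transform from a random start.

    With unit weights the majorizing update is
    ``X <- B(Z) Z / n`` where ``b_ij = -d_ij / ||z_i - z_j||`` for
    ``i != j`` and ``b_ii = -sum_{j != i} b_ij``; raw stress is
    non-increasing along the iteration.  Stops when the relative stress
    decrease falls below ``tol``.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T):
        raise ValueError("D must be symmetric")
    if (np.diag(D) != 0).any():
        raise ValueError("D must have zero diagonal")
    off = D[~np.eye(n, dtype=bool)]
    if (off < 0).any():
        raise ValueError("off-diagonal distances must be non-negative")

    rng = np.random.default_rng(seed)
    scale = off.max() if off.size and off.max() > 0 else 1.0
    X = rng.uniform(-scale, scale, size=(n, 2))
    while n > 1 and np.allclose(pdist(X), 0):  # degenerate start: re-draw
        X = rng.uniform(-scale, scale, size=(n, 2))

    history = [_raw_stress(X, D)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        E = squareform(pdist(X))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(E > 0, D / E, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
        s = _raw_stress(X, D)
        history.append(s)
        prev = history[-2]
        if prev > 0 and (prev - s) / prev < tol:
            converged = True
            break
        if s == 0:
            converged = True
            break
    return LayoutResult(
        nodes=nodes or [f"n{i}" for i in range(n)],
        coordinates=X,
        stress=history[-1],
        stress_history=np.asarray(history),
        iterations_run=it,
        converged=converged,
    )


def layout_network(
    net: GeneNetwork,
    seed: int = 0,
    restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> LayoutResult:
    """Best-of-restarts stress-majorization layout of a gene network."""
    nodes, D = target_distances(net)
    seeds = np.random.SeedSequence(seed).generate_state(restarts, dtype=np.uint32)
    best: LayoutResult | None = None
    for s in seeds:
        res = stress_majorization(D, seed=int(s), tol=tol, max_iter=max_iter,
                                  nodes=nodes)
        if best is None or res.stress < best.stress:
            best = res
    return best


_EDGE_COLORS = {POSITIVE: "#1f5fbf", NEGATIVE: "#c0392b", GREY: "#9e9e9e"}


def plot_network(net: GeneNetwork, layout: LayoutResult,
                 path: str | Path, title: str | None = None) -> None:
    """Static network drawing: node positions from the layout, blue/red/grey
    edges by correlation sign, line width proportional to importance."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = {g: xy for g, xy in zip(layout.nodes, layout.coordinates)}
    fig, ax = plt.subplots(figsize=(8, 8))
    for u, v, d in net.graph.edges(data=True):
        (x0, y0), (x1, y1) = pos[u], pos[v]
        ax.plot(
            [x0, x1], [y0, y1],
            color=_EDGE_COLORS[d["color"]],
            linewidth=0.5 + 2.5 * d["weight_norm"],
            zorder=1,
        )
    xs, ys = layout.coordinates[:, 0], layout.coordinates[:, 1]
    ax.scatter(xs, ys, s=60, c="white", edgecolors="black", zorder=2)
    for g, (x, y) in pos.items():
        ax.annotate(g, (x, y), fontsize=6, ha="center", va="bottom",
                    xytext=(0, 4), textcoords="offset points")
    ax.set_title(title or net.pool_label)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
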