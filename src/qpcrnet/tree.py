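"""Gain-ratio (C4.5-family) decision trees over gene-expression features.

Binary axis-aligned threshold trees: each internal node tests one gene
against a threshold, ``<=`` routes left.  Split quality is the
information gain ratio (gain divided by split information), the criterion
underlying the C4.5/C5.0 family.  Leaves keep the full set of class
labels present in their training partition rather than collapsing to a
majority vote, matching how such trees are read as displays of splitting
criteria in small-n studies.

``reference_tree`` packages the published inter-group classification
tree from the rat cardiac-graft study (Flt1 / Gpx3 / Cflar / Bcl2
thresholds) so samples can be routed through the printed rules.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class TreeNode:
    """Internal node (feature + threshold) or leaf (label set + counts)."""

    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    labels: frozenset[str] | None = None
    counts: dict[str, int] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def validate(self) -> None:
        if self.is_leaf:
            if not self.labels:
                raise ValueError("leaf with empty label set")
        else:
            if self.left is None or self.right is None:
                raise ValueError("internal node must have two children")
            if not np.isfinite(self.threshold):
                raise ValueError("threshold must be finite")
            self.left.validate()
            self.right.validate()


@dataclass
class DecisionTreeModel:
    root: TreeNode

    def __post_init__(self) -> None:
        self.root.validate()

    def features_used(self) -> set[str]:
        out: set[str] = set()

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                out.add(node.feature)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        def encode(node: TreeNode) -> dict:
            if node.is_leaf:
                return {
                    "labels": sorted(node.labels),
                    "counts": node.counts or {},
                }
            return {
                "feature": node.feature,
                "threshold": node.threshold,
                "left": encode(node.left),
                "right": encode(node.right),
            }

        text = json.dumps(encode(self.root), indent=2) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "DecisionTreeModel":
        def decode(obj: dict) -> TreeNode:
            if "labels" in obj:
                return TreeNode(
                    labels=frozenset(obj["labels"]),
                    counts=dict(obj.get("counts") or {}),
                )
            return TreeNode(
                feature=obj["feature"],
                threshold=float(obj["threshold"]),
                left=decode(obj["left"]),
                right=decode(obj["right"]),
            )

        return cls(root=decode(json.loads(text)))

    def render(self) -> str:
        """Indented if/else rendering in the printed-rule style."""
        lines: list[str] = []

        def walk(node: TreeNode, indent: int) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(pad + "-> {" + ", ".join(sorted(node.labels)) + "}")
                return
            lines.append(f"{pad}if {node.feature} <= {node.threshold:g}:")
            walk(node.left, indent + 1)
            lines.append(f"{pad}else:  # {node.feature} > {node.threshold:g}")
            walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class TreeConfig:
    min_leaf: int = 2
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


_TIE_EPS = 1e-9


def _best_split_full(
    values: np.ndarray, labels: np.ndarray, min_leaf: int = 1
) -> tuple[float, float, float] | None:
    """(threshold, gain_ratio, gain) of the best cut, or None.

    Candidate thresholds are midpoints of consecutive distinct sorted
    values; partitions leaving fewer than ``min_leaf`` samples on a side
    are not considered.  Near-ties in gain ratio are broken toward the
    larger absolute information gain (gain ratio rewards lopsided pure
    cuts as much as balanced ones; preferring gain is the classic C4.5
    stabilizer), remaining ties toward the smaller threshold.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = values.size
    if n < 2 * min_leaf or np.unique(labels).size < 2:
        return None
    order = np.argsort(values, kind="stable")
    v, lab = values[order], labels[order]
    classes, y = np.unique(lab, return_inverse=True)
    k = classes.size
    total = np.bincount(y, minlength=k)
    h_parent = _entropy(total)

    best: tuple[float, float, float] | None = None
    left = np.zeros(k, dtype=int)
    for i in range(n - 1):
        left[y[i]] += 1
        if v[i] == v[i + 1]:
            continue
        n_l = i + 1
        n_r = n - n_l
        if n_l < min_leaf or n_r < min_leaf:
            continue
        right = total - left
        gain = h_parent - (n_l * _entropy(left) + n_r * _entropy(right)) / n
        p_l = n_l / n
        split_info = -(p_l * math.log2(p_l) + (1 - p_l) * math.log2(1 - p_l))
        ratio = gain / split_info if split_info > 0 else 0.0
        thr = (v[i] + v[i + 1]) / 2.0
        if (
            best is None
            or ratio > best[1] + _TIE_EPS
            or (ratio > best[1] - _TIE_EPS and gain > best[2] + _TIE_EPS)
        ):
            best = (thr, ratio, gain)
    return best


def best_split(
    values: np.ndarray, labels: np.ndarray, min_leaf: int = 1
) -> tuple[float, float] | None:
    """Threshold maximizing the information gain ratio, or None.

    Returns (threshold, gain_ratio); None when no valid split exists.
    """
    full = _best_split_full(values, labels, min_leaf)
    return None if full is None else full[:2]


def induce_tree(
    X: pd.DataFrame, labels, cfg: TreeConfig = TreeConfig()
) -> DecisionTreeModel:
    """Recursive partitioning by the best gain-ratio split across genes.

    Feature ties are broken by column (panel) order; recursion stops at
    purity, the min_leaf floor, the depth cap, or when no split improves.
    """
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise ValueError("X and labels disagree in length")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    if X.shape[0] < 2 * cfg.min_leaf:
        raise ValueError("too few samples for min_leaf")

    def leaf(idx: np.ndarray) -> TreeNode:
        counts = Counter(y[idx])
        return TreeNode(
            labels=frozenset(counts), counts={str(c): n for c, n in counts.items()}
        )

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        if (
            np.unique(y[idx]).size < 2
            or idx.size < 2 * cfg.min_leaf
            or (cfg.max_depth is not None and depth >= cfg.max_depth)
        ):
            return leaf(idx)
        chosen: tuple[str, float, float, float] | None = None
        for gene in X.columns:
            cand = _best_split_full(X[gene].to_numpy()[idx], y[idx], cfg.min_leaf)
            if cand is None:
                continue
            thr, ratio, gain = cand
            if (
                chosen is None
                or ratio > chosen[2] + _TIE_EPS
                or (ratio > chosen[2] - _TIE_EPS and gain > chosen[3] + _TIE_EPS)
            ):
                chosen = (gene, thr, ratio, gain)
        if chosen is None or chosen[2] <= 0:
            return leaf(idx)
        gene, thr = chosen[0], chosen[1]
        mask = X[gene].to_numpy()[idx] <= thr
        return TreeNode(
            feature=gene,
            threshold=thr,
            left=grow(idx[mask], depth + 1),
            right=grow(idx[~mask], depth + 1),
        )

    return DecisionTreeModel(root=grow(np.arange(y.size), 0))


def apply_tree(
    model: DecisionTreeModel, sample: Mapping[str, float]
) -> frozenset[str]:
    """Route one sample root-to-leaf; values equal to a threshold go left."""
    node = model.root
    while not node.is_leaf:
        if node.feature not in sample:
            raise KeyError(
                f"sample does not define gene {node.feature!r} tested by the tree"
            )
        node = node.left if sample[node.feature] <= node.threshold else node.right
    return node.labels


def training_accuracy(model: DecisionTreeModel, X: pd.DataFrame, labels) -> float:
    """Fraction of samples whose leaf label-set contains the true label."""
    y = np.asarray(labels)
    hits = sum(
        str(y[i]) in {str(l) for l in apply_tree(model, X.iloc[i].to_dict())}
        for i in range(len(y))
    )
    return hits / len(y)


def reference_tree() -> DecisionTreeModel:
    """The published inter-group classification tree (C5.0 display).

    Splits on Flt1, Gpx3, Cflar and Bcl2 expression; leaves may name
    several study arms, exactly as printed.  Training counts were not
    published.
    """
    g_1h = "1h ischemia"
    g_5h = "5h ischemia"
    g_5h_aat = "5h ischemia+AAT"
    return DecisionTreeModel(
        root=TreeNode(
            feature="Flt1",
            threshold=23.029,
            left=TreeNode(
                feature="Gpx3",
                threshold=20.448,
                left=TreeNode(labels=frozenset({g_1h, g_5h})),
                right=TreeNode(labels=frozenset({g_5h_aat})),
            ),
            right=TreeNode(
                feature="Cflar",
                threshold=21.651,
                left=TreeNode(labels=frozenset({g_5h})),
                right=TreeNode(
                    feature="Bcl2",
                    threshold=21.798,
                    left=TreeNode(labels=frozenset({g_1h, g_5h, g_5h_aat})),
                    right=TreeNode(labels=frozenset({g_1h, g_5h_aat})),
                ),
            ),
        )
    )
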