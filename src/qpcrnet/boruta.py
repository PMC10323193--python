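"""All-relevant feature selection with shadow features (Boruta), regression mode.

Each iteration augments the design matrix with independently row-permuted
copies ("shadows") of every feature, fits a randomized-tree regression
ensemble, and scores a *hit* for every real feature whose importance
exceeds the best shadow importance.  Features whose running hit count is
binomially significantly above chance are Confirmed, significantly below
chance Rejected; the rest stay Tentative when the iteration budget runs
out (the default), or are resolved against the median shadow maximum
when the rough fix is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

CONFIRMED = "Confirmed"
TENTATIVE = "Tentative"
REJECTED = "Rejected"


@dataclass(frozen=True)
class BorutaConfig:
    n_trees: int = 200
    max_iterations: int = 100
    alpha: float = 0.01
    importance: str = "permutation"  # Z-scored OOB; or "impurity" (faster)
    multiple_test: str = "bonferroni"  # or "none"
    seed: int = 0
    # "leave_tentative" mirrors the canonical behavior (the rough fix is
    # an opt-in post-processing step there too); "median_vs_shadow"
    # applies that rough fix: undecided features are kept when their
    # median importance beats the median of the shadow maxima
    tentative_resolution: str = "leave_tentative"

    def __post_init__(self) -> None:
        if self.n_trees < 10:
            raise ValueError("n_trees must be >= 10")
        if self.max_iterations < 10:
            raise ValueError("max_iterations must be >= 10")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError(f"unknown importance kind {self.importance!r}")
        if self.multiple_test not in ("bonferroni", "none"):
            raise ValueError(f"unknown multiple_test {self.multiple_test!r}")
        if self.tentative_resolution not in ("median_vs_shadow", "leave_tentative"):
            raise ValueError(
                f"unknown tentative_resolution {self.tentative_resolution!r}"
            )


@dataclass
class BorutaResult:
    decisions: np.ndarray  # per-feature label
    hit_counts: np.ndarray
    median_importance: np.ndarray
    shadow_max_history: np.ndarray  # per-iteration max shadow importance
    iterations_run: int
    feature_names: list[str] | None = None

    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.decisions == CONFIRMED)

    def to_dict(self) -> dict:
        names = self.feature_names or [f"f{i}" for i in range(len(self.decisions))]
        return {
            "iterations_run": self.iterations_run,
            "features": {
                n: {
                    "decision": str(d),
                    "hits": int(h),
                    "median_importance": float(m),
                }
                for n, d, h, m in zip(
                    names, self.decisions, self.hit_counts, self.median_importance
                )
            },
            "shadow_max_history": [float(s) for s in self.shadow_max_history],
        }


def _oob_permutation_importance(
    X: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator
) -> np.ndarray:
    """Z-scored out-of-bag permutation importance of a bagged tree ensemble.

    Per tree: prediction MSE on the out-of-bag samples with feature j
    shuffled, minus the unshuffled OOB MSE (zero for trees that never
    split on j).  The score is the mean of these per-tree decreases
    divided by its standard error over trees — the scaled variable
    importance of the classic random forest.  The normalization is what
    keeps weak chance correlates of the target comparable to their
    shadows: their mean decrease is small relative to its tree-to-tree
    spread, while a genuinely relevant feature's is not.
    """
    n, m = X.shape
    d = np.zeros((n_trees, m))
    tree_seeds = rng.integers(0, 2**31, size=n_trees)
    valid = 0
    for t in range(n_trees):
        t_rng = np.random.default_rng(tree_seeds[t])
        in_bag = t_rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), in_bag)
        if oob.size < 2:
            continue
        valid += 1
        tree = DecisionTreeRegressor(
            max_features="sqrt", random_state=int(tree_seeds[t])
        )
        tree.fit(X[in_bag], y[in_bag])
        X_oob = X[oob]
        in_tree = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
        # one stacked predict: unpermuted OOB block + one block per
        # feature the tree actually split on, with that column shuffled
        blocks = [X_oob]
        for j in in_tree:
            X_perm = X_oob.copy()
            X_perm[:, j] = t_rng.permutation(X_perm[:, j])
            blocks.append(X_perm)
        preds = tree.predict(np.vstack(blocks)).reshape(len(blocks), oob.size)
        errs = np.mean((preds - y[oob]) ** 2, axis=1)
        d[t, in_tree] = errs[1:] - errs[0]
    if valid == 0:
        return np.zeros(m)
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    se = sd / np.sqrt(n_trees)
    z = np.zeros(m)
    nonzero = se > 0
    z[nonzero] = mean[nonzero] / se[nonzero]
    return z


def ensemble_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 200,
    seed: int = 0,
    importance: str = "permutation",
) -> np.ndarray:
    """Per-feature importance from a randomized-tree regression ensemble.

    ``permutation`` (default): Z-scored out-of-bag permutation
    importance, the classic random-forest measure; it gives no credit to
    features the trees only used to overfit the in-bag data, which is
    what keeps chance correlates of the target from consistently beating
    their shadows.  ``impurity``: mean variance-reduction (MDI)
    importance — faster on large panels, but runs hotter on null data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 5:
        raise ValueError("X must be 2-D with at least 5 rows")
    if np.ptp(y) == 0:
        raise ValueError("constant target: no splits definable")
    if importance == "impurity":
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(seed) % (2**32),
            n_jobs=1,
        )
        forest.fit(X, y)
        return forest.feature_importances_
    if importance == "permutation":
        return _oob_permutation_importance(
            X, y, n_trees, np.random.default_rng(int(seed) % (2**32))
        )
    raise ValueError(f"unknown importance kind {importance!r}")


def add_shadows(
    X: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Append one independently row-permuted copy of every column.

    Returns the augmented matrix and the number of real columns; columns
    ``[m, 2m)`` are the shadows of columns ``[0, m)`` in order.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    if m < 1:
        raise ValueError("need at least one feature")
    shadows = np.column_stack(
        [rng.permutation(X[:, j]) for j in range(m)]
    )
    return np.hstack([X, shadows]), m


def _binomial_p(hits: int, n: int) -> float:
    return stats.binomtest(hits, n, 0.5, alternative="two-sided").pvalue


def boruta_run(
    X: np.ndarray,
    y: np.ndarray,
    cfg: BorutaConfig = BorutaConfig(),
    feature_names: list[str] | None = None,
) -> BorutaResult:
    """Iterative shadow-comparison selection of all relevant features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if n < 5:
        raise ValueError("need at least 5 rows")
    ss = np.random.SeedSequence(cfg.seed)
    iter_seeds = ss.generate_state(2 * cfg.max_iterations, dtype=np.uint32)

    decisions = np.array([TENTATIVE] * m, dtype=object)
    hits = np.zeros(m, dtype=int)
    importances: list[np.ndarray] = []
    shadow_max: list[float] = []

    t = 0
    while t < cfg.max_iterations and (decisions == TENTATIVE).any():
        rng = np.random.default_rng(iter_seeds[2 * t])
        X_aug, _ = add_shadows(X, rng)
        imp = ensemble_importance(
            X_aug, y, n_trees=cfg.n_trees,
            seed=int(iter_seeds[2 * t + 1]), importance=cfg.importance,
        )
        real, shadow = imp[:m], imp[m:]
        s_max = float(shadow.max())
        shadow_max.append(s_max)
        importances.append(real)
        hits += (real > s_max).astype(int)
        t += 1

        undecided = np.flatnonzero(decisions == TENTATIVE)
        if undecided.size == 0:
            break
        level = cfg.alpha
        if cfg.multiple_test == "bonferroni":
            # every feature is re-tested after every iteration, so the
            # multiplicity is features x tests performed, not features alone
            level = cfg.alpha / (m * t)
        for j in undecided:
            p = _binomial_p(int(hits[j]), t)
            if p < level:
                decisions[j] = CONFIRMED if hits[j] > t / 2 else REJECTED

    median_imp = np.median(np.vstack(importances), axis=0) if importances else np.zeros(m)
    if cfg.tentative_resolution == "median_vs_shadow":
        # the canonical rough fix: a lingering Tentative feature is kept
        # only if its median importance beats the median shadow maximum
        shadow_med = float(np.median(shadow_max)) if shadow_max else 0.0
        for j in np.flatnonzero(decisions == TENTATIVE):
            decisions[j] = CONFIRMED if median_imp[j] > shadow_med else REJECTED

    return BorutaResult(
        decisions=decisions,
        hit_counts=hits,
        median_importance=np.maximum(median_imp, 0.0),
        shadow_max_history=np.asarray(shadow_max),
        iterations_run=t,
        feature_names=feature_names,
    )
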