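"""Ct-level quantification: ΔCt normalization, fold regulation, group tests.

The computation chain is the classic array-format qPCR workflow:

1. per-sample ΔCt against the mean of the reference (housekeeping) genes,
2. linear relative expression ``2**(-ΔCt)``,
3. per-gene two-sided pooled-variance Student's t-test on the linear
   replicate values of a test vs a control group,
4. fold change ``FC = 2**(-ΔΔCt)`` with
   ``ΔΔCt = mean ΔCt(test) - mean ΔCt(control)`` (log-domain averaging,
   the RT^2 Profiler convention),
5. fold regulation ``FR = FC`` if ``FC >= 1`` else ``-1/FC``,
6. a QC flag for genes whose group-mean raw Ct is high (low expression),
7. a significance filter at ``p < alpha`` and ``|FR| > cutoff``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panel import PanelSpec

logger = logging.getLogger(__name__)

QC_NONE = ""
QC_A = "A"  # high Ct (> 30) in exactly one of the two groups
QC_B = "B"  # high Ct (> 30) in both groups


@dataclass
class CtMatrix:
    """Raw threshold-cycle values for a set of replicates over a gene panel.

    ``values`` is a samples x genes DataFrame of Ct cycles; ``groups`` maps
    each sample to its study arm; ``missing`` marks wells that were reported
    undetermined by the instrument and substituted with the panel ceiling.
    """

    values: pd.DataFrame
    groups: pd.Series
    missing: pd.DataFrame | None = None
    missing_mark: str = "Undetermined"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = pd.Series(self.groups, index=self.values.index)
        if self.groups.isna().any():
            bad = list(self.values.index[self.groups.isna()])
            raise ValueError(f"samples without a group label: {bad}")
        if self.values.columns.duplicated().any():
            dup = list(self.values.columns[self.values.columns.duplicated()])
            raise ValueError(f"duplicate gene symbols: {dup}")
        arr = self.values.to_numpy()
        if not (np.isfinite(arr).all() and (arr > 0).all()):
            raise ValueError("Ct values must be finite and > 0")
        if self.missing is None:
            self.missing = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        else:
            self.missing = self.missing.reindex(
                index=self.values.index, columns=self.values.columns
            ).fillna(False).astype(bool)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_set(self) -> list[str]:
        return list(dict.fromkeys(self.groups))

    def n_substituted(self) -> int:
        return int(self.missing.to_numpy().sum())

    def substitutions(self) -> list[tuple[str, str]]:
        """(sample, gene) pairs where an undetermined well was ceiled."""
        rows, cols = np.nonzero(self.missing.to_numpy())
        idx, genes = self.missing.index, self.missing.columns
        return [(idx[r], genes[c]) for r, c in zip(rows, cols)]


@dataclass
class ExpressionMatrix:
    """Normalized expression; ``scale`` is ``delta_ct`` or ``linear``."""

    values: pd.DataFrame
    groups: pd.Series
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in ("delta_ct", "linear"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and not (self.values.to_numpy() > 0).all():
            raise ValueError("linear expression values must be positive")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ComparisonResult:
    """Per-gene outcome of one test-vs-control contrast."""

    gene: str
    p_value: float
    fold_change: float
    fold_regulation: float
    qc_flag: str = QC_NONE
    mean_ct_test: float = float("nan")
    mean_ct_control: float = float("nan")


@dataclass(frozen=True)
class FilterConfig:
    """Significance cut-offs: p < alpha and |fold regulation| > fr_cutoff."""

    alpha: float = 0.05
    fr_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fr_cutoff < 1:
            raise ValueError("fr_cutoff must be >= 1")


@dataclass
class FilterResult:
    up: list[str]
    down: list[str]

    @property
    def n_altered(self) -> int:
        return len(self.up) + len(self.down)

    def summary(self) -> str:
        return (
            f"altered: {self.n_altered} "
            f"(up: {len(self.up)} {self.up}; down: {len(self.down)} {self.down})"
        )


def read_ct_table(path: str | Path, panel: PanelSpec) -> CtMatrix:
    """Read a delimited Ct table (columns: sample_id, group, one per gene).

    Undetermined wells (the literal ``Undetermined``, ``NA`` or an empty
    cell) are replaced by ``panel.ct_ceiling`` and recorded in the returned
    matrix's ``missing`` mask.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError("Ct table must have 'sample_id' and 'group' columns")
    gene_cols = [c for c in df.columns if c not in ("sample_id", "group")]
    unknown = sorted(set(gene_cols) - set(panel.all_genes))
    if unknown:
        raise ValueError(f"gene columns not in panel: {unknown}")
    absent = sorted(set(panel.all_genes) - set(gene_cols))
    if absent:
        raise ValueError(f"panel genes missing from table: {absent}")

    raw = df[gene_cols]
    sentinel = raw.isna() | raw.apply(
        lambda col: col.str.strip().str.lower().isin(
            {"undetermined", "undet", "na", "nan", ""}
        )
    )
    numeric = raw.mask(sentinel).apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~sentinel
    if bad.to_numpy().any():
        r, c = np.nonzero(bad.to_numpy())
        coords = [(df["sample_id"].iloc[i], gene_cols[j]) for i, j in zip(r, c)]
        raise ValueError(f"non-numeric Ct values at (sample, gene): {coords}")
    values = numeric.fillna(panel.ct_ceiling)
    values.index = df["sample_id"]
    values.index.name = None
    sentinel.index = values.index
    groups = pd.Series(df["group"].to_numpy(), index=values.index)
    n_sub = int(sentinel.to_numpy().sum())
    if n_sub:
        logger.info(
            "substituted ct_ceiling=%s for %d undetermined well(s)",
            panel.ct_ceiling, n_sub,
        )
    return CtMatrix(values=values, groups=groups, missing=sentinel)


def normalize_delta_ct(ct: CtMatrix, panel: PanelSpec) -> ExpressionMatrix:
    """ΔCt per sample and gene against the mean reference-gene Ct.

    The arithmetic mean of reference Ct equals the geometric mean of their
    linear expression, the standard multi-reference aggregation.  Reference
    genes are dropped from the output.  A reference well that was itself
    undetermined invalidates the sample's normalizer and is an error.
    """
    missing_ref = [g for g in panel.reference_genes if g not in ct.genes]
    if missing_ref:
        raise ValueError(f"reference genes absent from Ct matrix: {missing_ref}")
    ref_missing = ct.missing[list(panel.reference_genes)]
    if ref_missing.to_numpy().any():
        s, g = np.nonzero(ref_missing.to_numpy())
        pairs = [
            (ref_missing.index[i], ref_missing.columns[j])
            for i, j in zip(s, g)
        ]
        raise ValueError(
            f"undetermined reference-gene wells (sample, gene): {pairs}"
        )
    ref_mean = ct.values[list(panel.reference_genes)].mean(axis=1)
    targets = [g for g in ct.genes if g not in panel.reference_genes]
    delta = ct.values[targets].sub(ref_mean, axis=0)
    return ExpressionMatrix(values=delta, groups=ct.groups.copy(), scale="delta_ct")


def linearize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Convert ΔCt to linear relative expression ``2**(-ΔCt)``."""
    if expr.scale != "delta_ct":
        raise ValueError(f"expected delta_ct scale, got {expr.scale!r}")
    return ExpressionMatrix(
        values=2.0 ** (-expr.values), groups=expr.groups.copy(), scale="linear"
    )


def fold_regulation(fold_change: float) -> float:
    """Signed symmetric representation: FC if FC >= 1, else -1/FC."""
    if not fold_change > 0:
        raise ValueError("fold change must be positive")
    return fold_change if fold_change >= 1.0 else -1.0 / fold_change


def qc_flag(
    mean_ct_test: float, mean_ct_control: float, ct_high: float = 30.0
) -> str:
    """Low-expression flag from group-mean raw Ct.

    ``A``: high (> ct_high) in exactly one group and low (< ct_high) in the
    other — the fold estimate leans on one barely-detected group.
    ``B``: high in both groups — the transcript is near the detection floor
    everywhere.  Strict inequalities; a mean exactly at the threshold
    counts as neither high nor low.
    """
    if not (np.isfinite(mean_ct_test) and np.isfinite(mean_ct_control)):
        raise ValueError("group-mean Ct must be finite")
    hi_t, hi_c = mean_ct_test > ct_high, mean_ct_control > ct_high
    lo_t, lo_c = mean_ct_test < ct_high, mean_ct_control < ct_high
    if hi_t and hi_c:
        return QC_B
    if (hi_t and lo_c) or (hi_c and lo_t):
        return QC_A
    return QC_NONE


def _group_rows(groups: pd.Series, label: str) -> pd.Index:
    rows = groups.index[groups == label]
    if len(rows) == 0:
        raise ValueError(f"group {label!r} not present")
    if len(rows) < 2:
        raise ValueError(f"group {label!r} has fewer than 2 samples")
    return rows


def compare_groups(
    expr: ExpressionMatrix,
    ct: CtMatrix,
    test_group: str,
    control_group: str,
    max_missing_frac: float = 0.5,
) -> list[ComparisonResult]:
    """Per-gene contrast of a test vs a control group.

    p-value: two-sided pooled-variance Student's t-test on the linear
    ``2**(-ΔCt)`` replicate values.  Fold change: ``2**(-ΔΔCt)`` from the
    group means of ΔCt (equivalently, the ratio of within-group geometric
    means of linear expression).  Genes whose raw Ct was undetermined in
    more than ``max_missing_frac`` of either group's wells are excluded
    with a warning.
    """
    if expr.scale != "linear":
        raise ValueError("compare_groups expects linear-scale expression")
    rows_t = _group_rows(expr.groups, test_group)
    rows_c = _group_rows(expr.groups, control_group)

    results: list[ComparisonResult] = []
    for gene in expr.genes:
        miss_t = ct.missing.loc[rows_t, gene].mean()
        miss_c = ct.missing.loc[rows_c, gene].mean()
        if miss_t > max_missing_frac or miss_c > max_missing_frac:
            warnings.warn(
                f"{gene}: undetermined in {miss_t:.0%} of {test_group!r} and "
                f"{miss_c:.0%} of {control_group!r} wells; "
                f"excluded from this comparison",
                stacklevel=2,
            )
            continue
        x_t = expr.values.loc[rows_t, gene].to_numpy()
        x_c = expr.values.loc[rows_c, gene].to_numpy()
        if np.ptp(x_t) == 0 and np.ptp(x_c) == 0 and x_t[0] == x_c[0]:
            # both groups constant and identical: no evidence of change
            p = 1.0
            logger.info("%s: zero variance in both groups; p set to 1", gene)
        else:
            p = float(stats.ttest_ind(x_t, x_c, equal_var=True).pvalue)
        ddct = float(np.mean(np.log2(x_c)) - np.mean(np.log2(x_t)))
        fc = float(2.0 ** (-ddct))
        mean_ct_t = float(ct.values.loc[rows_t, gene].mean())
        mean_ct_c = float(ct.values.loc[rows_c, gene].mean())
        results.append(
            ComparisonResult(
                gene=gene,
                p_value=p,
                fold_change=fc,
                fold_regulation=fold_regulation(fc),
                qc_flag=qc_flag(mean_ct_t, mean_ct_c),
                mean_ct_test=mean_ct_t,
                mean_ct_control=mean_ct_c,
            )
        )
    return results


def significance_filter(
    results: list[ComparisonResult], cfg: FilterConfig = FilterConfig()
) -> FilterResult:
    """Genes passing p < alpha with |FR| strictly above the cut-off."""
    if not results:
        raise ValueError("no comparison results to filter")
    up = [
        r.gene for r in results
        if r.p_value < cfg.alpha and r.fold_regulation > cfg.fr_cutoff
    ]
    down = [
        r.gene for r in results
        if r.p_value < cfg.alpha and r.fold_regulation < -cfg.fr_cutoff
    ]
    return FilterResult(up=up, down=down)


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "p_value": [r.p_value for r in results],
            "fold_change": [r.fold_change for r in results],
            "fold_regulation": [r.fold_regulation for r in results],
            "qc_flag": [r.qc_flag for r in results],
            "mean_ct_test": [r.mean_ct_test for r in results],
            "mean_ct_control": [r.mean_ct_control for r in results],
        }
    )


def write_comparison_csv(results: list[ComparisonResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False, float_format="%.6g")
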