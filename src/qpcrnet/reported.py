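"""Published per-contrast statistics from the rat heart-transplant study.

The study reported, for each of four test-vs-control contrasts, the genes
reaching nominal significance together with their p-values, fold
regulations and low-expression QC flags.  These tables are packaged here
as plain CSV so the significance filter and its worked examples can be
exercised without the (unpublished) raw Ct data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .quant import ComparisonResult

#: contrast slug -> (test group, control group)
REPORTED_CONTRASTS: dict[str, tuple[str, str]] = {
    "5h_vs_1h": ("5h ischemia", "1h ischemia"),
    "1h_aat_vs_1h": ("1h ischemia+AAT", "1h ischemia"),
    "5h_aat_vs_5h": ("5h ischemia+AAT", "5h ischemia"),
    "5h_aat_vs_1h_aat": ("5h ischemia+AAT", "1h ischemia+AAT"),
}


def reported_frame(contrast: str) -> pd.DataFrame:
    """The published table for one contrast slug, as a DataFrame."""
    if contrast not in REPORTED_CONTRASTS:
        raise KeyError(
            f"unknown contrast {contrast!r}; "
            f"choose from {sorted(REPORTED_CONTRASTS)}"
        )
    ref = resources.files("qpcrnet.data") / f"reported_{contrast}.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, keep_default_na=False)
    df["p_value"] = df["p_value"].astype(float)
    df["fold_regulation"] = df["fold_regulation"].astype(float)
    return df


def reported_comparison(contrast: str) -> list[ComparisonResult]:
    """The published table as ComparisonResult rows.

    Fold change is reconstructed from the signed fold regulation; raw
    group-mean Ct values were not published and are left NaN.
    """
    rows = []
    for rec in reported_frame(contrast).itertuples(index=False):
        fr = rec.fold_regulation
        fc = fr if fr >= 1 else -1.0 / fr
        rows.append(
            ComparisonResult(
                gene=rec.gene,
                p_value=rec.p_value,
                fold_change=fc,
                fold_regulation=fr,
                qc_flag=rec.qc_flag,
            )
        )
    return rows
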