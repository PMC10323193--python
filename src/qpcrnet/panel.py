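"""Gene panel and study-design constants.

The panel mirrors a custom RT^2 Profiler-style array: 88 target genes
involved in inflammation, apoptosis and oxidative stress, plus 5 stable
(non-regulated) genes used for reference normalization.  Group labels and
sizes follow the four-arm rat heterotopic heart-transplant design
(cold ischemia 1 h or 5 h, preservation solution with or without
alpha-1-antitrypsin).
"""

from __future__ import annotations

from dataclasses import dataclass

# Four study arms and their biological replicate counts.
GROUP_1H = "1h ischemia"
GROUP_1H_AAT = "1h ischemia+AAT"
GROUP_5H = "5h ischemia"
GROUP_5H_AAT = "5h ischemia+AAT"

GROUPS: tuple[str, ...] = (GROUP_1H, GROUP_1H_AAT, GROUP_5H, GROUP_5H_AAT)
GROUP_SIZES: dict[str, int] = {
    GROUP_1H: 7,
    GROUP_1H_AAT: 7,
    GROUP_5H: 7,
    GROUP_5H_AAT: 9,
}

# The four test-vs-control contrasts of the comparative analysis.
DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    (GROUP_5H, GROUP_1H),
    (GROUP_1H_AAT, GROUP_1H),
    (GROUP_5H_AAT, GROUP_5H),
    (GROUP_5H_AAT, GROUP_1H_AAT),
)

# Arm pools used for per-treatment network inference: placebo-preserved
# grafts (1h + 5h pooled) versus AAT-preserved grafts (1h + 5h pooled).
ARM_POOLS: dict[str, tuple[str, ...]] = {
    "ischemia": (GROUP_1H, GROUP_5H),
    "AAT": (GROUP_1H_AAT, GROUP_5H_AAT),
}

# Stable normalization genes (rat symbols).
REFERENCE_GENES: tuple[str, ...] = ("Rplp1", "ACTB", "B2m", "Hprt1", "Ldha")

# 88 target genes: apoptosis / cell death, oxidative stress, inflammation.
TARGET_GENES: tuple[str, ...] = (
    # apoptosis and cell death (23)
    "Aifm1", "Apaf1", "Bad", "Bak1", "Bax", "Bcl2", "Bcl2l1", "Birc2",
    "Casp1", "Casp3", "Casp7", "Casp8", "Casp9", "Cflar", "Cycs",
    "Fadd", "Fas", "Faslg", "Fos", "Mcl1", "Tnfrsf1a", "Tp53", "Xiap",
    # oxidative and nitrosative stress (35)
    "Cat", "Ccs", "Cyba", "Flt1", "Gclc", "Gclm", "Gpx1", "Gpx2",
    "Gpx3", "Gpx4", "Gpx5", "Gpx6", "Gpx7", "Gsr", "Gstk1", "Hmox1",
    "Hspa1a", "Keap1", "Ncf1", "Ncf2", "Nfe2l2", "Nos2", "Nos3",
    "Nox4", "Nqo1", "Prdx1", "Prdx2", "Prdx3", "Sod1", "Sod2", "Sod3",
    "Txn1", "Txnrd1", "Txnrd2", "Ucp2",
    # inflammatory response (30)
    "Ccl2", "Ccl3", "Ccl5", "Ccl11", "Ccl20", "Ccr2", "Cxcl1",
    "CxCr4", "Icam1", "Ifng", "Il1b", "Il1rn", "Il6", "Il9", "Il10",
    "Il18", "Mmp9", "Myd88", "Nfkb1", "Ptgs2", "Sele", "Selp",
    "Tgfb1", "Tlr2", "Tlr4", "Tnf", "Tollip", "Vcam1", "Vegfa", "Vegfc",
)


@dataclass(frozen=True)
class PanelSpec:
    """Array layout: ordered gene list, reference subset, missing-well rule.

    ``ct_ceiling`` is substituted for wells the instrument reports as
    undetermined (no amplification within the run), the usual convention
    for array-format qPCR exports.
    """

    all_genes: tuple[str, ...] = TARGET_GENES + REFERENCE_GENES
    reference_genes: tuple[str, ...] = REFERENCE_GENES
    ct_ceiling: float = 35.0

    def __post_init__(self) -> None:
        if len(set(self.all_genes)) != len(self.all_genes):
            raise ValueError("panel gene symbols must be unique")
        if not self.reference_genes:
            raise ValueError("at least one reference gene is required")
        missing = set(self.reference_genes) - set(self.all_genes)
        if missing:
            raise ValueError(
                f"reference genes not in panel: {sorted(missing)}"
            )
        if not self.ct_ceiling > 0:
            raise ValueError("ct_ceiling must be positive")

    @property
    def target_genes(self) -> tuple[str, ...]:
        return tuple(g for g in self.all_genes if g not in self.reference_genes)


def default_panel() -> PanelSpec:
    """The 88-target / 5-reference array used throughout."""
    return PanelSpec()
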