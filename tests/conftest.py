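import pandas as pd
import pytest

from qpcrnet.panel import GROUPS, PanelSpec, default_panel
from qpcrnet.quant import CtMatrix
from qpcrnet.simulate import CorrelationModule, GeneratorConfig


@pytest.fixture(scope="session")
def tiny_panel() -> PanelSpec:
    """Three target genes plus two reference genes."""
    return PanelSpec(
        all_genes=("g1", "g2", "g3", "ref1", "ref2"),
        reference_genes=("ref1", "ref2"),
    )


@pytest.fixture
def tiny_ct(tiny_panel) -> CtMatrix:
    """Hand-sized Ct matrix: 4 samples, 2 groups, easy arithmetic."""
    values = pd.DataFrame(
        {
            "g1": [25.0, 24.0, 22.0, 21.0],
            "g2": [30.0, 30.5, 30.2, 30.4],
            "g3": [20.0, 20.5, 20.2, 20.1],
            "ref1": [20.0, 20.0, 20.0, 20.0],
            "ref2": [22.0, 22.0, 22.0, 22.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    groups = pd.Series(["ctrl", "ctrl", "test", "test"], index=values.index)
    return CtMatrix(values=values, groups=groups)


@pytest.fixture(scope="session")
def recovery_config() -> GeneratorConfig:
    """Two planted 4-gene modules over all arms, 8 samples per group.

    Pairwise within-module correlation is ~0.88 (loading 0.9, latent sd
    1.5 cycles against 0.5 cycles of well noise); three near-silent genes
    and three independent noise genes round out a 14-target panel.
    """
    refs = default_panel().reference_genes
    mod_a = tuple(f"mA_{i}" for i in range(4))
    mod_b = tuple(f"mB_{i}" for i in range(4))
    noise = tuple(f"nz_{i}" for i in range(3))
    silent = ("sil_0", "sil_1", "sil_2")
    panel = PanelSpec(
        all_genes=mod_a + mod_b + noise + silent + refs, reference_genes=refs
    )
    return GeneratorConfig(
        panel=panel,
        group_sizes=tuple((g, 8) for g in GROUPS),
        modules=(
            CorrelationModule(genes=mod_a, pool=GROUPS, loadings=0.9),
            CorrelationModule(genes=mod_b, pool=GROUPS, loadings=0.9),
        ),
        silent_genes=silent,
        master_seed=0,
    )


def module_pairs(cfg: GeneratorConfig) -> set[frozenset[str]]:
    return {
        frozenset((a, b))
        for m in cfg.modules
        for i, a in enumerate(m.genes)
        for b in m.genes[i + 1:]
    }
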