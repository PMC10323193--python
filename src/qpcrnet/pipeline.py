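"""End-to-end orchestration: quantify -> filter -> networks -> layout -> tree.

``run_full`` executes every stage on either a Ct table on disk or a
simulated study, writing plain delimited text and JSON artifacts plus a
run log (seeds, stage timings, package versions), so a fixed master seed
reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .boruta import BorutaConfig
from .layout import layout_network, plot_network
from .network import (
    GeneNetwork,
    compare_networks,
    crossboruta,
    summarize_network,
    write_summary_json,
)
from .panel import ARM_POOLS, DEFAULT_CONTRASTS, PanelSpec, default_panel
from .quant import (
    CtMatrix,
    FilterConfig,
    compare_groups,
    linearize,
    normalize_delta_ct,
    read_ct_table,
    significance_filter,
    write_comparison_csv,
)
from .simulate import GeneratorConfig, simulate_study, write_ct_csv
from .tree import TreeConfig, induce_tree, training_accuracy

logger = logging.getLogger(__name__)


def _slug(text: str) -> str:
    return text.replace(" ", "_").replace("+", "_")


@dataclass
class RunConfig:
    out_dir: Path
    input_path: Path | None = None  # mutually exclusive with generator
    generator: GeneratorConfig | None = None
    panel: PanelSpec = field(default_factory=default_panel)
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    arm_pools: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(ARM_POOLS)
    )
    boruta: BorutaConfig = field(default_factory=BorutaConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    ml_scale: str = "ct"  # matrix feeding networks/tree: ct | delta_ct | linear
    master_seed: int = 0
    write_plots: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("provide exactly one of input_path or generator")
        if self.ml_scale not in ("ct", "delta_ct", "linear"):
            raise ValueError(f"unknown ml_scale {self.ml_scale!r}")


def _load_ct(cfg: RunConfig) -> CtMatrix:
    if cfg.input_path is not None:
        return read_ct_table(cfg.input_path, cfg.panel)
    ct, truth = simulate_study(cfg.generator)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    write_ct_csv(ct, cfg.out_dir / "simulated_ct.csv")
    truth.to_json(cfg.out_dir / "simulated_truth.json")
    return ct


def _ml_matrix(cfg: RunConfig, ct: CtMatrix):
    """Feature matrix for the machine-learning stages (default: raw Ct)."""
    if cfg.ml_scale == "ct":
        targets = [g for g in ct.genes if g not in cfg.panel.reference_genes]
        return ct.values[targets], ct.groups
    expr = normalize_delta_ct(ct, cfg.panel)
    if cfg.ml_scale == "linear":
        expr = linearize(expr)
    return expr.values, expr.groups


def run_full(cfg: RunConfig) -> dict:
    """Execute every stage; returns a manifest of written artifacts."""
    t0 = time.time()
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"artifacts": [], "stages": {}}
    log: dict[str, object] = {
        "package_version": __version__,
        "python": platform.python_version(),
        "master_seed": cfg.master_seed,
        "ml_scale": cfg.ml_scale,
    }

    def record(name: str, started: float) -> None:
        manifest["stages"][name] = round(time.time() - started, 3)

    def fail(stage: str, err: Exception) -> None:
        manifest["error"] = {"stage": stage, "message": str(err)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    # quantification + comparisons
    started = time.time()
    try:
        ct = _load_ct(cfg)
        declared = set(ct.group_set)
        for test, control in cfg.contrasts:
            missing = {test, control} - declared
            if missing:
                raise ValueError(
                    f"contrast {test!r} vs {control!r} references "
                    f"undeclared group(s) {sorted(missing)}"
                )
        expr_lin = linearize(normalize_delta_ct(ct, cfg.panel))
        filter_lines = []
        for test, control in cfg.contrasts:
            results = compare_groups(expr_lin, ct, test, control)
            name = f"comparison_{_slug(test)}_vs_{_slug(control)}.csv"
            write_comparison_csv(results, out / name)
            manifest["artifacts"].append(name)
            filt = significance_filter(results, cfg.filter)
            filter_lines.append(f"{test} vs {control}: {filt.summary()}")
        (out / "filter_summary.txt").write_text("\n".join(filter_lines) + "\n")
        manifest["artifacts"].append("filter_summary.txt")
    except Exception as err:  # noqa: BLE001 - abort with stage context
        fail("quantify", err)
    record("quantify", started)

    # per-arm networks + layouts
    started = time.time()
    nets: dict[str, GeneNetwork] = {}
    try:
        X, groups = _ml_matrix(cfg, ct)
        seed_root = np.random.SeedSequence(cfg.master_seed)
        arm_seeds = seed_root.generate_state(len(cfg.arm_pools) + 1,
                                             dtype=np.uint32)
        for k, (arm, pool) in enumerate(cfg.arm_pools.items()):
            rows = groups.index[groups.isin(pool)]
            sub = X.loc[rows]
            from .quant import ExpressionMatrix

            expr_arm = ExpressionMatrix(
                values=sub, groups=groups.loc[rows], scale="delta_ct"
            )
            b = cfg.boruta
            arm_cfg = BorutaConfig(
                n_trees=b.n_trees, max_iterations=b.max_iterations,
                alpha=b.alpha, importance=b.importance,
                multiple_test=b.multiple_test, seed=int(arm_seeds[k]),
                tentative_resolution=b.tentative_resolution,
            )
            net = crossboruta(expr_arm, arm_cfg, pool_label=arm)
            nets[arm] = net
            net.write_edge_list(out / f"network_{_slug(arm)}_edges.tsv")
            net.write_node_table(out / f"network_{_slug(arm)}_nodes.tsv")
            write_summary_json(
                summarize_network(net), out / f"network_{_slug(arm)}_summary.json"
            )
            lay = layout_network(net, seed=int(arm_seeds[-1]) + k)
            lay.write_csv(out / f"layout_{_slug(arm)}.csv")
            manifest["artifacts"] += [
                f"network_{_slug(arm)}_edges.tsv",
                f"network_{_slug(arm)}_nodes.tsv",
                f"network_{_slug(arm)}_summary.json",
                f"layout_{_slug(arm)}.csv",
            ]
            if cfg.write_plots:
                plot_network(net, lay, out / f"network_{_slug(arm)}.png",
                             title=arm)
                manifest["artifacts"].append(f"network_{_slug(arm)}.png")
        if len(nets) == 2:
            a, b_ = nets.values()
            write_summary_json(compare_networks(a, b_),
                               out / "network_comparison.json")
            manifest["artifacts"].append("network_comparison.json")
    except Exception as err:  # noqa: BLE001
        fail("network", err)
    record("network", started)

    # inter-group decision tree on all samples
    started = time.time()
    try:
        X, groups = _ml_matrix(cfg, ct)
        model = induce_tree(X, groups.to_numpy(), cfg.tree)
        model.to_json(out / "tree.json")
        (out / "tree.txt").write_text(model.render())
        manifest["artifacts"] += ["tree.json", "tree.txt"]
        log["tree_training_accuracy"] = training_accuracy(
            model, X, groups.to_numpy()
        )
    except Exception as err:  # noqa: BLE001
        fail("tree", err)
    record("tree", started)

    log["total_seconds"] = round(time.time() - t0, 3)
    manifest["log"] = log
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
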