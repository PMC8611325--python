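"""End-to-end analysis runs: config, manifest, and report assembly."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .data_model import (
    MultilayerNetwork,
    Roster,
    build_multilayer,
    read_nominations,
    union_layer,
)
from .permutation_tests import (
    DEFAULT_STATISTICS,
    run_cross_network_comparison,
    run_structural_comparison,
)
from .synthetic import SyntheticConfig, generate_baseline

logger = logging.getLogger(__name__)

#: Conventions stamped into every run manifest.
CONVENTIONS = {
    "p_value": "two-tailed, add-one Monte-Carlo, ties in both tails",
    "quantiles": "type-7 linear interpolation, strict inequality at bounds",
    "variance": "sample variance, n-1 divisor",
    "eccentricity": "in-eccentricity over all roster nodes; unreachable pairs ignored",
    "multiple_testing": "none; n_simultaneous_tests column reports the grid size",
}


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    input: str | None = None  # nominations CSV; exclusive with `synthetic`
    synthetic: dict | None = None  # SyntheticConfig fields
    statistics: tuple[str, ...] = DEFAULT_STATISTICS
    edge_null_models: tuple[str, ...] = ("edge1", "edge2")
    cross_null_models: tuple[str, ...] = ("cross1", "cross2")
    focal: str = "T.Bycatch"
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    n_swaps: int | None = None
    plots: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if (self.input is None) == (self.synthetic is None):
            raise ValueError("exactly one of input / synthetic must be given")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("statistics", "edge_null_models", "cross_null_models"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def load_network(cfg: RunConfig) -> MultilayerNetwork:
    """Materialize the input network from file or from the generator.

    For file input the roster is the sorted union of all identifiers in
    the file (every named individual is treated as surveyed); supply a
    pre-filtered file to restrict to respondents.
    """
    if cfg.synthetic is not None:
        return generate_baseline(SyntheticConfig.from_dict(cfg.synthetic))
    records = read_nominations(cfg.input)
    ids = sorted({r.sender for r in records} | {r.receiver for r in records})
    return build_multilayer(records, Roster(tuple(ids)))


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Run structural and cross-network comparisons; write all artifacts.

    Writes ``structural.csv``, ``cross_network.csv``, ``summary.txt``
    and ``manifest.json`` under ``out_dir`` and returns the manifest.
    Reruns from the same manifest seed are bit-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = load_network(cfg)
    if cfg.n_perm < 40:
        logger.warning(
            "n_perm=%d gives coarse p-value resolution (minimum attainable p=%.3g)",
            cfg.n_perm,
            2.0 / (cfg.n_perm + 1),
        )
    logger.info("structural comparison: 9 layers x %d statistics", len(cfg.statistics))
    structural = run_structural_comparison(
        net,
        statistics=cfg.statistics,
        null_models=cfg.edge_null_models,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        alpha=cfg.alpha,
        n_swaps=cfg.n_swaps,
    )
    logger.info("cross-network comparison: focal=%s", cfg.focal)
    cross = run_cross_network_comparison(
        net,
        focal=cfg.focal,
        null_models=cfg.cross_null_models,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
        alpha=cfg.alpha,
        n_swaps=cfg.n_swaps,
    )
    structural.to_csv(out / "structural.csv", index=False, float_format="%.10g")
    cross.to_csv(out / "cross_network.csv", index=False, float_format="%.10g")
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "alpha": cfg.alpha,
        "n_swaps": cfg.n_swaps,
        "statistics": list(cfg.statistics),
        "edge_null_models": list(cfg.edge_null_models),
        "cross_null_models": list(cfg.cross_null_models),
        "focal": cfg.focal,
        "input": cfg.input,
        "synthetic": cfg.synthetic,
        "conventions": CONVENTIONS,
        "network": {
            "n_nodes": len(net.roster),
            "union_edges": union_layer(net).n_edges,
            "layer_edges": {t: net.layers[t].n_edges for t in net.layers},
            **{k: v for k, v in net.meta.items() if isinstance(v, (int, float, str))},
        },
        "n_rows": {"structural": len(structural), "cross_network": len(cross)},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _write_summary(structural, cross, out / "summary.txt")
    if cfg.plots:
        _write_plots(structural, cross, out)
    return manifest


def _write_summary(structural: pd.DataFrame, cross: pd.DataFrame, path) -> None:
    lines = ["structural comparison (per layer x statistic x null model)", ""]
    for _, r in structural.iterrows():
        if r["direction"] == "undefined":
            lines.append(f"  {r['layer']:<10} {r['statistic']:<26} {r['null_model']}: undefined")
        else:
            lines.append(
                f"  {r['layer']:<10} {r['statistic']:<26} {r['null_model']}: "
                f"obs={r['observed']:+.3f} null={r['null_mean']:+.3f}"
                f"±{(r['null_sd'] if pd.notna(r['null_sd']) else 0):.3f} "
                f"p={r['p']:.3f} [{r['direction']}]"
            )
    lines += ["", "cross-network dyadic correlations (focal vs other layers)", ""]
    for _, r in cross.iterrows():
        lines.append(
            f"  {r['layer']:<20} {r['null_model']}: obs={r['observed']:+.3f} "
            f"null={r['null_mean']:+.3f} p={r['p']:.3f} [{r['direction']}]"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_plots(structural: pd.DataFrame, cross: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, df in (("structural", structural), ("cross_network", cross)):
        sub = df.dropna(subset=["observed", "null_mean"])
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(8, 4))
        xs = range(len(sub))
        ax.errorbar(
            xs, sub["null_mean"], yerr=sub["null_sd"].fillna(0), fmt="o", label="null mean ± sd"
        )
        ax.scatter(xs, sub["observed"], color="crimson", zorder=3, label="observed")
        ax.set_xticks(list(xs))
        ax.set_xticklabels(
            [f"{l}\n{m}" for l, m in zip(sub["layer"], sub["null_model"])],
            fontsize=6,
            rotation=90,
        )
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / f"{name}.png", dpi=120)
        plt.close(fig)
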