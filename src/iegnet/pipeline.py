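"""End-to-end orchestration: counts -> activation stats -> co-activation
matrices and dendrograms -> thresholded networks -> centrality contrasts.

``run_all`` executes the full analysis for every group x marker
combination present in the data, writes all tables, matrices, networks
and figures under an output directory, and produces one deterministic
machine-readable JSON summary with the resolved configuration embedded
for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from . import activation as act
from . import coactivation as coact
from . import metrics as met
from . import network as netmod
from .data import (
    GROUPS,
    RegionPanel,
    default_panel,
    read_counts,
    write_comparisons,
    write_network,
)

log = logging.getLogger("iegnet")

CONTRAST_GROUPS = ("vehicle", "iso")  # groups whose networks are compared
MARKER_EPOCHS = ("H1a", "Arc")

ANATOMY_COLORS = {
    "hippocampus": "#1f77b4",
    "RSC": "#2ca02c",
    "PFC": "#d62728",
    "thalamus": "#9467bd",
}


@dataclass
class RunConfig:
    """Resolved pipeline options; every default matches the pipeline's
    documented conventions and is written into the output summary."""

    counts: str = "counts.csv"
    out_dir: str = "results"
    panel_path: str | None = None
    marker_convention: str = "inclusive"  # inclusive | exclusive
    sd_ddof: int = 1  # sample SD in the threshold rule
    efficiency_weighted: bool = False
    pair_sets: tuple[str, ...] = ("all", "hippocampus", "RSC", "PFC", "thalamus")
    layout_seed: int = 7
    make_figures: bool = True

    def panel(self) -> RegionPanel:
        if self.panel_path:
            return RegionPanel.from_yaml(self.panel_path)
        return default_panel()


def _network_figure(
    net, panel: RegionPanel, hub: dict, path: Path, layout_seed: int
) -> None:
    g = net.graph
    pos = nx.spring_layout(g, seed=layout_seed, weight="weight")
    fig, ax = plt.subplots(figsize=(6, 6))
    widths = [4.0 * d["weight"] for _, _, d in g.edges(data=True)]
    colors = [ANATOMY_COLORS.get(panel.anatomical_group[v], "#7f7f7f") for v in g]
    sizes = [300 + 1200 * hub.get(v, 0.0) for v in g]
    nx.draw_networkx_edges(g, pos, width=widths, alpha=0.6, ax=ax)
    nx.draw_networkx_nodes(g, pos, node_color=colors, node_size=sizes, ax=ax)
    nx.draw_networkx_labels(g, pos, font_size=8, ax=ax)
    ax.set_title(f"{net.group} / {net.marker}  (threshold={net.threshold:.3f})")
    ax.axis("off")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _heatmap_figure(cmat, dendro, path: Path) -> None:
    order = list(dendro.leaf_order)
    m = cmat.matrix.loc[order, order]
    fig, (ax_d, ax_m) = plt.subplots(
        2, 1, figsize=(6, 8), height_ratios=[1, 3]
    )
    hierarchy.dendrogram(
        dendro.merges, labels=list(dendro.labels), ax=ax_d,
        color_threshold=0, no_labels=True,
    )
    ax_d.set_ylabel("Ward merge height")
    im = ax_m.imshow(m.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax_m.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax_m.set_yticks(range(len(order)), order, fontsize=7)
    fig.colorbar(im, ax=ax_m, label="Pearson r")
    fig.suptitle(f"{cmat.group} / {cmat.marker}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns the JSON-serializable summary."""
    panel = config.panel()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = read_counts(config.counts, panel)
    groups_present = [g for g in GROUPS if (counts["group"] == g).any()]
    log.info("stage activation: %d rows, groups %s", len(counts), groups_present)

    activation = act.percent_positive(counts, convention=config.marker_convention)
    activation.to_csv(out / "activation.csv", index=False)

    summary: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "groups": groups_present,
        "n_animals": {g: int(counts.loc[counts["group"] == g, "animal_id"].nunique())
                      for g in groups_present},
    }

    # --- activation contrasts (needs >= 2 groups) -------------------------
    if len(groups_present) >= 2:
        contrasts = act.activation_contrast_table(activation, panel)
        contrasts.to_csv(out / "activation_contrasts.csv", index=False)
        summary["activation_contrasts"] = {
            "n_tests": int(len(contrasts)),
            "n_significant": int((contrasts["tukey_p"] < 0.05).sum()),
        }
    else:
        log.info("single group: contrast stages skipped")
        summary["activation_contrasts"] = None

    # --- co-activation matrices, dendrograms, networks, metrics ----------
    networks: dict[tuple[str, str], object] = {}
    metrics: dict[tuple[str, str], met.NetworkMetrics] = {}
    summary["networks"] = {}
    for group in groups_present:
        for marker in MARKER_EPOCHS:
            cmat = coact.pearson_matrix(activation, group, marker, panel)
            cmat.to_csv(out / f"rmat_{group}_{marker}.csv")
            dendro = None
            if not np.isnan(cmat.matrix.to_numpy()).any():
                dendro = coact.ward_cluster(cmat)
                (out / f"dendro_{group}_{marker}.json").write_text(json.dumps({
                    "labels": list(dendro.labels),
                    "leaf_order": list(dendro.leaf_order),
                    "merges": dendro.merges.tolist(),
                }, indent=2))
            net = netmod.build_network(cmat, ddof=config.sd_ddof)
            write_network(net, out / f"net_{group}_{marker}.graphml")
            m = met.compute_metrics(
                net, efficiency_weighted=config.efficiency_weighted
            )
            m.per_node.to_csv(out / f"metrics_{group}_{marker}.csv")
            networks[(group, marker)] = net
            metrics[(group, marker)] = m
            summary["networks"][f"{group}/{marker}"] = {
                "threshold": net.threshold,
                "n_edges": m.n_edges,
                "giant_component": m.giant_component_size,
            }
            if config.make_figures:
                hub = m.per_node["hub_score"].to_dict()
                _network_figure(
                    net, panel, hub, out / f"net_{group}_{marker}.png",
                    config.layout_seed,
                )
                if dendro is not None:
                    _heatmap_figure(cmat, dendro, out / f"rmat_{group}_{marker}.png")

    # --- between-group comparisons ----------------------------------------
    if all(g in groups_present for g in CONTRAST_GROUPS):
        r_results, metric_results = [], []
        for marker in MARKER_EPOCHS:
            a = coact.pearson_matrix(activation, CONTRAST_GROUPS[0], marker, panel)
            b = coact.pearson_matrix(activation, CONTRAST_GROUPS[1], marker, panel)
            for pair_set in config.pair_sets:
                r_results.append(coact.rvalue_compare(a, b, pair_set, panel))
            for name in ("degree", "clustering", "efficiency"):
                metric_results.append(met.compare_metric(
                    metrics[(CONTRAST_GROUPS[0], marker)],
                    metrics[(CONTRAST_GROUPS[1], marker)],
                    name,
                ))
        write_comparisons(r_results, out / "r_comparisons.csv")
        write_comparisons(metric_results, out / "metric_comparisons.csv")
        summary["r_comparisons"] = {
            r.label: {"U": r.statistic, "p": r.p_value, "arrow": r.arrow_code}
            for r in r_results
        }
        summary["metric_comparisons"] = {
            r.label: {"U": r.statistic, "p": r.p_value, "arrow": r.arrow_code}
            for r in metric_results
        }
    else:
        log.info("contrast groups absent: between-group stages skipped")
        summary["r_comparisons"] = None
        summary["metric_comparisons"] = None

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, ensure_ascii=False)
    )
    return summary
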