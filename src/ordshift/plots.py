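"""Grotta bars and the cumulative odds-ratio diagnostic plot.

Vector (SVG) output first; PNG for convenience.  The cumulative-OR plot is
the recommended graphical check of the proportional-odds assumption: the
K-1 cut-point odds ratios with CIs against a dashed line at the fitted
common odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cutpoints import CORPlotData
from .data import TwoArmCounts

__all__ = ["PlotSpec", "render_grotta", "render_cor_plot"]


@dataclass(frozen=True)
class PlotSpec:
    kind: Literal["grotta", "cor_plot"]
    output_path: str
    format: Literal["svg", "png"] = "svg"
    title: str = ""
    log_axis: bool = True  # OR axis on log scale (cor_plot only)
    palette: str = "RdYlGn_r"
    label_threshold: float = 0.05  # suppress in-bar labels below this width


def render_grotta(data: TwoArmCounts, spec: PlotSpec) -> str:
    """Horizontal stacked percentage bars per arm with connecting lines."""
    props = data.proportions()
    k = data.k
    cmap = plt.get_cmap(spec.palette, k)
    fig, ax = plt.subplots(figsize=(8, 2.8))
    y = [1.0, 0.0]  # control on top
    edges = np.hstack([np.zeros((2, 1)), np.cumsum(props, axis=1)])
    for j in range(k):
        ax.barh(
            y,
            props[:, j] * 100,
            left=edges[:, j] * 100,
            height=0.55,
            color=cmap(j),
            edgecolor="white",
            label=data.scale.labels[j],
        )
        for g in range(2):
            if props[g, j] >= spec.label_threshold:
                ax.text(
                    (edges[g, j] + props[g, j] / 2) * 100,
                    y[g],
                    f"{props[g, j] * 100:.0f}%",
                    ha="center",
                    va="center",
                    fontsize=8,
                )
    for j in range(1, k):  # connect category boundaries between the bars
        ax.plot(
            [edges[0, j] * 100, edges[1, j] * 100],
            [y[0] - 0.275, y[1] + 0.275],
            color="0.4",
            lw=0.8,
        )
    ax.set_yticks(y)
    ax.set_yticklabels(data.arm_names)
    ax.set_xlim(0, 100)
    ax.set_xlabel("percentage of participants")
    ax.set_title(spec.title or "Outcome distribution by arm")
    ax.legend(
        loc="upper center",
        bbox_to_anchor=(0.5, -0.35),
        ncol=min(k, 8),
        fontsize=8,
        frameon=False,
    )
    fig.savefig(spec.output_path, format=spec.format, bbox_inches="tight")
    plt.close(fig)
    return spec.output_path


def render_cor_plot(plot_data: CORPlotData, spec: PlotSpec) -> str:
    """Cut-point ORs with CI whiskers, dashed common-OR line, PO-test annotation."""
    fig, ax = plt.subplots(figsize=(6.5, 4))
    undefined = False
    for c in plot_data.cutpoint_ors:
        if not c.defined:
            ax.plot(c.cutpoint_index, 1.0, "o", mfc="none", color="0.5")
            undefined = True
            continue
        ax.errorbar(
            c.cutpoint_index,
            c.or_value,
            yerr=[[c.or_value - c.ci_low], [c.ci_high - c.or_value]],
            fmt="o",
            color="0.35",
            capsize=3,
        )
    lo, hi = plot_data.common_or_ci
    ax.axhline(plot_data.common_or, color="tab:orange", ls="--", lw=1.5)
    if np.isfinite(lo) and np.isfinite(hi):
        ax.axhspan(lo, hi, color="tab:orange", alpha=0.12)
    ax.axhline(1.0, color="0.7", lw=0.8)
    if spec.log_axis:
        ax.set_yscale("log")
    ticks = [c.cutpoint_index for c in plot_data.cutpoint_ors]
    ax.set_xticks(ticks)
    ax.set_xticklabels(
        [c.label for c in plot_data.cutpoint_ors], rotation=30, ha="right", fontsize=8
    )
    ax.set_ylabel("odds ratio (treatment vs control)")
    po = plot_data.po_test
    note = (
        f"common OR {plot_data.common_or:.2f} "
        f"({lo:.2f}-{hi:.2f}); PO assumption LR test: "
        f"stat {po.statistic:.2f}, df {po.df:g}, p = {po.p_value:.3f}"
    )
    if undefined:
        note += "\nopen markers: OR undefined (zero margin, strict rule)"
    ax.set_title(spec.title or "Cumulative odds ratios by cut-point", fontsize=10)
    ax.text(
        0.02, 0.02, note, transform=ax.transAxes, fontsize=8, va="bottom"
    )
    fig.savefig(spec.output_path, format=spec.format, bbox_inches="tight")
    plt.close(fig)
    return spec.output_path
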