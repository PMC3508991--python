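"""Optional matplotlib figures: LTT/MLTT, interval-rate bars, branch-length
cumulative density, and per-node ancestral-range pies."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .divstats import BranchLengthCDF, IntervalRates, LTTCurve
from .biogeo import SDivaSummary
from .treeio import Chronogram

__all__ = ["plot_ltt", "plot_interval_rates", "plot_blcdf", "plot_node_pies"]


def _steps(curve: LTTCurve):
    # step function in negative time (past at the left)
    t = np.concatenate([[-curve.times[0]], -curve.times])
    n = np.concatenate([[curve.lineage_counts[0]], curve.lineage_counts])
    return t, n


def plot_ltt(curves: list[LTTCurve], path: str, bold_first: bool = True) -> None:
    """LTT plot; with several curves the first is drawn bold (the consensus)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, c in enumerate(curves):
        t, n = _steps(c)
        if i == 0 and bold_first:
            ax.step(t, n, where="post", color="black", lw=2, zorder=3)
        else:
            ax.step(t, n, where="post", color="grey", lw=0.6, alpha=0.6)
    ax.set_yscale("log")
    ax.set_xlabel("time (Ma)")
    ax.set_ylabel("lineages")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_interval_rates(rates: IntervalRates, path: str) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    mids = -(rates.bin_edges[:-1] + rates.bin_edges[1:]) / 2
    widths = rates.bin_edges[:-1] - rates.bin_edges[1:]
    ax.bar(mids, rates.rate, width=widths * 0.9, color="steelblue")
    ax.set_xlabel("time (Ma)")
    ax.set_ylabel(r"new species per lineage per $\Delta t$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_blcdf(cdf: BranchLengthCDF, path: str) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(cdf.class_edges, cdf.cumulative_freq, "o-", color="black",
            label="empirical")
    ax.plot(cdf.class_edges, cdf.fitted_constant_cdf, "--", color="steelblue",
            label="constant rate (exponential)")
    ax.plot(cdf.class_edges, cdf.fitted_variable_cdf, ":", color="firebrick",
            label="variable rates (mixture)")
    ax.set_xlabel("branch length class (Ma)")
    ax.set_ylabel("cumulative frequency")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_node_pies(
    reference: Chronogram, summary: SDivaSummary, path: str, max_slices: int = 4
) -> None:
    """Reference tree with per-node pies of ancestral-range probabilities."""
    tree = reference.tree
    ages = reference.node_ages()
    leaves = list(tree.leaf_node_iter())
    ypos = {leaf: i for i, leaf in enumerate(leaves)}
    for node in tree.postorder_node_iter():
        if not node.is_leaf():
            ypos[node] = float(np.mean([ypos[c] for c in node.child_nodes()]))
    fig, ax = plt.subplots(figsize=(7, 0.28 * len(leaves) + 1.5))
    for node in tree.preorder_node_iter():
        x, y = -ages[node], ypos[node]
        for child in node.child_nodes():
            cx, cy = -ages[child], ypos[child]
            ax.plot([x, x, cx], [y, cy, cy], color="black", lw=0.8)
        if node.is_leaf():
            ax.text(0.1, y, node.taxon.label, fontsize=6, va="center")
    cmap = plt.get_cmap("tab10")
    all_ranges = sorted(
        {r for probs in summary.clade_probs.values() for r in probs},
        key=lambda r: "".join(sorted(r)),
    )
    color = {r: cmap(i % 10) for i, r in enumerate(all_ranges)}
    crown = reference.crown_age
    for node in tree.preorder_internal_node_iter():
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        probs = summary.clade_probs.get(clade) or {}
        if not probs:
            continue
        top = sorted(probs.items(), key=lambda kv: -kv[1])[:max_slices]
        start = 90.0
        for r, p in top:
            ax.pie(
                [p, 1 - p], center=(-ages[node], ypos[node]),
                radius=crown * 0.02, startangle=start, frame=True,
                colors=[color[r], (0, 0, 0, 0)],
            )
            start -= 360.0 * p
    ax.set_xlim(-crown * 1.05, crown * 0.35)
    ax.set_ylim(-1, len(leaves))
    ax.set_yticks([])
    ax.set_xlabel("time (Ma)")
    handles = [plt.Line2D([], [], marker="o", ls="", color=color[r],
                          label="".join(sorted(r))) for r in all_ranges]
    ax.legend(handles=handles, fontsize=6, frameon=False, loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
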