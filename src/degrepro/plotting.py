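"""Optional trend plots: DEG counts, overlap rates, power and union/intersection.

Requires matplotlib; imported lazily so the core pipeline has no plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["plot_reports"]


def plot_reports(repro: pd.DataFrame, power: pd.DataFrame, outdir) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    n = repro.index.to_numpy()

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(n, repro["deg_count_mean"], yerr=repro["deg_count_sd"],
                marker="o", capsize=3)
    ax.set_xlabel("biological replicates (n)")
    ax.set_ylabel("DEGs (mean ± SD over 4 repeats)")
    fig.tight_layout()
    p = outdir / "deg_counts.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for k, color in ((2, "purple"), (3, "orange"), (4, "red")):
        axes[0].plot(n, repro[f"common_count_k{k}"], marker="o", color=color,
                     label=f"any {k} repeats")
        axes[1].plot(n, 100 * repro[f"overlap_rate_k{k}"], marker="o",
                     color=color, label=f"any {k} repeats")
    axes[0].plot(n, repro["deg_count_mean"], marker="s", color="tab:blue",
                 label="mean total DEGs")
    axes[0].set_ylabel("common DEGs (mean over combinations)")
    axes[1].set_ylabel("overlap rate (%)")
    for ax in axes:
        ax.set_xlabel("biological replicates (n)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    p = outdir / "overlap.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, kind in zip(axes[:2], ("intersection", "union")):
        ax.bar(n, power[f"matched_{kind}"], color="tab:blue", label="matched")
        ax.bar(n, power[f"specific_{kind}"], bottom=power[f"matched_{kind}"],
               color="tab:orange", label="specific")
        ax2 = ax.twinx()
        ax2.plot(n, 100 * power[f"power_{kind}"], color="black", marker="o",
                 label="power")
        ax2.set_ylabel("power (%)")
        ax.set_title(kind)
        ax.set_xlabel("biological replicates (n)")
        ax.set_ylabel("DEGs")
        ax.legend(fontsize=8, loc="upper left")
    axes[2].bar(n - 0.2, repro["union_size"], width=0.4, color="tab:green",
                label="union")
    axes[2].bar(n + 0.2, repro["intersection_size"], width=0.4, color="tab:pink",
                label="intersection")
    ax2 = axes[2].twinx()
    ax2.plot(n, repro["union_over_intersection"], color="tab:orange", marker="o")
    ax2.set_ylabel("union / intersection")
    axes[2].set_xlabel("biological replicates (n)")
    axes[2].set_ylabel("DEGs")
    axes[2].legend(fontsize=8)
    fig.tight_layout()
    p = outdir / "power.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
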