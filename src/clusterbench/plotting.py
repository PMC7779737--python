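"""Plain metrics-vs-relative-risk plots from a benchmark metric table."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["plot_metrics_vs_rr"]

_COLORS = {"bn": "tab:green", "sss": "tab:blue", "bym": "tab:red"}
_NAMES = {"bn": "Besag-Newell", "sss": "Spatial scan", "bym": "BYM"}


def plot_metrics_vs_rr(
    table: pd.DataFrame,
    measures: tuple[str, ...] = ("sens", "spec", "ppv", "npv"),
    out_file: str | Path | None = None,
):
    """One panel per measure; one line per method per cluster size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ncol = 2
    nrow = (len(measures) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(5 * ncol, 3.5 * nrow), squeeze=False)
    for ax, meas in zip(axes.ravel(), measures):
        for (method, size), grp in table.groupby(["method", "cluster_size"]):
            grp = grp.sort_values("rr")
            ax.plot(
                grp["rr"], grp[f"{meas}_mean"],
                marker="o", ms=3, color=_COLORS.get(method),
                alpha=0.5 + 0.5 / max(1, size),
                label=f"{_NAMES.get(method, method)} (size {size})",
            )
        ax.set_xscale("log")
        ax.set_xlabel("relative risk")
        ax.set_ylabel(f"{meas} (%)")
        ax.set_ylim(-2, 102)
    for ax in axes.ravel()[len(measures):]:
        ax.set_visible(False)
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    if out_file is not None:
        fig.savefig(out_file, dpi=120)
    return fig
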