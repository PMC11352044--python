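"""Optional matplotlib output for experiment reports.

These are plain diagnostic renderings (error heatmap, error-vs-FC panels,
correlation matrix, volcano with crossover connectors), not publication
figures.  Everything is written as PNG with the Agg backend.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_report"]


def _stress_heatmap(report, outdir: Path) -> list[Path]:
    paths = []
    summ = report.summary
    for (n, transform), grp in summ.groupby(["n", "transform"]):
        if transform != "raw":
            continue
        piv = grp.pivot_table(
            index=["family", "fc_true"], columns="method", values="mean_abs_error"
        )
        fig, ax = plt.subplots(figsize=(9, 0.35 * len(piv) + 2))
        im = ax.imshow(piv.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(piv.columns)), piv.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(piv)), [f"{f} fc={fc:g}" for f, fc in piv.index])
        ax.set_title(f"mean |ErrorFC|, n={n}")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        path = outdir / f"{report.experiment_id}_heatmap_n{n}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def _sweep_panels(report, outdir: Path) -> list[Path]:
    summ = report.summary
    paths = []
    for s_a, grp in summ.groupby("s_a"):
        ratios = sorted(grp["s_ratio"].unique())
        fig, axes = plt.subplots(
            1, len(ratios), figsize=(3 * len(ratios), 3), sharey=True
        )
        axes = np.atleast_1d(axes)
        for ax, ratio in zip(axes, ratios):
            sub = grp[grp["s_ratio"] == ratio]
            for method, mg in sub.groupby("method"):
                mg = mg.sort_values("fc_true")
                ax.plot(mg["fc_true"], mg["mean_error"], label=method, lw=1)
            ax.axhline(0, color="grey", lw=0.5)
            ax.set_title(f"s_b/s_a={ratio:g}")
            ax.set_xlabel("true FC")
        axes[0].set_ylabel("mean ErrorFC")
        axes[-1].legend(fontsize=6)
        fig.suptitle(f"s_a={s_a:g}")
        fig.tight_layout()
        path = outdir / f"{report.experiment_id}_errors_sa{s_a:g}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def _volcano(report, outdir: Path) -> list[Path]:
    cells = report.cells
    if cells.empty:
        return []
    paths = []
    wanted = {"LOG_OF_MEANS", "MEAN_OF_LOGS"}
    for family, grp in cells.groupby("family"):
        sub = grp[
            (grp["test"] == "WILCOXON_MWU") & grp["method"].isin(wanted)
        ]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        for method, mg in sub.groupby("method"):
            ax.scatter(mg["log_ratio"], mg["neg_log10_p"], s=8, label=method)
        piv = sub.pivot_table(
            index="variable_id", columns="method", values=["log_ratio", "neg_log10_p"]
        )
        if set(("log_ratio", m) for m in wanted) <= set(piv.columns):
            for _, r in piv.iterrows():
                ax.plot(
                    [r[("log_ratio", "LOG_OF_MEANS")], r[("log_ratio", "MEAN_OF_LOGS")]],
                    [r[("neg_log10_p", "LOG_OF_MEANS")], r[("neg_log10_p", "MEAN_OF_LOGS")]],
                    color="grey", lw=0.3, zorder=0,
                )
        ax.set_xlabel("log2 FC")
        ax.set_ylabel("-log10 p (Wilcoxon)")
        ax.set_title(f"{family} panel")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = outdir / f"{report.experiment_id}_volcano_{family}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def _correlation_matrix(report, outdir: Path) -> list[Path]:
    corr = report.tables.get("method_correlations")
    if corr is None or corr.empty:
        return []
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(corr.index)), corr.index)
    for i in range(len(corr.index)):
        for j in range(len(corr.columns)):
            ax.text(j, i, f"{corr.iloc[i, j]:.2f}", ha="center", va="center", fontsize=6)
    ax.set_title("Spearman rho of |log2 FC| between methods")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    path = outdir / f"{report.experiment_id}_method_correlations.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return [path]


def plot_report(report, outdir: str | Path) -> list[Path]:
    """Write the plots appropriate for a report's experiment type."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dispatch = {
        "distribution_stress": _stress_heatmap,
        "variance_sweep": _sweep_panels,
        "significance_panel": _volcano,
        "permutation_stress": _correlation_matrix,
    }
    fn = dispatch.get(report.experiment_id)
    return fn(report, outdir) if fn else []
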