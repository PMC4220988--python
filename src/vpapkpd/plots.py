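"""Plot-ready views of diagnostics: observed vs predicted, CWRES, VPC panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_gof", "plot_vpc"]


def plot_gof(gof: pd.DataFrame, path) -> None:
    """Three-panel goodness-of-fit figure for the population PK model."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, col, label in [
        (axes[0], "pred_population", "population predicted (mg/L)"),
        (axes[1], "pred_individual", "individual predicted (mg/L)"),
    ]:
        ax.scatter(gof[col], gof["observed"], s=8, alpha=0.5)
        lim = (0, max(gof["observed"].max(), gof[col].max()) * 1.05)
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(label)
        ax.set_ylabel("observed (mg/L)")
    axes[2].scatter(gof["pred_population"], gof["cwres"], s=8, alpha=0.5)
    axes[2].axhline(0.0, color="k", ls="--", lw=1)
    axes[2].set_xlabel("population predicted (mg/L)")
    axes[2].set_ylabel("CWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_vpc(vpc_table: pd.DataFrame, path) -> None:
    """One panel per stratum: observed proportion vs 90% prediction band."""
    strata = list(vpc_table["stratum"].unique())
    fig, axes = plt.subplots(1, len(strata), figsize=(4 * len(strata), 4),
                             squeeze=False)
    for ax, s in zip(axes[0], strata):
        part = vpc_table[vpc_table["stratum"] == s]
        x = range(len(part))
        ax.fill_between(x, part["pi_low"], part["pi_high"], alpha=0.3,
                        label="90% prediction interval")
        ax.plot(x, part["observed"], "o-", color="k", label="observed")
        ax.set_title(str(s))
        ax.set_xticks(list(x))
        ax.set_xticklabels(part["bin"], rotation=45, ha="right", fontsize=7)
        ax.set_ylabel("proportion elevated")
        ax.set_ylim(0, 1)
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
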