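"""Advisory figures: coefficient plots and the rho group plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def coefficient_plot(reports: dict, path) -> None:
    """Forest-style coefficient plot for one or more regression reports.

    ``reports`` maps a label to a RegressionReport; intercepts are omitted.
    Error bars are ±1.96 SE.
    """
    fig, ax = plt.subplots(figsize=(6, 4.5))
    offsets = np.linspace(-0.15, 0.15, len(reports)) if len(reports) > 1 else [0.0]
    for (label, rep), off in zip(reports.items(), offsets):
        terms = rep.terms[rep.terms["term"] != "const"]
        y = np.arange(len(terms)) + off
        ax.errorbar(
            terms["coef"], y, xerr=1.96 * terms["se"], fmt="o", capsize=3, label=label
        )
        ax.set_yticks(np.arange(len(terms)))
        ax.set_yticklabels(terms["term"])
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("coefficient (95% CI)")
    if len(reports) > 1:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def rho_group_plot(rho: pd.Series, groups: pd.Series, path) -> None:
    """Strip plot of per-subject instruction sensitivity by group."""
    fig, ax = plt.subplots(figsize=(4, 4))
    levels = sorted(groups.unique())
    rng = np.random.default_rng(0)
    for i, lv in enumerate(levels):
        vals = rho[groups == lv]
        x = i + rng.uniform(-0.08, 0.08, len(vals))
        ax.plot(x, vals, "o", alpha=0.6)
        ax.hlines(vals.mean(), i - 0.2, i + 0.2, color="k")
    ax.set_xticks(range(len(levels)))
    ax.set_xticklabels(levels)
    ax.set_ylabel(r"instruction sensitivity $\rho$")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
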