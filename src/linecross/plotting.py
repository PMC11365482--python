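"""Convenience plot: cohort means against genome composition.

Plots each cohort's mean ± SE at its expected P2 genome proportion
((1 − Aa)/2 on the parental ±1 scale) with a dashed line joining the two
parents — the expectation every cohort would sit on under a purely
additive architecture.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_means"]


def plot_means(
    cmatrix: pd.DataFrame,
    trait_summaries: pd.DataFrame,
    trait: str,
    path: str | Path | None = None,
):
    """Means ± SE vs P2 genome proportion, with the additive expectation line."""
    ordered = trait_summaries.set_index("cohort").loc[cmatrix.index]
    p2_prop = (1.0 - cmatrix["Aa"]) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        p2_prop, ordered["mean"], yerr=ordered["se"], fmt="o", capsize=3, color="k"
    )
    for cohort, x in p2_prop.items():
        ax.annotate(cohort, (x, ordered.loc[cohort, "mean"]), textcoords="offset points",
                    xytext=(5, 5), fontsize=8)
    parents = p2_prop.sort_values()
    lo, hi = parents.index[0], parents.index[-1]
    ax.plot(
        [p2_prop[lo], p2_prop[hi]],
        [ordered.loc[lo, "mean"], ordered.loc[hi, "mean"]],
        "k--", lw=1, label="additive expectation",
    )
    ax.set_xlabel("proportion of P2 genome")
    ax.set_ylabel(f"{trait} mean")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
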