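"""Matplotlib figures mirroring the study's descriptive and validation plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .comparison import ComparisonTable
from .task import CONDITION_LABELS
from .validation import PpcSummary

_CONDITION_STYLE = {
    "go_immediate": dict(color="#d95f02", linestyle="-"),
    "go_delayed": dict(color="#7570b3", linestyle="-"),
    "nogo_immediate": dict(color="#d95f02", linestyle="--"),
    "nogo_delayed": dict(color="#7570b3", linestyle="--"),
}


def plot_model_comparison(table: ComparisonTable, path=None):
    """Bar charts of median AIC and model frequency across participants."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    models = list(table.median_aic.index)
    ax1.bar(models, table.median_aic.values, color="#666666")
    ax1.set_ylabel("median AIC")
    lo = min(table.median_aic.values)
    ax1.set_ylim(lo * 0.95, None)
    ax2.bar(models, table.frequency.values, color="#666666")
    ax2.set_ylabel("model frequency")
    ax2.set_ylim(0, 1)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_ppc(ppc: PpcSummary, path=None):
    """Trial-by-trial predicted go curves per condition, with 95% bands.

    Observed raw curves (when present in the summary) are overlaid as
    scatter points.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    for lab in CONDITION_LABELS:
        sub = ppc.condition_curve(lab)
        style = _CONDITION_STYLE[lab]
        ax.plot(sub["occurrence"] + 1, sub["mean"], label=lab, **style)
        ax.fill_between(
            sub["occurrence"] + 1, sub["ci_low"], sub["ci_high"],
            alpha=0.15, color=style["color"],
        )
        if ppc.observed is not None:
            obs = ppc.observed[ppc.observed["condition"] == lab]
            ax.scatter(obs["occurrence"] + 1, obs["mean"], s=6, alpha=0.5,
                       color=style["color"])
    ax.set_xlabel("condition presentation")
    ax.set_ylabel("p(go)")
    ax.set_ylim(0, 1)
    ax.set_title(f"Posterior predictive, {ppc.model_id} ({ppc.n_datasets} datasets)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
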