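"""ROC-curve panels for the cohort report."""

from __future__ import annotations

import numpy as np

from .stats import RocResult


def plot_roc_panel(roc_results: dict[str, RocResult], title: str = "", ax=None):
    """Plot a family of empirical ROC curves with AUC +/- SD in the legend.

    Parameters
    ----------
    roc_results : mapping variable name -> RocResult
    ax : matplotlib axes, optional

    Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, roc in roc_results.items():
        ax.plot(roc.fpr, roc.tpr, label=f"{name}: AUC {roc.auc:.2f} ± {roc.auc_sd:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("sensitivity")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    return ax
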