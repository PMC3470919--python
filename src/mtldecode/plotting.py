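"""Small matplotlib helpers for group accuracies and behavior curves."""

from __future__ import annotations

import numpy as np

__all__ = ["accuracy_bars", "psychometric_curve"]


def accuracy_bars(group_table, chance: float = 0.5, ax=None):
    """Bar plot of mean decoding accuracy per ROI with subject SEM bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    means = group_table.mean(axis=0)
    sems = group_table.std(axis=0, ddof=1) / np.sqrt(len(group_table))
    ax.bar(means.index, means.to_numpy(), yerr=sems.to_numpy(),
           color="steelblue", capsize=4)
    ax.axhline(chance, color="k", ls="--", lw=1, label=f"chance ({chance})")
    ax.set_ylabel("classifier accuracy")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    return ax


def psychometric_curve(summary, ax=None):
    """Observed P(choose A) per morph level with the fitted logistic curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    lv = summary.per_level["level_pct_A"].to_numpy()
    ax.plot(lv, summary.per_level["p_choose_A"], "o", color="k",
            label="observed")
    grid = np.linspace(0, 100, 201)
    ax.plot(grid, summary.fit.predict(grid), "-", color="crimson",
            label="MLE fit")
    ax.set_xlabel("% scene A in morph")
    ax.set_ylabel("P(choose A)")
    ax.legend(frameon=False)
    return ax
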