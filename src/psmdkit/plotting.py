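"""Simple plots of study outputs (requires matplotlib, extra ``plot``)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_roc_curves(cohort: pd.DataFrame, roc_table: pd.DataFrame, config=None, ax=None):
    """ROC curves for each battery score, labelled with the tabulated AUC."""
    import matplotlib.pyplot as plt

    from .pipeline import StudyConfig

    config = config or StudyConfig()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    score_map = {lbl: (col, ori) for lbl, col, ori in config.roc_scores}
    for row in roc_table.itertuples(index=False):
        col, ori = score_map[row.score]
        data = cohort.dropna(subset=[col, "acer"])
        y = (data["acer"] < config.acer_cutoff).to_numpy()
        s = ori * data[col].to_numpy(dtype=float)
        thresholds = np.unique(s)[::-1]
        tpr = [(s[y] >= t).mean() for t in thresholds] + [1.0]
        fpr = [(s[~y] >= t).mean() for t in thresholds] + [1.0]
        ax.plot(fpr, tpr, label=f"{row.score} (AUC {row.auc:.2f})", lw=1.2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    return ax


def plot_regional_matrix(matrix_table: pd.DataFrame, ax=None):
    """Heatmap of the regional PSMD × WMH robust-correlation matrix."""
    import matplotlib.pyplot as plt

    pivot = matrix_table.pivot(index="psmd_region", columns="wmh_region", values="r")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(pivot.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(pivot.index)), pivot.index, fontsize=7)
    ax.set_xlabel("WMH region")
    ax.set_ylabel("PSMD region")
    ax.figure.colorbar(im, ax=ax, label="percentage-bend r")
    return ax
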