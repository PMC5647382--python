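"""Plotting helpers (visualization only, no analysis assertions)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import BetaMatrix

__all__ = ["plot_pca", "plot_km"]


def plot_pca(beta: BetaMatrix, labels: pd.Series | None = None, ax=None):
    """Scatter the first two principal components of a β matrix."""
    import matplotlib.pyplot as plt
    from sklearn.decomposition import PCA

    X = beta.fill_median().to_numpy()
    pcs = PCA(n_components=2).fit_transform(X - X.mean(axis=0))
    if ax is None:
        _, ax = plt.subplots()
    if labels is None:
        ax.scatter(pcs[:, 0], pcs[:, 1], s=12)
    else:
        lab = pd.Series(list(labels), index=beta.sample_ids)
        for g in sorted(lab.unique(), key=str):
            mask = (lab == g).to_numpy()
            ax.scatter(pcs[mask, 0], pcs[mask, 1], s=12, label=str(g))
        ax.legend(frameon=False)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    return ax


def plot_km(curves: dict, ax=None, landmark: float | None = 60.0):
    """Step-plot Kaplan–Meier curves per group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for group, est in curves.items():
        times = np.concatenate([[0.0], est.times])
        surv = np.concatenate([[1.0], est.survival])
        ax.step(times, surv, where="post", label=f"{group} (n={est.n})")
    if landmark is not None:
        ax.axvline(landmark, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("Months")
    ax.set_ylabel("Progression-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    return ax
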