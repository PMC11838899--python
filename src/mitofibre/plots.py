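"""2Dmito scatter plots with classification overlays (non-interactive)."""

from __future__ import annotations

import numpy as np

from .data import MitoDataset


def plot_classification(dataset: MitoDataset, probability, band=None, ax=None):
    """Scatter controls in grey and patient fibres coloured blue-to-red by
    their posterior probability of being not-like-control; optionally overlay
    a (lower, fitted, upper) band on a grid.

    ``band`` is either None or a tuple ``(x_grid, lower, fitted, upper)``.
    Returns the matplotlib axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for s in dataset.controls:
        ax.scatter(s.x, s.y, s=8, c="0.6", alpha=0.5, linewidths=0)
    pat = dataset.patient
    probability = np.asarray(probability, dtype=float)
    sc = ax.scatter(pat.x, pat.y, s=12, c=probability, cmap="coolwarm",
                    vmin=0, vmax=1, linewidths=0)
    plt.colorbar(sc, ax=ax, label="P(not-like-control)")
    if band is not None:
        x_grid, lower, fitted, upper = band
        ax.plot(x_grid, fitted, color="green")
        ax.plot(x_grid, lower, color="green", linestyle="--")
        ax.plot(x_grid, upper, color="green", linestyle="--")
    ax.set_xlabel(f"log {dataset.mass_channel}")
    ax.set_ylabel(f"log {dataset.oxphos_channel}")
    return ax
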