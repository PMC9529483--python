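"""Sweep-figure helpers (matplotlib)."""

from __future__ import annotations

import numpy as np

from .groupstats import SweepComparison


def plot_sweep(comparisons: dict[str, SweepComparison],
               sigma_curves: dict[str, np.ndarray] | None = None,
               gate_value: float | None = None):
    """Group-mean metric curves along the threshold grid, significant
    thresholds starred, plus optional sigma curves and the ln(N) degree gate.

    Returns the matplotlib Figure.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n_panels = len(comparisons) + (1 if sigma_curves else 0)
    fig, axes = plt.subplots(1, n_panels, figsize=(4 * n_panels, 3.2), squeeze=False)
    axes = axes[0]
    for ax, (name, comp) in zip(axes, comparisons.items()):
        ma, mb = comp.group_means
        ax.plot(comp.thresholds, ma, "r-", label="group A")
        ax.plot(comp.thresholds, mb, "b-", label="group B")
        sig = comp.significant
        if sig.any():
            ymax = np.nanmax([ma, mb])
            ax.plot(comp.thresholds[sig], np.full(sig.sum(), ymax * 1.05), "b*",
                    markersize=4)
        if name == "mean_degree" and gate_value is not None:
            ax.axhline(gate_value, color="g", linestyle="--", linewidth=1,
                       label="ln(N)")
        ax.set_xlabel("threshold T")
        ax.set_title(name)
        ax.legend(fontsize=7)
    if sigma_curves:
        ax = axes[-1]
        for g, sig in sigma_curves.items():
            ax.plot(np.arange(sig.size), sig, label=f"sigma {g}")
        ax.axhline(1.0, color="k", linewidth=0.8)
        ax.set_xlabel("threshold index")
        ax.set_title("small-world sigma")
        ax.legend(fontsize=7)
    fig.tight_layout()
    return fig
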