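"""Diagnostic plots for threshold pairs.

One plotting convention throughout: raw unit observations as small
points, upper-boundary points as diamonds, the selected fitted curve as
a solid line, and the detected threshold as a dashed vertical line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .thresholds.boundary import BoundarySeries
from .thresholds.select import ThresholdResult


def plot_threshold_pair(x, y, series: BoundarySeries,
                        result: ThresholdResult | None,
                        xlabel: str = "configuration metric",
                        ylabel: str = "ESDR",
                        path: str | Path | None = None):
    """Scatter + boundary diamonds + fitted curve + threshold line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(x, y, ".", ms=3, color="0.6", alpha=0.6, label="units")
    ax.plot(series.x, series.y, "D", ms=6, color="tab:orange",
            label=f"boundary (q{series.tau:g})")
    if result is not None and result.fit is not None:
        grid = np.linspace(series.x.min(), series.x.max(), 200)
        ax.plot(grid, result.fit.predict(grid), "-", color="tab:blue",
                label=f"{result.family} fit")
        ax.axvline(result.threshold, ls="--", color="tab:red",
                   label=f"threshold = {result.threshold_2dp:.2f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
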