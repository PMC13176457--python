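"""Upper-boundary (constraint-line) point extraction.

The envelope of a predictor-response scatter is summarized by binning
the predictor into adaptive equal-frequency bins and taking the
empirical 0.90 quantile of the response in each bin; the resulting
(mean x, upper-quantile y) series is what the threshold models are
fitted to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: empirical-quantile convention used throughout (numpy default)
QUANTILE_METHOD = "linear"


@dataclass
class BoundarySeries:
    """Per-bin upper-boundary points of a scatter."""

    x: np.ndarray          # representative x: mean of member x
    y: np.ndarray          # empirical tau-quantile of member responses
    counts: np.ndarray     # members per bin
    edges: np.ndarray      # bin edges on the metric scale (n_bins + 1)
    tau: float = 0.90
    quantile_method: str = QUANTILE_METHOD

    @property
    def n_bins(self) -> int:
        return len(self.x)

    @property
    def x_range(self) -> tuple[float, float]:
        return float(self.x.min()), float(self.x.max())


def extract_boundary(x: np.ndarray, y: np.ndarray, tau: float = 0.90,
                     min_bin_n: int = 10) -> BoundarySeries:
    """Extract the upper-boundary series with adaptive equal-frequency bins.

    ``n_bins = clamp(n // min_bin_n, 5, 20)``; members are assigned by a
    stable sort on x (ties keep input order), so every bin holds at
    least ``min_bin_n`` points.  Requires ``n >= 5 * min_bin_n``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5 * min_bin_n:
        raise ValueError(
            f"insufficient points for boundary extraction: n={n} < "
            f"{5 * min_bin_n}"
        )
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; boundary undefined")
    n_bins = int(np.clip(n // min_bin_n, 5, 20))
    order = np.argsort(x, kind="stable")
    chunks = np.array_split(order, n_bins)
    bx = np.array([x[c].mean() for c in chunks])
    by = np.array([
        np.quantile(y[c], tau, method=QUANTILE_METHOD) for c in chunks
    ])
    counts = np.array([len(c) for c in chunks])
    inner = [(x[chunks[i]].max() + x[chunks[i + 1]].min()) / 2.0
             for i in range(n_bins - 1)]
    edges = np.concatenate([[x.min()], inner, [x.max()]])
    return BoundarySeries(x=bx, y=by, counts=counts, edges=edges, tau=tau)
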