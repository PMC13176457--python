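"""Model selection, threshold summary and bootstrap uncertainty.

Among the valid candidate fits the minimum-BIC family wins; when BICs
differ by at most 2 the less complex family is preferred (parsimony
ordering quadratic < segmented < GAM).  The selected threshold is then
summarized by the mean boundary response on each side, and its
uncertainty quantified by resampling the raw unit-level pairs with
replacement and re-running the whole extract-fit-select chain per
replicate: the success rate is the fraction of replicates re-detecting
a valid threshold of the same family, and the CI the 2.5/97.5
percentiles of the replicate thresholds among successes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boundary import BoundarySeries, extract_boundary
from .fits import CandidateFit, fit_gam, fit_quadratic, fit_segmented

_COMPLEXITY = {"quadratic": 0, "segmented": 1, "gam": 2}
_DELTA_BIC = 2.0


def triple_fit(series: BoundarySeries) -> list[CandidateFit]:
    """Fit all applicable candidate families to a boundary series."""
    fits = []
    n = series.n_bins
    if n >= 5:
        fits.append(fit_quadratic(series))
    if n >= 6:
        fits.append(fit_segmented(series))
    if n >= 8:
        fits.append(fit_gam(series))
    return fits


def linear_null_bic(series: BoundarySeries) -> float:
    """BIC of the straight-line (no-threshold) model of the boundary."""
    from .fits import _ols, bic_from_sse

    n = series.n_bins
    X = np.column_stack([np.ones(n), series.x])
    res = _ols(X, series.y, with_stats=False)
    if res is None:
        return np.inf
    return bic_from_sse(res[1], n, 2)


def select_model(fits: list[CandidateFit], null_bic: float | None = None
                 ) -> tuple[CandidateFit | None, dict[str, str]]:
    """Pick the valid fit with minimum BIC; parsimony breaks near-ties.

    Returns (selected fit or None, reasons per family).  Candidates
    whose BIC is within 2 of the minimum form a tie set resolved toward
    the less complex family.  When ``null_bic`` (the straight-line
    no-threshold model) is supplied, a candidate is additionally valid
    only if it beats that null by more than the 2-point parsimony
    window — the framework reports no threshold when a line describes
    the boundary equally well.  "No valid threshold" (None) is a legal
    outcome.
    """
    if not fits:
        raise ValueError("at least one candidate fit is required")
    reasons = {}
    valid = []
    for f in fits:
        if not f.ok:
            reasons[f.family] = f"fit failed: {f.notes or 'error'}"
        elif f.threshold is None:
            reasons[f.family] = f.notes or "no threshold located"
        elif not f.in_range:
            reasons[f.family] = "threshold outside supported range"
        elif not f.significant:
            reasons[f.family] = "key parameter not significant"
        elif null_bic is not None and not f.bic < null_bic - _DELTA_BIC:
            reasons[f.family] = "not better than the linear null (BIC)"
        else:
            reasons[f.family] = "valid"
            valid.append(f)
    if not valid:
        return None, reasons
    best_bic = min(f.bic for f in valid)
    tied = [f for f in valid if f.bic <= best_bic + _DELTA_BIC]
    tied.sort(key=lambda f: (_COMPLEXITY[f.family], f.bic))
    return tied[0], reasons


@dataclass
class ThresholdResult:
    """Detected threshold for one screened pair."""

    pair: dict                        # cluster / metric / response labels
    family: str
    threshold: float                  # full precision
    threshold_2dp: float              # as reported
    pre_mean: float
    post_mean: float
    delta: float
    direction: str                    # increase | decrease | tie
    flags: list[str] = field(default_factory=list)
    fit: CandidateFit | None = None
    bootstrap: dict | None = None     # ci_low, ci_high, success_rate, B


def summarize_threshold(series: BoundarySeries, fit: CandidateFit,
                        pair: dict | None = None) -> ThresholdResult:
    """Pre/post boundary means flanking the selected threshold.

    pre = mean boundary y with x < x*; post = mean with x >= x*;
    direction follows sign(post - pre).  A threshold leaving fewer than
    two boundary points on either side is flagged ``edge-supported``
    (retained); an exact tie in the means is flagged.
    """
    if fit is None or fit.threshold is None:
        raise ValueError("summarize_threshold needs a valid selected fit")
    xstar = float(fit.threshold)
    pre_mask = series.x < xstar
    post_mask = ~pre_mask
    flags = []
    if pre_mask.sum() < 2 or post_mask.sum() < 2:
        flags.append("edge-supported")
    pre = float(series.y[pre_mask].mean()) if pre_mask.any() else np.nan
    post = float(series.y[post_mask].mean()) if post_mask.any() else np.nan
    delta = post - pre
    if np.isnan(delta) or delta == 0:
        direction = "tie"
        if delta == 0:
            flags.append("tie")
    else:
        direction = "increase" if delta > 0 else "decrease"
    return ThresholdResult(
        pair=pair or {}, family=fit.family, threshold=xstar,
        threshold_2dp=round(xstar, 2), pre_mean=pre, post_mean=post,
        delta=delta, direction=direction, flags=flags, fit=fit,
    )


def bootstrap_threshold(x: np.ndarray, y: np.ndarray, family: str,
                        tau: float = 0.90, min_bin_n: int = 10,
                        B: int = 1000, seed: int = 0,
                        fit_boundary: bool = True) -> dict:
    """Resample raw unit pairs; re-run extract -> triple fit -> select.

    Resampling the units (not the boundary points) propagates binning
    variability.  A replicate counts as a success when selection again
    returns a valid threshold of ``family``.  Deterministic given seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(x)
    hits = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            if fit_boundary:
                series = extract_boundary(x[idx], y[idx], tau=tau,
                                          min_bin_n=min_bin_n)
            else:
                series = raw_series(x[idx], y[idx])
            selected, _ = select_model(triple_fit(series),
                                       null_bic=linear_null_bic(series))
        except (ValueError, np.linalg.LinAlgError):
            selected = None
        if selected is not None and selected.family == family:
            hits.append(selected.threshold)
    success_rate = len(hits) / B
    if hits:
        ci_low, ci_high = np.percentile(hits, [2.5, 97.5])
    else:
        ci_low = ci_high = np.nan
    out = {
        "ci_low": float(ci_low), "ci_high": float(ci_high),
        "success_rate": success_rate, "n_replicates": B,
        "flags": [] if success_rate >= 0.5 else ["unstable"],
    }
    return out


def raw_series(x: np.ndarray, y: np.ndarray) -> BoundarySeries:
    """Treat the raw unit points themselves as the fitted series.

    Sensitivity-analysis alternative to upper-boundary extraction: the
    threshold models then describe the mean response rather than the
    envelope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    return BoundarySeries(
        x=xs, y=ys, counts=np.ones(len(xs), dtype=int),
        edges=np.concatenate([[xs[0]], (xs[:-1] + xs[1:]) / 2, [xs[-1]]]),
        tau=np.nan, quantile_method="raw points",
    )


def analyze_pair(x: np.ndarray, y: np.ndarray, pair: dict | None = None,
                 tau: float = 0.90, min_bin_n: int = 10,
                 B: int = 1000, seed: int = 0,
                 run_bootstrap: bool = True,
                 fit_boundary: bool = True
                 ) -> tuple[ThresholdResult | None, dict]:
    """Full per-pair chain: boundary, triple fit, selection, bootstrap.

    Returns (result or None, diagnostics).  ``None`` means no valid
    threshold; diagnostics carry the per-family reasons either way.
    ``fit_boundary=False`` fits the raw unit points instead of the
    extracted envelope (sensitivity analysis).
    """
    if fit_boundary:
        series = extract_boundary(x, y, tau=tau, min_bin_n=min_bin_n)
    else:
        series = raw_series(x, y)
    fits = triple_fit(series)
    selected, reasons = select_model(fits, null_bic=linear_null_bic(series))
    diagnostics = {
        "reasons": reasons,
        "bics": {f.family: f.bic for f in fits if f.ok},
        "n_boundary_points": series.n_bins,
    }
    if selected is None:
        return None, diagnostics
    result = summarize_threshold(series, selected, pair=pair)
    if run_bootstrap:
        boot = bootstrap_threshold(x, y, selected.family, tau=tau,
                                   min_bin_n=min_bin_n, B=B, seed=seed,
                                   fit_boundary=fit_boundary)
        ci_low, ci_high = boot["ci_low"], boot["ci_high"]
        if np.isfinite(ci_low) and not (ci_low <= result.threshold
                                        <= ci_high):
            result.flags.append("threshold outside bootstrap CI")
        result.flags.extend(boot.pop("flags"))
        result.bootstrap = boot
    return result, diagnostics
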