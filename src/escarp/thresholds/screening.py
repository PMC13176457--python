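"""Correlation + FDR screening of (cluster, metric, response) pairs.

Before any threshold model is fitted, each candidate pair is screened:
Spearman rank correlation with average-rank ties, Benjamini-Hochberg
step-up correction applied jointly over the full family of tested pairs
(all clusters x configuration metrics x responses), a correlation-
strength floor, and a minimum-sample rule.  Failed pairs carry a reason
code so screening attrition is auditable.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONFIG_METRICS = ("PD", "LPI", "ED", "PAFRAC", "AI")

#: exhaustive permutation null up to this n; Monte Carlo above, t beyond 20
_EXACT_N = 7
_MC_PERMS = 9999


def spearman_test(x: np.ndarray, y: np.ndarray, seed: int = 0
                  ) -> tuple[float, float]:
    """Spearman rho and p-value.

    Ties get average ranks.  For n <= 7 the p-value is exact (full
    permutation enumeration); for 8 <= n <= 20 a seeded Monte Carlo
    permutation test (9999 draws); above that the usual t
    approximation.  Returns (nan, nan) for constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= _EXACT_N:
        null = np.array([
            np.corrcoef(rx, ry[list(p)])[0, 1]
            for p in permutations(range(n))
        ])
        p = float((np.abs(null) >= abs(rho) - 1e-12).mean())
        return rho, p
    if n <= 20:
        rng = np.random.default_rng(seed)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        scale = np.sqrt((rxc @ rxc) * (ryc @ ryc))
        null = np.array([
            rxc @ rng.permutation(ryc) for _ in range(_MC_PERMS)
        ]) / scale
        p = (1 + int((np.abs(null) >= abs(rho) - 1e-12).sum())) / (_MC_PERMS + 1)
        return rho, float(p)
    t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(min(1.0, p))


def screen_pairs(esdr: pd.DataFrame, metrics: pd.DataFrame,
                 labels: np.ndarray,
                 alpha: float = 0.05, rho_min: float = 0.20,
                 n_min: int = 30,
                 config_metrics: tuple[str, ...] = CONFIG_METRICS,
                 responses: tuple[str, ...] | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """Screen every (cluster, metric, response) pair.

    ``esdr`` and ``metrics`` are aligned on unit_id; ``labels`` gives a
    cluster per unit (same row order as the tables after alignment).
    PAFRAC-undefined units are dropped pairwise.  Returns one row per
    pair with rho, p, BH-adjusted p and a pass flag with reason code
    (``pass | fdr_fail | weak_rho | small_n | undefined``).
    """
    if responses is None:
        responses = tuple(c for c in esdr.columns if c != "unit_id")
    merged = metrics.merge(esdr, on="unit_id", validate="one_to_one")
    if len(merged) != len(labels):
        raise ValueError("labels length does not match unit tables")
    merged = merged.assign(_cluster=np.asarray(labels))
    rows = []
    for cl, grp in merged.groupby("_cluster", sort=True):
        for metric in config_metrics:
            for resp in responses:
                sub = grp[[metric, resp]].dropna()
                x = sub[metric].to_numpy(dtype=float)
                y = sub[resp].to_numpy(dtype=float)
                n = len(sub)
                if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                    rho, p = np.nan, np.nan
                else:
                    rho, p = spearman_test(x, y, seed=seed)
                rows.append({"cluster": cl, "metric": metric,
                             "response": resp, "n": n, "rho": rho, "p": p})
    out = pd.DataFrame(rows)

    # BH step-up over the full family of pairs with a defined p-value
    out["p_adj"] = np.nan
    defined = out["p"].notna()
    if defined.any():
        out.loc[defined, "p_adj"] = multipletests(
            out.loc[defined, "p"], alpha=alpha, method="fdr_bh"
        )[1]

    def _reason(r) -> str:
        if not np.isfinite(r["p"]):
            return "undefined"
        if r["n"] < n_min:
            return "small_n"
        if r["p_adj"] >= alpha:
            return "fdr_fail"
        if abs(r["rho"]) < rho_min:
            return "weak_rho"
        return "pass"

    out["reason"] = out.apply(_reason, axis=1)
    out["passed"] = out["reason"] == "pass"
    return out
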