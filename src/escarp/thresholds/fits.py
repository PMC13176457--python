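"""Triple candidate fits to a boundary series.

Three model families are fitted in parallel to the upper-boundary
points: a quadratic polynomial (vertex threshold), a continuous
single-breakpoint segmented regression (breakpoint threshold), and a
penalized cubic regression spline GAM (threshold from the fitted
derivative).  All three report a Gaussian working log-likelihood and a
BIC of ``n_params * ln(n) - 2 * logLik`` so model selection can compare
them on one scale; complexity enters as 3 (quadratic), 4 (segmented)
and the effective degrees of freedom (GAM).

A candidate's threshold is *valid* only if it lies in the observation-
supported range and the family's key parameter passes its significance
rule at the 0.05 level: a t-test of the quadratic term; seeded
residual-permutation tests (against the straight-line null) for the
searched families — the slope change at an estimated breakpoint and the
GCV-chosen smooth, where naive conditional tests are anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

from .boundary import BoundarySeries

_SSE_FLOOR = 1e-30


def _scale_floor(y: np.ndarray) -> float:
    """SSE below numerical resolution of the response scale.

    Gaussian log-likelihoods diverge as SSE -> 0, so fits whose residuals
    are pure floating-point noise are clamped to a common floor; their
    BICs then differ only in complexity and parsimony resolves the tie.
    """
    n = len(y)
    return n * (1e-8 * max(float(np.ptp(y)), 1e-300)) ** 2


def gaussian_loglik(sse: float, n: int, floor: float = _SSE_FLOOR) -> float:
    sse = max(sse, floor, _SSE_FLOOR)
    return -0.5 * n * (np.log(2.0 * np.pi * sse / n) + 1.0)


def bic_from_sse(sse: float, n: int, n_params: float,
                 floor: float = _SSE_FLOOR) -> float:
    return n_params * np.log(n) - 2.0 * gaussian_loglik(sse, n, floor)


@dataclass
class CandidateFit:
    family: str                      # quadratic | segmented | gam
    params: dict
    loglik: float
    n_params: float
    bic: float
    threshold: float | None
    in_range: bool
    significant: bool
    notes: str = ""
    ok: bool = True                  # fit itself succeeded

    @property
    def valid(self) -> bool:
        return (self.ok and self.threshold is not None
                and self.in_range and self.significant)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family == "quadratic":
            return p["b0"] + p["b1"] * x + p["b2"] * x * x
        if self.family == "segmented":
            return (p["b0"] + p["b1"] * x
                    + p["b2"] * np.maximum(x - p["psi"], 0.0))
        if self.family == "gam":
            return BSpline(np.asarray(p["knots"]), np.asarray(p["coefs"]),
                           3, extrapolate=True)(x)
        raise ValueError(self.family)


def _ols(X: np.ndarray, y: np.ndarray, with_stats: bool = True):
    """Least squares; classical t-tests unless ``with_stats=False``.

    Returns (beta, sse, se, pvals) or None if the design is singular.
    """
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        return None
    resid = y - X @ beta
    sse = float(resid @ resid)
    if not with_stats or n <= p:
        nan = np.full(p, np.nan)
        return beta, sse, nan, nan
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sse / (n - p), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - p)
    return beta, sse, se, pvals


def _hinge_sse_grid(x: np.ndarray, y: np.ndarray,
                    psis: np.ndarray) -> np.ndarray:
    """SSE of y ~ 1 + x + (x - psi)+ for every candidate psi, batched."""
    n = len(x)
    h = np.maximum(x[None, :] - psis[:, None], 0.0)
    sx, sxx = x.sum(), float(x @ x)
    sy, sxy, syy = y.sum(), float(x @ y), float(y @ y)
    sh = h.sum(axis=1)
    shh = np.einsum("ij,ij->i", h, h)
    sxh = h @ x
    shy = h @ y
    m = len(psis)
    A = np.empty((m, 3, 3))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = sx
    A[:, 0, 2] = A[:, 2, 0] = sh
    A[:, 1, 1] = sxx
    A[:, 1, 2] = A[:, 2, 1] = sxh
    A[:, 2, 2] = shh
    b = np.empty((m, 3))
    b[:, 0] = sy
    b[:, 1] = sxy
    b[:, 2] = shy
    scale = np.abs(A).max(axis=(1, 2)) ** 3
    det = np.linalg.det(A)
    good = np.abs(det) > 1e-12 * np.maximum(scale, 1e-300)
    sse = np.full(m, np.inf)
    if good.any():
        beta = np.linalg.solve(A[good], b[good][:, :, None])[:, :, 0]
        sse[good] = np.maximum(
            syy - np.einsum("ij,ij->i", beta, b[good]), 0.0
        )
    return sse


def fit_quadratic(series: BoundarySeries) -> CandidateFit:
    """OLS parabola; threshold at the vertex -b1 / (2 b2)."""
    x, y = series.x, series.y
    n = len(x)
    if n < 5:
        raise ValueError("quadratic fit needs >= 5 boundary points")
    floor = _scale_floor(y)
    X = np.column_stack([np.ones(n), x, x * x])
    res = _ols(X, y)
    if res is None:
        return CandidateFit("quadratic", {}, -np.inf, 3, np.inf, None,
                            False, False, notes="singular design", ok=False)
    beta, sse, _, pvals = res
    b0, b1, b2 = beta
    vertex = float(-b1 / (2.0 * b2)) if b2 != 0 else None
    xmin, xmax = series.x_range
    in_range = vertex is not None and xmin <= vertex <= xmax
    significant = bool(np.isfinite(pvals[2]) and pvals[2] < 0.05)
    return CandidateFit(
        family="quadratic",
        params={"b0": float(b0), "b1": float(b1), "b2": float(b2),
                "p_b2": float(pvals[2]), "sse": sse},
        loglik=gaussian_loglik(sse, n, floor), n_params=3,
        bic=bic_from_sse(sse, n, 3, floor),
        threshold=vertex, in_range=in_range, significant=significant,
    )


def _segmented_permutation_p(x: np.ndarray, y: np.ndarray,
                             grid: np.ndarray, sse_seg: float,
                             n_perm: int = 199) -> float:
    """Permutation p-value for the slope change at a *searched* breakpoint.

    A t-test of the hinge coefficient at the SSE-minimizing breakpoint is
    anti-conservative (the breakpoint is estimated from the same data —
    Davies' problem), so significance is judged against a sup-F null:
    residuals of the straight-line fit are permuted (seeded, hence
    deterministic for fixed data), the grid search is re-run on each
    permuted sample, and the observed variance reduction of the best
    hinge over the line is compared with its null distribution.
    """
    n = len(x)
    X1 = np.column_stack([np.ones(n), x])
    res_lin = _ols(X1, y, with_stats=False)
    if res_lin is None:
        return np.nan
    beta_lin, sse_lin, _, _ = res_lin
    if sse_lin <= _SSE_FLOOR:
        return 1.0
    fitted = X1 @ beta_lin
    resid = y - fitted
    stat_obs = (sse_lin - sse_seg) / sse_lin
    rng = np.random.default_rng(12345)  # fixed seed: pure in the data
    Y = fitted[None, :] + rng.permuted(
        np.tile(resid, (n_perm, 1)), axis=1
    )
    syy = np.einsum("ij,ij->i", Y, Y)
    Q1, _ = np.linalg.qr(X1)
    p1 = Y @ Q1
    sse0 = syy - np.einsum("ij,ij->i", p1, p1)
    best_drop = np.full(n_perm, -np.inf)
    for psi in grid:
        X = np.column_stack([X1, np.maximum(x - psi, 0.0)])
        Q, _ = np.linalg.qr(X)
        pr = Y @ Q
        sse1 = syy - np.einsum("ij,ij->i", pr, pr)
        np.maximum(best_drop, sse0 - sse1, out=best_drop)
    stat_null = best_drop / np.maximum(sse0, _SSE_FLOOR)
    hits = int((stat_null >= stat_obs - 1e-12).sum())
    return (1 + hits) / (n_perm + 1)


def fit_segmented(series: BoundarySeries, n_grid: int = 100,
                  tol: float = 1e-6, max_iter: int = 50) -> CandidateFit:
    """Continuous two-segment linear model y = b0 + b1 x + b2 (x - psi)+.

    The breakpoint is located by exhaustive SSE search over ``n_grid``
    candidates spanning the inner 80% of the x-range, then refined by
    the iterative-linearization update ``psi <- psi + gamma / b2``.  On
    non-convergence the grid optimum is kept (flagged).  The slope
    change is tested against the straight-line null by a seeded
    residual-permutation sup-F test (see
    :func:`_segmented_permutation_p`), which stays calibrated despite
    the breakpoint search.
    """
    x, y = series.x, series.y
    n = len(x)
    if n < 6:
        raise ValueError("segmented fit needs >= 6 boundary points")
    xmin, xmax = series.x_range
    rng_x = xmax - xmin
    floor = _scale_floor(y)
    grid = np.linspace(xmin + 0.1 * rng_x, xmin + 0.9 * rng_x, n_grid)
    sses = _hinge_sse_grid(x, y, grid)
    sse_grid_min = float(sses.min())
    psi = float(grid[int(np.argmin(sses))])

    notes = ""
    converged = False
    cur = psi
    for _ in range(max_iter):
        U = np.maximum(x - cur, 0.0)
        V = -(x > cur).astype(float)
        res = _ols(np.column_stack([np.ones(n), x, U, V]), y,
                   with_stats=False)
        if res is None:
            break
        beta = res[0]
        b2, gamma = beta[2], beta[3]
        if b2 == 0:
            break
        new = cur + gamma / b2
        if not (xmin < new < xmax):
            break
        if abs(new - cur) < tol * max(rng_x, 1.0):
            cur = new
            converged = True
            break
        cur = new
    if converged and _hinge_sse_grid(x, y, np.array([cur, psi]))[0] <= \
            sses.min():
        psi = cur
    else:
        notes = "refinement did not converge; grid optimum kept"

    X = np.column_stack([np.ones(n), x, np.maximum(x - psi, 0.0)])
    res = _ols(X, y)
    if res is None:
        return CandidateFit("segmented", {}, -np.inf, 4, np.inf, None,
                            False, False, notes="singular design", ok=False)
    beta, sse, _, _ = res
    # test statistic uses the grid-only optimum so observed and permuted
    # samples undergo the identical search (exchangeability)
    p_change = _segmented_permutation_p(x, y, grid, sse_grid_min)
    inner_lo = xmin + 0.05 * rng_x
    inner_hi = xmax - 0.05 * rng_x
    return CandidateFit(
        family="segmented",
        params={"b0": float(beta[0]), "b1": float(beta[1]),
                "b2": float(beta[2]), "psi": psi,
                "p_slope_change": float(p_change), "sse": sse},
        loglik=gaussian_loglik(sse, n, floor), n_params=4,
        bic=bic_from_sse(sse, n, 4, floor),
        threshold=psi,
        in_range=bool(inner_lo <= psi <= inner_hi),
        significant=bool(np.isfinite(p_change) and p_change < 0.05),
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Penalized cubic regression spline GAM


def _bspline_knots(xmin: float, xmax: float, q: int) -> np.ndarray:
    """Open cubic knot vector giving q basis functions on [xmin, xmax]."""
    n_interior = q - 4
    interior = np.linspace(xmin, xmax, n_interior + 2)[1:-1]
    return np.concatenate([[xmin] * 4, interior, [xmax] * 4])


def _curvature_penalty(knots: np.ndarray, q: int) -> np.ndarray:
    """Integrated squared-second-derivative penalty matrix.

    P[i, j] = int B_i'' B_j'' dx over the knot span.  Second derivatives
    of cubic B-splines are piecewise linear, so 2-point Gauss-Legendre
    per knot interval is exact.  Linear functions lie in the null space:
    an infinitely smoothed fit is exactly the straight line.
    """
    uniq = np.unique(knots)
    # Gauss-Legendre nodes/weights on [-1, 1]
    g = 1.0 / np.sqrt(3.0)
    P = np.zeros((q, q))
    eye = np.eye(q)
    for a, b in zip(uniq[:-1], uniq[1:]):
        half = (b - a) / 2.0
        mid = (a + b) / 2.0
        pts = np.array([mid - half * g, mid + half * g])
        D = np.column_stack([
            BSpline(knots, eye[i], 3).derivative(2)(pts) for i in range(q)
        ])  # (2, q)
        P += half * D.T @ D  # both Gauss weights are 1
    return P


_LAMBDA_GRID = np.logspace(-6.0, 8.0, 29)


def fit_gam(series: BoundarySeries, deriv_grid: int = 200) -> CandidateFit:
    """Penalized cubic regression spline with GCV smoothing.

    Basis dimension ``min(8, n - 2)``; integrated squared-second-
    derivative (curvature) penalty, so straight lines are penalty-free;
    smoothing parameter minimizes ``GCV = n * SSE / (n - edf)^2`` over a
    log-spaced grid (ties resolved toward the smoother fit); edf is the
    trace of the hat matrix and acts as the parameter count in BIC.
    Smooth-term significance comes from a seeded residual-permutation
    test against the straight-line null.

    Threshold rule: evaluate the fitted first derivative on a 200-point
    grid.  If it changes sign, the threshold is the sign-change location
    with the largest |second derivative|; if the fit is monotone, the
    threshold is argmax |f''| provided max |f''| exceeds twice its grid
    median (curvature-prominence gate), else no threshold.  An
    essentially linear smoother (edf <= 1.1) yields no threshold.
    """
    x, y = series.x, series.y
    n = len(x)
    if n < 8:
        raise ValueError("GAM fit needs >= 8 boundary points")
    xmin, xmax = series.x_range
    q = min(8, n - 2)
    knots = _bspline_knots(xmin, xmax, q)
    B = BSpline.design_matrix(x, knots, 3).toarray()
    P = _curvature_penalty(knots, q)
    # make the lambda grid scale-free in x
    P = P / max(np.trace(P), 1e-300) * np.trace(B.T @ B)
    BtB = B.T @ B
    Bty = B.T @ y

    floor = _scale_floor(y)
    hats, edfs, lams = [], [], []
    for lam in _LAMBDA_GRID[::-1]:  # descending: ties prefer smoother
        A = BtB + lam * P
        try:
            M = np.linalg.solve(A, np.column_stack([BtB, Bty]))
        except np.linalg.LinAlgError:
            continue
        edf = float(np.trace(M[:, :q]))
        if edf >= n:
            continue
        hats.append(B @ np.linalg.solve(A, B.T))
        edfs.append(edf)
        lams.append(lam)
    if not hats:
        return CandidateFit("gam", {}, -np.inf, np.nan, np.inf, None,
                            False, False, notes="smoother failed", ok=False)

    def gcv_pick(yy: np.ndarray) -> tuple[int, float]:
        """Index of the GCV-minimizing lambda and its SSE for one sample."""
        best_j, best_gcv, best_sse = 0, np.inf, np.inf
        for j, (H, edf) in enumerate(zip(hats, edfs)):
            r = yy - H @ yy
            sse = max(float(r @ r), floor)
            gcv = n * sse / (n - edf) ** 2
            if gcv < best_gcv:
                best_j, best_gcv, best_sse = j, gcv, sse
        return best_j, best_sse

    jbest, sse = gcv_pick(y)
    lam, edf = lams[jbest], edfs[jbest]
    coefs = np.linalg.solve(BtB + lam * P, Bty)

    # smooth-term significance: residual-permutation test against the
    # line null (the GCV search makes a conditional F-test
    # anti-conservative, same as the searched breakpoint)
    res_lin = _ols(np.column_stack([np.ones(n), x]), y, with_stats=False)
    if res_lin is None or res_lin[1] <= _SSE_FLOOR:
        p_smooth = 1.0
    else:
        beta_lin, sse_lin = res_lin[0], res_lin[1]
        fitted = np.column_stack([np.ones(n), x]) @ beta_lin
        resid_lin = y - fitted
        stat_obs = (sse_lin - sse) / sse_lin
        rng = np.random.default_rng(54321)  # fixed seed: pure in the data
        n_perm = 199
        Y = fitted[None, :] + rng.permuted(
            np.tile(resid_lin, (n_perm, 1)), axis=1)
        X1 = np.column_stack([np.ones(n), x])
        Q1, _ = np.linalg.qr(X1)
        syy = np.einsum("ij,ij->i", Y, Y)
        p1 = Y @ Q1
        sse0 = syy - np.einsum("ij,ij->i", p1, p1)
        sse_gam0 = np.full(n_perm, np.inf)
        gcv0 = np.full(n_perm, np.inf)
        for H, edf_j in zip(hats, edfs):
            R = Y - Y @ H.T
            ssej = np.einsum("ij,ij->i", R, R)
            gcvj = n * ssej / (n - edf_j) ** 2
            take = gcvj < gcv0
            gcv0[take] = gcvj[take]
            sse_gam0[take] = ssej[take]
        stat_null = (sse0 - sse_gam0) / np.maximum(sse0, _SSE_FLOOR)
        hits = int((stat_null >= stat_obs - 1e-12).sum())
        p_smooth = (1 + hits) / (n_perm + 1)

    spl = BSpline(knots, coefs, 3, extrapolate=True)
    grid = np.linspace(xmin, xmax, deriv_grid)
    d1 = spl.derivative(1)(grid)
    d2 = spl.derivative(2)(grid)

    threshold = None
    notes = ""
    # curvature below numerical resolution of the response scale carries
    # no threshold information (e.g. an exactly linear series)
    curv_scale = np.abs(spl.derivative(2)(grid)).max() * (xmax - xmin) ** 2
    if edf <= 1.1:
        notes = "smoother degenerated to linear"
    elif curv_scale < 1e-8 * max(np.ptp(y), 1e-30):
        notes = "negligible curvature"
    else:
        sign_changes = np.nonzero(np.diff(np.sign(d1)) != 0)[0]
        if len(sign_changes):
            # root of f' between grid[i] and grid[i+1], largest curvature
            locs, curvs = [], []
            for i in sign_changes:
                if d1[i + 1] != d1[i]:
                    frac = d1[i] / (d1[i] - d1[i + 1])
                else:
                    frac = 0.5
                loc = grid[i] + frac * (grid[i + 1] - grid[i])
                locs.append(loc)
                curvs.append(abs(spl.derivative(2)(loc)))
            threshold = float(locs[int(np.argmax(curvs))])
        else:
            abs_d2 = np.abs(d2)
            if abs_d2.max() > 2.0 * np.median(abs_d2):
                threshold = float(grid[int(np.argmax(abs_d2))])
            else:
                notes = "monotone fit without curvature prominence"

    return CandidateFit(
        family="gam",
        params={"knots": knots.tolist(), "coefs": coefs.tolist(),
                "lambda": float(lam), "edf": edf,
                "p_smooth": p_smooth, "sse": sse},
        loglik=gaussian_loglik(sse, n, floor), n_params=edf,
        bic=bic_from_sse(sse, n, edf, floor),
        threshold=threshold,
        in_range=threshold is not None and xmin <= threshold <= xmax,
        significant=bool(p_smooth < 0.05 and edf > 1.5),
        notes=notes,
    )
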