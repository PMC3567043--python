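"""Ordinary and segmented (one-breakpoint) logistic regression.

The threshold model for an occupancy dynamic is a piecewise ("broken-stick")
logistic regression of a binary outcome y on percent forest cover x:

    logit p(x) = b0 + b1·x + b2·max(0, x − ψ)

with breakpoint ψ estimated jointly with the coefficients.  Estimation uses
the classic iterative linearization for segmented GLMs: at a working
breakpoint ψ the model is refit with the extra regressors

    U = max(0, x − ψ)           (slope change above ψ)
    V = −1[x > ψ]               (first-order correction term)

and the breakpoint updated by ψ ← ψ + β_V / β_U until the update is below
tolerance.  At convergence β_V ≈ 0 and the delta-method standard error of
the breakpoint is SE(ψ) = SE(β_V) / |β_U|.

The inner maximum-likelihood logistic fits run a small dedicated IRLS whose
residual, weight and log-likelihood formulas are written sign-symmetrically,
so fitting on the complementary outcome 1 − y reproduces the breakpoint and
its standard error *exactly* (bit-for-bit) with all slopes negated — a
structural identity of the model that the implementation preserves rather
than approximates.

A profile-likelihood grid evaluator (`profile_psi_oracle`) provides an
independent route to the same maximum for validation: for each fixed ψ on a
grid it fits the logistic model with regressors {x, U(ψ)} and records the
log-likelihood.

Non-convergence is treated as data, not as an exception: real atlas species
that persist in (nearly) all blocks genuinely yield no finite MLE or no
converged breakpoint, and downstream reports must be able to say so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import DegenerateResponseError, InvalidInitializerError, ValidationError

__all__ = [
    "LogisticFit",
    "SegmentedFit",
    "SegmentedFailure",
    "fit_logistic",
    "loess_initial_psi",
    "fit_segmented",
    "fit_segmented_grid",
    "profile_psi_oracle",
]

# Convergence defaults: breakpoint update below 1e-4 % cover, IRLS relative
# log-likelihood change below 1e-10, at most 50 breakpoint iterations.
PSI_TOL = 1e-4
IRLS_TOL = 1e-10
MAX_PSI_ITER = 50
MAX_IRLS_ITER = 100


@dataclass
class LogisticFit:
    """Ordinary logistic regression fit (two parameters, AIC = −2ℓ + 4)."""

    intercept: float
    slope: float
    loglik: float
    aic: float
    converged: bool
    fitted: np.ndarray


@dataclass
class SegmentedFit:
    """Segmented logistic fit (four parameters incl. ψ, AIC = −2ℓ + 8)."""

    intercept: float
    slope_below: float
    slope_change: float
    psi: float
    psi_se: float
    loglik: float
    aic: float
    converged: bool
    n_iter: int
    fitted: np.ndarray


@dataclass
class SegmentedFailure:
    """No converged segmented fit could be obtained for this dataset."""

    reason: str
    n_starts_tried: int = 0


# ---------------------------------------------------------------------------
# Sign-symmetric IRLS core
# ---------------------------------------------------------------------------

def _loglik(s_eta: np.ndarray) -> float:
    # s = 2y-1; per-point loglik = -log(1 + exp(-s*eta)), stable and exactly
    # invariant under (y, eta) -> (1-y, -eta)
    return float(-np.logaddexp(0.0, -s_eta).sum())


def _irls(X: np.ndarray, y: np.ndarray,
          tol: float = IRLS_TOL, max_iter: int = MAX_IRLS_ITER):
    """Logistic IRLS returning (beta, cov, loglik, converged, mu).

    Residuals are computed as expit(−η) for y=1 and −expit(η) for y=0, and
    weights as expit(η)·expit(−η), so that the iteration commutes exactly
    with the complement map y → 1−y, β → −β.
    """
    n, p = X.shape
    y = np.asarray(y, dtype=float)
    s = 2.0 * y - 1.0
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        eta_c = np.clip(eta, -30.0, 30.0)
        mu_pos = expit(eta_c)       # P(y=1)
        mu_neg = expit(-eta_c)      # P(y=0), not 1-mu_pos bitwise
        w = mu_pos * mu_neg
        resid = np.where(y == 1.0, mu_neg, -mu_pos)
        z = eta_c + resid / w
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            return beta, None, _loglik(s * eta_c), False, mu_pos
        # likelihood on the clipped predictor: under (quasi-)separation the
        # unclipped likelihood creeps forever as coefficients diverge, while
        # the clipped one plateaus and the fit is declared converged with
        # finite estimates
        ll = _loglik(np.clip(s * (X @ beta_new), -30.0, 30.0))
        if not np.isfinite(ll):
            return beta, None, _loglik(s * eta_c), False, mu_pos
        beta = beta_new
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu_pos = expit(eta)
    w = mu_pos * expit(-eta)
    try:
        cov = np.linalg.inv((X.T * w) @ X)
    except np.linalg.LinAlgError:
        cov = None
    return beta, cov, _loglik(np.clip(s * (X @ beta), -30.0, 30.0)), converged, mu_pos


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.shape != x.shape:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValidationError("need at least 2 observations")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("y must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateResponseError(
            "response is constant (all 0 or all 1); no finite logistic MLE"
        )
    return x, y


def fit_logistic(x, y) -> LogisticFit:
    """Maximum-likelihood ordinary logistic regression of y on x.

    Raises
    ------
    DegenerateResponseError
        If y is constant — e.g. a species persistent in every block.
    """
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0.0:
        # no-information covariate: slope 0, intercept = logit(mean y)
        pbar = float(y.mean())
        mu = np.full_like(y, pbar)
        ll = float(np.sum(y * np.log(pbar) + (1 - y) * np.log1p(-pbar)))
        return LogisticFit(
            intercept=float(np.log(pbar / (1 - pbar))), slope=0.0,
            loglik=ll, aic=-2.0 * ll + 4.0, converged=True, fitted=mu,
        )
    X = np.column_stack([np.ones_like(x), x])
    beta, _, ll, converged, mu = _irls(X, y)
    return LogisticFit(
        intercept=float(beta[0]), slope=float(beta[1]),
        loglik=ll, aic=-2.0 * ll + 4.0, converged=converged, fitted=mu,
    )


# ---------------------------------------------------------------------------
# Loess initializer
# ---------------------------------------------------------------------------

def loess_smooth(x, y, grid, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Loess (locally weighted polynomial) smooth evaluated on a grid.

    Local polynomial of the given degree with tricube weights over the
    nearest ``span`` fraction of points — the classic loess used to
    visualise occupancy–cover relationships.  Degree 2 (local quadratic)
    tracks the inflection of a sigmoidal response far better than a local
    line, which matters because the smooth's steepest point seeds the
    breakpoint search.  No robustifying iterations: on a 0/1 response they
    can down-weight every observation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n = x.size
    k = max(int(np.ceil(span * n)), degree + 1)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(grid.shape)
    for j, g in enumerate(grid):
        d = np.abs(xs - g)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0.0:
            h = max(d.max(), 1e-12)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        mask = w > 0
        xm, ym, wm = xs[mask] - g, ys[mask], w[mask]
        deg = min(degree, max(np.unique(xm).size - 1, 0))
        X = np.vander(xm, deg + 1, increasing=True)
        XtW = X.T * wm
        try:
            coef = np.linalg.solve(XtW @ X, XtW @ ym)
        except np.linalg.LinAlgError:
            coef = [np.average(ym, weights=wm)]
        out[j] = coef[0]  # polynomial evaluated at the grid point itself
    return out


def loess_initial_psi(x, y, span: float = 0.75) -> float:
    """Breakpoint initializer from a loess smooth of y on x.

    Smooths the 0/1 outcome on cover with the given span (local quadratic,
    tricube weights), then returns the cover value at the steepest point of
    the smooth (maximum absolute finite-difference slope on an even grid),
    clamped strictly inside the observed range.  With fewer than 10 points
    the smooth is unreliable and the median of x is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        warnings.warn("fewer than 10 observations; falling back to median(x)")
        return float(np.median(x))
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return lo
    xg = np.linspace(lo, hi, 101)
    yg = loess_smooth(x, y, xg, span=span, degree=2)
    slopes = np.diff(yg) / np.diff(xg)
    mids = 0.5 * (xg[:-1] + xg[1:])
    # confine the search to the interior quantile range: at the data edges
    # the smooth's derivative is boundary noise, and an edge initializer
    # sends the breakpoint search into sparse tails it can only overfit
    q_lo, q_hi = np.quantile(x, [0.05, 0.95])
    interior = (mids >= q_lo) & (mids <= q_hi)
    if interior.any():
        slopes = np.where(interior, slopes, 0.0)
    i = int(np.argmax(np.abs(slopes)))
    candidate = mids[i]
    eps = 1e-3 * (hi - lo)
    return float(np.clip(candidate, lo + eps, hi - eps))


# ---------------------------------------------------------------------------
# Segmented fit
# ---------------------------------------------------------------------------

def _refit_at_psi(x: np.ndarray, y: np.ndarray, psi: float):
    """Fit the logistic model with regressors {x, max(0, x−ψ)} (ψ fixed)."""
    U = np.maximum(0.0, x - psi)
    X = np.column_stack([np.ones_like(x), x, U])
    return _irls(X, y)


def _polish_psi(x: np.ndarray, y: np.ndarray, psi: float,
                window: float = 5.0) -> float:
    """Local profile-likelihood refinement of a converged breakpoint.

    The profile log-likelihood in ψ is smooth between data points but has
    kinks at them, so the linearization can stall a few percent cover from
    the local profile optimum (its update direction is noise near
    saturated regions).  A two-stage scan (0.25 %-cover grid over
    ±``window`` with a monotone outward march when the winner sits at the
    window edge, then a 0.02 grid and a bounded Brent step around the
    winner) repairs this.  The window is deliberately local: the estimator
    refines the breakpoint the iteration converged to — a whole-range scan
    would turn the fit into a global profile maximiser, which on data with
    no true threshold cherry-picks the best chance kink and overstates the
    evidence for a breakpoint.  Global starts are the job of the
    grid-multistart wrapper.  All evaluations use the same sign-symmetric
    inner fit, preserving exact complement symmetry.
    """
    from scipy.optimize import minimize_scalar

    lo, hi = float(x.min()), float(x.max())
    margin = 1e-3 * (hi - lo)

    def profile(p: float) -> float:
        _, _, ll, ok, _ = _refit_at_psi(x, y, float(p))
        # large finite penalty rather than -inf: keeps Brent arithmetic finite
        return ll if ok and np.isfinite(ll) else -1e300

    best_psi, best_ll = psi, profile(psi)
    coarse_step = 0.25
    grid = np.arange(psi - window, psi + window + coarse_step / 2, coarse_step)
    grid = grid[(grid > lo + margin) & (grid < hi - margin)]
    coarse_ll = np.array([profile(float(p)) for p in grid])
    if grid.size and np.nanmax(coarse_ll) > best_ll:
        best_psi = float(grid[int(np.nanargmax(coarse_ll))])
        best_ll = float(np.nanmax(coarse_ll))
    # if the winner sits at the window edge the optimum may lie just
    # beyond it: march outward while the profile keeps improving — a
    # contiguous ascent, not a jump to a distant chance kink
    if grid.size and (best_psi <= grid[0] + coarse_step / 2
                      or best_psi >= grid[-1] - coarse_step / 2):
        direction = -1.0 if best_psi <= grid[0] + coarse_step / 2 else 1.0
        for _ in range(60):
            trial = best_psi + direction * coarse_step
            if not lo + margin < trial < hi - margin:
                break
            ll = profile(float(trial))
            if ll <= best_ll:
                break
            best_ll, best_psi = ll, float(trial)
    # fine scan around the leading coarse candidates, not just the winner:
    # a profile spike narrower than the coarse spacing can hide next to a
    # runner-up grid point
    centres = [best_psi]
    if grid.size:
        order = np.argsort(coarse_ll)[::-1]
        centres += [float(grid[k]) for k in order[:3]]
    for centre in centres:
        fine = np.arange(centre - 0.3, centre + 0.3 + 0.01, 0.02)
        fine = fine[(fine > lo + margin) & (fine < hi - margin)]
        for p in fine:
            ll = profile(float(p))
            if ll > best_ll:
                best_ll, best_psi = ll, float(p)
    # walk uphill at fine resolution so the returned breakpoint is a local
    # maximum even when the profile peak falls just outside a fine window
    for direction in (-1.0, 1.0):
        while True:
            trial = best_psi + direction * 0.02
            if not lo + margin < trial < hi - margin:
                break
            ll = profile(float(trial))
            if ll <= best_ll:
                break
            best_ll, best_psi = ll, float(trial)

    res = minimize_scalar(
        lambda p: -profile(p), bounds=(best_psi - 0.02, best_psi + 0.02),
        method="bounded", options={"xatol": 1e-6},
    )
    if np.isfinite(res.fun) and -res.fun > best_ll:
        best_psi = float(np.clip(res.x, lo + margin, hi - margin))
    return best_psi


def fit_segmented(
    x, y, psi0: float,
    psi_tol: float = PSI_TOL, max_iter: int = MAX_PSI_ITER,
) -> SegmentedFit:
    """Segmented logistic regression from a single breakpoint initializer.

    Runs the iterative linearization described in the module docstring.
    Non-convergence (oscillation, breakpoint repeatedly pushed to the data
    edge, inner-fit failure) is returned as ``converged=False``, not raised.

    Raises
    ------
    InvalidInitializerError
        If ``psi0`` is not strictly inside the observed range of x.
    DegenerateResponseError
        If y is constant.
    """
    x, y = _check_xy(x, y)
    lo, hi = float(x.min()), float(x.max())
    if not lo < psi0 < hi:
        raise InvalidInitializerError(
            f"psi0={psi0} outside the observed cover range ({lo}, {hi})"
        )
    span = hi - lo
    margin = 1e-3 * span
    psi = float(psi0)
    psi_se = np.nan
    n_iter = 0
    converged = False
    _, _, ll_cur, ok0, _ = _refit_at_psi(x, y, psi)
    if not ok0:
        ll_cur = -np.inf
    for n_iter in range(1, max_iter + 1):
        U = np.maximum(0.0, x - psi)
        V = -(x > psi).astype(float)
        X = np.column_stack([np.ones_like(x), x, U, V])
        beta, cov, _, ok, _ = _irls(X, y)
        if not ok or cov is None:
            return SegmentedFit(
                intercept=np.nan, slope_below=np.nan, slope_change=np.nan,
                psi=psi, psi_se=np.nan, loglik=np.nan, aic=np.nan,
                converged=False, n_iter=n_iter, fitted=np.empty(0),
            )
        b_u, b_v = beta[2], beta[3]
        if b_u == 0.0 or not np.isfinite(b_u) or not np.isfinite(b_v):
            break
        step = b_v / b_u
        if abs(step) < psi_tol:
            converged = True
            break
        # trust region: the linearization is a first-order local
        # approximation, so updates beyond a few percent cover are
        # extrapolation noise; capping them keeps the estimator local
        # instead of letting the halving probes sweep the whole range
        step = float(np.clip(step, -5.0, 5.0))
        # step-halving: the raw update oscillates between the piecewise
        # intervals of the profile likelihood near the optimum, so damp it
        # until the profile log-likelihood does not deteriorate
        cand, ll_new = psi, ll_cur
        h = 1.0
        for _ in range(8):
            trial = float(np.clip(psi + h * step, lo + margin, hi - margin))
            _, _, ll_t, ok_t, _ = _refit_at_psi(x, y, trial)
            if ok_t and ll_t >= ll_cur - 1e-12:
                cand, ll_new = trial, ll_t
                break
            h *= 0.5
        if abs(cand - psi) < psi_tol:
            psi = cand
            converged = True
            break
        if ll_new <= ll_cur + 1e-9:
            # profile likelihood has stabilised: accept as converged
            psi = cand if ll_new > ll_cur else psi
            converged = True
            break
        psi, ll_cur = cand, ll_new
    if converged:
        psi = _polish_psi(x, y, psi)
        # delta-method SE from the linearized fit at the final breakpoint
        U = np.maximum(0.0, x - psi)
        V = -(x > psi).astype(float)
        X = np.column_stack([np.ones_like(x), x, U, V])
        beta, cov, _, ok, _ = _irls(X, y)
        if ok and cov is not None and beta[2] != 0.0:
            psi_se = float(np.sqrt(max(cov[3, 3], 0.0))) / abs(float(beta[2]))
        else:
            psi_se = np.nan
    # final coefficients and likelihood at the estimated breakpoint (no V)
    beta2, _, ll, ok2, mu = _refit_at_psi(x, y, psi)
    if not ok2:
        converged = False
    return SegmentedFit(
        intercept=float(beta2[0]), slope_below=float(beta2[1]),
        slope_change=float(beta2[2]), psi=psi, psi_se=float(psi_se),
        loglik=ll, aic=-2.0 * ll + 8.0, converged=converged,
        n_iter=n_iter, fitted=mu,
    )


def fit_segmented_grid(x, y, step: float = 5.0) -> SegmentedFit | SegmentedFailure:
    """Segmented fit with a loess start and a 5 %-step grid-search fallback.

    Tries the loess-based initializer first; if that start does not
    converge, retries from every initial value 5, 10, …, 95 % cover
    (clamped to the observed range) and returns the converged fit with the
    highest log-likelihood.  If no start converges a `SegmentedFailure` is
    returned, mirroring species for which no threshold model converges.
    """
    x = np.asarray(x, dtype=float)
    first = fit_segmented(x, y, loess_initial_psi(x, y))
    if first.converged:
        return first
    lo, hi = float(x.min()), float(x.max())
    margin = 1e-3 * (hi - lo) if hi > lo else 0.0
    starts = []
    for p in np.arange(step, 100.0, step):
        p_cl = float(np.clip(p, lo + 2 * margin, hi - 2 * margin))
        if lo < p_cl < hi and all(abs(p_cl - q) > 1e-9 for q in starts):
            starts.append(p_cl)
    best: SegmentedFit | None = None
    tried = 1
    for p0 in starts:
        tried += 1
        fit = fit_segmented(x, y, p0)
        if fit.converged and (best is None or fit.loglik > best.loglik):
            best = fit
    if best is None:
        return SegmentedFailure(reason="no start converged", n_starts_tried=tried)
    return best


def profile_psi_oracle(x, y, grid) -> tuple[float, np.ndarray]:
    """Profile log-likelihood of the breakpoint over a fixed grid.

    For each ψ in ``grid`` (restricted to the open data range) fits the
    logistic model with regressors {x, max(0, x−ψ)} and records the
    log-likelihood.  Returns the argmax ψ (ties → lowest) and the curve,
    aligned with the input grid (NaN where ψ falls outside the data range
    or the inner fit fails).
    """
    x, y = _check_xy(x, y)
    grid = np.asarray(grid, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    curve = np.full(grid.shape, np.nan)
    for i, psi in enumerate(grid):
        if not lo < psi < hi:
            continue
        _, _, ll, ok, _ = _refit_at_psi(x, y, float(psi))
        if ok:
            curve[i] = ll
    if np.all(np.isnan(curve)):
        raise ValidationError("no grid point lies inside the data range")
    best = float(grid[int(np.nanargmax(curve))])
    return best, curve
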