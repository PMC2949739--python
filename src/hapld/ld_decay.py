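"""LD-decay curves: drift–recombination expectation and spline smoother.

The parametric model is the Hill & Weir equilibrium approximation of E[r²]
as a function of the population-scaled recombination distance C = rho * d
between two sites, with a sample-size adjustment term:

    E[r²](C, n) = (10+C) / ((2+C)(11+C))
                  * [1 + (3+C)(12+12C+C²) / (n (2+C)(11+C))]

Its value at C=0 is a ceiling (~0.46-0.48 for typical n); datasets whose
observed r² sit above the ceiling cannot be fitted, which is reported as a
boundary/failed fit rather than raised.  The Sved form 1/(1+C) is available
as an alternative.  The nonparametric smoother is a penalized cubic
B-spline regression (P-spline) with the smoothing parameter chosen by
generalized cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline

from .errors import InsufficientDataError

RHO_GRID_MIN = 1e-6
RHO_GRID_MAX = 1.0


def expected_r2(C, n: int | None = None, model: str = "hill-weir"):
    """Expected r² at scaled recombination distance ``C`` for sample size n.

    ``n=None`` gives the large-sample limit (the adjustment term vanishes).
    Vectorized over ``C``; raises ``ValueError`` for negative C.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("scaled recombination distance C must be >= 0")
    if model == "sved":
        out = 1.0 / (1.0 + C)
    elif model == "hill-weir":
        base = (10.0 + C) / ((2.0 + C) * (11.0 + C))
        if n is None:
            out = base
        else:
            if n < 2:
                raise ValueError("sample size n must be >= 2")
            adj = ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (
                n * (2.0 + C) * (11.0 + C)
            )
            out = base * (1.0 + adj)
    else:
        raise ValueError(f"unknown decay model {model!r}")
    return out if out.ndim else float(out)


@dataclass
class DecayFit:
    """A fitted decay curve on a distance grid.

    ``status`` is one of ``converged`` (interior optimum), ``boundary``
    (optimum pinned at the rho search boundary — typical when observed LD
    exceeds the model ceiling), ``failed`` (optimizer failure) or ``ok``
    (nonparametric fit).  Non-convergence is a valid returned outcome, never
    an exception.
    """

    method: str  # "parametric" | "nonparametric"
    model: str | None
    rho_hat: float | None
    n_used: int | None
    grid: np.ndarray
    curve: np.ndarray
    converged: bool
    status: str
    failure_reason: str | None = None
    gcv_lambda: float | None = None
    edf: float | None = None


def _as_xy(pairs_or_d, r2=None):
    if r2 is None:
        d = np.array([p.distance for p in pairs_or_d], dtype=float)
        y = np.array([p.r2 for p in pairs_or_d], dtype=float)
    else:
        d = np.asarray(pairs_or_d, dtype=float)
        y = np.asarray(r2, dtype=float)
    return d, y


def fit_parametric_decay(
    pairs_or_distances,
    r2=None,
    *,
    n: int,
    model: str = "hill-weir",
    grid: np.ndarray | None = None,
) -> DecayFit:
    """Least-squares fit of rho in E[r²](rho*d, n) to observed (d, r²).

    Accepts either a list of :class:`~hapld.ld_pairwise.PairwiseLD` or two
    arrays of distances and r² values.  A coarse log-grid scan over
    rho in [1e-6, 1] seeds a local refinement, avoiding local minima;
    optima pinned at the grid boundary are reported as ``boundary`` with
    ``converged=False``.
    """
    d, y = _as_xy(pairs_or_distances, r2)
    if d.size < 3 or np.unique(d).size < 2:
        raise InsufficientDataError(
            "parametric decay fit needs >= 3 pairs at >= 2 distinct distances"
        )

    def sse(rho: float) -> float:
        resid = y - expected_r2(rho * d, n=n, model=model)
        return float(resid @ resid)

    rho_scan = np.logspace(np.log10(RHO_GRID_MIN), np.log10(RHO_GRID_MAX), 61)
    scores = np.array([sse(r) for r in rho_scan])
    best = rho_scan[int(np.argmin(scores))]

    def resid_log(lg):
        return y - expected_r2(np.exp(lg[0]) * d, n=n, model=model)

    try:
        res = optimize.least_squares(
            resid_log, x0=[np.log(best)], method="lm", xtol=1e-14, ftol=1e-14
        )
        rho_hat = float(np.exp(res.x[0]))
        opt_ok = bool(res.success)
    except Exception as exc:  # pragma: no cover - defensive
        rho_hat, opt_ok = best, False
        failure = f"optimizer error: {exc}"
    else:
        failure = None if opt_ok else "optimizer did not converge"

    ceiling = expected_r2(0.0, n=n, model=model)
    at_boundary = rho_hat <= 2.0 * RHO_GRID_MIN or rho_hat >= RHO_GRID_MAX
    if at_boundary:
        status = "boundary"
        converged = False
        if float(np.mean(y)) > ceiling:
            failure = (
                f"mean observed r2 {np.mean(y):.3f} exceeds the model ceiling "
                f"{ceiling:.3f} at C=0; no interior optimum"
            )
        elif failure is None:
            failure = "rho estimate pinned at the search boundary"
    elif not opt_ok:
        status = "failed"
        converged = False
    else:
        status = "converged"
        converged = True

    if grid is None:
        grid = np.linspace(0.0, float(d.max()), 201)
    curve = expected_r2(np.clip(rho_hat, 0.0, None) * grid, n=n, model=model)
    return DecayFit(
        method="parametric", model=model, rho_hat=rho_hat, n_used=n,
        grid=np.asarray(grid, float), curve=np.asarray(curve, float),
        converged=converged, status=status, failure_reason=failure,
    )


def _pspline_design(d: np.ndarray, n_basis: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform (unclamped) cubic B-spline design over [min d, max d].

    Uniform knots keep straight lines in the null space of the
    second-difference penalty, so a linear trend is never shrunk.
    """
    dmin, dmax = float(d.min()), float(d.max())
    m = n_basis - 3  # interior segments
    h = (dmax - dmin) / m
    knots = dmin + h * np.arange(-3, m + 4)
    B = BSpline.design_matrix(d, knots, 3).toarray()
    D2 = np.diff(np.eye(n_basis), n=2, axis=0)
    return B, D2.T @ D2, knots


def fit_nonparametric_decay(
    pairs_or_distances,
    r2=None,
    *,
    grid: np.ndarray | None = None,
    lam: float | None = None,
    max_basis: int = 10,
) -> DecayFit:
    """Penalized cubic-spline regression of r² on distance (GCV-smoothed).

    The smoothing parameter is chosen by minimizing the generalized
    cross-validation score n*RSS/(n - edf)² over a log-spaced grid, unless
    ``lam`` is given explicitly.  The curve is only evaluated inside the
    observed distance range (no extrapolation).  Tied distances are kept as
    separate observations.
    """
    d, y = _as_xy(pairs_or_distances, r2)
    distinct = np.unique(d)
    if distinct.size < 4:
        raise InsufficientDataError(
            "nonparametric decay fit needs >= 4 distinct distances"
        )
    n_basis = min(max_basis, max(4, distinct.size - 1))
    B, P, knots = _pspline_design(d, n_basis)
    BtB = B.T @ B
    Bty = B.T @ y
    n_obs = d.size

    def solve(l):
        coef = np.linalg.solve(BtB + l * P, Bty)
        fitted = B @ coef
        rss = float(np.sum((y - fitted) ** 2))
        edf = float(np.trace(np.linalg.solve(BtB + l * P, BtB)))
        return coef, rss, edf

    if lam is None:
        scale = np.trace(BtB) / max(np.trace(P), 1e-12)
        lam_grid = scale * np.logspace(-8, 8, 49)
        best_lam, best_gcv, best_coef = None, np.inf, None
        for l in lam_grid:
            coef, rss, edf = solve(l)
            denom = max(n_obs - edf, 1e-9)
            gcv = n_obs * rss / denom**2
            if gcv < best_gcv:
                best_lam, best_gcv, best_coef = l, gcv, coef
        lam_used, coef = float(best_lam), best_coef
    else:
        lam_used = float(lam)
        coef, _, _ = solve(lam_used)

    _, rss, edf = solve(lam_used)
    if grid is None:
        grid = np.linspace(float(d.min()), float(d.max()), 201)
    else:
        grid = np.asarray(grid, float)
        grid = grid[(grid >= d.min()) & (grid <= d.max())]
    spline = BSpline(knots, coef, 3)
    curve = spline(grid)
    return DecayFit(
        method="nonparametric", model=None, rho_hat=None, n_used=None,
        grid=grid, curve=np.asarray(curve, float),
        converged=True, status="ok", gcv_lambda=lam_used, edf=edf,
    )


def distance_at_threshold(fit: DecayFit, threshold: float) -> float | None:
    """Smallest grid distance where the fitted curve first drops below
    ``threshold``; ``None`` if the curve never does within the data range."""
    below = fit.curve < threshold
    if not below.any():
        return None
    return float(fit.grid[int(np.argmax(below))])
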