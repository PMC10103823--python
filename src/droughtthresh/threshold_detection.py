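"""Drought-threshold detection on coincidence response curves.

A cell's response curve r(theta) is first gated for non-linearity: an
exponential curve ``r = m * exp(beta * theta) + k`` is compared with a
straight line by AIC, with two overrides — a near-perfect linear fit
(R^2 > 0.95) keeps the cell linear regardless of AIC, and a poor exponential
fit (adjusted R^2 <= 0.5) excludes the cell.  Cells passing the gate get a
continuous two-segment piecewise regression

    r = b0 + b1 * theta                          for theta >= theta_T
    r = b0 + b1 * theta + b2 * (theta - theta_T) for theta <  theta_T

with the breakpoint searched over the sampled percentile grid and chosen by
minimal squared error.  The detected threshold T is the percentile of the
winning breakpoint.  The severe-drought segment must steepen the response
(b2 < 0); otherwise the cell is excluded as a slope-order violation.  A
threshold in a curve whose maximum coincidence rate stays below 0.3 is kept
but marked low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .coincidence import ResponseCurve

__all__ = [
    "LinearFit",
    "ExponentialFit",
    "SegmentedFit",
    "ThresholdResult",
    "fit_linear",
    "fit_exponential",
    "gate_nonlinearity",
    "segmented_fit",
    "detect_threshold",
    "aic",
]

FLAG_VALID = "valid"
FLAG_LINEAR = "linear_better"
FLAG_POOR_EXP = "poor_exp_fit"
FLAG_LOW_R = "low_coincidence"
FLAG_SLOPE_ORDER = "slope_order_violation"
FLAG_UNESTIMABLE = "unestimable"


def aic(rss: float, n: int, n_params: int) -> float:
    """AIC = n * ln(rss / n) + 2p, shared by every candidate model."""
    return n * float(np.log(max(rss, 1e-300) / n)) + 2 * n_params


@dataclass
class LinearFit:
    slope: float
    intercept: float
    rss: float
    r2: float
    aic: float


@dataclass
class ExponentialFit:
    m: float
    beta: float
    k: float
    rss: float
    adj_r2: float
    aic: float
    converged: bool

    def predict(self, theta: np.ndarray) -> np.ndarray:
        return self.m * np.exp(self.beta * np.asarray(theta, dtype=float)) + self.k


@dataclass
class SegmentedFit:
    beta0: float
    beta1: float
    beta2: float
    break_theta: float
    break_q: float
    sse: float
    residuals: np.ndarray = field(repr=False)

    def predict(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        below = theta < self.break_theta
        return (
            self.beta0
            + self.beta1 * theta
            + self.beta2 * np.where(below, theta - self.break_theta, 0.0)
        )


@dataclass
class ThresholdResult:
    """Terminal status of threshold detection for one cell-indicator pair."""

    T: float | None
    flags: set[str]
    max_r: float
    linear: LinearFit | None = None
    exponential: ExponentialFit | None = None
    segmented: SegmentedFit | None = None
    cell: int | None = None
    indicator: str = ""

    @property
    def valid(self) -> bool:
        return FLAG_VALID in self.flags


def _xy(curve: ResponseCurve) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ok = curve.defined()
    return curve.theta[ok], curve.r[ok], curve.q[ok]


def fit_linear(curve: ResponseCurve) -> LinearFit:
    """OLS of r on theta over the defined samples."""
    theta, r, _ = _xy(curve)
    if theta.size < 5:
        raise ValueError("need at least 5 defined samples for the linear fit")
    if np.ptp(theta) == 0:
        raise ValueError("degenerate theta: all sampled cutoffs equal")
    tm, rm = theta.mean(), r.mean()
    sxx = np.sum((theta - tm) ** 2)
    slope = np.sum((theta - tm) * (r - rm)) / sxx
    intercept = rm - slope * tm
    resid = r - (intercept + slope * theta)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((r - rm) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return LinearFit(slope=float(slope), intercept=float(intercept), rss=rss, r2=r2,
                     aic=aic(rss, theta.size, 2))


def _profile_mk(beta: float, theta: np.ndarray, r: np.ndarray) -> tuple[float, float, float]:
    """Best (m, k) and rss for a fixed beta via linear least squares."""
    z = np.exp(np.clip(beta * theta, -700.0, 700.0))
    zm = z.mean()
    rm = r.mean()
    szz = float(np.sum((z - zm) ** 2))
    if not np.isfinite(szz) or szz < 1e-28 * max(1.0, zm * zm) * z.size:
        # beta -> 0 (or overflow) collapses to a constant model
        k = float(rm)
        return 0.0, k, float(np.sum((r - k) ** 2))
    m = float(np.sum((z - zm) * (r - rm)) / szz)
    k = float(rm - m * zm)
    resid = r - (m * z + k)
    return m, k, float(np.sum(resid**2))


# Profile-search beta grid, scaled by 1/range(theta); both signs.  The low
# end reaches deep into the near-linear regime so the beta->0 nesting of a
# straight line is captured without a separate branch.
_BETA_GRID = np.geomspace(0.005, 15.0, 24)


def fit_exponential(curve: ResponseCurve) -> ExponentialFit:
    """Nonlinear least squares for r = m * exp(beta * theta) + k.

    (m, k) are profiled out by linear least squares at each beta; beta comes
    from a log-spaced grid of both signs refined by bounded minimization of
    the profile rss.  Since profiling is exact, the refined beta is the joint
    optimum — no separate three-parameter polish is needed.
    """
    theta, r, _ = _xy(curve)
    if theta.size < 6:
        raise ValueError("need at least 6 defined samples for the exponential fit")
    scale = np.ptp(theta)
    if scale == 0:
        raise ValueError("degenerate theta: all sampled cutoffs equal")

    tss = float(np.sum((r - r.mean()) ** 2))
    grid = np.concatenate([_BETA_GRID, -_BETA_GRID]) / scale
    rss_grid = np.array([_profile_mk(b, theta, r)[2] for b in grid])
    b_best = float(grid[np.argmin(rss_grid)])
    best_beta, best_rss = 0.0, _profile_mk(0.0, theta, r)[2]
    lo, hi = b_best / 3.0, b_best * 3.0
    res = minimize_scalar(
        lambda b: _profile_mk(b, theta, r)[2],
        bounds=(min(lo, hi), max(lo, hi)),
        method="bounded",
        options={"xatol": 1e-10 * abs(b_best)},
    )
    if res.fun < best_rss:
        best_beta, best_rss = float(res.x), float(res.fun)

    m, k, rss = _profile_mk(best_beta, theta, r)
    # Profiling (m, k) out is exact, so the refined beta is the joint optimum;
    # no separate (m, beta, k) polish is needed.
    converged = bool(np.isfinite(rss))

    n = theta.size
    if tss > 0:
        adj_r2 = 1.0 - (rss / max(n - 3, 1)) / (tss / (n - 1))
    else:
        adj_r2 = 0.0
    return ExponentialFit(m=m, beta=best_beta, k=k, rss=rss, adj_r2=float(adj_r2),
                          aic=aic(rss, n, 3), converged=converged)


def gate_nonlinearity(
    linear: LinearFit,
    exponential: ExponentialFit,
    lin_r2_override: float = 0.95,
    min_adj_r2: float = 0.5,
) -> str:
    """Decide whether the response curve is genuinely non-linear.

    Returns ``"nonlinear"`` when AIC favors the exponential, the linear fit
    is not already near-perfect (R^2 <= 0.95) and the exponential explains
    the curve well (adjusted R^2 > 0.5); otherwise the matching exclusion
    flag (``poor_exp_fit`` or ``linear_better``).
    """
    if (not exponential.converged) or exponential.adj_r2 <= min_adj_r2:
        return FLAG_POOR_EXP
    if exponential.aic < linear.aic and linear.r2 <= lin_r2_override:
        return "nonlinear"
    return FLAG_LINEAR


def segmented_fit(curve: ResponseCurve, min_seg_points: int = 3) -> SegmentedFit | None:
    """Continuous two-segment regression with the breakpoint on the q grid.

    Every sampled theta_q leaving at least ``min_seg_points`` samples
    strictly below and at-or-above it is a candidate; each candidate is fit
    by OLS on the design {1, theta, (theta - theta_c) * [theta < theta_c]}
    and the minimal-SSE candidate wins (first such candidate in ascending
    theta order on ties).  Returns None when no candidate is admissible.
    """
    theta, r, q = _xy(curve)
    n = theta.size
    if n < 2 * min_seg_points:
        return None
    order = np.argsort(theta, kind="stable")
    theta, r, q = theta[order], r[order], q[order]

    # Prefix sums turn every candidate's normal equations into O(1) lookups.
    b_idx = np.searchsorted(theta, theta, side="left")  # count strictly below
    admissible = (b_idx >= min_seg_points) & (n - b_idx >= min_seg_points)
    if not admissible.any():
        return None
    cand = np.nonzero(admissible)[0]
    tc = theta[cand]
    b = b_idx[cand]

    P1 = np.concatenate([[0.0], np.cumsum(theta)])
    P2 = np.concatenate([[0.0], np.cumsum(theta**2)])
    Pr = np.concatenate([[0.0], np.cumsum(r)])
    Ptr = np.concatenate([[0.0], np.cumsum(theta * r)])
    S1, S2, Sr, Str = P1[n], P2[n], Pr[n], Ptr[n]
    Srr = float(np.sum(r**2))

    Sz = P1[b] - tc * b
    Szz = P2[b] - 2 * tc * P1[b] + tc**2 * b
    Stz = P2[b] - tc * P1[b]
    Szr = Ptr[b] - tc * Pr[b]

    m = cand.size
    A = np.empty((m, 3, 3))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = S1
    A[:, 1, 1] = S2
    A[:, 0, 2] = A[:, 2, 0] = Sz
    A[:, 1, 2] = A[:, 2, 1] = Stz
    A[:, 2, 2] = Szz
    bvec = np.empty((m, 3))
    bvec[:, 0] = Sr
    bvec[:, 1] = Str
    bvec[:, 2] = Szr
    try:
        coefs = np.linalg.solve(A, bvec[..., None])[..., 0]
    except np.linalg.LinAlgError:
        coefs = np.array([np.linalg.lstsq(a, v, rcond=None)[0] for a, v in zip(A, bvec)])
    sse = np.maximum(Srr - np.einsum("ij,ij->i", coefs, bvec), 0.0)

    win = int(np.argmin(sse))  # first candidate wins ties, ascending theta
    coef = coefs[win]
    tc_win = float(tc[win])
    below = theta < tc_win
    pred = coef[0] + coef[1] * theta + coef[2] * np.where(below, theta - tc_win, 0.0)
    resid = r - pred
    return SegmentedFit(
        beta0=float(coef[0]),
        beta1=float(coef[1]),
        beta2=float(coef[2]),
        break_theta=tc_win,
        break_q=float(q[cand[win]]),
        sse=float(np.sum(resid**2)),
        residuals=resid,
    )


def detect_threshold(
    curve: ResponseCurve,
    lin_r2_override: float = 0.95,
    min_adj_r2: float = 0.5,
    low_r_cutoff: float = 0.3,
    min_seg_points: int = 3,
    require_steepening: bool = True,
) -> ThresholdResult:
    """Full gate -> segmented-fit -> exclusion-rule orchestration for one curve.

    The result carries exactly one terminal status: ``valid`` (T reported,
    possibly marked ``low_coincidence`` as a confidence qualifier) or one of
    the named exclusion flags.
    """
    max_r = curve.max_r
    base = dict(cell=curve.cell, indicator=curve.indicator, max_r=max_r)
    ok = curve.defined()
    if ok.sum() < max(6, 2 * min_seg_points) or np.ptp(curve.theta[ok]) == 0:
        return ThresholdResult(T=None, flags={FLAG_UNESTIMABLE}, **base)

    linear = fit_linear(curve)
    exponential = fit_exponential(curve)
    decision = gate_nonlinearity(linear, exponential, lin_r2_override, min_adj_r2)
    if decision != "nonlinear":
        return ThresholdResult(T=None, flags={decision}, linear=linear,
                               exponential=exponential, **base)

    seg = segmented_fit(curve, min_seg_points=min_seg_points)
    if seg is None:
        return ThresholdResult(T=None, flags={FLAG_UNESTIMABLE}, linear=linear,
                               exponential=exponential, **base)
    # The severe-drought segment (theta < break) must be the steeper decline:
    # its slope b1 + b2 must lie below the mild segment's slope b1, i.e. b2 < 0.
    if require_steepening and not seg.beta2 < 0:
        return ThresholdResult(T=None, flags={FLAG_SLOPE_ORDER}, linear=linear,
                               exponential=exponential, segmented=seg, **base)

    flags = {FLAG_VALID}
    if np.isfinite(max_r) and max_r < low_r_cutoff:
        flags.add(FLAG_LOW_R)
    return ThresholdResult(T=float(seg.break_q), flags=flags, linear=linear,
                           exponential=exponential, segmented=seg, **base)
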