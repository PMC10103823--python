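"""Shuffle-surrogate significance testing of detected drought thresholds.

The null hypothesis is that the detected threshold arises from chance
alignment of drought and vegetation years.  Surrogates destroy the temporal
coupling while preserving every marginal distribution: each member cell's
vegetation year order is permuted independently, soil moisture is left
untouched, and the full curve -> gate -> segmented-fit pipeline reruns.  The
original threshold is significant when it falls outside the 2.5th–97.5th
percentile band of the surrogate thresholds (two-sided, P < 0.05).

Because soil moisture is untouched and permutation preserves the pooled
vegetation multiset, the drought cutoffs, denominators and vegetation
cutoff are all permutation-invariant; only the numerators change per
surrogate, which the engine exploits.

A caveat of banding the threshold percentile itself: coincidence rates are
running averages of nested counts, so even a decoupled surrogate curve shows
smooth spurious structure, and the spurious thresholds it yields spread over
much of the sweep.  The band on surrogate thresholds is therefore wide, and
a genuine threshold in the middle of the sweep can rarely escape it — the
test is exactly calibrated but has little power for that statistic.  The
``statistic="max_r"`` mode instead bands the curve's maximum coincidence
rate, which is always defined, equally calibrated (by the same
exchangeability), and separates coupled from shuffled series sharply; it is
the surrogate-test counterpart of the max-coincidence robustness screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coincidence import DEFAULT_QS, DEFAULT_VEG_Q, ResponseCurve, response_curve
from .threshold_detection import ThresholdResult, detect_threshold

__all__ = ["SurrogateTest", "shuffle_test", "DEFAULT_N_SURROGATES", "DEFAULT_MIN_DETECTED"]

#: Default number of surrogate series.
DEFAULT_N_SURROGATES = 500

#: Minimum surrogate detections for a conclusive band.
DEFAULT_MIN_DETECTED = 100


@dataclass
class SurrogateTest:
    """Outcome of the shuffle test for one cell-indicator pair."""

    original_T: float
    surrogate_Ts: np.ndarray = field(repr=False)
    n_surrogates: int
    n_detected: int
    band: tuple[float, float]  # (2.5th, 97.5th) percentiles of the statistic
    significant: bool | None  # None when inconclusive
    inconclusive: bool
    statistic: str = "threshold"
    original_stat: float = float("nan")
    original: ThresholdResult | None = None


def _permuted_numerators(
    veg_by_cell: np.ndarray,
    veg_threshold: float,
    sm_order: np.ndarray,
    denom: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Numerator counts per q after permuting each cell's vegetation years."""
    k, y = veg_by_cell.shape
    perm = np.argsort(rng.random((k, y)), axis=1)
    veg_perm = np.take_along_axis(veg_by_cell, perm, axis=1)
    suppressed = (veg_perm.ravel() < veg_threshold)[sm_order]
    csum = np.cumsum(suppressed)
    numer = np.zeros(denom.shape, dtype=float)
    nz = denom > 0
    numer[nz] = csum[denom[nz] - 1]
    return numer


def _max_r(curve: ResponseCurve) -> float:
    """Maximum coincidence rate over the sweep (0 when nothing is defined)."""
    v = curve.max_r
    return float(v) if np.isfinite(v) else 0.0


def shuffle_test(
    sm_by_cell: np.ndarray,
    veg_by_cell: np.ndarray,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    seed: int | np.random.Generator | None = None,
    min_detected: int = DEFAULT_MIN_DETECTED,
    qs: np.ndarray = DEFAULT_QS,
    veg_q: float = DEFAULT_VEG_Q,
    detect_kwargs: dict | None = None,
    statistic: str = "threshold",
) -> SurrogateTest:
    """Run the shuffle test on one pooled neighborhood.

    ``sm_by_cell`` and ``veg_by_cell`` are ``(member_cell, year)`` arrays for
    the neighborhood being tested; they must be complete (no missing years).
    The cell must have a detectable original threshold, else ValueError.

    With the default ``statistic="threshold"`` the band is over detected
    surrogate thresholds: surrogates with no valid threshold are excluded,
    and the test is inconclusive when fewer than ``min_detected`` surrogates
    detect one.  With ``statistic="max_r"`` the band is over the maximum
    coincidence rate, defined for every surrogate (see module notes).
    """
    if statistic not in ("threshold", "max_r"):
        raise ValueError("statistic must be 'threshold' or 'max_r'")
    sm_by_cell = np.asarray(sm_by_cell, dtype=float)
    veg_by_cell = np.asarray(veg_by_cell, dtype=float)
    if sm_by_cell.shape != veg_by_cell.shape or sm_by_cell.ndim != 2:
        raise ValueError("sm_by_cell and veg_by_cell must be matching (cell, year) arrays")
    if not (np.all(np.isfinite(sm_by_cell)) and np.all(np.isfinite(veg_by_cell))):
        raise ValueError("shuffle test requires complete (no-missing) member series")
    if np.ptp(veg_by_cell) == 0:
        raise ValueError("degenerate vegetation series: constant, permutation-invariant")

    detect_kwargs = detect_kwargs or {}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sm = sm_by_cell.ravel()
    veg = veg_by_cell.ravel()
    original_curve = response_curve(sm, veg, qs=qs, veg_q=veg_q)
    original = detect_threshold(original_curve, **detect_kwargs)
    if not original.valid or original.T is None:
        raise ValueError("cell has no detected original threshold; shuffle test undefined")

    # Permutation-invariant pieces, computed once.
    sm_order = np.argsort(sm, kind="stable")
    qs_arr = np.asarray(qs, dtype=float)
    thetas = original_curve.theta
    denom = original_curve.n_drought
    veg_thr = original_curve.veg_threshold

    surrogate_Ts: list[float] = []
    surrogate_stats: list[float] = []
    for _ in range(n_surrogates):
        numer = _permuted_numerators(veg_by_cell, veg_thr, sm_order, denom, rng)
        r = np.full(qs_arr.shape, np.nan)
        nz = denom > 0
        r[nz] = numer[nz] / denom[nz]
        curve = ResponseCurve(
            q=qs_arr,
            theta=thetas,
            r=r,
            n_drought=denom,
            veg_threshold=veg_thr,
            pooled_n=original_curve.pooled_n,
        )
        if statistic == "max_r":
            surrogate_stats.append(_max_r(curve))
        else:
            res = detect_threshold(curve, **detect_kwargs)
            if res.valid and res.T is not None:
                surrogate_Ts.append(res.T)

    if statistic == "max_r":
        stats = np.asarray(surrogate_stats, dtype=float)
        original_stat = _max_r(original_curve)
        lo, hi = np.percentile(stats, [2.5, 97.5])
        return SurrogateTest(
            original_T=float(original.T),
            surrogate_Ts=stats,
            n_surrogates=int(n_surrogates),
            n_detected=int(stats.size),
            band=(float(lo), float(hi)),
            significant=bool(original_stat < lo or original_stat > hi),
            inconclusive=False,
            statistic=statistic,
            original_stat=original_stat,
            original=original,
        )

    ts = np.asarray(surrogate_Ts, dtype=float)
    n_detected = int(ts.size)
    inconclusive = n_detected < min_detected
    if n_detected > 0:
        lo, hi = np.percentile(ts, [2.5, 97.5])
        band = (float(lo), float(hi))
    else:
        band = (float("nan"), float("nan"))
    significant: bool | None
    if inconclusive:
        significant = None
    else:
        significant = bool(original.T < band[0] or original.T > band[1])
    return SurrogateTest(
        original_T=float(original.T),
        surrogate_Ts=ts,
        n_surrogates=int(n_surrogates),
        n_detected=n_detected,
        band=band,
        significant=significant,
        inconclusive=inconclusive,
        statistic=statistic,
        original_stat=float(original.T),
        original=original,
    )
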