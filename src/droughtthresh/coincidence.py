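"""Coincidence analysis: how often does vegetation suppression accompany drought?

For a pool of cell-years (a PC-space neighborhood), the coincidence rate at
drought percentile ``q`` is::

    r(q) = #{cell-years: sm <= theta_q  and  veg < theta_veg}
           ------------------------------------------------
           #{cell-years: sm <= theta_q}

where ``theta_q`` is the pooled q-th percentile of soil-moisture anomalies
and ``theta_veg`` the pooled 10th percentile of vegetation anomalies.  The
drought comparison is <= and the vegetation comparison strict <; with
continuous data the distinction is immaterial but the convention is encoded
literally.  Sweeping q = 1..50 yields the response curve whose inflection is
the drought threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cubes import AnomalyCube

__all__ = [
    "ResponseCurve",
    "pooled_threshold",
    "coincidence_rate",
    "response_curve",
    "pool_cell_years",
    "DEFAULT_QS",
    "DEFAULT_VEG_Q",
]

#: Drought-percentile sweep: 1st to 50th percentile in steps of 1.
DEFAULT_QS = np.arange(1, 51)

#: Vegetation-suppression percentile.
DEFAULT_VEG_Q = 10.0


@dataclass
class ResponseCurve:
    """The (q, theta, r) samples for one cell (or pooled neighborhood)."""

    q: np.ndarray  # percentile levels
    theta: np.ndarray  # pooled soil-moisture anomaly at each q
    r: np.ndarray  # coincidence rates, NaN where the denominator is empty
    n_drought: np.ndarray  # denominator counts per q
    veg_threshold: float  # pooled vegetation-suppression anomaly cutoff
    pooled_n: int  # total pooled cell-years
    cell: int | None = None
    indicator: str = ""

    def __post_init__(self) -> None:
        if not (len(self.q) == len(self.theta) == len(self.r) == len(self.n_drought)):
            raise ValueError("q, theta, r, n_drought must align")

    @property
    def max_r(self) -> float:
        defined = self.r[np.isfinite(self.r)]
        return float(defined.max()) if defined.size else float("nan")

    def defined(self) -> np.ndarray:
        """Mask of q levels with a defined rate (non-empty denominator)."""
        return np.isfinite(self.r) & np.isfinite(self.theta)


def pooled_threshold(values: np.ndarray, q: float) -> tuple[float, int]:
    """Empirical q-th percentile of the pooled non-missing values.

    Uses linear interpolation between order statistics (quantile type 7),
    the same convention for drought and vegetation cutoffs.  Returns the
    threshold and the pooled count.
    """
    if not 0.0 < q < 100.0:
        raise ValueError("percentile q must lie in (0, 100)")
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("all-missing pool")
    if v.size < 2:
        raise ValueError("need at least 2 non-missing values")
    return float(np.quantile(v, q / 100.0)), int(v.size)


def coincidence_rate(
    sm: np.ndarray,
    veg: np.ndarray,
    q: float,
    veg_q: float = DEFAULT_VEG_Q,
) -> tuple[float, int, int]:
    """Coincidence rate at drought percentile ``q`` for aligned pooled values.

    Returns ``(r, numerator, denominator)``; ``r`` is NaN when the
    denominator is empty (never reported as 0).
    """
    sm = np.asarray(sm, dtype=float).ravel()
    veg = np.asarray(veg, dtype=float).ravel()
    if sm.shape != veg.shape:
        raise ValueError("sm and veg must align on identical cell-year keys")
    ok = np.isfinite(sm) & np.isfinite(veg)
    sm, veg = sm[ok], veg[ok]
    theta_dro, _ = pooled_threshold(sm, q)
    theta_veg, _ = pooled_threshold(veg, veg_q)
    drought = sm <= theta_dro
    denom = int(np.count_nonzero(drought))
    numer = int(np.count_nonzero(drought & (veg < theta_veg)))
    r = numer / denom if denom > 0 else float("nan")
    return r, numer, denom


def pool_cell_years(
    sm_cube: AnomalyCube,
    veg_cube: AnomalyCube,
    members: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool member cells' years, dropping cell-years missing in either cube."""
    sm = sm_cube.values[members].ravel()
    veg = veg_cube.values[members].ravel()
    ok = np.isfinite(sm) & np.isfinite(veg)
    return sm[ok], veg[ok]


def response_curve(
    sm: np.ndarray,
    veg: np.ndarray,
    qs: np.ndarray = DEFAULT_QS,
    veg_q: float = DEFAULT_VEG_Q,
    cell: int | None = None,
    indicator: str = "",
) -> ResponseCurve:
    """Sweep the drought percentile over pooled, aligned cell-year values.

    ``sm`` and ``veg`` are 1-D pooled arrays on identical cell-year keys
    (see :func:`pool_cell_years`).  Rates with an empty denominator come
    back NaN and are excluded from downstream fits.
    """
    sm = np.asarray(sm, dtype=float).ravel()
    veg = np.asarray(veg, dtype=float).ravel()
    if sm.shape != veg.shape:
        raise ValueError("sm and veg must align on identical cell-year keys")
    ok = np.isfinite(sm) & np.isfinite(veg)
    sm, veg = sm[ok], veg[ok]
    if sm.size < 2:
        raise ValueError("pooled sample too small for a response curve")

    order = np.argsort(sm, kind="stable")
    sm_sorted = sm[order]
    theta_veg, _ = pooled_threshold(veg, veg_q)
    suppressed_sorted = (veg < theta_veg)[order]
    csum = np.cumsum(suppressed_sorted)

    qs = np.asarray(qs, dtype=float)
    thetas = np.quantile(sm, qs / 100.0)
    denom = np.searchsorted(sm_sorted, thetas, side="right")
    r = np.full(qs.shape, np.nan)
    nz = denom > 0
    r[nz] = csum[denom[nz] - 1] / denom[nz]
    return ResponseCurve(
        q=qs,
        theta=thetas,
        r=r,
        n_drought=denom.astype(int),
        veg_threshold=float(theta_veg),
        pooled_n=int(sm.size),
        cell=cell,
        indicator=indicator,
    )
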