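"""From monthly indicator cubes to detrended growing-season anomalies.

Also houses the derived indices and masks used throughout: the kernel NDVI
transform, validity masking of NDVI/NIRv, the P/PET aridity index with its
climate classes, and block aggregation to coarser grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cubes import AnomalyCube, MonthlyCube

__all__ = [
    "AridityRecord",
    "compute_kndvi",
    "mask_invalid",
    "season_mean",
    "detrend",
    "aridity_index",
    "block_aggregate",
]


@dataclass(frozen=True)
class AridityRecord:
    """Multiyear-mean P/PET ratio and its climate class."""

    aridity: float
    label: str  # one of arid, semi-arid, semi-humid, humid


def compute_kndvi(ndvi):
    """Kernel NDVI: elementwise tanh(NDVI**2); NaN propagates.

    NDVI must lie in [-1, 1] where observed.
    """
    arr = np.asarray(ndvi, dtype=float)
    finite = np.isfinite(arr)
    if np.any((arr[finite] < -1.0) | (arr[finite] > 1.0)):
        raise ValueError("NDVI values must lie in [-1, 1]")
    out = np.tanh(arr**2)
    out = np.where(finite, out, np.nan)
    if np.isscalar(ndvi) or np.ndim(ndvi) == 0:
        return float(out)
    return out


# Indicators with a validity rule; all others pass through untouched.
_MASK_RULES = {
    "NDVI": lambda v: v < 0.1,  # barren/rock/sand/snow screen, strict <
    "NIRv": lambda v: v <= 0.0,
}


def mask_invalid(cube: MonthlyCube, require_rule: bool = False) -> MonthlyCube:
    """Set physically invalid observations to missing.

    NDVI below 0.1 (strictly) and NIRv at or below 0 are removed; other
    indicators are returned unchanged.  With ``require_rule`` a cube whose
    indicator has no masking rule raises instead of passing through.
    """
    rule = _MASK_RULES.get(cube.indicator)
    if rule is None:
        if require_rule:
            raise ValueError(f"no masking rule defined for indicator {cube.indicator!r}")
        return MonthlyCube(cube.values.copy(), cube.indicator, cube.units, cube.grid)
    values = cube.values.copy()
    with np.errstate(invalid="ignore"):
        values[rule(values)] = np.nan
    return MonthlyCube(values, cube.indicator, cube.units, cube.grid)


def season_mean(cube: MonthlyCube, season_mask: np.ndarray) -> np.ndarray:
    """Per cell-year mean over that cell's growing-season months.

    ``season_mask`` is ``(cell, 12)`` boolean.  A year with every in-season
    month missing comes back NaN.  An empty month set raises, naming the cell.
    """
    mask = np.asarray(season_mask, dtype=bool)
    if mask.shape != (cube.n_cells, 12):
        raise ValueError("season_mask must be (n_cells, 12)")
    empty = ~mask.any(axis=1)
    if empty.any():
        raise ValueError(f"empty growing-season month set for cell(s) {np.nonzero(empty)[0].tolist()}")
    sel = np.where(mask[:, None, :], cube.values, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN year slices
        return np.nanmean(sel, axis=2)


def detrend(series: np.ndarray, indicator: str = "", units: str = "", grid=None) -> AnomalyCube:
    """OLS-detrend each cell's yearly series; residuals become anomalies.

    Missing years are excluded from the fit and stay missing.  Cells with
    fewer than 3 observed years are flagged unusable (all-NaN), not an abort.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
        squeeze = True
    else:
        squeeze = False
    n_cells, n_years = x.shape
    t = np.arange(n_years, dtype=float)
    out = np.full_like(x, np.nan)
    usable = np.zeros(n_cells, dtype=bool)
    for c in range(n_cells):
        ok = np.isfinite(x[c])
        if ok.sum() < 3:
            continue
        usable[c] = True
        tt = t[ok]
        yy = x[c, ok]
        tm = tt.mean()
        ym = yy.mean()
        denom = np.sum((tt - tm) ** 2)
        slope = np.sum((tt - tm) * (yy - ym)) / denom if denom > 0 else 0.0
        out[c, ok] = yy - (ym + slope * (tt - tm))
    if squeeze:
        out = out
    return AnomalyCube(out, indicator=indicator, units=units, grid=grid, usable=usable)


_CLASS_EDGES = ((0.2, "arid"), (0.5, "semi-arid"), (0.65, "semi-humid"))


def aridity_index(P: np.ndarray, PET: np.ndarray) -> AridityRecord:
    """Multiyear-mean P/PET with the dryland classification.

    Classes use left-closed intervals: <0.2 arid, [0.2, 0.5) semi-arid,
    [0.5, 0.65) semi-humid, >=0.65 humid (non-dryland).
    """
    P = np.asarray(P, dtype=float)
    PET = np.asarray(PET, dtype=float)
    if P.shape != PET.shape:
        raise ValueError("P and PET must align year by year")
    if np.any(PET <= 0):
        raise ValueError("PET must be > 0 in every year")
    if np.any(P < 0):
        raise ValueError("P must be >= 0")
    ai = float(np.mean(P / PET))
    label = "humid"
    for edge, name in _CLASS_EDGES:
        if ai < edge:
            label = name
            break
    return AridityRecord(aridity=ai, label=label)


def block_aggregate(fine: np.ndarray, factor: int) -> np.ndarray:
    """Average ``factor x factor`` spatial blocks of a (lat, lon, ...) field.

    Non-missing subpixels are averaged; an all-missing block is missing.  Edge
    rows/columns not filling a block are dropped with a warning.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    arr = np.asarray(fine, dtype=float)
    if arr.ndim < 2:
        raise ValueError("need at least (lat, lon) dimensions")
    nlat, nlon = arr.shape[:2]
    clat, clon = nlat // factor, nlon // factor
    if clat == 0 or clon == 0:
        raise ValueError("grid smaller than one block")
    if nlat % factor or nlon % factor:
        warnings.warn("grid not divisible by factor; edge blocks dropped", stacklevel=2)
        arr = arr[: clat * factor, : clon * factor]
    blocks = arr.reshape(clat, factor, clon, factor, *arr.shape[2:])
    blocks = np.moveaxis(blocks, 2, 1).reshape(clat, clon, factor * factor, *arr.shape[2:])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(blocks, axis=2)
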