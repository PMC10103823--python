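"""Synthetic gridded drought/vegetation data with a known two-phase coupling.

The generator emulates the study conditions of the real analysis: per-cell
18-year detrended growing-season anomaly series for soil moisture and four
correlated vegetation proxies, spatially smooth climate/vegetation covariates,
a growing-season month mask, and a future soil-moisture period with a
configurable mean shift and trend.

The ground truth is a two-phase coincidence response, engineered to be exactly
recoverable.  The target is the pooled response curve itself: coincidence rate
r as a function of the drought cutoff anomaly theta is two-segment linear with
its inflection at the cell's true threshold percentile — slope ``-slope_mild``
in the resistant phase (theta above the threshold anomaly) and the steeper
``-slope_severe`` in the rapid-response phase below it.  The conditional
probability p(u) that a year at soil-moisture percentile u falls under the
pooled 10th-percentile vegetation cutoff is derived by analytically inverting
that target (p = r + F dr/dF with F the Gaussian CDF), and each vegetation
anomaly is the implied deterministic response ``A0(u) = -PhiInv(p(u))`` plus
correlated Gaussian noise.  Note one deliberate idealization: near the
threshold p(u) is non-monotone (it must dip just below the kink for the pooled
running average to stay piecewise linear); real vegetation does not do this —
the construction exists so that every downstream stage is verifiable by exact
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .cubes import AnomalyCube

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "COVARIATE_NAMES",
    "gen_covariates",
    "true_thresholds",
    "gen_anomaly_cubes",
    "gen_future_sm",
    "simulate",
]

#: The covariate fields entering the PCA feature extraction.
COVARIATE_NAMES = ("MAP", "MAT", "VPDvar", "Treefrac", "NDVIvar", "NIRvvar", "SpeciesN")

#: Labels given to the synthetic vegetation proxies (anomaly cubes).
PROXY_NAMES = ("NDVI", "kNDVI", "NIRv", "SIF")

# Fixed substream tags so each stage draws from an independent, reproducible
# stream regardless of call order.
_STREAM_COVARIATES = 0
_STREAM_ANOMALIES = 1
_STREAM_FUTURE = 2


@dataclass
class SimulationConfig:
    """Parameters of the synthetic world.

    Defaults encode the study conditions: an 18-year record, four vegetation
    proxies, a true inflection at the 15th soil-moisture percentile, and a
    clearly steeper severe-drought coupling.
    """

    n_lat: int = 10
    n_lon: int = 10
    n_years: int = 18
    true_threshold_pct: float = 15.0
    slope_mild: float = 0.05
    slope_severe: float = 0.28
    noise_sd: float = 1.0
    n_indicators: int = 4
    indicator_corr: float = 0.6
    covariate_link: float = 0.0
    seed: int = 0
    future_shift: float = 0.0
    future_trend: float = 0.0
    n_future_years: int = 20
    sm_sd: float = 1.0
    smoothness: float = 2.0  # correlation length of covariate fields, in cells

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3 (detrending undefined below that)")
        if not 1.0 <= self.true_threshold_pct <= 50.0:
            raise ValueError("true_threshold_pct must lie in [1, 50]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.indicator_corr <= 1.0:
            raise ValueError("indicator_corr must lie in [0, 1]")
        if self.slope_mild < 0 or self.slope_severe <= 0:
            raise ValueError("phase slopes must be non-negative, severe phase > 0")
        if abs(self.slope_severe) < abs(self.slope_mild):
            raise ValueError("|slope_severe| must be >= |slope_mild| (steeper Phase B)")
        if self.n_indicators < 1:
            raise ValueError("n_indicators must be >= 1")
        if self.sm_sd <= 0:
            raise ValueError("sm_sd must be > 0")
        if self.n_future_years < 2:
            raise ValueError("n_future_years must be >= 2")

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class SyntheticDataset:
    """One realization of the synthetic world."""

    config: SimulationConfig
    sm_cube: AnomalyCube
    veg_cubes: list[AnomalyCube]
    covariates: pd.DataFrame
    season_mask: np.ndarray  # (cell, 12) bool, True for growing-season months
    truth: np.ndarray  # per-cell true threshold percentile
    future_sm: np.ndarray  # (cell, n_future_years)

    def __post_init__(self) -> None:
        n = self.sm_cube.n_cells
        y = self.sm_cube.n_years
        for cube in self.veg_cubes:
            if cube.n_cells != n or cube.n_years != y:
                raise ValueError("all cubes must share cell index and year count")
        if len(self.covariates) != n or self.truth.shape != (n,):
            raise ValueError("covariates/truth must have one row per cell")
        if np.any((self.truth < 1) | (self.truth > 50)):
            raise ValueError("truth percentiles must lie in [1, 50]")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized Gaussian random field with correlation length ``sigma``."""
    white = rng.normal(size=shape)
    if sigma > 0 and min(shape) > 1:
        f = gaussian_filter(white, sigma=sigma, mode="wrap")
    else:
        f = white
    sd = f.std()
    if sd > 0:
        f = (f - f.mean()) / sd
    return f


def gen_covariates(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the 7-field covariate table on a smooth spatial grid.

    Two latent fields — a moisture gradient and a temperature gradient — drive
    all seven covariates so that a handful of principal components capture
    most of their variance, as for real climate/vegetation covariates.  Tree
    cover loads strongly on the moisture gradient and, through
    ``covariate_link``, controls the per-cell true threshold (higher tree
    cover => lower, i.e. more drought-resistant, threshold percentile).
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, _STREAM_COVARIATES])
    shape = (config.n_lat, config.n_lon)
    sig = config.smoothness
    moist = _smooth_field(rng, shape, sig).ravel()
    temp = _smooth_field(rng, shape, sig).ravel()
    eps = [_smooth_field(rng, shape, sig).ravel() for _ in range(5)]

    map_ = np.clip(800.0 + 500.0 * moist, 50.0, None)
    mat = 12.0 + 8.0 * temp
    vpdvar = np.exp(0.25 * (-0.7 * moist + 0.6 * temp + 0.3 * eps[0]))
    treefrac = expit(1.6 * moist + 0.4 * temp + 0.4 * eps[1])
    ndvivar = 0.05 * np.exp(0.3 * (0.5 * moist + 0.2 * eps[2]))
    nirvvar = 0.03 * np.exp(0.3 * (0.5 * moist + 0.2 * eps[3]))
    speciesn = np.maximum(1.0, np.round(np.exp(3.0 + 0.8 * moist + 0.2 * temp + 0.2 * eps[4])))

    return pd.DataFrame(
        {
            "MAP": map_,
            "MAT": mat,
            "VPDvar": vpdvar,
            "Treefrac": treefrac,
            "NDVIvar": ndvivar,
            "NIRvvar": nirvvar,
            "SpeciesN": speciesn,
        }
    )


def true_thresholds(config: SimulationConfig, covariates: pd.DataFrame) -> np.ndarray:
    """Per-cell true inflection percentile implied by tree cover.

    ``covariate_link = 0`` gives a spatially constant threshold at
    ``true_threshold_pct``; positive values tilt the threshold downward with
    increasing tree cover (forests resist drought longer), spanning roughly
    ``±10 * covariate_link`` percentiles across the tree-cover range.
    """
    tf = covariates["Treefrac"].to_numpy(dtype=float)
    if config.covariate_link == 0:
        return np.full(tf.size, float(config.true_threshold_pct))
    centered = tf - float(np.median(tf))
    truth = config.true_threshold_pct - config.covariate_link * 20.0 * centered
    # stay inside the exactly-calibrated design range, quantized for profile reuse
    return np.round(np.clip(truth, 3.0, 24.0), 1)


#: Soil-moisture percentile below which the suppression profile is frozen
#: (the sweep starts at the 1st percentile; freezing deeper keeps p bounded).
_TAIL_FREEZE = 0.002

#: Safety margin keeping the suppression probability positive at the kink.
_KINK_MARGIN = 1.08

#: Fraction of pooled vegetation anomalies defined as suppressed.
_VEG_MASS = 0.10


def suppression_probability(
    u: np.ndarray,
    truth_pct: float,
    slope_mild: float,
    slope_severe: float,
) -> np.ndarray:
    """Conditional suppression probability p(u) implied by the target curve.

    ``u`` is the population soil-moisture percentile (0..1).  The target
    pooled response curve is two-segment linear in the anomaly theta with its
    kink at ``truth_pct``: r(theta) = rT - slope_mild*(theta - thetaT) above
    the kink and rT - slope_severe*(theta - thetaT) below, where the plateau
    level rT is set as low as feasibility allows (all probabilities in [0,1]
    and total suppressed mass exactly 10%).  Inverting r = N/F gives
    p = r + F dr/dF = r - slope*F/phi(theta).  Above the median (outside the
    1st-50th percentile sweep) p is the constant absorbing the remaining
    suppression mass; below ``_TAIL_FREEZE`` it is frozen.
    """
    from scipy.stats import norm

    u = np.asarray(u, dtype=float)
    FT = truth_pct / 100.0
    thT = norm.ppf(FT)
    fT = norm.pdf(thT)
    lam = fT / FT
    rT = max(_KINK_MARGIN * slope_severe / lam, slope_mild * (abs(thT) + 1.27))
    r50 = rT - slope_mild * abs(thT)
    c0 = 2.0 * (_VEG_MASS - 0.5 * r50)

    th = norm.ppf(np.clip(u, 1e-12, 1.0 - 1e-12))
    f = norm.pdf(th)
    p = np.empty_like(u, dtype=float)

    mA = (u >= FT) & (u < 0.5)
    p[mA] = (rT - slope_mild * (th - thT) - slope_mild * u / f)[mA]
    mB = (u >= _TAIL_FREEZE) & (u < FT)
    p[mB] = (rT - slope_severe * (th - thT) - slope_severe * u / f)[mB]
    th_lo = norm.ppf(_TAIL_FREEZE)
    p_lo = rT - slope_severe * (th_lo - thT) - slope_severe * _TAIL_FREEZE / norm.pdf(th_lo)
    p[u < _TAIL_FREEZE] = p_lo
    p[u >= 0.5] = c0
    return np.clip(p, 1e-9, 1.0 - 1e-9)


def response_profile(
    u: np.ndarray,
    truth_pct: float,
    slope_mild: float,
    slope_severe: float,
) -> np.ndarray:
    """Deterministic vegetation response A0(u) = -PhiInv(p(u)), centered.

    At unit noise the pooled 10th-percentile vegetation cutoff reproduces
    p(u) exactly, so the expected coincidence curve is the designed
    two-segment line with its inflection at ``truth_pct``.
    """
    from scipy.stats import norm

    p = suppression_probability(u, truth_pct, slope_mild, slope_severe)
    a0 = -norm.ppf(p)
    grid = np.linspace(5e-4, 1.0 - 5e-4, 2001)
    center = float(np.mean(-norm.ppf(suppression_probability(grid, truth_pct, slope_mild, slope_severe))))
    return a0 - center


def gen_anomaly_cubes(
    config: SimulationConfig,
    covariates: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Generate soil-moisture and vegetation anomaly cubes plus the future period.

    Soil-moisture anomalies are iid normal draws centered at zero.  Each
    vegetation proxy is the cell's deterministic two-phase response profile
    evaluated at the year's soil-moisture percentile, plus Gaussian noise
    split into a shared and an idiosyncratic component so that proxy noise
    correlates at ``indicator_corr``.
    """
    from scipy.stats import norm

    if covariates is None:
        covariates = gen_covariates(config)
    if rng is None:
        rng = np.random.default_rng([config.seed, _STREAM_ANOMALIES])
    n, y = config.n_cells, config.n_years
    truth = true_thresholds(config, covariates)

    sm = rng.normal(0.0, config.sm_sd, size=(n, y))
    u = norm.cdf(sm / config.sm_sd)
    signal = np.empty_like(sm)
    # one profile per distinct truth value (constant-truth grids hit one entry)
    for t in np.unique(truth):
        rows = truth == t
        signal[rows] = response_profile(u[rows], float(t), config.slope_mild, config.slope_severe)

    c = config.indicator_corr
    shared = rng.normal(size=(n, y))
    veg_cubes = []
    names = list(PROXY_NAMES) + [f"proxy{i}" for i in range(len(PROXY_NAMES), config.n_indicators)]
    for i in range(config.n_indicators):
        idio = rng.normal(size=(n, y))
        noise = config.noise_sd * (np.sqrt(c) * shared + np.sqrt(1.0 - c) * idio)
        veg_cubes.append(AnomalyCube(signal + noise, indicator=names[i], grid=(config.n_lat, config.n_lon)))

    sm_cube = AnomalyCube(sm, indicator="SMsurf", grid=(config.n_lat, config.n_lon))
    season_mask = _season_mask_from_mat(covariates["MAT"].to_numpy(dtype=float))
    future = gen_future_sm(config)
    return SyntheticDataset(
        config=config,
        sm_cube=sm_cube,
        veg_cubes=veg_cubes,
        covariates=covariates,
        season_mask=season_mask,
        truth=truth,
        future_sm=future,
    )


def _season_mask_from_mat(mat: np.ndarray) -> np.ndarray:
    """Growing-season months from mean annual temperature: warmer cells get a
    longer season, centered on July; every cell keeps at least 3 months."""
    n_months = np.clip(np.round(5 + (mat - 5.0) / 3.0), 3, 12).astype(int)
    mask = np.zeros((mat.size, 12), dtype=bool)
    center = 6  # July, 0-based
    for i, m in enumerate(n_months):
        lo = center - (m - 1) // 2
        months = (np.arange(lo, lo + m)) % 12
        mask[i, months] = True
    return mask


def gen_future_sm(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-cell future soil-moisture series: the historical generator shifted
    by ``future_shift`` plus ``future_trend`` per year (year index 0-based)."""
    if rng is None:
        rng = np.random.default_rng([config.seed, _STREAM_FUTURE])
    n, y = config.n_cells, config.n_future_years
    base = rng.normal(0.0, config.sm_sd, size=(n, y))
    t = np.arange(y, dtype=float)
    return base + config.future_shift + config.future_trend * t


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Full dataset from one config: covariates, anomaly cubes, future period."""
    cov = gen_covariates(config)
    return gen_anomaly_cubes(config, cov)
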