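"""End-to-end orchestration: cubes + covariates -> per-cell thresholds.

Runs PCA feature extraction, mesh-neighborhood construction, the
coincidence-rate sweep and threshold detection for every cell and
vegetation indicator, then aggregates thresholds across indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coincidence import DEFAULT_QS, DEFAULT_VEG_Q, pool_cell_years, response_curve
from .cubes import AnomalyCube
from .pc_clustering import DEFAULT_MIN_SAMPLES, NeighborhoodIndex, PCEmbedding, fit_pca, mesh_assign, neighborhoods
from .threshold_detection import FLAG_UNESTIMABLE, ThresholdResult, detect_threshold
from .aggregation import aggregate_cells

__all__ = ["PipelineResult", "run_threshold_pipeline", "analyze_dataset"]


@dataclass
class PipelineResult:
    """Long-format thresholds plus the intermediate spatial structures."""

    thresholds: pd.DataFrame  # cell, indicator, T, max_r, flag, fit diagnostics
    aggregated: pd.DataFrame  # cell, mean_T, n_indicators, robust
    embedding: PCEmbedding
    neighborhoods: NeighborhoodIndex
    results: dict[tuple[int, str], ThresholdResult] = field(repr=False, default_factory=dict)


def _result_row(cell: int, indicator: str, res: ThresholdResult) -> dict:
    seg = res.segmented
    return {
        "cell": cell,
        "indicator": indicator,
        "T": res.T if res.T is not None else np.nan,
        "max_r": res.max_r,
        "flag": "+".join(sorted(res.flags)),
        "beta0": seg.beta0 if seg else np.nan,
        "beta1": seg.beta1 if seg else np.nan,
        "beta2": seg.beta2 if seg else np.nan,
        "aic_lin": res.linear.aic if res.linear else np.nan,
        "aic_exp": res.exponential.aic if res.exponential else np.nan,
        "adj_r2_exp": res.exponential.adj_r2 if res.exponential else np.nan,
    }


def run_threshold_pipeline(
    sm_cube: AnomalyCube,
    veg_cubes: list[AnomalyCube],
    covariates: pd.DataFrame,
    qs: np.ndarray = DEFAULT_QS,
    veg_q: float = DEFAULT_VEG_Q,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    detect_kwargs: dict | None = None,
    keep_results: bool = False,
) -> PipelineResult:
    """Detect thresholds for every cell and indicator.

    Neighborhoods are computed once from the covariates and reused for every
    indicator.  Cells whose pooled sample count misses the gate are reported
    as unestimable.
    """
    detect_kwargs = detect_kwargs or {}
    emb = fit_pca(covariates)
    mesh = mesh_assign(emb)
    nbr = neighborhoods(mesh, n_years=sm_cube.n_years, min_samples=min_samples)

    rows: list[dict] = []
    results: dict[tuple[int, str], ThresholdResult] = {}
    for cell in range(sm_cube.n_cells):
        members = nbr.members[cell]
        for cube in veg_cubes:
            if not nbr.sufficient[cell]:
                res = ThresholdResult(
                    T=None, flags={FLAG_UNESTIMABLE}, max_r=np.nan,
                    cell=cell, indicator=cube.indicator,
                )
            else:
                sm, veg = pool_cell_years(sm_cube, cube, members)
                if sm.size < min_samples:
                    res = ThresholdResult(
                        T=None, flags={FLAG_UNESTIMABLE}, max_r=np.nan,
                        cell=cell, indicator=cube.indicator,
                    )
                else:
                    curve = response_curve(sm, veg, qs=qs, veg_q=veg_q,
                                           cell=cell, indicator=cube.indicator)
                    res = detect_threshold(curve, **detect_kwargs)
            rows.append(_result_row(cell, cube.indicator, res))
            if keep_results:
                results[(cell, cube.indicator)] = res

    thresholds = pd.DataFrame(rows)
    aggregated = aggregate_cells(thresholds)
    return PipelineResult(
        thresholds=thresholds,
        aggregated=aggregated,
        embedding=emb,
        neighborhoods=nbr,
        results=results,
    )


def analyze_dataset(dataset, **kwargs) -> PipelineResult:
    """Convenience wrapper taking a :class:`~droughtthresh.synthetic.SyntheticDataset`."""
    return run_threshold_pipeline(dataset.sm_cube, dataset.veg_cubes, dataset.covariates, **kwargs)
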