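"""Combining thresholds across indicators and stratifying them spatially.

A cell's thresholds from the individual vegetation proxies are averaged; the
average is robust only when it rests on at least two proxies and at least
one of them reached a maximum coincidence rate above 0.3.  Aggregated
thresholds are then binned over aridity x tree-cover, with a dedicated
non-forest category below 1% tree cover and bins holding fewer than five
cells excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .threshold_detection import ThresholdResult

__all__ = [
    "AggregatedThreshold",
    "aggregate_indicators",
    "aggregate_cells",
    "stratify_bins",
    "difference_bins",
    "MIN_CELLS_PER_BIN",
    "NONFOREST_TREEFRAC",
]

#: Bins averaging fewer cells than this are excluded.
MIN_CELLS_PER_BIN = 5

#: Tree-cover fraction below which a cell counts as non-forest.
NONFOREST_TREEFRAC = 0.01

#: Maximum coincidence rate a contributing proxy must exceed for robustness.
ROBUST_MAX_R = 0.3


@dataclass
class AggregatedThreshold:
    cell: int | None
    mean_T: float
    n_indicators: int
    robust: bool


def aggregate_indicators(results: Mapping[str, ThresholdResult]) -> AggregatedThreshold | None:
    """Average the valid thresholds of one cell across vegetation proxies.

    Returns None when no proxy produced a valid threshold (absence is the
    signal).  Robustness requires >= 2 contributing proxies and a maximum
    coincidence rate above 0.3 in at least one of them.
    """
    valid = {name: res for name, res in results.items() if res.valid and res.T is not None}
    if not valid:
        return None
    ts = np.array([res.T for res in valid.values()], dtype=float)
    max_rs = np.array([res.max_r for res in valid.values()], dtype=float)
    cell = next(iter(valid.values())).cell
    robust = len(valid) >= 2 and bool(np.any(max_rs > ROBUST_MAX_R))
    return AggregatedThreshold(cell=cell, mean_T=float(ts.mean()),
                               n_indicators=len(valid), robust=robust)


def aggregate_cells(thresholds: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-cell aggregation of a long-format threshold table.

    ``thresholds`` needs columns ``cell``, ``indicator``, ``T``, ``max_r``,
    ``flag``; rows without a valid T are ignored.  Returns one row per cell
    with ``mean_T``, ``n_indicators``, ``robust``.
    """
    valid = thresholds[thresholds["flag"].str.contains("valid") & thresholds["T"].notna()]
    if valid.empty:
        return pd.DataFrame(columns=["cell", "mean_T", "n_indicators", "robust"])
    g = valid.groupby("cell")
    out = pd.DataFrame(
        {
            "mean_T": g["T"].mean(),
            "n_indicators": g["T"].size(),
            "any_high_r": g["max_r"].max() > ROBUST_MAX_R,
        }
    )
    out["robust"] = (out["n_indicators"] >= 2) & out["any_high_r"]
    return out.drop(columns="any_high_r").reset_index()


def stratify_bins(
    aggregated: pd.DataFrame,
    aridity: np.ndarray,
    treefrac: np.ndarray,
    aridity_edges: Sequence[float] | None = None,
    tree_edges: Sequence[float] | None = None,
    min_cells: int = MIN_CELLS_PER_BIN,
    nonforest_below: float = NONFOREST_TREEFRAC,
    aridity_range: tuple[float, float] = (0.0, 1.5),
) -> pd.DataFrame:
    """Mean aggregated threshold over aridity x tree-cover bins.

    ``aggregated`` carries one row per cell (columns ``cell``, ``mean_T``);
    ``aridity`` and ``treefrac`` are indexed by cell id.  Aridity is clipped
    to the display range before binning.  Cells below ``nonforest_below``
    tree cover fall into a dedicated "non-forest" category.  Bins averaging
    fewer than ``min_cells`` cells are marked excluded.
    """
    if aridity_edges is None:
        aridity_edges = np.round(np.arange(aridity_range[0], aridity_range[1] + 1e-9, 0.1), 10)
    if tree_edges is None:
        tree_edges = np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 10)
    aridity_edges = np.asarray(aridity_edges, dtype=float)
    tree_edges = np.asarray(tree_edges, dtype=float)
    for edges in (aridity_edges, tree_edges):
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
    if aggregated.empty:
        return pd.DataFrame(columns=["aridity_bin", "tree_bin", "mean_T", "n_cells", "included"])

    cells = aggregated["cell"].to_numpy()
    ai = np.clip(np.asarray(aridity, dtype=float)[cells], *aridity_range)
    tf = np.asarray(treefrac, dtype=float)[cells]

    a_idx = np.clip(np.searchsorted(aridity_edges, ai, side="right") - 1, 0, len(aridity_edges) - 2)
    t_idx = np.clip(np.searchsorted(tree_edges, tf, side="right") - 1, 0, len(tree_edges) - 2)
    a_label = np.array(
        [f"[{aridity_edges[i]:g},{aridity_edges[i + 1]:g})" for i in range(len(aridity_edges) - 1)]
    )[a_idx]
    t_label = np.array(
        [f"[{tree_edges[i]:g},{tree_edges[i + 1]:g})" for i in range(len(tree_edges) - 1)]
    )[t_idx]
    t_label = np.where(tf < nonforest_below, "non-forest", t_label)
    t_order = np.where(tf < nonforest_below, -1, t_idx)

    df = pd.DataFrame(
        {
            "aridity_bin": a_label,
            "tree_bin": t_label,
            "_a": a_idx,
            "_t": t_order,
            "T": aggregated["mean_T"].to_numpy(),
        }
    )
    g = df.groupby(["aridity_bin", "tree_bin"], sort=False).agg(
        mean_T=("T", "mean"), n_cells=("T", "size"), _a=("_a", "first"), _t=("_t", "first")
    )
    g = g.sort_values(["_a", "_t"]).drop(columns=["_a", "_t"]).reset_index()
    g["included"] = g["n_cells"] >= min_cells
    return g


def difference_bins(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Per-bin threshold difference a - b on identical bin specs
    (e.g. observations minus model simulations)."""
    merged = a.merge(b, on=["aridity_bin", "tree_bin"], suffixes=("_a", "_b"))
    merged["delta_T"] = merged["mean_T_a"] - merged["mean_T_b"]
    merged["included"] = merged["included_a"] & merged["included_b"]
    return merged[["aridity_bin", "tree_bin", "delta_T", "n_cells_a", "n_cells_b", "included"]]
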