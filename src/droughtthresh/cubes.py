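"""In-memory containers for gridded indicator data.

Cubes hold one indicator on a flattened cell index (row-major from the
north-west corner of the grid, 0-based).  Missing data is NaN, never a
silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MonthlyCube", "AnomalyCube"]


@dataclass
class MonthlyCube:
    """Monthly values of one indicator, shaped ``(cell, year, month)``.

    The month axis always has length 12 (calendar months 1..12 at indices
    0..11).  NaN marks missing observations.
    """

    values: np.ndarray
    indicator: str
    units: str = ""
    grid: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 12:
            raise ValueError(
                "MonthlyCube values must be (cell, year, 12), got "
                f"{self.values.shape}"
            )
        if self.values.shape[1] < 3:
            raise ValueError("MonthlyCube needs at least 3 years")
        if self.grid is not None and int(np.prod(self.grid)) != self.values.shape[0]:
            raise ValueError("grid shape inconsistent with cell count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_years(self) -> int:
        return self.values.shape[1]


@dataclass
class AnomalyCube:
    """Per-cell, per-year detrended growing-season anomalies of one indicator.

    ``values`` is ``(cell, year)``; NaN marks years that are missing or cells
    flagged unusable (fewer than 3 observed years).  ``usable`` reports which
    cells carry enough data for percentile statistics.
    """

    values: np.ndarray
    indicator: str
    units: str = ""
    grid: tuple[int, int] | None = None
    usable: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"AnomalyCube values must be (cell, year), got {self.values.shape}")
        if self.grid is not None and int(np.prod(self.grid)) != self.values.shape[0]:
            raise ValueError("grid shape inconsistent with cell count")
        if self.usable is None:
            self.usable = np.sum(np.isfinite(self.values), axis=1) >= 3
        else:
            self.usable = np.asarray(self.usable, dtype=bool)
            if self.usable.shape != (self.values.shape[0],):
                raise ValueError("usable mask must have one entry per cell")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_years(self) -> int:
        return self.values.shape[1]
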