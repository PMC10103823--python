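"""Reading and writing the pipeline's on-disk formats.

Cubes travel as NetCDF (via xarray's scipy backend, dims lat/lon/year with
NaN fill), tables as headered CSV, and simulation configs as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .cubes import AnomalyCube, MonthlyCube
from .synthetic import SimulationConfig, SyntheticDataset

__all__ = [
    "write_anomaly_cube",
    "read_anomaly_cube",
    "write_monthly_cube",
    "read_monthly_cube",
    "write_covariates",
    "read_covariates",
    "write_season_mask",
    "read_season_mask",
    "load_config",
    "save_config",
    "write_dataset",
]

_ENGINE = "scipy"  # NetCDF3 backend; no external netCDF library required


def _grid(cube) -> tuple[int, int]:
    if cube.grid is not None:
        return cube.grid
    return (1, cube.n_cells)


def write_anomaly_cube(cube: AnomalyCube, path: str | Path) -> None:
    nlat, nlon = _grid(cube)
    da = xr.DataArray(
        cube.values.reshape(nlat, nlon, cube.n_years),
        dims=("lat", "lon", "year"),
        name=cube.indicator or "anomaly",
        attrs={"units": cube.units, "indicator": cube.indicator},
    )
    da.to_dataset().to_netcdf(path, engine=_ENGINE)


def read_anomaly_cube(path: str | Path) -> AnomalyCube:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        name = list(ds.data_vars)[0]
        da = ds[name].load()
    nlat, nlon = da.sizes["lat"], da.sizes["lon"]
    values = da.transpose("lat", "lon", "year").values.reshape(nlat * nlon, -1)
    return AnomalyCube(values, indicator=str(da.attrs.get("indicator", name)),
                       units=str(da.attrs.get("units", "")), grid=(nlat, nlon))


def write_monthly_cube(cube: MonthlyCube, path: str | Path) -> None:
    nlat, nlon = _grid(cube)
    da = xr.DataArray(
        cube.values.reshape(nlat, nlon, cube.n_years, 12),
        dims=("lat", "lon", "year", "month"),
        coords={"month": np.arange(1, 13)},
        name=cube.indicator or "monthly",
        attrs={"units": cube.units, "indicator": cube.indicator},
    )
    da.to_dataset().to_netcdf(path, engine=_ENGINE)


def read_monthly_cube(path: str | Path) -> MonthlyCube:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        name = list(ds.data_vars)[0]
        da = ds[name].load()
    nlat, nlon = da.sizes["lat"], da.sizes["lon"]
    values = da.transpose("lat", "lon", "year", "month").values.reshape(nlat * nlon, -1, 12)
    return MonthlyCube(values, indicator=str(da.attrs.get("indicator", name)),
                       units=str(da.attrs.get("units", "")), grid=(nlat, nlon))


def write_covariates(covariates: pd.DataFrame, path: str | Path) -> None:
    covariates.to_csv(path, index_label="cell")


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="cell")


def write_season_mask(mask: np.ndarray, path: str | Path) -> None:
    """Season mask as long-format (cell, month) CSV, months 1..12."""
    cells, months = np.nonzero(np.asarray(mask, dtype=bool))
    pd.DataFrame({"cell": cells, "month": months + 1}).to_csv(path, index=False)


def read_season_mask(path: str | Path, n_cells: int) -> np.ndarray:
    df = pd.read_csv(path)
    mask = np.zeros((n_cells, 12), dtype=bool)
    mask[df["cell"].to_numpy(int), df["month"].to_numpy(int) - 1] = True
    return mask


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write every component of a synthetic dataset under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_anomaly_cube(dataset.sm_cube, out / "sm.nc")
    for cube in dataset.veg_cubes:
        write_anomaly_cube(cube, out / f"veg_{cube.indicator}.nc")
    write_covariates(dataset.covariates, out / "covariates.csv")
    pd.DataFrame({"cell": np.arange(dataset.truth.size), "true_threshold_pct": dataset.truth}).to_csv(
        out / "truth.csv", index=False
    )
    write_season_mask(dataset.season_mask, out / "season_mask.csv")
    fut = AnomalyCube(dataset.future_sm, indicator="SMsurf_future",
                      grid=dataset.sm_cube.grid)
    write_anomaly_cube(fut, out / "future_sm.nc")
    save_config(dataset.config, out / "config.yaml")
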