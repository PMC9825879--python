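"""Bioclimatic extreme indices from daily climate cubes.

Six predictors summarise both average conditions and climatic limits for
drought/frost exposure:

* ``bio1_95_c``   - 95th percentile of daily mean temperature (degC),
  pooled over the period;
* ``bio4_c``      - temperature seasonality: standard deviation of the 12
  monthly mean temperatures (degC), averaged over years;
* ``cfd_ann_days``- annual maximum run of consecutive frost days
  (tas <= 0 degC), averaged over years;
* ``cdd_ann_days``- annual maximum run of consecutive dry days
  (pr < 1 mm/day), averaged over years;
* ``bio12_5_mm``  - 5th percentile of the per-year precipitation totals;
* ``bio15_pct``   - precipitation seasonality: coefficient of variation (%)
  of the 12 monthly totals, averaged over years.

All computations assume the synthetic 365-day calendar. BIO15 is computed
on month-length-normalised totals (mm per 30-day-equivalent month) so that
a climate with no seasonal cycle has exactly zero seasonality; with raw
totals the unequal month lengths alone would register ~3% "seasonality"
for perfectly uniform rain. Percentiles use linear interpolation between
order statistics (numpy default) for bit-stable results.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "MONTH_LENGTHS",
    "ClimateConfig",
    "max_consecutive_run",
    "compute_bioclim_cell",
    "period_tables",
    "overlap_weights",
    "extract_survey_values",
]

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
DAYS_PER_YEAR = int(MONTH_LENGTHS.sum())  # 365, no leap days
_MONTH_EDGES = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])
_MONTH_OF_DOY = np.repeat(np.arange(12), MONTH_LENGTHS)


@dataclass(frozen=True)
class ClimateConfig:
    """Index definitions left open by convention are configured here.

    ``frost_threshold_c`` applies to the cube's daily mean temperature
    (whether frost days should instead use daily minima is a data choice;
    the cube carries only tas). ``span_year_boundaries=False`` restricts
    frost/dry runs to single calendar years, matching the "annual
    consecutive days" reading; the spanning variant credits each year with
    the longest run that overlaps it.
    """

    frost_threshold_c: float = 0.0
    dry_threshold_mm: float = 1.0
    span_year_boundaries: bool = False


def max_consecutive_run(flags) -> int:
    """Length of the longest uninterrupted run of True values."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("flags must contain at least one day")
    longest = 0
    for val, grp in itertools.groupby(flags):
        if val:
            longest = max(longest, sum(1 for _ in grp))
    return longest


def _annual_max_runs(flags_by_year: np.ndarray, span: bool) -> np.ndarray:
    """Per-year maximum run; optionally letting runs cross year boundaries."""
    n_years = flags_by_year.shape[0]
    if not span:
        return np.array(
            [max_consecutive_run(flags_by_year[i]) for i in range(n_years)],
            dtype=float,
        )
    flat = flags_by_year.ravel()
    out = np.zeros(n_years)
    pos = 0
    for val, grp in itertools.groupby(flat):
        length = sum(1 for _ in grp)
        if val:
            first = pos // DAYS_PER_YEAR
            last = (pos + length - 1) // DAYS_PER_YEAR
            for yr in range(first, last + 1):
                out[yr] = max(out[yr], length)
        pos += length
    return out


def _monthly_stat(daily_by_year: np.ndarray, how: str) -> np.ndarray:
    """(n_years, 365) daily values -> (n_years, 12) monthly means or totals."""
    out = np.empty((daily_by_year.shape[0], 12))
    for m in range(12):
        sl = daily_by_year[:, _MONTH_EDGES[m]:_MONTH_EDGES[m + 1]]
        out[:, m] = sl.mean(axis=1) if how == "mean" else sl.sum(axis=1)
    return out


def compute_bioclim_cell(
    tas: np.ndarray,
    pr: np.ndarray,
    config: ClimateConfig = ClimateConfig(),
) -> dict[str, float]:
    """All six indices for one cell's daily series (whole years required)."""
    tas = np.asarray(tas, dtype=float)
    pr = np.asarray(pr, dtype=float)
    if tas.shape != pr.shape or tas.ndim != 1:
        raise ValueError("tas and pr must be equal-length 1-D daily series")
    if tas.size == 0 or tas.size % DAYS_PER_YEAR != 0:
        raise ValueError(
            f"series length {tas.size} is not a multiple of {DAYS_PER_YEAR} days"
        )
    n_years = tas.size // DAYS_PER_YEAR
    tas_y = tas.reshape(n_years, DAYS_PER_YEAR)
    pr_y = pr.reshape(n_years, DAYS_PER_YEAR)

    monthly_t = _monthly_stat(tas_y, "mean")
    bio4 = float(np.mean(np.std(monthly_t, axis=1, ddof=1)))

    cfd = _annual_max_runs(tas_y <= config.frost_threshold_c,
                           config.span_year_boundaries)
    cdd = _annual_max_runs(pr_y < config.dry_threshold_mm,
                           config.span_year_boundaries)

    monthly_p = _monthly_stat(pr_y, "sum") * (30.0 / MONTH_LENGTHS)
    mean_p = monthly_p.mean(axis=1)
    sd_p = np.std(monthly_p, axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean_p > 0, 100.0 * sd_p / mean_p, 0.0)

    return {
        "bio1_95_c": float(np.percentile(tas, 95)),
        "bio4_c": bio4,
        "cfd_ann_days": float(cfd.mean()),
        "cdd_ann_days": float(cdd.mean()),
        "bio12_5_mm": float(np.percentile(pr_y.sum(axis=1), 5)),
        "bio15_pct": float(cv.mean()),
    }


def period_tables(
    cube: xr.Dataset,
    periods: dict[str, tuple[int, int]],
    config: ClimateConfig = ClimateConfig(),
) -> pd.DataFrame:
    """One bioclim row per climate-grid cell per named period.

    ``periods`` maps a period label to an inclusive (first_year, last_year)
    range on the cube's ``year`` coordinate.
    """
    years = cube["year"].to_numpy()
    rows = []
    for label, (y0, y1) in periods.items():
        if y0 > y1:
            raise ValueError(f"period {label!r}: first year exceeds last year")
        available = np.unique(years)
        wanted = np.arange(y0, y1 + 1)
        missing = np.setdiff1d(wanted, available)
        if missing.size:
            raise ValueError(
                f"period {label!r}: cube lacks years {missing.tolist()}"
            )
        mask = (years >= y0) & (years <= y1)
        tas = cube["tas"].to_numpy()[mask]
        pr = cube["pr"].to_numpy()[mask]
        lat = cube["y"].to_numpy()
        lon = cube["x"].to_numpy()
        for iy in range(tas.shape[1]):
            for ix in range(tas.shape[2]):
                rec = compute_bioclim_cell(tas[:, iy, ix], pr[:, iy, ix], config)
                rec.update(
                    cell_id=f"clim_{iy:03d}_{ix:03d}",
                    lat=float(lat[iy]),
                    lon=float(lon[ix]),
                    period=label,
                    scenario=cube.attrs.get("scenario", ""),
                    model=cube.attrs.get("model", ""),
                )
                rows.append(rec)
    cols = ["cell_id", "lat", "lon", "period", "scenario", "model",
            "bio1_95_c", "bio4_c", "cfd_ann_days", "cdd_ann_days",
            "bio12_5_mm", "bio15_pct"]
    return pd.DataFrame(rows)[cols]


def overlap_weights(survey_cells: pd.DataFrame,
                    climate_cells: pd.DataFrame) -> pd.DataFrame:
    """Rectangle-overlap area fractions between survey and climate cells.

    Both frames need cell_id and lat/lon bounds columns. Weights for one
    survey cell are the fractions of its area covered by each climate
    cell; cells are axis-aligned so plain interval arithmetic is exact.
    """
    recs = []
    c = climate_cells
    for _, s in survey_cells.iterrows():
        area = (s["lat_max"] - s["lat_min"]) * (s["lon_max"] - s["lon_min"])
        dlat = np.minimum(c["lat_max"], s["lat_max"]) - np.maximum(
            c["lat_min"], s["lat_min"]
        )
        dlon = np.minimum(c["lon_max"], s["lon_max"]) - np.maximum(
            c["lon_min"], s["lon_min"]
        )
        ov = np.clip(dlat, 0, None) * np.clip(dlon, 0, None)
        hit = ov > 0
        for cid, w in zip(c.loc[hit, "cell_id"], ov[hit] / area):
            recs.append(
                {"survey_cell": s["cell_id"], "climate_cell": cid,
                 "weight": float(w)}
            )
    return pd.DataFrame(recs)


def extract_survey_values(
    bioclim: pd.DataFrame,
    weights: pd.DataFrame,
    value_columns: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Occupancy-weighted transfer of climate-grid values to survey cells.

    For each survey cell: value = sum_i w_i v_i / sum_i w_i over the
    climate cells it overlaps. Keyed metadata columns (period, scenario,
    model) are carried through; the transfer is computed independently for
    each (period, scenario, model) slice present in ``bioclim``.
    """
    if value_columns is None:
        value_columns = tuple(
            c for c in bioclim.columns
            if c not in ("cell_id", "lat", "lon", "period", "scenario", "model")
        )
    keys = [k for k in ("period", "scenario", "model") if k in bioclim.columns]
    out = []
    surveys = weights["survey_cell"].unique()
    grouped = bioclim.groupby(keys) if keys else [((), bioclim)]
    for key, sub in grouped:
        merged = weights.merge(
            sub, left_on="climate_cell", right_on="cell_id", how="inner"
        )
        totals = merged.groupby("survey_cell")["weight"].sum()
        dead = set(surveys) - set(totals.index[totals > 0])
        if dead:
            raise ValueError(
                "survey cells with zero climate overlap: "
                + ", ".join(sorted(dead))
            )
        rec = {}
        for col in value_columns:
            num = (
                merged.assign(val=merged[col] * merged["weight"])
                .groupby("survey_cell")["val"].sum()
            )
            rec[col] = num / totals
        df = pd.DataFrame(rec).rename_axis("cell_id").reset_index()
        if keys:
            key = key if isinstance(key, tuple) else (key,)
            for k, v in zip(keys, key):
                df[k] = v
        out.append(df)
    return pd.concat(out, ignore_index=True)
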