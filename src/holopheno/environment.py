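"""Environmental sensor processing.

Greenhouse conditions are logged by four stations (air temperature, relative
humidity, illuminance) every 15 min.  This module derives photosynthetically
active radiation (PAR) from illuminance, vapor-pressure deficit (VPD) from
temperature and humidity via the Arden-Buck saturation-vapor-pressure
formula, and aggregates all channels into 30-min bins: raw points are pooled
across stations within each bin, outliers are removed by Tukey's
interquartile-range fences, and the mean of the retained points is reported.
Bins whose points are all removed (or missing) propagate as missing values,
never as zeros.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PAR_PER_LUX",
    "lux_to_par",
    "vpd_arden_buck",
    "tukey_iqr_filter",
    "tukey_iqr_mask",
    "bin_and_average",
    "read_station_log",
    "write_binned",
]

#: Conversion factor from illuminance (lux) to PAR (umol m^-2 s^-1) for the
#: greenhouse light environment.
PAR_PER_LUX = 0.0185

#: Channels a station log carries, in the order they are binned.
ENV_CHANNELS = ("temp_c", "rh_pct", "lux", "par", "vpd_kpa")


def lux_to_par(lux):
    """Convert illuminance (lux) to PAR (umol m^-2 s^-1).

    Scalar or array input; negative illuminance is a sensor fault and raises
    ``ValueError``.  NaN passes through (missing reading).
    """
    arr = np.asarray(lux, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("illuminance must be >= 0")
    out = PAR_PER_LUX * arr
    return float(out) if np.isscalar(lux) else out


def vpd_arden_buck(temp_c, rh_pct):
    """Vapor-pressure deficit (kPa) from the Arden-Buck equation.

    VPD = (1 - RH/100) * 0.61121 * exp(17.502*T / (240.97 + T))

    with T in degC and RH in percent.  VPD is zero exactly at saturation
    (RH = 100) and increases with temperature at fixed RH < 100.
    """
    t = np.asarray(temp_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    finite = ~np.isnan(rh)
    if np.any((rh[finite] < 0) | (rh[finite] > 100)):
        raise ValueError("relative humidity must lie in [0, 100]")
    if np.any(t[~np.isnan(t)] <= -240.97):
        raise ValueError("temperature out of the Arden-Buck domain")
    es = 0.61121 * np.exp(17.502 * t / (240.97 + t))
    out = (1.0 - rh / 100.0) * es
    if np.isscalar(temp_c) and np.isscalar(rh_pct):
        return float(out)
    return out


def tukey_iqr_filter(values: Iterable[float], k: float = 1.5):
    """Partition ``values`` into (retained, removed) by Tukey's IQR fences.

    A point is removed when it falls below ``Q1 - k*IQR`` or above
    ``Q3 + k*IQR``; quartiles use linear interpolation between order
    statistics.  Input order is preserved in both outputs, and their
    multiset union is always the input.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("tukey_iqr_filter requires at least one value")
    keep = tukey_iqr_mask(arr, k=k)
    return arr[keep], arr[~keep]


def tukey_iqr_mask(arr: np.ndarray, k: float = 1.5, axis: int | None = None):
    """Boolean mask of points retained by Tukey's IQR fences.

    Vectorised along ``axis`` (each slice filtered independently); NaNs are
    never retained but do not influence the fences.
    """
    arr = np.asarray(arr, dtype=float)
    with np.errstate(invalid="ignore"):
        if axis is None:
            q1, q3 = np.nanpercentile(arr, [25, 75])
        else:
            q1 = np.nanpercentile(arr, 25, axis=axis, keepdims=True)
            q3 = np.nanpercentile(arr, 75, axis=axis, keepdims=True)
        iqr = q3 - q1
        lo = q1 - k * iqr
        hi = q3 + k * iqr
        return (arr >= lo) & (arr <= hi)


def _check_width(width_min: int) -> None:
    if width_min <= 0 or 1440 % width_min:
        raise ValueError(f"bin width {width_min} min must divide 24 h")


def bin_and_average(
    records: pd.DataFrame,
    width_min: int = 30,
    channels: Sequence[str] = ("temp_c", "rh_pct", "lux"),
    iqr_k: float = 1.5,
    derive: bool = True,
) -> pd.DataFrame:
    """Bin station records into clock-aligned windows and average.

    Per bin and channel, the raw points of all stations are pooled, the
    Tukey-IQR filter is applied, and the mean of the retained points is
    reported together with retained/removed counts.  Timestamps are assigned
    to half-open ``[start, start + width)`` bins aligned to midnight.

    Parameters
    ----------
    records
        Long station log with columns ``timestamp`` plus the channels.
    derive
        When true, PAR and VPD rows are derived from the binned means of
        lux and of (temp_c, rh_pct) respectively.

    Returns
    -------
    DataFrame with columns ``bin_start``, ``width_min``, ``variable``,
    ``mean``, ``n_retained``, ``n_removed``; bins with no retained points
    carry ``mean = NaN``.
    """
    _check_width(width_min)
    if records.empty:
        raise ValueError("no records to bin")
    ts = pd.to_datetime(records["timestamp"])
    bins = ts.dt.floor(f"{width_min}min")
    frames = []
    for ch in channels:
        vals = records[ch].astype(float)
        grouped = pd.DataFrame({"bin_start": bins, "value": vals}).groupby(
            "bin_start", sort=True
        )["value"]

        def _stats(v: pd.Series) -> pd.Series:
            arr = v.to_numpy()
            n_nan = int(np.isnan(arr).sum())
            arr = arr[~np.isnan(arr)]
            if arr.size == 0:
                return pd.Series({"mean": np.nan, "n_retained": 0, "n_removed": n_nan})
            keep = tukey_iqr_mask(arr, k=iqr_k)
            kept = arr[keep]
            return pd.Series(
                {
                    "mean": kept.mean() if kept.size else np.nan,
                    "n_retained": int(kept.size),
                    "n_removed": int(arr.size - kept.size) + n_nan,
                }
            )

        out = grouped.apply(_stats).unstack()
        out["variable"] = ch
        frames.append(out.reset_index())
    binned = pd.concat(frames, ignore_index=True)
    binned["width_min"] = width_min
    binned = binned[["bin_start", "width_min", "variable", "mean", "n_retained", "n_removed"]]
    binned["n_retained"] = binned["n_retained"].astype(int)
    binned["n_removed"] = binned["n_removed"].astype(int)
    if derive:
        binned = pd.concat([binned, _derived_rows(binned, width_min)], ignore_index=True)
    return binned.sort_values(["variable", "bin_start"], ignore_index=True)


def _derived_rows(binned: pd.DataFrame, width_min: int) -> pd.DataFrame:
    wide = binned.pivot(index="bin_start", columns="variable", values="mean")
    rows = []
    if "lux" in wide:
        par = lux_to_par(wide["lux"].to_numpy())
        rows.append(pd.DataFrame({"bin_start": wide.index, "variable": "par", "mean": par}))
    if {"temp_c", "rh_pct"} <= set(wide.columns):
        rh = wide["rh_pct"].to_numpy().clip(0.0, 100.0)  # binned means stay in range
        vpd = vpd_arden_buck(wide["temp_c"].to_numpy(), rh)
        rows.append(
            pd.DataFrame({"bin_start": wide.index, "variable": "vpd_kpa", "mean": vpd})
        )
    if not rows:
        return pd.DataFrame(columns=binned.columns)
    out = pd.concat(rows, ignore_index=True)
    out["width_min"] = width_min
    out["n_retained"] = 0
    out["n_removed"] = 0
    return out[["bin_start", "width_min", "variable", "mean", "n_retained", "n_removed"]]


def read_station_log(path) -> pd.DataFrame:
    """Read a station log CSV (``timestamp, station, temp_c, rh_pct, lux``)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = {"timestamp", "station", "temp_c", "rh_pct", "lux"} - set(df.columns)
    if missing:
        raise ValueError(f"station log missing columns: {sorted(missing)}")
    return df


def write_binned(binned: pd.DataFrame, path) -> None:
    binned.to_csv(path, index=False)
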