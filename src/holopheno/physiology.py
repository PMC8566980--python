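"""Plant-level sensor time-series analyses.

The central statistic is the *signed significant area* of the leaf-temperature
contrast: per 30-min bin, the difference in mean leaf temperature between
inoculated and uninoculated plants (dT_leaf) is tested with a two-sample test
across the biological replicates; the areas above and below the x-axis are
then integrated over the *significant* bins only, in "arbitrary area units"
(1 aau = 1 degC x one 30-min bin).  The same per-bin machinery serves the
soil-water-content contrast, and a daily-window comparison (10:00-16:00, the
hours of maximal transpiration) serves the sap-flow analysis.  Sap flow can
optionally be converted from the raw heat-dissipation (Granier) probe signal
to g H2O h^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .environment import tukey_iqr_mask

__all__ = [
    "AggregatedSeries",
    "aggregate_plant_series",
    "delta_tleaf_series",
    "swc_contrast",
    "AreaSummary",
    "significant_area_summary",
    "GranierCalibration",
    "granier_sap_flow",
    "daily_window_compare",
    "star_code",
    "TreatmentContrast",
    "ContrastResults",
    "read_plant_log",
]

_VALID_REGIMES = {"WW", "DS", "SDS"}
_CELL_KEYS = ["hybrid", "inoculated", "regime"]


def read_plant_log(path) -> pd.DataFrame:
    """Read a per-plant sensor log CSV.

    Expected columns: ``timestamp, plant_id, hybrid, inoculated (0/1),
    regime (WW/DS), tleaf_c, sapflow, swc``.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"timestamp", "plant_id", "hybrid", "inoculated", "regime"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plant log missing columns: {sorted(missing)}")
    _validate_labels(df)
    return df


def _validate_labels(df: pd.DataFrame) -> None:
    bad_regime = set(df["regime"].unique()) - _VALID_REGIMES
    if bad_regime:
        raise ValueError(f"unknown irrigation regime labels: {sorted(bad_regime)}")
    inoc = set(pd.unique(df["inoculated"]))
    if not inoc <= {0, 1, True, False}:
        raise ValueError(f"inoculated flag must be 0/1, got {sorted(map(str, inoc))}")


@dataclass
class AggregatedSeries:
    """Per-bin replicate values after binning and outlier removal.

    ``per_plant`` is long-form: one row per (treatment cell, bin, plant) with
    the plant's bin mean and a ``retained`` flag from the Tukey-IQR filter
    applied across the replicates of that cell and bin.
    """

    per_plant: pd.DataFrame
    value_col: str
    width_min: int

    def cell_matrix(self, hybrid: str, inoculated: int, regime: str) -> pd.DataFrame:
        """Bins x replicates matrix of retained values (NaN where removed)."""
        m = self.per_plant
        sel = m[
            (m["hybrid"] == hybrid)
            & (m["inoculated"] == int(inoculated))
            & (m["regime"] == regime)
        ]
        if sel.empty:
            raise KeyError(f"no data for cell ({hybrid}, inoculated={inoculated}, {regime})")
        vals = sel["value"].where(sel["retained"])
        return sel.assign(value=vals).pivot(
            index="bin_start", columns="plant_id", values="value"
        )

    def cell_means(self) -> pd.DataFrame:
        """Mean of retained replicates per (cell, bin)."""
        m = self.per_plant
        kept = m[m["retained"]]
        out = (
            kept.groupby(_CELL_KEYS + ["bin_start"], observed=True)["value"]
            .agg(mean="mean", n_retained="count")
            .reset_index()
        )
        removed = (
            m[~m["retained"]]
            .groupby(_CELL_KEYS + ["bin_start"], observed=True)["value"]
            .size()
        )
        out["n_removed"] = (
            removed.reindex(
                out.set_index(_CELL_KEYS + ["bin_start"]).index, fill_value=0
            ).to_numpy()
        )
        return out


def aggregate_plant_series(
    records: pd.DataFrame,
    value_col: str = "tleaf_c",
    width_min: int = 30,
    iqr_k: float = 1.5,
) -> AggregatedSeries:
    """Bin plant sensor records and filter outliers across replicates.

    Within each 30-min bin, each plant contributes the mean of its raw 5-min
    points; the Tukey-IQR filter is then applied *across* the replicate
    values of each treatment cell, so one gross sensor failure does not
    contaminate the cell mean.
    """
    if width_min <= 0 or 1440 % width_min:
        raise ValueError(f"bin width {width_min} min must divide 24 h")
    _validate_labels(records)
    df = records[["timestamp", "plant_id", *_CELL_KEYS, value_col]].copy()
    df["inoculated"] = df["inoculated"].astype(int)
    df["bin_start"] = pd.to_datetime(df["timestamp"]).dt.floor(f"{width_min}min")
    per_plant = (
        df.groupby(_CELL_KEYS + ["bin_start", "plant_id"], observed=True)[value_col]
        .mean()
        .rename("value")
        .reset_index()
    )
    # Replicate filter, vectorised: pivot each cell to bins x plants.
    retained = np.ones(len(per_plant), dtype=bool)
    per_plant["_row"] = np.arange(len(per_plant))
    for _, cell in per_plant.groupby(_CELL_KEYS, observed=True):
        wide = cell.pivot(index="bin_start", columns="plant_id", values="value")
        rows = cell.pivot(index="bin_start", columns="plant_id", values="_row")
        keep = tukey_iqr_mask(wide.to_numpy(), k=iqr_k, axis=1)
        idx = rows.to_numpy()
        ok = ~np.isnan(idx)
        retained[idx[ok].astype(int)] = keep[ok]
    per_plant = per_plant.drop(columns="_row")
    per_plant["retained"] = retained & per_plant["value"].notna()
    return AggregatedSeries(per_plant=per_plant, value_col=value_col, width_min=width_min)


def _bin_test(a: np.ndarray, b: np.ndarray, test: str) -> np.ndarray:
    """Per-bin two-sample p-values for bins x replicates matrices."""
    if test in ("student", "welch"):
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(
                a, b, axis=1, equal_var=(test == "student"), nan_policy="omit"
            )
        return np.asarray(res.pvalue, dtype=float)
    if test == "mannwhitney":
        p = np.full(a.shape[0], np.nan)
        for i in range(a.shape[0]):
            x = a[i][~np.isnan(a[i])]
            y = b[i][~np.isnan(b[i])]
            if x.size >= 2 and y.size >= 2:
                p[i] = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        return p
    raise ValueError(f"unknown test {test!r}; use student, welch or mannwhitney")


def _contrast(
    arm_a: pd.DataFrame,
    arm_b: pd.DataFrame,
    alpha: float,
    test: str,
    bh: bool,
) -> pd.DataFrame:
    if not arm_a.index.equals(arm_b.index):
        raise ValueError("contrast arms have misaligned bins")
    A = arm_a.to_numpy(dtype=float)
    B = arm_b.to_numpy(dtype=float)
    n_a = (~np.isnan(A)).sum(axis=1)
    n_b = (~np.isnan(B)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        delta = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
    testable = (n_a >= 2) & (n_b >= 2)
    p = np.full(A.shape[0], np.nan)
    if testable.any():
        p[testable] = _bin_test(A[testable], B[testable], test)
    if bh:
        p = _benjamini_hochberg(p)
    significant = np.where(np.isnan(p), False, p <= alpha)
    return pd.DataFrame(
        {
            "bin_start": arm_a.index,
            "delta": delta,
            "p_value": p,
            "significant": significant,
            "n_a": n_a,
            "n_b": n_b,
        }
    ).reset_index(drop=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def delta_tleaf_series(
    cell_inoculated: pd.DataFrame,
    cell_uninoculated: pd.DataFrame,
    alpha: float = 0.05,
    test: str = "student",
    bh: bool = False,
) -> pd.DataFrame:
    """Per-bin leaf-temperature contrast, inoculated minus uninoculated.

    Both arguments are bins x replicates matrices (as from
    :meth:`AggregatedSeries.cell_matrix`) with aligned bin indexes.  Bins
    with fewer than two retained replicates in either arm are untestable:
    their p-value is missing and they are never flagged significant, but
    they still count toward the temporal bin total.

    Returns a DataFrame with ``bin_start, delta, p_value, significant,
    n_a, n_b`` (a = inoculated arm).
    """
    return _contrast(cell_inoculated, cell_uninoculated, alpha, test, bh)


def swc_contrast(
    cell_ww: pd.DataFrame,
    cell_ds: pd.DataFrame,
    alpha: float = 0.05,
    test: str = "student",
    bh: bool = False,
) -> pd.DataFrame:
    """Per-bin soil-water-content contrast, DS minus WW (same machinery as
    the leaf-temperature contrast)."""
    return _contrast(cell_ds, cell_ww, alpha, test, bh)


@dataclass(frozen=True)
class AreaSummary:
    """Signed significant areas of a per-bin contrast, in aau.

    ``pos_area``: integrated |delta| over significant bins with delta > 0
    (first arm warmer); ``neg_area``: the same for delta < 0.  One aau is
    1 degC x one 30-min bin; other bin widths scale proportionally.
    """

    pos_area: float
    neg_area: float
    n_bins: int
    n_significant: int

    @property
    def pct_significant(self) -> float:
        if self.n_bins == 0:
            return 0.0
        return round(100.0 * self.n_significant / self.n_bins, 1)


def significant_area_summary(delta: pd.DataFrame, width_min: int = 30) -> AreaSummary:
    """Integrate the contrast over significant bins, split by sign.

    Rectangle integration: each significant bin contributes
    ``|delta| * width_min / 30`` aau to the area on its side of the x-axis;
    non-significant and untestable bins contribute nothing.  No contiguity
    of bins is required.
    """
    if delta.empty:
        raise ValueError("empty contrast series")
    w = width_min / 30.0
    sig = delta["significant"].to_numpy(dtype=bool)
    d = delta["delta"].to_numpy(dtype=float)
    pos = float(np.sum(np.where(sig & (d > 0), d, 0.0)) * w)
    neg = float(-np.sum(np.where(sig & (d < 0), d, 0.0)) * w)
    return AreaSummary(
        pos_area=pos,
        neg_area=neg,
        n_bins=int(len(delta)),
        n_significant=int(sig.sum()),
    )


@dataclass(frozen=True)
class GranierCalibration:
    """Heat-dissipation (Granier) sap-flow calibration.

    ``flux = alpha * K**beta`` with ``K = (dT_max - dT)/dT``; alpha/beta
    default to the classic calibration (119e-6 m3 m-2 s-1, 1.231).
    """

    alpha: float = 119e-6
    beta: float = 1.231
    sapwood_area_cm2: float = 1.0
    delta_t_max_c: float = 10.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.sapwood_area_cm2, self.delta_t_max_c) <= 0:
            raise ValueError("Granier calibration constants must be > 0")


def granier_sap_flow(delta_t_c, cal: GranierCalibration = GranierCalibration()):
    """Convert the raw probe temperature differential to sap flow (g H2O/h).

    The dimensionless flow index K = (dT_max - dT)/dT is zero at the no-flow
    reference dT_max; flux density alpha*K^beta (m3 m-2 s-1) times the
    sapwood area and the density of water gives mass flow per hour.
    """
    arr = np.asarray(delta_t_c, dtype=float)
    if np.any((arr <= 0) | (arr > cal.delta_t_max_c)):
        raise ValueError("probe dT must lie in (0, dT_max]")
    k = (cal.delta_t_max_c - arr) / arr
    flux = cal.alpha * np.power(k, cal.beta)  # m3 m-2 s-1
    flow = flux * (cal.sapwood_area_cm2 * 1e-4) * 1e6 * 3600.0
    return float(flow) if np.isscalar(delta_t_c) else flow


def star_code(p: float, levels: Sequence[float] = (0.05, 0.01, 0.001)) -> str:
    """Significance stars: one per passed threshold, smallest threshold wins."""
    if np.isnan(p):
        return ""
    stars = sum(p <= lv for lv in sorted(levels, reverse=True))
    return "*" * stars


def daily_window_compare(
    records: pd.DataFrame,
    value_col: str = "sapflow",
    window: tuple[str, str] = ("10:00", "16:00"),
    alpha_levels: Sequence[float] = (0.05, 0.01, 0.001),
    test: str = "student",
    group_col: str = "inoculated",
) -> pd.DataFrame:
    """Compare two arms day by day on their daily-window means.

    For each plant and day, the mean of all raw points falling in
    ``[window start, window end)`` is taken (10:00-16:00 by default, the
    hours of maximal transpiration); per day, the two arms' plant-level
    means are compared with the same two-sample test engine as the per-bin
    contrasts, and the smallest passed threshold is reported as stars.
    """
    start, end = (pd.Timedelta(w + ":00") for w in window)
    if not pd.Timedelta(0) <= start < end <= pd.Timedelta(days=1):
        raise ValueError(f"invalid daily window {window}")
    df = records.copy()
    ts = pd.to_datetime(df["timestamp"])
    tod = ts - ts.dt.normalize()
    df = df[(tod >= start) & (tod < end)]
    if df.empty:
        raise ValueError("no records inside the daily window")
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    per_plant = (
        df.groupby(["date", group_col, "plant_id"], observed=True)[value_col]
        .mean()
        .reset_index()
    )
    groups = sorted(per_plant[group_col].unique(), reverse=True)
    if len(groups) != 2:
        raise ValueError(f"{group_col} must have exactly two levels, got {groups}")
    g_a, g_b = groups  # inoculated flag: 1 first
    rows = []
    for date, day in per_plant.groupby("date"):
        a = day.loc[day[group_col] == g_a, value_col].to_numpy()
        b = day.loc[day[group_col] == g_b, value_col].to_numpy()
        if a.size >= 2 and b.size >= 2:
            p = float(_bin_test(a[None, :], b[None, :], test)[0])
        else:
            p = np.nan
        rows.append(
            {
                "date": date,
                "mean_a": a.mean() if a.size else np.nan,
                "mean_b": b.mean() if b.size else np.nan,
                "n_a": a.size,
                "n_b": b.size,
                "p_value": p,
                "stars": star_code(p, alpha_levels),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ContrastResults:
    """Fitted treatment contrast: per-bin series plus its area summary."""

    delta: pd.DataFrame
    area: AreaSummary
    alpha: float
    test: str
    value_col: str
    labels: tuple[str, str]

    def summary(self) -> str:
        a = self.area
        lines = [
            f"Treatment contrast on {self.value_col} ({self.labels[0]} - {self.labels[1]})",
            f"  per-bin test: {self.test}, alpha = {self.alpha}",
            f"  bins: {a.n_bins}  significant: {a.n_significant} ({a.pct_significant}%)",
            f"  area above x-axis: {a.pos_area:.1f} aau",
            f"  area below x-axis: {a.neg_area:.1f} aau",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Signed contrast over time, significant bins highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        d = self.delta
        ax.bar(d["bin_start"], d["delta"], width=0.02, color="lightgray", label="n.s.")
        sig = d[d["significant"]]
        pos = sig[sig["delta"] > 0]
        neg = sig[sig["delta"] < 0]
        ax.bar(pos["bin_start"], pos["delta"], width=0.02, color="tab:blue")
        ax.bar(neg["bin_start"], neg["delta"], width=0.02, color="tab:red")
        ax.axhline(0.0, color="black", lw=0.8)
        ax.set_ylabel(f"delta {self.value_col}")
        return ax


class TreatmentContrast:
    """Model object for a per-bin two-arm contrast of a plant sensor channel.

    Built from raw per-plant records; :meth:`fit` aggregates to 30-min bins,
    removes replicate outliers, runs the per-bin two-sample test and returns
    a :class:`ContrastResults` carrying the contrast series and its signed
    significant-area summary.

    Example
    -------
    >>> model = TreatmentContrast(records, value_col="tleaf_c",
    ...                           hybrid="DKB177", regime="WW")
    >>> res = model.fit(alpha=0.05)
    >>> print(res.summary())
    """

    def __init__(
        self,
        records: pd.DataFrame,
        value_col: str = "tleaf_c",
        hybrid: str | None = None,
        regime: str | None = None,
    ):
        df = records
        if hybrid is not None:
            df = df[df["hybrid"] == hybrid]
        if regime is not None:
            df = df[df["regime"] == regime]
        if df.empty:
            raise ValueError("no records for the requested hybrid/regime")
        self.records = df
        self.value_col = value_col
        self.hybrid = hybrid
        self.regime = regime

    def fit(
        self,
        alpha: float = 0.05,
        test: str = "student",
        width_min: int = 30,
        iqr_k: float = 1.5,
        bh: bool = False,
    ) -> ContrastResults:
        agg = aggregate_plant_series(
            self.records, value_col=self.value_col, width_min=width_min, iqr_k=iqr_k
        )
        hybrids = self.records["hybrid"].unique()
        regimes = self.records["regime"].unique()
        if len(hybrids) != 1 or len(regimes) != 1:
            raise ValueError("contrast requires a single hybrid and regime; pass them")
        inoc = agg.cell_matrix(hybrids[0], 1, regimes[0])
        uninoc = agg.cell_matrix(hybrids[0], 0, regimes[0])
        common = inoc.index.intersection(uninoc.index)
        delta = _contrast(inoc.loc[common], uninoc.loc[common], alpha, test, bh)
        area = significant_area_summary(delta, width_min=width_min)
        return ContrastResults(
            delta=delta,
            area=area,
            alpha=alpha,
            test=test,
            value_col=self.value_col,
            labels=("inoculated", "uninoculated"),
        )
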