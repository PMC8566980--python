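"""Synthetic greenhouse experiments.

Generators for every data stream the analysis consumes: diurnal environment
logs per station (sinusoid + AR(1) noise), per-plant sensor series with
treatment-structured responses (leaf temperature, sap flow, soil water
content), Dirichlet-multinomial OTU count tables with SynCom spike-ins, and
per-plant yield/phenology tables with a genotype x inoculation interaction
under drought.  All generators are deterministic given (design, params,
seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import (
    SYNCOM_ISOLATES,
    DesignError,
    ExperimentDesign,
    SimulationParams,
)
from .environment import vpd_arden_buck
from .microbiome import OtuTable

__all__ = [
    "simulate_environment",
    "simulate_plants",
    "simulate_otu_table",
    "simulate_yield",
    "simulate_experiment",
]


def _time_grid(design: ExperimentDesign, cadence_min: int) -> pd.DatetimeIndex:
    n = design.duration_das * 1440 // cadence_min
    return pd.date_range(design.sowing, periods=n, freq=f"{cadence_min}min")


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """AR(1) series with stationary standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n)
    if rho == 0.0:
        return eps
    x0 = rng.normal(0.0, sd)
    out, _ = lfilter([1.0], [1.0, -rho], eps, zi=np.array([rho * x0]))
    return out


def _diurnal(design: ExperimentDesign, ts: pd.DatetimeIndex, env) -> dict[str, np.ndarray]:
    hours = (ts - design.sowing).total_seconds().to_numpy() / 3600.0 % 24.0
    phase = 2.0 * np.pi * (hours - env.t_peak_hour) / 24.0
    temp = env.t_mean_c + env.t_amplitude_c * np.cos(phase)
    rh = np.clip(env.rh_mean_pct - env.rh_amplitude_pct * np.cos(phase), 0.0, 100.0)
    frac = (hours - env.dawn_hour) / env.day_length_h
    daylight = (frac >= 0.0) & (frac <= 1.0)
    lux = np.where(daylight, env.lux_max * np.sin(np.pi * np.clip(frac, 0, 1)), 0.0)
    return {"temp_c": temp, "rh_pct": rh, "lux": lux, "daylight": daylight}


def simulate_environment(
    design: ExperimentDesign, params: SimulationParams, seed: int
) -> pd.DataFrame:
    """Per-station environment logs at the station cadence.

    Air temperature follows a sinusoid peaking at ``t_peak_hour``; relative
    humidity runs in anti-phase and is clamped to [0, 100]; illuminance
    follows a half-sine daylight curve and is exactly zero between dusk and
    dawn.  Each station gets independent AR(1) noise.
    """
    env = params.env
    ts = _time_grid(design, design.env_cadence_min)
    base = _diurnal(design, ts, env)
    rng = np.random.default_rng(seed)
    frames = []
    for s in range(1, design.n_stations + 1):
        temp = base["temp_c"] + _ar1(rng, len(ts), env.ar1_rho, env.t_noise_sd)
        rh = np.clip(
            base["rh_pct"] + _ar1(rng, len(ts), env.ar1_rho, env.rh_noise_sd), 0.0, 100.0
        )
        lux_noise = _ar1(rng, len(ts), env.ar1_rho, env.lux_noise_sd)
        lux = np.where(base["daylight"], np.maximum(base["lux"] + lux_noise, 0.0), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": ts,
                    "station": f"S{s}",
                    "temp_c": temp,
                    "rh_pct": rh,
                    "lux": lux,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _station_mean_env(env_records: pd.DataFrame) -> pd.DataFrame:
    return (
        env_records.groupby("timestamp", sort=True)[["temp_c", "rh_pct"]]
        .mean()
        .reset_index()
    )


def _swc_deficit(
    design: ExperimentDesign,
    das: np.ndarray,
    vpd: np.ndarray,
    decay_per_day: float,
    recovery_per_day: float,
    dt_days: float,
) -> np.ndarray:
    """Fractional soil-water deficit under the DS regime, in [0, 1].

    Evapotranspirative loss during the reduced-irrigation window is
    proportional to VPD (normalised by its daytime mean); after rehydration
    the deficit relaxes back to zero at a fixed daily rate.
    """
    ds_start, _ = design.ds_window_das
    vpd_pos = np.maximum(vpd, 0.0)
    scale = vpd_pos[vpd_pos > 0].mean() if np.any(vpd_pos > 0) else 1.0
    rate = np.where(
        (das >= ds_start) & (das < design.rehydration_das),
        decay_per_day * vpd_pos / scale,
        0.0,
    )
    rate = np.where(das >= design.rehydration_das, -recovery_per_day, rate)
    deficit = np.empty_like(rate)
    f = 0.0
    for i, r in enumerate(rate * dt_days):
        f = min(1.0, max(0.0, f + r))
        deficit[i] = f
    return deficit


def simulate_plants(
    design: ExperimentDesign,
    env_records: pd.DataFrame,
    params: SimulationParams,
    seed: int,
) -> pd.DataFrame:
    """Per-plant 5-min sensor series for every treatment cell.

    Leaf temperature = air T + cell offset + VPD coupling + Gaussian noise;
    sap flow = cell gain x VPD x soil-water availability; SWC follows the
    irrigation schedule, declining through the drought window and recovering
    after rehydration.
    """
    phys = params.physiology
    ts = _time_grid(design, design.plant_cadence_min)
    env_mean = _station_mean_env(env_records)
    env_ts = pd.to_datetime(env_mean["timestamp"])
    if env_ts.iloc[0] > ts[0] or env_ts.iloc[-1] < ts[-1] - pd.Timedelta(
        minutes=design.env_cadence_min
    ):
        raise DesignError("environment series does not cover the plant series")
    t_epoch = ts.asi8 / 1e9
    e_epoch = env_ts.to_numpy().astype("datetime64[ns]").astype(np.int64) / 1e9
    air_t = np.interp(t_epoch, e_epoch, env_mean["temp_c"].to_numpy())
    rh = np.interp(t_epoch, e_epoch, env_mean["rh_pct"].to_numpy())
    vpd = vpd_arden_buck(air_t, np.clip(rh, 0.0, 100.0))
    das = (ts - design.sowing).total_seconds().to_numpy() / 86400.0
    dt_days = design.plant_cadence_min / 1440.0

    deficit_ds = _swc_deficit(
        design, das, vpd, phys.swc_decay_per_day, phys.swc_recovery_per_day, dt_days
    )
    swc_span = phys.swc_setpoint - phys.swc_min
    swc_by_regime = {
        "WW": np.full(len(ts), phys.swc_setpoint),
        "DS": phys.swc_setpoint - swc_span * deficit_ds,
    }
    avail_by_regime = {
        r: np.clip((s - phys.swc_min) / swc_span, 0.0, 1.0)
        for r, s in swc_by_regime.items()
    }

    rng = np.random.default_rng(seed)
    frames = []
    for hybrid, inoculation, regime in design.cells():
        offset = phys.offset_for(hybrid, inoculation, regime)
        gain = phys.gain_for(hybrid, inoculation, regime)
        inoc_flag = int(inoculation == "inoculated")
        for rep in range(1, design.replicates_per_cell + 1):
            tleaf = (
                air_t
                + offset
                + phys.tleaf_coupling_c_per_kpa * vpd
                + rng.normal(0.0, phys.tleaf_noise_sd, len(ts))
                if phys.tleaf_noise_sd
                else air_t + offset + phys.tleaf_coupling_c_per_kpa * vpd
            )
            sap = gain * np.maximum(vpd, 0.0) * avail_by_regime[regime]
            if phys.sapflow_noise_sd:
                sap = sap + rng.normal(0.0, phys.sapflow_noise_sd, len(ts))
            swc = swc_by_regime[regime]
            if phys.swc_noise_sd:
                swc = swc + rng.normal(0.0, phys.swc_noise_sd, len(ts))
            frames.append(
                pd.DataFrame(
                    {
                        "timestamp": ts,
                        "plant_id": f"{hybrid}_{'I' if inoc_flag else 'U'}_{regime}_r{rep}",
                        "hybrid": hybrid,
                        "inoculated": inoc_flag,
                        "regime": regime,
                        "tleaf_c": tleaf,
                        "sapflow": sap,
                        "swc": swc,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _base_composition(rng: np.random.Generator, otu) -> tuple[np.ndarray, np.ndarray]:
    """Baseline (uninoculated) composition: ranked lognormal residents plus a
    small flat SynCom background (seed/soil carry-over)."""
    resident_raw = np.sort(rng.lognormal(0.0, 1.5, otu.n_resident_otus))[::-1]
    syncom_total = otu.syncom_base_proportion * otu.n_syncom_otus
    resident = resident_raw / resident_raw.sum() * (1.0 - syncom_total)
    syncom = np.full(otu.n_syncom_otus, otu.syncom_base_proportion)
    return syncom, resident


def simulate_otu_table(
    design: ExperimentDesign, params: SimulationParams, seed: int
) -> OtuTable:
    """OTU x sample counts with SynCom spike-ins in inoculated samples.

    Counts are multinomial draws of fixed library size from
    Dirichlet-distributed sample compositions; in inoculated samples the
    expected proportions of SynCom OTUs are multiplied by
    ``syncom_fold_change`` and of ``n_shifted_resident`` resident OTUs by
    ``resident_fold_change`` before renormalisation.
    """
    otu = params.otu
    rng = np.random.default_rng(seed)
    syncom_base, resident_base = _base_composition(rng, otu)
    base = np.concatenate([syncom_base, resident_base])
    spiked = base.copy()
    spiked[: otu.n_syncom_otus] *= otu.syncom_fold_change
    # Resident shifts: half enriched by the fold change, half depleted by its
    # inverse (displacement), drawn from mid-abundance ranks so the shifted
    # mass does not swamp the renormalisation.
    lo = otu.n_syncom_otus + otu.shifted_resident_rank_start
    half = otu.n_shifted_resident // 2
    spiked[lo : lo + half] *= otu.resident_fold_change
    spiked[lo + half : lo + otu.n_shifted_resident] /= otu.resident_fold_change
    spiked /= spiked.sum()

    n_otus = otu.n_syncom_otus + otu.n_resident_otus
    otu_ids = [f"SYN{i + 1:03d}" for i in range(otu.n_syncom_otus)] + [
        f"RES{i + 1:04d}" for i in range(otu.n_resident_otus)
    ]
    syncom_flag = np.array([True] * otu.n_syncom_otus + [False] * otu.n_resident_otus)
    isolate = [SYNCOM_ISOLATES[i % len(SYNCOM_ISOLATES)] for i in range(otu.n_syncom_otus)]
    isolate += [""] * otu.n_resident_otus
    taxonomy = [f"Bacteria;SynCom;{iso}" for iso in isolate[: otu.n_syncom_otus]]
    taxonomy += [f"Bacteria;Resident;taxon_{i + 1:04d}" for i in range(otu.n_resident_otus)]

    samples, meta_rows = [], []
    counts = np.zeros((n_otus, design.n_cells * design.replicates_per_cell), dtype=int)
    col = 0
    for hybrid, inoculation, regime in design.cells():
        mean = spiked if inoculation == "inoculated" else base
        alpha = otu.dirichlet_concentration * mean / mean.sum()
        for rep in range(1, design.replicates_per_cell + 1):
            p = rng.dirichlet(alpha)
            counts[:, col] = rng.multinomial(otu.library_size, p)
            sid = f"{hybrid}_{'I' if inoculation == 'inoculated' else 'U'}_{regime}_s{rep}"
            samples.append(sid)
            meta_rows.append(
                {
                    "sample": sid,
                    "hybrid": hybrid,
                    "inoculated": int(inoculation == "inoculated"),
                    "regime": regime,
                    "replicate": rep,
                }
            )
            col += 1
    return OtuTable(
        counts=pd.DataFrame(counts, index=otu_ids, columns=samples),
        taxonomy=pd.Series(taxonomy, index=otu_ids, name="taxonomy"),
        syncom=pd.Series(syncom_flag, index=otu_ids, name="syncom"),
        isolate=pd.Series(isolate, index=otu_ids, name="syncom_isolate"),
        sample_meta=pd.DataFrame(meta_rows).set_index("sample"),
    )


def simulate_yield(
    design: ExperimentDesign, params: SimulationParams, seed: int
) -> pd.DataFrame:
    """Per-plant yield components, biomass and phenology dates.

    Each component is its cell mean plus a Gaussian residual; drought delays
    anthesis and silking by ``ds_flowering_delay_das``; flowerless plants
    (per-cell probability) carry missing flowering dates.
    """
    y = params.yields
    rng = np.random.default_rng(seed)
    rows = []
    for hybrid, inoculation, regime in design.cells():
        mean = y.mean_for(hybrid, inoculation, regime)
        inoc_flag = int(inoculation == "inoculated")
        ds = regime != "WW"
        biomass_mean = y.biomass_ds_mean_g if ds else y.biomass_ww_mean_g
        flower_delay = y.ds_flowering_delay_das if ds else 0.0
        p_flowerless = y.flowerless_probability.get((hybrid, inoculation, regime), 0.0)
        for rep in range(1, y.plants_per_cell + 1):
            grain = max(0.0, mean + rng.normal(0.0, y.yield_residual_sd_g))
            biomass = max(
                grain + 1.0, biomass_mean + rng.normal(0.0, y.biomass_residual_sd_g)
            )
            flowerless = rng.random() < p_flowerless
            anthesis = (
                np.nan
                if flowerless
                else y.anthesis_ww_das + flower_delay + rng.normal(0.0, y.flowering_sd_das)
            )
            silking = (
                np.nan
                if flowerless
                else y.silking_ww_das + flower_delay + rng.normal(0.0, y.flowering_sd_das)
            )
            rows.append(
                {
                    "plant_id": f"{hybrid}_{'I' if inoc_flag else 'U'}_{regime}_p{rep}",
                    "hybrid": hybrid,
                    "inoculated": inoc_flag,
                    "regime": regime,
                    "yield_g": grain,
                    "kernels": int(round(grain * y.kernels_per_g)),
                    "kernel_rows": max(
                        2, int(round(y.kernel_rows_mean + rng.normal(0.0, 1.0)))
                    ),
                    "ear_length_mm": max(
                        0.0,
                        (y.ear_length_ds_mm if ds else y.ear_length_ww_mm)
                        + rng.normal(0.0, 10.0),
                    ),
                    "ear_diameter_mm": max(
                        0.0,
                        (y.ear_diameter_ds_mm if ds else y.ear_diameter_ww_mm)
                        + rng.normal(0.0, 3.0),
                    ),
                    "biomass_g": biomass,
                    "emergence_das": max(
                        1.0, y.emergence_mean_das + rng.normal(0.0, y.emergence_sd_das)
                    ),
                    "anthesis_das": anthesis,
                    "silking_das": silking,
                }
            )
    return pd.DataFrame(rows)


def simulate_experiment(
    design: ExperimentDesign | None = None,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> dict:
    """Run all four generators with sub-seeds derived from ``seed``.

    Returns a dict with keys ``env``, ``plants``, ``otu``, ``yield``.
    """
    design = design or ExperimentDesign()
    params = params or SimulationParams()
    ss = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    env = simulate_environment(design, params, seeds[0])
    plants = simulate_plants(design, env, params, seeds[1])
    otu = simulate_otu_table(design, params, seeds[2])
    yields = simulate_yield(design, params, seeds[3])
    return {"env": env, "plants": plants, "otu": otu, "yield": yields}
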