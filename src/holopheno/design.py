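"""Experimental design and simulation parameter containers.

The design mirrors a greenhouse factorial experiment on maize: three
commercial hybrids crossed with seed inoculation by a synthetic bacterial
community (SynCom) and with two irrigation regimes (well-watered ``WW`` and
drought-stressed ``DS``, the latter receiving reduced irrigation over a fixed
window of days-after-sowing and full rehydration afterwards).  Plant sensors
log every 5 min, environment stations every 15 min.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "ExperimentDesign",
    "EnvParams",
    "PhysiologyParams",
    "OtuParams",
    "YieldParams",
    "SimulationParams",
    "DesignError",
    "SYNCOM_ISOLATES",
]

#: The 17 community-based isolates the SynCom is assembled from.  OTU-level
#: profiling resolves them into more than 17 OTUs (default 23); the mapping
#: from OTUs to isolate labels is cyclic unless the caller supplies one.
SYNCOM_ISOLATES = (
    "Agrobacterium sp. E09",
    "Asticcacaulis sp. F02",
    "Burkholderia sp. A10",
    "Dyella sp. G12",
    "Ensifer sp. B04",
    "Enterobacter sp. B02",
    "Lysobacter sp. A02",
    "Microbacterium sp. C05",
    "Pantoea sp. B02/C12",
    "Pedobacter sp. A01",
    "Sphingomonas sp. D05",
    "Stenotrophomonas sp. E09",
    "Streptomyces sp. G01",
    "Un. Bradyrhizobiaceae C05",
    "Un. Xanthomonadaceae B08",
    "Un. Xanthomonadaceae G08",
    "Variovorax sp. F04",
)


class DesignError(ValueError):
    """An experiment design or parameter set violates its invariants."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout and timing of the greenhouse experiment.

    Parameters
    ----------
    hybrids
        Genotype labels.
    replicates_per_cell
        Sensor-equipped plants per (hybrid x inoculation x regime) cell.
    plant_cadence_min, env_cadence_min
        Logging cadence of plant sensors and environment stations (minutes);
        both must divide the 30-min analysis bin.
    ds_window_das
        ``(start, end)`` of the reduced-irrigation window in days after
        sowing (DAS); rehydration restores full irrigation at
        ``rehydration_das``.
    duration_das
        Experiment length, sowing (0 DAS) to harvest.
    """

    hybrids: tuple[str, ...] = ("DKB177", "SX7341", "P3707VYH")
    inoculations: tuple[str, ...] = ("inoculated", "uninoculated")
    regimes: tuple[str, ...] = ("WW", "DS")
    replicates_per_cell: int = 4
    plant_cadence_min: int = 5
    env_cadence_min: int = 15
    n_stations: int = 4
    ds_window_das: tuple[int, int] = (50, 80)
    rehydration_das: int = 80
    duration_das: int = 117
    sowing_date: str = "2018-08-25"

    def __post_init__(self) -> None:
        if self.duration_das <= 0:
            raise DesignError("duration_das must be positive")
        start, end = self.ds_window_das
        if not (0 <= start < end <= self.duration_das):
            raise DesignError(
                f"ds_window_das {self.ds_window_das} must satisfy "
                f"0 <= start < end <= duration ({self.duration_das})"
            )
        for name in ("plant_cadence_min", "env_cadence_min"):
            cad = getattr(self, name)
            if cad <= 0 or 30 % cad:
                raise DesignError(f"{name}={cad} must be positive and divide 30")
        if self.replicates_per_cell < 2:
            raise DesignError("replicates_per_cell must be >= 2")
        if self.n_stations < 1:
            raise DesignError("n_stations must be >= 1")
        if len(self.hybrids) < 1:
            raise DesignError("at least one hybrid required")

    @property
    def sowing(self) -> pd.Timestamp:
        return pd.Timestamp(self.sowing_date)

    @property
    def n_cells(self) -> int:
        return len(self.hybrids) * len(self.inoculations) * len(self.regimes)

    def cells(self):
        """Iterate over (hybrid, inoculation, regime) treatment cells."""
        for h in self.hybrids:
            for i in self.inoculations:
                for r in self.regimes:
                    yield (h, i, r)


@dataclass(frozen=True)
class EnvParams:
    """Diurnal environment model: sinusoid + AR(1) noise per channel.

    Temperature peaks at ``t_peak_hour``; relative humidity runs in
    anti-phase.  Illuminance follows a half-sine daylight curve, exactly zero
    between dusk and dawn.  ``*_noise_sd`` are stationary standard deviations
    of the AR(1) component (rho = ``ar1_rho``).
    """

    t_mean_c: float = 25.0
    t_amplitude_c: float = 8.0
    t_peak_hour: float = 14.0
    rh_mean_pct: float = 65.0
    rh_amplitude_pct: float = 20.0
    lux_max: float = 21650.0
    dawn_hour: float = 6.0
    day_length_h: float = 12.0
    ar1_rho: float = 0.6
    t_noise_sd: float = 0.8
    rh_noise_sd: float = 3.0
    lux_noise_sd: float = 500.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1_rho < 1.0:
            raise DesignError("ar1_rho must lie in [0, 1)")
        for name in ("t_noise_sd", "rh_noise_sd", "lux_noise_sd"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if self.lux_max < 0:
            raise DesignError("lux_max must be >= 0")


@dataclass(frozen=True)
class PhysiologyParams:
    """Plant physiological response model.

    Leaf temperature tracks air temperature plus a treatment-cell offset and
    a VPD coupling term; sap flow is proportional to VPD times a soil-water
    availability factor; soil water content (SWC) declines through the
    drought window (evapotranspiration proportional to VPD) and recovers
    after rehydration.

    ``tleaf_offset_c`` and ``sapflow_gain`` may be given per cell as a
    mapping keyed by ``(hybrid, inoculation, regime)`` (missing cells fall
    back to the inoculation-arm default).
    """

    tleaf_coupling_c_per_kpa: float = 0.8
    tleaf_offset_c: Mapping[tuple, float] = field(default_factory=dict)
    tleaf_inoculated_offset_c: float = -1.5
    tleaf_noise_sd: float = 0.3
    sapflow_gain: Mapping[tuple, float] = field(default_factory=dict)
    sapflow_gain_inoculated: float = 2.5  # g H2O h^-1 kPa^-1
    sapflow_gain_uninoculated: float = 1.1
    sapflow_noise_sd: float = 0.15
    swc_setpoint: float = 500.0  # capacitive-sensor units
    swc_min: float = 200.0
    swc_decay_per_day: float = 0.08
    swc_recovery_per_day: float = 0.5
    swc_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        for name in ("tleaf_noise_sd", "sapflow_noise_sd", "swc_noise_sd"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if not self.swc_min < self.swc_setpoint:
            raise DesignError("swc_min must be below swc_setpoint")
        if self.swc_decay_per_day < 0 or self.swc_recovery_per_day < 0:
            raise DesignError("SWC rates must be >= 0")

    def offset_for(self, hybrid: str, inoculation: str, regime: str) -> float:
        key = (hybrid, inoculation, regime)
        if key in self.tleaf_offset_c:
            return float(self.tleaf_offset_c[key])
        return self.tleaf_inoculated_offset_c if inoculation == "inoculated" else 0.0

    def gain_for(self, hybrid: str, inoculation: str, regime: str) -> float:
        key = (hybrid, inoculation, regime)
        if key in self.sapflow_gain:
            return float(self.sapflow_gain[key])
        return (
            self.sapflow_gain_inoculated
            if inoculation == "inoculated"
            else self.sapflow_gain_uninoculated
        )


@dataclass(frozen=True)
class OtuParams:
    """Dirichlet-multinomial OTU count model with SynCom spike-ins.

    Each sample's composition is Dirichlet-distributed around a base
    composition; in inoculated samples the expected proportions of the
    SynCom-flagged OTUs are multiplied by ``syncom_fold_change`` and
    ``n_shifted_resident`` resident OTUs by ``resident_fold_change`` (then
    renormalised).  Defaults place the inoculated-arm SynCom aggregate near
    10% of reads, the range observed in real root profiles.
    """

    n_syncom_otus: int = 23
    n_resident_otus: int = 200
    library_size: int = 50_000
    dirichlet_concentration: float = 2000.0
    syncom_base_proportion: float = 0.0005  # per SynCom OTU, uninoculated
    syncom_fold_change: float = 10.0
    n_shifted_resident: int = 20
    resident_fold_change: float = 5.0
    shifted_resident_rank_start: int = 50  # skip the dominant head

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise DesignError("library_size must be positive")
        if self.syncom_fold_change <= 0 or self.resident_fold_change <= 0:
            raise DesignError("fold changes must be > 0")
        if self.dirichlet_concentration <= 0:
            raise DesignError("dirichlet_concentration must be > 0")
        if self.shifted_resident_rank_start + self.n_shifted_resident > self.n_resident_otus:
            raise DesignError("shifted resident OTUs exceed n_resident_otus")
        if not 0 < self.syncom_base_proportion * self.n_syncom_otus < 1:
            raise DesignError("SynCom base proportions must sum inside (0, 1)")


def _default_yield_means() -> dict:
    """Per-cell mean grain yield (g/plant) anchored to the observed DS
    contrasts; WW cells show no inoculation effect."""
    means = {}
    ds = {
        ("DKB177", "inoculated"): 38.7,
        ("DKB177", "uninoculated"): 9.8,
        ("P3707VYH", "inoculated"): 42.7,
        ("P3707VYH", "uninoculated"): 12.4,
        ("SX7341", "inoculated"): 25.0,
        ("SX7341", "uninoculated"): 25.0,
    }
    for (h, i), m in ds.items():
        means[(h, i, "DS")] = m
        means[(h, i, "WW")] = 70.0
    return means


@dataclass(frozen=True)
class YieldParams:
    """Yield-component generator: cell mean + Gaussian residual.

    Biomass is generated with its own cell means so the harvest index is
    computable; phenology dates carry the drought flowering delay.
    """

    yield_cell_means_g: Mapping[tuple, float] = field(
        default_factory=_default_yield_means
    )
    yield_residual_sd_g: float = 8.0
    plants_per_cell: int = 10
    biomass_ww_mean_g: float = 200.0
    biomass_ds_mean_g: float = 150.0
    biomass_residual_sd_g: float = 20.0
    kernels_per_g: float = 3.2
    kernel_rows_mean: float = 14.0
    ear_length_ww_mm: float = 180.0
    ear_length_ds_mm: float = 120.0
    ear_diameter_ww_mm: float = 45.0
    ear_diameter_ds_mm: float = 32.0
    emergence_mean_das: float = 5.0
    emergence_sd_das: float = 0.8
    anthesis_ww_das: float = 73.0
    silking_ww_das: float = 75.0
    ds_flowering_delay_das: float = 9.0
    flowering_sd_das: float = 1.5
    flowerless_probability: Mapping[tuple, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.yield_cell_means_g.values()):
            raise DesignError("yield cell means must be >= 0")
        for name in ("yield_residual_sd_g", "biomass_residual_sd_g",
                     "emergence_sd_das", "flowering_sd_das"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if self.plants_per_cell < 2:
            raise DesignError("plants_per_cell must be >= 2")

    def mean_for(self, hybrid: str, inoculation: str, regime: str) -> float:
        key = (hybrid, inoculation, regime)
        try:
            return float(self.yield_cell_means_g[key])
        except KeyError:
            raise DesignError(f"no yield mean configured for cell {key}") from None


@dataclass(frozen=True)
class SimulationParams:
    """Bundle of all generator parameter blocks."""

    env: EnvParams = field(default_factory=EnvParams)
    physiology: PhysiologyParams = field(default_factory=PhysiologyParams)
    otu: OtuParams = field(default_factory=OtuParams)
    yields: YieldParams = field(default_factory=YieldParams)

    def replace(self, **blocks) -> "SimulationParams":
        return dataclasses.replace(self, **blocks)
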