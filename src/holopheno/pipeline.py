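"""End-to-end orchestration: simulate -> environment -> physiology ->
agronomy -> microbiome, with a reproducible manifest.

Each enabled stage writes its outputs under ``out_dir`` and registers them
in a manifest carrying row counts and SHA-256 content checksums; identical
configuration and seeds give byte-identical manifests.  Filtering decisions
(outliers removed, untestable bins/cells) are logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from . import agronomy, environment, microbiome, physiology
from .microbiome import OtuTable
from .simulate import simulate_experiment

__all__ = ["run_pipeline", "write_report", "PipelineError"]

log = logging.getLogger("holopheno")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig):
        self.data = {
            "package": "holopheno",
            "version": __version__,
            "seed": config.seed,
            "stages": {},
        }

    def add(self, stage: str, name: str, path: Path, n_rows: int | None = None) -> None:
        entry = {"path": path.name, "sha256": _sha256(path)}
        if n_rows is not None:
            entry["n_rows"] = n_rows
        self.data["stages"].setdefault(stage, {})[name] = entry

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, float_format="%.10g")
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the manifest dict.

    On stage failure a :class:`PipelineError` is raised carrying the stage
    name and the partial manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    data: dict = {}
    for stage in ("simulate", "env", "physio", "agro", "micro"):
        if stage not in config.stages:
            continue
        try:
            _STAGES[stage](config, data, out, manifest)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            manifest.write(out / "manifest.json")
            raise PipelineError(stage, manifest.data, exc) from exc
    manifest.write(out / "manifest.json")
    log.info("pipeline complete: %s", out / "manifest.json")
    return manifest.data


def _stage_simulate(config: RunConfig, data: dict, out: Path, manifest: _Manifest) -> None:
    sim = simulate_experiment(config.design, config.params, config.seed)
    data.update(sim)
    n = _write(sim["env"], out / "env_log.csv")
    manifest.add("simulate", "env_log", out / "env_log.csv", n)
    if config.write_raw:
        n = _write(sim["plants"], out / "plant_log.csv")
        manifest.add("simulate", "plant_log", out / "plant_log.csv", n)
    sim["otu"].to_tsv(out / "otu_counts.tsv", out / "otu_meta.csv")
    manifest.add("simulate", "otu_counts", out / "otu_counts.tsv")
    manifest.add("simulate", "otu_meta", out / "otu_meta.csv")
    n = _write(sim["yield"], out / "yield_table.csv")
    manifest.add("simulate", "yield_table", out / "yield_table.csv", n)


def _need(data: dict, key: str, loader, path) -> None:
    if key not in data:
        if path is None:
            raise ValueError(f"no {key} data available and no input path configured")
        data[key] = loader(path)


def _stage_env(config: RunConfig, data: dict, out: Path, manifest: _Manifest) -> None:
    _need(data, "env", environment.read_station_log, config.env_log)
    binned = environment.bin_and_average(
        data["env"], width_min=config.bin_width_min, iqr_k=config.iqr_k
    )
    removed = int(binned["n_removed"].sum())
    log.info("env stage: %d outlier points removed across bins", removed)
    data["env_binned"] = binned
    n = _write(binned, out / "env_binned.csv")
    manifest.add("env", "env_binned", out / "env_binned.csv", n)


def _stage_physio(config: RunConfig, data: dict, out: Path, manifest: _Manifest) -> None:
    _need(data, "plants", physiology.read_plant_log, config.plant_log)
    plants = data["plants"]
    deltas, areas = [], []
    for hybrid in sorted(plants["hybrid"].unique()):
        for regime in sorted(plants["regime"].unique()):
            model = physiology.TreatmentContrast(
                plants, value_col="tleaf_c", hybrid=hybrid, regime=regime
            )
            res = model.fit(
                alpha=config.alpha,
                test=config.test,
                width_min=config.bin_width_min,
                iqr_k=config.iqr_k,
                bh=config.bh,
            )
            d = res.delta.assign(hybrid=hybrid, regime=regime)
            deltas.append(d)
            a = res.area
            areas.append(
                {
                    "hybrid": hybrid,
                    "regime": regime,
                    "pos_area_aau": a.pos_area,
                    "neg_area_aau": a.neg_area,
                    "n_bins": a.n_bins,
                    "n_significant": a.n_significant,
                    "pct_significant": a.pct_significant,
                }
            )
            log.info(
                "physio: %s/%s %d/%d significant bins",
                hybrid, regime, a.n_significant, a.n_bins,
            )
    n = _write(pd.concat(deltas, ignore_index=True), out / "delta_tleaf.csv")
    manifest.add("physio", "delta_tleaf", out / "delta_tleaf.csv", n)
    n = _write(pd.DataFrame(areas), out / "tleaf_area_summary.csv")
    manifest.add("physio", "tleaf_area_summary", out / "tleaf_area_summary.csv", n)

    # sap flow: daily-window comparison over the configured DAS span
    lo, hi = config.sapflow_window_das
    sowing = config.design.sowing
    ts = pd.to_datetime(plants["timestamp"])
    das = (ts - sowing).dt.total_seconds() / 86400.0
    span = plants[(das >= lo) & (das < hi + 1)]
    sap_rows = []
    for hybrid in sorted(plants["hybrid"].unique()):
        for regime in sorted(plants["regime"].unique()):
            sub = span[(span["hybrid"] == hybrid) & (span["regime"] == regime)]
            if sub.empty:
                continue
            day = physiology.daily_window_compare(
                sub, value_col="sapflow", window=config.window, test=config.test
            ).assign(hybrid=hybrid, regime=regime)
            sap_rows.append(day)
    if sap_rows:
        n = _write(pd.concat(sap_rows, ignore_index=True), out / "sapflow_daily.csv")
        manifest.add("physio", "sapflow_daily", out / "sapflow_daily.csv", n)

    # SWC: WW vs DS per hybrid, all plants of a regime pooled as replicates
    swc_rows = []
    agg = physiology.aggregate_plant_series(
        plants, value_col="swc", width_min=config.bin_width_min, iqr_k=config.iqr_k
    )
    for hybrid in sorted(plants["hybrid"].unique()):
        mats = {}
        for regime in ("WW", "DS"):
            arms = []
            for flag in (0, 1):
                try:
                    arms.append(agg.cell_matrix(hybrid, flag, regime))
                except KeyError:
                    pass
            if arms:
                mats[regime] = pd.concat(arms, axis=1)
        if {"WW", "DS"} <= set(mats):
            common = mats["WW"].index.intersection(mats["DS"].index)
            contrast = physiology.swc_contrast(
                mats["WW"].loc[common], mats["DS"].loc[common],
                alpha=config.alpha, test=config.test,
            )
            swc_rows.append(contrast.assign(hybrid=hybrid))
    if swc_rows:
        n = _write(pd.concat(swc_rows, ignore_index=True), out / "swc_contrast.csv")
        manifest.add("physio", "swc_contrast", out / "swc_contrast.csv", n)


def _stage_agro(config: RunConfig, data: dict, out: Path, manifest: _Manifest) -> None:
    _need(data, "yield", agronomy.read_yield_table, config.yield_table)
    table = data["yield"]
    res = agronomy.yield_stats(table, "yield_g", alpha=config.alpha)
    anova = res.anova_table.reset_index(names="term")
    anova["shapiro_p"] = res.shapiro_p
    anova["levene_p"] = res.levene_p
    n = _write(anova, out / "yield_anova.csv")
    manifest.add("agro", "yield_anova", out / "yield_anova.csv", n)

    cells = (
        table.groupby(["hybrid", "inoculated", "regime"], observed=True)[
            ["yield_g", "biomass_g"]
        ]
        .mean()
        .reset_index()
    )
    cells["harvest_index_pct"] = [
        agronomy.harvest_index(g, b)
        for g, b in zip(cells["yield_g"], cells["biomass_g"])
    ]
    n = _write(cells, out / "harvest_index.csv")
    manifest.add("agro", "harvest_index", out / "harvest_index.csv", n)

    pheno = agronomy.phenology_summary(table)
    n = _write(pheno, out / "phenology.csv")
    manifest.add("agro", "phenology", out / "phenology.csv", n)
    data["yield_results"] = res


def _stage_micro(config: RunConfig, data: dict, out: Path, manifest: _Manifest) -> None:
    if "otu" not in data:
        if config.otu_counts is None or config.otu_meta is None:
            raise ValueError("no OTU data available and no input paths configured")
        data["otu"] = OtuTable.from_tsv(config.otu_counts, config.otu_meta)
    table: OtuTable = data["otu"]

    robust = microbiome.classify_robust_colonizers(
        table, alpha=config.alpha, mode=config.kw_mode, bh=config.bh
    )
    n = _write(robust, out / "robust_colonizers.csv")
    manifest.add("micro", "robust_colonizers", out / "robust_colonizers.csv", n)
    rollup = microbiome.robust_rollup(robust)
    rollup["robust_otus"] = rollup["robust_otus"].map(";".join)
    n = _write(rollup, out / "robust_rollup.csv")
    manifest.add("micro", "robust_rollup", out / "robust_rollup.csv", n)

    shifted = microbiome.classify_enriched_depleted(
        table, alpha=config.alpha, mode=config.kw_mode, bh=config.bh
    )
    n = _write(shifted, out / "resident_shifts.csv")
    manifest.add("micro", "resident_shifts", out / "resident_shifts.csv", n)

    rel = microbiome.relative_abundance(table)
    d = microbiome.bray_curtis(rel)
    d.to_csv(out / "bray_curtis.tsv", sep="\t", float_format="%.10g")
    manifest.add("micro", "bray_curtis", out / "bray_curtis.tsv")
    ord_res = microbiome.pcoa(d, k=2)
    coords = ord_res.coordinates.reset_index(names="sample")
    n = _write(coords, out / "pcoa_coordinates.csv")
    manifest.add("micro", "pcoa_coordinates", out / "pcoa_coordinates.csv", n)

    groups = table.sample_meta.loc[list(d.index), "inoculated"].to_numpy()
    ares = microbiome.anosim(d, groups, n_perm=config.n_perm, seed=config.seed)
    summary = pd.DataFrame(
        [{"R": ares.r, "p_value": ares.p_value, "n_permutations": ares.n_permutations}]
    )
    n = _write(summary, out / "anosim.csv")
    manifest.add("micro", "anosim", out / "anosim.csv", n)
    data["anosim"] = ares


_STAGES = {
    "simulate": _stage_simulate,
    "env": _stage_env,
    "physio": _stage_physio,
    "agro": _stage_agro,
    "micro": _stage_micro,
}


def write_report(out_dir, path=None) -> str:
    """Render a Markdown summary of a completed run's result classes."""
    out = Path(out_dir)
    lines = ["# holopheno run report", ""]
    areas = out / "tleaf_area_summary.csv"
    if areas.exists():
        lines += ["## Leaf-temperature significant areas", "",
                  pd.read_csv(areas).to_markdown(index=False), ""]
    anova = out / "yield_anova.csv"
    if anova.exists():
        lines += ["## Yield ANOVA (type II)", "",
                  pd.read_csv(anova).to_markdown(index=False), ""]
    hi = out / "harvest_index.csv"
    if hi.exists():
        lines += ["## Harvest index", "", pd.read_csv(hi).to_markdown(index=False), ""]
    rollup = out / "robust_rollup.csv"
    if rollup.exists():
        lines += ["## Robust SynCom colonizers", "",
                  pd.read_csv(rollup).to_markdown(index=False), ""]
    an = out / "anosim.csv"
    if an.exists():
        lines += ["## Community separation (ANOSIM)", "",
                  pd.read_csv(an).to_markdown(index=False), ""]
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text
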