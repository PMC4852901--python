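"""End-to-end orchestration: simulate (or read) → date → infer chl-a →
trends → deposition → report.

The pipeline operates on a :class:`RunConfig` (built from a YAML mapping),
runs each stage in order, and returns a :class:`ResultBundle` of pandas
tables plus provenance metadata (config hash, seed).  Deterministic stages
are byte-reproducible for a fixed config; stochastic stages are reproducible
for equal seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from paleoprod import dating, deposition, spectral, trends
from paleoprod.synthetic import (
    ClimateSimConfig,
    CoreSimConfig,
    SnowSimConfig,
    simulate_climate,
    simulate_core,
    simulate_snow_grid,
)

log = logging.getLogger("paleoprod")


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and offending lake/site id."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic mode by default)."""

    seed: int = 0
    n_lakes: int = 8
    # per-lake DBT enrichment ratios spanning the minimally/highly gradient
    dbt_ratios: list[float] = dc_field(default_factory=lambda: [0.9, 1.3, 1.7, 2.5, 4.0, 7.0, 12.0, 25.0])
    chla_breakpoint_years: list[float] | None = None
    calibration: spectral.ChlaCalibration = dc_field(default_factory=spectral.ChlaCalibration)
    ef_modern: tuple[float, float | None] = trends.DEFAULT_MODERN
    ef_baseline: tuple[float, float] = trends.DEFAULT_BASELINE
    dbt_threshold: float = trends.DBT_THRESHOLD
    breakpoint_min_edge: int = 3
    bin_width: int = 5
    core: dict[str, Any] = dc_field(default_factory=dict)  # CoreSimConfig overrides
    snow: dict[str, Any] = dc_field(default_factory=dict)  # SnowSimConfig overrides
    climate: dict[str, Any] = dc_field(default_factory=dict)  # ClimateSimConfig overrides
    cell_size_m: float = 2000.0
    radius_m: float = 50_000.0
    center: tuple[float, float] = (0.0, 0.0)
    day_normalization: tuple[float, float] | None = None  # (days_source, days_target)
    mc_draws: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cal = raw.pop("calibration", None)
        cfg = cls(**raw)
        if cal:
            cfg.calibration = spectral.ChlaCalibration(**cal)
        return cfg

    def config_hash(self) -> str:
        payload = {k: repr(v) for k, v in sorted(vars(self).items())}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    tables: dict[str, pd.DataFrame]
    scalars: dict[str, float]
    provenance: dict[str, Any]

    def bundle_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(self.tables[name].to_csv(index=False).encode())
        h.update(json.dumps(self.scalars, sort_keys=True, default=float).encode())
        return h.hexdigest()

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        (out / "run_log.json").write_text(
            json.dumps({"scalars": self.scalars, "provenance": self.provenance}, indent=2,
                       default=float)
        )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # annotate with stage + offender
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return wrapped
    return deco


@_stage("simulate")
def _simulate_cores(config: RunConfig) -> list:
    cores = []
    bps = config.chla_breakpoint_years or [
        1960 + 5 * (i % 8) for i in range(config.n_lakes)
    ]
    for i in range(config.n_lakes):
        overrides = dict(config.core)
        overrides.setdefault("chla_post_slope", 0.003)
        overrides.setdefault("chla_noise_sd", 0.004)
        core_cfg = CoreSimConfig(
            lake_id=f"LAKE-{i:02d}",
            dbt_enrichment_ratio=config.dbt_ratios[i % len(config.dbt_ratios)],
            chla_breakpoint_year=bps[i % len(bps)],
            calibration=config.calibration,
            seed=config.seed + 17 * i + 1,
            **overrides,
        )
        cores.append(simulate_core(core_cfg))
    return cores


@_stage("date")
def _date_cores(cores, config: RunConfig):
    models, chron_rows, cs_rows = {}, [], []
    for core in cores:
        try:
            profile = dating.RadionuclideProfile.from_frame(core.intervals)
            model = dating.crs_age_model(
                profile, core.coring_year, mc_draws=config.mc_draws, seed=config.seed
            )
            model = dating.extrapolate_below_background(model, profile)
            model = dating.fit_age_depth_polynomial(model)
            peak = dating.locate_cs137_peak(profile, model)
        except Exception as exc:
            raise PipelineError(f"lake {core.lake_id}: {exc}") from exc
        models[core.lake_id] = model
        chron_rows.append(dating.chronology_frame(model))
        cs_rows.append(
            {
                "lake_id": core.lake_id,
                "cs137_peak_found": peak.found,
                "cs137_peak_year": peak.crs_year,
                "cs137_validated": peak.validated,
            }
        )
    return models, pd.concat(chron_rows, ignore_index=True), pd.DataFrame(cs_rows)


@_stage("chla")
def _infer_chla(cores, models, config: RunConfig) -> pd.DataFrame:
    rows = []
    for core in cores:
        model = models[core.lake_id]
        chla, censored = spectral.infer_profile(
            core.wavelength_nm, core.reflectance, config.calibration
        )
        rows.append(
            pd.DataFrame(
                {
                    "lake_id": core.lake_id,
                    "year": model.smoothed_year,
                    "chla_mg_g": chla,
                    "censored": censored,
                    "dbt_ng_g": core.intervals["dbt_ng_g"].to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@_stage("trends")
def _trend_analysis(profiles: pd.DataFrame, config: RunConfig, climate: pd.DataFrame):
    ef_rows, bp_rows, dbt_efs = [], [], {}
    for lake_id, grp in profiles.groupby("lake_id", sort=True):
        years = grp["year"].to_numpy()
        chla = grp["chla_mg_g"].to_numpy()
        for variant in trends.EF_VARIANTS:
            try:
                r = trends.enrichment_factor(
                    years, chla, modern=config.ef_modern, baseline=config.ef_baseline,
                    variant=variant, lake_id=lake_id,
                )
            except trends.WindowError:
                continue
            ef_rows.append(
                {"lake_id": lake_id, "variant": variant, "ef": r.ef,
                 "n_modern": r.n_modern, "n_baseline": r.n_baseline}
            )
        dbt_r = trends.dbt_enrichment_factor(
            years, grp["dbt_ng_g"].to_numpy(), modern=config.ef_modern,
            baseline=config.ef_baseline, lake_id=lake_id,
        )
        dbt_efs[lake_id] = dbt_r.ef if dbt_r is not None else None
        bp = trends.fit_breakpoint(
            years, chla, min_edge=config.breakpoint_min_edge, lake_id=lake_id
        )
        bp_rows.append(
            {"lake_id": lake_id, "applicable": bp.applicable, "tau": bp.tau,
             "tau_se": bp.tau_se, "slope_pre": bp.slope_pre, "slope_post": bp.slope_post,
             "f_stat": bp.f_stat, "p_value": bp.p_value, "n": bp.n, "reason": bp.reason}
        )

    classes = trends.classify_sites(dbt_efs, threshold=config.dbt_threshold)
    class_df = pd.DataFrame(
        [{"lake_id": c.lake_id, "dbt_ef": c.dbt_ef, "group": c.group} for c in classes]
    )

    # group composites: per-lake Z scores, pooled into 5-yr bins per group
    zrows = []
    for lake_id, grp in profiles.groupby("lake_id", sort=True):
        z = trends.zscores(grp["chla_mg_g"].to_numpy())
        zrows.append(pd.DataFrame({"lake_id": lake_id, "year": grp["year"].to_numpy(), "z": z}))
    zdf = pd.concat(zrows, ignore_index=True).merge(class_df[["lake_id", "group"]], on="lake_id")

    corr_rows = []
    group_sets = {"all": zdf}
    for g in ("minimally", "highly"):
        sub = zdf[zdf["group"] == g]
        if len(sub):
            group_sets[g] = sub
    for gname, sub in group_sets.items():
        binned_z = trends.bin_5yr(sub["year"].to_numpy(), sub["z"].to_numpy(), config.bin_width)
        for season in ("annual", "winter", "spring", "summer", "fall"):
            binned_t = trends.bin_5yr(
                climate["year"].to_numpy(), climate[f"temp_{season}"].to_numpy(), config.bin_width
            )
            merged = binned_z.merge(binned_t, on="bin_start", suffixes=("_z", "_t"))
            if len(merged) < 3:
                continue
            r, p, n = trends.pearson_with_p(
                merged["mean_z"].to_numpy(), merged["mean_t"].to_numpy()
            )
            corr_rows.append({"group": gname, "season": season, "r": r, "p": p, "n_bins": n})

    return (
        pd.DataFrame(ef_rows),
        pd.DataFrame(bp_rows),
        class_df,
        pd.DataFrame(corr_rows),
        zdf,
    )


@_stage("deposition")
def _deposition(config: RunConfig):
    snow_cfg = SnowSimConfig(seed=config.seed + 101, **config.snow)
    survey = simulate_snow_grid(snow_cfg)
    coords = survey.sites[["x_m", "y_m"]].to_numpy()
    loading = survey.sites["loading_mg_m2"].to_numpy()
    vario = deposition.fit_variogram(coords, loading)
    extent = snow_cfg.extent_km * 1000.0
    grid = deposition.GridSpec.covering(-extent, extent, -extent, extent, config.cell_size_m)
    field = deposition.ordinary_kriging(coords, loading, vario, grid, analyte="TN")
    tonnes = deposition.integrate_radius(field, config.center, config.radius_m)
    if config.day_normalization:
        tonnes_norm = deposition.day_normalize(tonnes, *config.day_normalization)
    else:
        tonnes_norm = tonnes
    cv = deposition.cross_validate(coords, loading, vario)
    summary = deposition.cv_summary(cv)
    dep_table = pd.DataFrame(
        [
            {
                "analyte": "TN",
                "tonnes_within_radius": tonnes,
                "tonnes_day_normalized": tonnes_norm,
                "radius_m": config.radius_m,
                "variogram_model": vario.model,
                "nugget": vario.nugget,
                "sill": vario.sill,
                "range_m": vario.range_m,
                "cv_rmse": summary["rmse"],
                "cv_mean_error": summary["mean_error"],
            }
        ]
    )
    return survey.sites, field, dep_table


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> ResultBundle:
    """Execute the full chain on synthetic data; see module docstring."""
    cores = _simulate_cores(config)
    models, chronology, cs_table = _date_cores(cores, config)
    profiles = _infer_chla(cores, models, config)
    climate = simulate_climate(ClimateSimConfig(seed=config.seed + 501, **config.climate))
    efs, bps, classes, correlations, zdf = _trend_analysis(profiles, config, climate)
    snow_sites, field, dep_table = _deposition(config)

    truth = pd.DataFrame(
        [
            {
                "lake_id": c.lake_id,
                "true_breakpoint_year": c.config.chla_breakpoint_year,
                "true_dbt_ratio": c.config.dbt_enrichment_ratio,
            }
            for c in cores
        ]
    )
    bundle = ResultBundle(
        tables={
            "chronology": chronology,
            "cs137_validation": cs_table,
            "chla_profiles": profiles,
            "enrichment_factors": efs,
            "breakpoints": bps,
            "classification": classes,
            "climate_correlations": correlations,
            "zscores": zdf,
            "snow_sites": snow_sites,
            "deposition": dep_table,
            "simulation_truth": truth,
            "loading_field": field.to_frame(),
        },
        scalars={"n_lakes": float(config.n_lakes)},
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package": "paleoprod 0.1.0",
        },
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def report_summary(bundle: ResultBundle) -> str:
    """Human-readable report mirroring the layout of multi-lake result tables:
    EF summaries by group, a breakpoint timeline ordered by DBT EF, climate
    correlations, and deposition tonnages."""
    lines = ["# paleoprod run summary", ""]
    cls = bundle.tables.get("classification")
    efs = bundle.tables.get("enrichment_factors")
    if cls is not None and efs is not None and len(efs):
        primary = efs[efs["variant"] == "primary"].merge(cls, on="lake_id")
        lines.append("## Chl-a enrichment factors by DBT group")
        for g, sub in primary.groupby("group"):
            lines.append(
                f"  {g:>12}: n={len(sub)}, mean EF={sub['ef'].mean():.2f}, "
                f"range {sub['ef'].min():.2f}-{sub['ef'].max():.2f}"
            )
        lines.append("")
    bps = bundle.tables.get("breakpoints")
    if bps is not None and cls is not None:
        ordered = bps.merge(cls, on="lake_id").sort_values("dbt_ef")
        lines.append("## Breakpoint timeline (ordered by DBT EF)")
        for row in ordered.itertuples():
            if row.applicable and row.tau is not None and np.isfinite(row.tau):
                lines.append(
                    f"  {row.lake_id}: tau={row.tau:.1f} +/- {row.tau_se:.1f} "
                    f"(DBT EF {row.dbt_ef:.1f}, p={row.p_value:.3g})"
                )
            else:
                lines.append(f"  {row.lake_id}: breakpoint not applied ({row.reason})")
        lines.append("")
    corr = bundle.tables.get("climate_correlations")
    if corr is not None and len(corr):
        lines.append("## Climate correlations (5-yr binned Z scores vs temperature)")
        for row in corr.itertuples():
            star = "*" if row.p < 0.05 else " "
            lines.append(f"  {row.group:>10} {row.season:>7}: r={row.r:+.2f}{star} (p={row.p:.3g})")
        lines.append("")
    dep = bundle.tables.get("deposition")
    if dep is not None and len(dep):
        lines.append("## Deposition within radius")
        for row in dep.itertuples():
            lines.append(
                f"  {row.analyte}: {row.tonnes_within_radius:.1f} t within "
                f"{row.radius_m/1000:.0f} km (day-normalized {row.tonnes_day_normalized:.1f} t)"
            )
    else:
        lines.append("## Deposition: not run")
    return "\n".join(lines) + "\n"


def table1_report() -> str:
    """Report of the shipped printed-table fixture (group counts, EF summary)."""
    s = trends.fixture_summary()
    return (
        "# Printed-table fixture summary\n"
        f"sites: {s['n_sites']}\n"
        f"chl-a EF mean {s['chla_ef_mean']:.2f} (range {s['chla_ef_min']:.1f}-{s['chla_ef_max']:.1f})\n"
        f"DBT EF range {s['dbt_ef_min']:.1f}-{s['dbt_ef_max']:.1f}\n"
        f"groups: {s['n_minimally']} minimally / {s['n_highly']} highly / "
        f"{s['n_undetermined']} undetermined\n"
        f"breakpoint-eligible: {s['n_breakpoint_minimally']} minimally, "
        f"{s['n_breakpoint_highly']} highly\n"
        f"Welch t={s['welch_t']:.2f} (df={s['welch_df']:.1f}, p={s['welch_p']:.2f})\n"
    )
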