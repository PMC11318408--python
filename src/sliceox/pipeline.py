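"""End-to-end orchestration: synthetic cohort -> fits -> features -> maps -> stats.

A single schema-validated configuration drives a deterministic run: it
generates (or loads) data, estimates CMRO2 from depth profiles in both
acquisition designs, extracts SD features and time-resolved CMRO2 from
episodes, produces perivascular oxygenation maps for the configured CMRO2
scenarios, runs the paired statistics, and writes a provenance-stamped
report.  Stages run independently where possible; a failing stage is
recorded in the report and does not abort the others.

Run-directory layout::

    <out>/inputs/    generated traces and profiles
    <out>/fits/      CMRO2 fits and series
    <out>/features/  per-event SD features
    <out>/maps/      oxygenation maps and boundary curves
    <out>/stats/     paired comparison tables
    <out>/report.json

Every tabular output carries the configuration hash on a leading comment
line, and re-running with the same configuration and seed reproduces every
output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .cmro2 import FitConfig, excess_cmro2_auc, fit_cmro2, fit_cmro2_timeseries
from .diffusion import SliceModelParams, ValidationError
from .krogh import KroghScanConfig, oxygenation_map
from .sd_traces import FeatureConfig
from .stats import bonferroni_adjust, summarize_median_iqr, wilcoxon_signed_rank
from .synth import (
    SdScenarioParams,
    generate_depth_profile,
    generate_paired_cohort,
    generate_sd_episode,
)

__all__ = ["PipelineConfig", "run_experiment_pipeline"]

log = logging.getLogger("sliceox.pipeline")


def _package_version() -> str:
    from . import __version__

    return __version__


class SliceModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    surface_po2: float = Field(gt=0)
    domain_depth: float = Field(default=160.0, gt=0)
    diffusion_constant: float = Field(default=1600.0, gt=0)
    km: float = Field(default=3.0, gt=0)
    layer_thickness: float = Field(default=1.0, gt=0)

    def to_params(self) -> SliceModelParams:
        return SliceModelParams(**self.model_dump())


class KroghConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    capillary_radius: float = Field(default=2.5, gt=0)
    shell_thickness: float = Field(default=0.5, gt=0)
    diffusion_constant: float = Field(default=1600.0, gt=0)
    km: float = Field(default=3.0, gt=0)
    hypoxia_threshold: float = Field(default=8.0, gt=0)

    def to_scan_config(self, radius_min: float, radius_max: float, radius_step: float) -> KroghScanConfig:
        return KroghScanConfig(
            radius_min=radius_min,
            radius_max=radius_max,
            radius_step=radius_step,
            **self.model_dump(),
        )


class MapGridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    capillary_po2_min: float = Field(default=20.0, gt=0)
    capillary_po2_max: float = Field(default=55.0, gt=0)
    capillary_po2_step: float = Field(default=5.0, gt=0)
    radius_min: float = Field(default=10.0, gt=0)
    radius_max: float = Field(default=35.0, gt=0)
    radius_step: float = Field(default=1.0, gt=0)

    def capillary_po2_grid(self) -> np.ndarray:
        n = int(round((self.capillary_po2_max - self.capillary_po2_min) / self.capillary_po2_step))
        return self.capillary_po2_min + np.arange(n + 1) * self.capillary_po2_step

    def radius_grid(self) -> np.ndarray:
        n = int(round((self.radius_max - self.radius_min) / self.radius_step))
        return self.radius_min + np.arange(n + 1) * self.radius_step


class MapScenarioConfig(BaseModel):
    """CMRO2 operating points (mmHg/s) for one condition's oxygenation maps."""

    model_config = ConfigDict(extra="forbid")
    baseline_cmro2: float = Field(gt=0)
    sd_cmro2: float = Field(gt=0)


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    baseline_cmro2: float = Field(default=34.4, gt=0)
    peak_ratio: float = Field(default=2.7, ge=1)
    cmro2_rise_tau: float = Field(default=10.0, gt=0)
    cmro2_decay_tau: float = Field(default=120.0, gt=0)
    dc_amplitude: float = Field(default=15.0, gt=0)
    dc_duration: float = Field(default=43.0, gt=0)
    delta_k: float = Field(default=22.6, gt=0)
    t1_50: float = Field(default=20.0, gt=0)
    t2_50: float = Field(default=65.0, gt=0)
    onset: float = Field(default=60.0, gt=0)
    sampling_rate: float = Field(default=10.0, gt=0)
    noise_sd_po2: float = Field(default=1.0, ge=0)
    noise_sd_dc: float = Field(default=0.2, ge=0)
    noise_sd_k_voltage: float = Field(default=0.2, ge=0)

    def to_params(self, seed: int) -> SdScenarioParams:
        return SdScenarioParams(**self.model_dump(), seed=seed)


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_slices: int = Field(default=12, ge=1)
    slice_effect_sd: float = Field(default=0.3, ge=0)
    episode_effect_sd: float = Field(default=0.1, ge=0)
    synthesize: bool = False
    depths: list[float] = Field(default=[40.0, 100.0, 160.0], min_length=3)
    duration_s: float = Field(default=420.0, gt=0)


class FitSectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    smoothing_window_s: float = Field(default=1.0, ge=0)
    baseline_window: tuple[float, float] = (0.0, 30.0)
    stride: int = Field(default=1, ge=1)
    bounds: tuple[float, float] = (0.0, 500.0)
    xtol: float = Field(default=1e-3, gt=0)
    profile_noise_sd: float = Field(default=1.0, ge=0)
    auc_horizon_s: float = Field(default=300.0, gt=0)


class StatsSectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    m_comparisons: int = Field(default=2, ge=1)
    method: str = "auto"
    features: list[str] = Field(default=["delta_k", "dc_duration", "t1_50", "t2_50"])

    @field_validator("method")
    @classmethod
    def _check_method(cls, v: str) -> str:
        if v not in ("auto", "exact", "approx"):
            raise ValueError("method must be one of auto/exact/approx")
        return v


class PipelineConfig(BaseModel):
    """Fully validated configuration of one end-to-end run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    slice_model: SliceModelConfig
    krogh: KroghConfig = KroghConfig()
    map_grid: MapGridConfig = MapGridConfig()
    map_scenarios: dict[str, MapScenarioConfig] = Field(default_factory=dict)
    episode: ScenarioConfig = ScenarioConfig()
    treated_episode: ScenarioConfig = ScenarioConfig()
    cohort: CohortConfig = CohortConfig()
    fit: FitSectionConfig = FitSectionConfig()
    stats: StatsSectionConfig = StatsSectionConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str, sep: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False, sep=sep)


def _write_json(payload: dict, path: Path, cfg_hash: str) -> None:
    payload = {"config_hash": cfg_hash, **payload}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _stage_depth_profiles(config: PipelineConfig, out: Path, cfg_hash: str,
                          seeds: list[int]) -> dict:
    """Multi-step vs three-point CMRO2 fits on the same synthetic slices."""
    sp = config.slice_model.to_params()
    core = sp.domain_depth
    multi_depths = np.arange(20.0, core + 1e-9, 20.0)
    three_depths = np.array(sorted(config.cohort.depths))
    rows = []
    for i in range(config.cohort.n_slices):
        cmro2_true = config.episode.baseline_cmro2
        prof_m, _ = generate_depth_profile(
            cmro2_true, sp, multi_depths, config.fit.profile_noise_sd, seeds[2 * i]
        )
        prof_3, _ = generate_depth_profile(
            cmro2_true, sp, three_depths, config.fit.profile_noise_sd, seeds[2 * i + 1]
        )
        fit_m = fit_cmro2(prof_m, sp, use_shallowest_as_surface=True,
                          bounds=config.fit.bounds, xtol=config.fit.xtol)
        fit_3 = fit_cmro2(prof_3, sp, bounds=config.fit.bounds, xtol=config.fit.xtol)
        rows.append(
            {
                "slice_id": i,
                "true_cmro2": cmro2_true,
                "multi_step_cmro2": fit_m.estimate,
                "three_point_cmro2": fit_3.estimate,
                "multi_step_sse": fit_m.sse,
                "three_point_sse": fit_3.sse,
            }
        )
    df = pd.DataFrame(rows)
    _write_table(df, out / "fits" / "depth_profile_fits.csv", cfg_hash)
    diffs = (df["multi_step_cmro2"] - df["three_point_cmro2"]).to_numpy()
    comparison = wilcoxon_signed_rank(diffs, labels=("multi_step", "three_point"),
                                      method=config.stats.method)
    return {
        "n_slices": int(len(df)),
        "multi_step": summarize_median_iqr(df["multi_step_cmro2"]),
        "three_point": summarize_median_iqr(df["three_point_cmro2"]),
        "design_comparison": comparison.to_dict(),
    }


def _stage_episodes(config: PipelineConfig, out: Path, cfg_hash: str, seed: int) -> dict:
    """Paired cohort features plus an exemplar time-resolved CMRO2 series."""
    sp = config.slice_model.to_params()
    cohort_df, truth = generate_paired_cohort(
        config.episode.to_params(seed),
        config.treated_episode.to_params(seed + 1),
        config.cohort.n_slices,
        seed=seed,
        slice_effect_sd=config.cohort.slice_effect_sd,
        episode_effect_sd=config.cohort.episode_effect_sd,
        synthesize=config.cohort.synthesize,
        slice_params=sp,
        depths=tuple(config.cohort.depths),
        duration_s=config.cohort.duration_s,
        feature_config=FeatureConfig(hypoxia_threshold=config.krogh.hypoxia_threshold),
    )
    _write_table(cohort_df, out / "features" / "cohort_features.csv", cfg_hash)

    summary: dict = {"n_rows": int(len(cohort_df)), "ground_truth": {
        "control": truth["control"], "treated": truth["treated"]}}

    # exemplar control episode: trace, features, time-resolved CMRO2, AUC
    scenario = config.episode.to_params(seed)
    traces, gt = generate_sd_episode(
        scenario, sp, tuple(config.cohort.depths), config.cohort.duration_s
    )
    _write_table(traces.to_frame(), out / "inputs" / "exemplar_episode.csv", cfg_hash)
    fit_cfg = FitConfig(
        surface_po2=sp.surface_po2,
        smoothing_window_s=config.fit.smoothing_window_s,
        baseline_window=config.fit.baseline_window,
        stride=config.fit.stride,
        bounds=config.fit.bounds,
        xtol=config.fit.xtol,
    )
    series = fit_cmro2_timeseries(traces, fit_cfg, core_depth=sp.domain_depth,
                                  diffusion_constant=sp.diffusion_constant,
                                  km=sp.km, layer_thickness=sp.layer_thickness)
    series.onset = scenario.onset
    _write_table(series.to_frame(), out / "fits" / "exemplar_cmro2_series.csv", cfg_hash)
    auc = excess_cmro2_auc(series, horizon=config.fit.auc_horizon_s, onset=scenario.onset)
    peak = float(series.estimates.max())
    summary["exemplar"] = {
        "baseline_cmro2_mmHg_per_s": series.baseline,
        "peak_cmro2_mmHg_per_s": peak,
        "peak_to_baseline_ratio": peak / series.baseline if series.baseline else None,
        "true_peak_ratio": scenario.peak_ratio,
        "excess_auc_mmHg": auc,
    }
    return summary


def _stage_maps(config: PipelineConfig, out: Path, cfg_hash: str) -> dict:
    pc_grid = config.map_grid.capillary_po2_grid()
    r_grid = config.map_grid.radius_grid()
    scan = config.krogh.to_scan_config(
        config.map_grid.radius_min, config.map_grid.radius_max, config.map_grid.radius_step
    )
    summary = {}
    for name, sc in config.map_scenarios.items():
        for phase, m in (("baseline", sc.baseline_cmro2), ("sd", sc.sd_cmro2)):
            tmap = oxygenation_map(pc_grid, r_grid, m, scan)
            _write_table(tmap.to_frame(), out / "maps" / f"{name}_{phase}_map.csv", cfg_hash)
            (out / "maps" / f"{name}_{phase}_boundary.json").write_text(
                tmap.boundary_to_json()
            )
            curve = [b.radius if b.within_scan else b.status for b in tmap.boundary_curve]
            summary[f"{name}_{phase}"] = {
                "cmro2_mmHg_per_s": m,
                "boundary_radius_um_at_lowest_po2": curve[0],
            }
    return summary


def _stage_stats(config: PipelineConfig, out: Path, cfg_hash: str,
                 cohort_path: Path) -> dict:
    df = pd.read_csv(cohort_path, comment="#")
    control = df[df["condition"] == "control"].set_index("slice_id")
    treated = df[df["condition"] == "treated"].set_index("slice_id")
    rows = []
    for feature in config.stats.features:
        if feature not in df.columns:
            continue
        diffs = (treated[feature] - control[feature]).dropna().to_numpy()
        comp = wilcoxon_signed_rank(diffs, labels=("treated", "control"),
                                    method=config.stats.method)
        comp = comp.adjusted(config.stats.m_comparisons)
        s_c = summarize_median_iqr(control[feature].dropna())
        s_t = summarize_median_iqr(treated[feature].dropna())
        rows.append(
            {
                "feature": feature,
                "control_median": s_c["median"],
                "control_q25": s_c["q25"],
                "control_q75": s_c["q75"],
                "treated_median": s_t["median"],
                "treated_q25": s_t["q25"],
                "treated_q75": s_t["q75"],
                "n": comp.n_nonzero,
                "W": comp.statistic,
                "p_raw": comp.p_raw,
                "p_adjusted": comp.p_adjusted,
                "method": comp.method,
            }
        )
    table = pd.DataFrame(rows)
    _write_table(table, out / "stats" / "paired_comparisons.tsv", cfg_hash, sep="\t")
    return {"comparisons": table.to_dict(orient="records")}


def run_experiment_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages under ``out_dir`` and return the run report.

    The report (also written to ``<out_dir>/report.json``) contains one
    section per stage — depth-profile fits, episodes/features, oxygenation
    maps, paired statistics — plus a provenance block with the configuration
    hash, package and library versions and the seed.  Stage failures are
    recorded under ``errors`` without aborting independent stages.
    """
    out = Path(out_dir)
    for sub in ("inputs", "fits", "features", "maps", "stats"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    rng = np.random.SeedSequence(config.seed)
    profile_seeds = [int(c.generate_state(1)[0] % (2**31))
                     for c in rng.spawn(2 * config.cohort.n_slices)]

    import scipy

    report: dict = {
        "provenance": {
            "config_hash": cfg_hash,
            "config": config.model_dump(mode="json"),
            "seed": config.seed,
            "package_version": _package_version(),
            "numpy_version": np.__version__,
            "scipy_version": scipy.__version__,
        },
        "errors": {},
    }

    stages = [
        ("depth_profile_fits", lambda: _stage_depth_profiles(config, out, cfg_hash, profile_seeds)),
        ("episodes", lambda: _stage_episodes(config, out, cfg_hash, config.seed)),
        ("oxygenation_maps", lambda: _stage_maps(config, out, cfg_hash)),
        ("paired_statistics", lambda: _stage_stats(config, out, cfg_hash,
                                                   out / "features" / "cohort_features.csv")),
    ]
    for name, fn in stages:
        try:
            log.info("stage %s: starting", name)
            report[name] = fn()
            log.info("stage %s: done", name)
        except Exception as exc:  # stage isolation: record, continue
            log.exception("stage %s failed", name)
            report["errors"][name] = f"{type(exc).__name__}: {exc}"

    _write_json({k: v for k, v in report.items() if k != "provenance"} |
                {"provenance": report["provenance"]}, out / "report.json", cfg_hash)
    return report
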