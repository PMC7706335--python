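"""Configuration-driven end-to-end pipeline runner.

Ties the stages together in processing order — simulate (or ingest),
multiview aggregation, feature extraction, time-point traits, spatial
correction, dynamic modelling — with a validated YAML configuration, a run
manifest carrying checksums of every output, and stage-level resume from
cached outputs.  Deterministic stages are pure functions of
(inputs, config, seed): rerunning with an identical config reproduces
outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, multiview_core, stat_genetics, synthetic_field, trait_extraction

logger = logging.getLogger("mvgc")

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline",
           "DEFAULT_CONFIG", "write_fixture_config"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "output_dir": "mvgc_run",
    "stages": ["simulate", "multiview", "traits", "stats"],
    "trial": {
        "n_genotypes": 4,
        "n_reps": 2,
        "year_sites": ["Y1"],
        "n_campaigns": 12,
        "gs30_mean_gdd": 612.0,
        "gs30_spread_days": 20.0,
    },
    "render": {
        "n_views": 12,
        "effective_gsd_mm": 2.0,
        "erectness_jitter_px": 2.0,
        "plot_l_mm": 1000.0,
        "plot_w_mm": 375.0,
    },
    "traits": {
        "watershed": {"i_thresh": 0.10, "i_peak": 0.30, "d_min": 12},  # 25 mm / 2 mm eff. GSD
        "gs30": {"cost": 32.0, "gamma": 0.125, "window": 20.0},
        "shoots": {"max_cover": 0.90, "aggregation_window": 12.5},
    },
    "statgen": {"knots_factor": 0.6667, "reps_to_use": None},
}

_SCHEMA = {
    "seed": int,
    "output_dir": str,
    "stages": list,
    "trial": {
        "n_genotypes": int, "n_reps": int, "year_sites": list, "n_campaigns": int,
        "gs30_mean_gdd": (int, float), "gs30_spread_days": (int, float),
        "phyllochron_range": list, "t0_range": list, "leaf_area_range": list,
    },
    "render": {
        "n_views": int, "effective_gsd_mm": (int, float),
        "erectness_jitter_px": (int, float),
        "plot_l_mm": (int, float), "plot_w_mm": (int, float),
    },
    "traits": {
        "watershed": {"i_thresh": (int, float), "i_peak": (int, float), "d_min": int},
        "gs30": {"cost": (int, float), "gamma": (int, float), "window": (int, float)},
        "shoots": {"max_cover": (int, float), "aggregation_window": (int, float)},
    },
    "statgen": {"knots_factor": (int, float), "reps_to_use": (int, type(None))},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see :data:`DEFAULT_CONFIG` for keys)."""

    data: dict

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        merged = _deep_merge(DEFAULT_CONFIG, raw)
        report = validate_config_dict(merged)
        if report:
            raise ValueError("invalid config:\n" + "\n".join(report))
        return cls(data=merged)

    @classmethod
    def default(cls, **overrides) -> "PipelineConfig":
        merged = _deep_merge(DEFAULT_CONFIG, overrides)
        report = validate_config_dict(merged)
        if report:
            raise ValueError("invalid config:\n" + "\n".join(report))
        return cls(data=merged)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _deep_merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if k in override and isinstance(v, dict) and isinstance(override[k], dict):
            out[k] = _deep_merge(v, override[k])
        elif k in override:
            out[k] = override[k]
        else:
            out[k] = v
    for k in override:
        if k not in base:
            out[k] = override[k]  # flagged by validation
    return out


def _check_keys(d: dict, schema: dict, prefix: str, errors: list) -> None:
    for k, v in d.items():
        if k not in schema:
            errors.append(f"unknown config key: {prefix}{k}")
            continue
        spec = schema[k]
        if isinstance(spec, dict):
            if not isinstance(v, dict):
                errors.append(f"{prefix}{k} must be a mapping")
            else:
                _check_keys(v, spec, f"{prefix}{k}.", errors)
        elif v is not None and spec is not list and not isinstance(v, spec):
            if not (spec is int and isinstance(v, bool) is False and isinstance(v, int)):
                errors.append(f"{prefix}{k} has wrong type {type(v).__name__}")


def validate_config_dict(cfg: dict) -> list[str]:
    """Schema + invariant check; returns a list of violations (empty = valid)."""
    errors: list[str] = []
    _check_keys(cfg, _SCHEMA, "", errors)

    ws = cfg.get("traits", {}).get("watershed", {})
    if ws and not (0 < ws.get("i_thresh", 0.1) <= ws.get("i_peak", 0.3) <= 1):
        errors.append("traits.watershed: need 0 < i_thresh <= i_peak <= 1")
    if ws and ws.get("d_min", 1) < 1:
        errors.append("traits.watershed: d_min must be >= 1")
    g = cfg.get("traits", {}).get("gs30", {})
    if g and (g.get("cost", 1) <= 0 or g.get("gamma", 1) <= 0):
        errors.append("traits.gs30: cost and gamma must be > 0")
    tr = cfg.get("trial", {})
    if "phyllochron_range" in tr and min(tr["phyllochron_range"]) <= 0:
        errors.append("trial.phyllochron_range: phyllochron must be > 0")
    sh = cfg.get("traits", {}).get("shoots", {})
    if sh and not (0 < sh.get("max_cover", 0.9) <= 1):
        errors.append("traits.shoots: max_cover must be in (0, 1]")
    return errors


def validate_config(path) -> list[str]:
    """Validate a YAML config file; returns the violation report (empty = valid)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config_dict(_deep_merge(DEFAULT_CONFIG, raw))


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    version: str
    outputs: dict = field(default_factory=dict)   # path -> sha256
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    completed_stages: list = field(default_factory=list)

    def record(self, path: Path) -> None:
        self.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=1, default=str))


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    # full precision so cached stages resume bit-identically
    df.to_csv(path, index=False, float_format="%.17g")
    manifest.record(path)


def run_pipeline(config: PipelineConfig, resume: bool = False) -> RunManifest:
    """Execute the configured stages in order and write the run manifest.

    Stage outputs land in ``output_dir``; with ``resume=True`` a stage whose
    outputs already exist is skipped.  A stage failure records partial
    completion in the manifest and re-raises.
    """
    cfg = config.data
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.hash(), version=__version__)
    state: dict = {}
    try:
        for stage in cfg["stages"]:
            t0 = time.time()
            fn = _STAGES.get(stage)
            if fn is None:
                raise ValueError(f"unknown stage {stage!r}")
            logger.info("stage %s starting", stage)
            fn(cfg, out, state, manifest, resume)
            manifest.completed_stages.append(stage)
            manifest.timings[stage] = round(time.time() - t0, 3)
            logger.info("stage %s done in %.1fs", stage, manifest.timings[stage])
    finally:
        manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, out, state, manifest, resume):
    tr = cfg["trial"]
    cache = [out / f for f in ("truth_plots.csv", "truth_shoot_series.csv",
                               "truth_plants.csv", "genotype_params.json")]
    if resume and all(p.exists() for p in cache):
        truth = _load_cached_truth(out)
        state["truth"] = truth
        for p in cache:
            manifest.record(p)
        logger.info("simulate: resumed from cached truth tables")
        return
    param_ranges = {}
    if "phyllochron_range" in tr:
        param_ranges["phyllochron"] = tuple(tr["phyllochron_range"])
    if "t0_range" in tr:
        param_ranges["t0"] = tuple(tr["t0_range"])
    if "leaf_area_range" in tr:
        param_ranges["leaf_area_mm2"] = tuple(tr["leaf_area_range"])
    truth = synthetic_field.make_trial(
        n_genotypes=tr["n_genotypes"],
        n_reps=tr["n_reps"],
        year_sites=tuple(tr["year_sites"]),
        n_campaigns=tr["n_campaigns"],
        gs30_mean_gdd=tr["gs30_mean_gdd"],
        gs30_spread_days=tr["gs30_spread_days"],
        seed=cfg["seed"],
        param_ranges=param_ranges or None,
    )
    state["truth"] = truth
    _write_csv(truth.plots, out / "truth_plots.csv", manifest)
    _write_csv(truth.shoot_series, out / "truth_shoot_series.csv", manifest)
    plants_rows = []
    for plot_id, plants in truth.plants_by_plot.items():
        for p in plants:
            plants_rows.append((plot_id, p.x_mm, p.y_mm, p.genotype.name,
                                p.emergence_jitter_gdd))
    plants_df = pd.DataFrame(
        plants_rows,
        columns=["plot_id", "x_mm", "y_mm", "genotype", "emergence_jitter_gdd"],
    )
    truth.plants = plants_df[["plot_id", "x_mm", "y_mm", "genotype"]]
    _write_csv(plants_df, out / "truth_plants.csv", manifest)
    params_path = out / "genotype_params.json"
    params_path.write_text(json.dumps(
        {name: {k: v for k, v in g.__dict__.items()}
         for name, g in truth.genotype_params.items()}, indent=1))
    manifest.record(params_path)


def _load_cached_truth(out):
    """Rebuild the in-memory trial truth from the simulate stage's outputs."""
    from .synthetic_field import FieldTruth, GenotypeParams, SimPlant

    plots = pd.read_csv(out / "truth_plots.csv", float_precision="round_trip")
    series = pd.read_csv(out / "truth_shoot_series.csv", float_precision="round_trip")
    plants_df = pd.read_csv(out / "truth_plants.csv", float_precision="round_trip")
    params = {
        name: GenotypeParams(**fields)
        for name, fields in json.loads((out / "genotype_params.json").read_text()).items()
    }
    plants_by_plot = {}
    for plot_id, grp in plants_df.groupby("plot_id", sort=False):
        plants_by_plot[plot_id] = [
            SimPlant(plot_id=plot_id, x_mm=r.x_mm, y_mm=r.y_mm,
                     genotype=params[r.genotype],
                     emergence_jitter_gdd=getattr(r, "emergence_jitter_gdd", 0.0))
            for r in grp.itertuples()
        ]
    truth = FieldTruth(
        plants=plants_df[["plot_id", "x_mm", "y_mm", "genotype"]],
        plots=plots,
        shoot_series=series,
        genotype_params=params,
    )
    truth.plants_by_plot = plants_by_plot
    truth.gdd_grid = np.sort(series["gdd"].unique())
    return truth


def _stage_multiview(cfg, out, state, manifest, resume):
    truth = state["truth"]
    cache = [out / "timepoint_features.csv", out / "watershed_regions.csv"]
    if resume and all(p.exists() for p in cache):
        state["timepoints"] = pd.read_csv(cache[0], float_precision="round_trip")
        state["regions"] = pd.read_csv(cache[1], float_precision="round_trip")
        for p in cache:
            manifest.record(p)
        logger.info("multiview: resumed from cached feature tables")
        return
    rd = cfg["render"]
    ws = trait_extraction.WatershedConfig(**cfg["traits"]["watershed"])
    rows = []
    region_rows = []
    seed_base = cfg["seed"] * 1000
    for p_i, plot in truth.plots.iterrows():
        plants = truth.plants_by_plot[plot.plot_id]
        for c_i, gdd in enumerate(truth.gdd_grid):
            mv, _ = synthetic_field.render_views(
                plants,
                gdd,
                n_views=rd["n_views"],
                seed=seed_base + p_i * 97 + c_i,
                plot_l_mm=rd["plot_l_mm"],
                plot_w_mm=rd["plot_w_mm"],
                effective_gsd_mm=rd["effective_gsd_mm"],
                erectness_jitter_px=rd["erectness_jitter_px"],
            )
            pct = multiview_core.gc_percentiles(mv)
            la = multiview_core.apparent_leaf_area(mv)
            areas = trait_extraction.watershed_regions(mv, ws)
            row = {
                "plot_id": plot.plot_id,
                "campaign": c_i,
                "gdd": float(gdd),
                "delta_gdd_true": float(gdd - plot.gs30_gdd),
                "la_px": la.la_px,
                "n_regions": len(areas),
                **pct.as_dict(),
            }
            rows.append(row)
            labels = trait_extraction.watershed_labels(mv, ws)
            pts = truth.plants[truth.plants.plot_id == plot.plot_id]
            px = (pts.x_mm.to_numpy() / rd["effective_gsd_mm"]).astype(int)
            py = (pts.y_mm.to_numpy() / rd["effective_gsd_mm"]).astype(int)
            h, w = labels.shape
            valid = (px >= 0) & (px < w) & (py >= 0) & (py < h)
            lab_at_plant = labels[py[valid], px[valid]]
            ids, counts = np.unique(labels[labels > 0], return_counts=True)
            for rid, area in zip(ids, counts):
                region_rows.append({
                    "plot_id": plot.plot_id,
                    "campaign": c_i,
                    "region": int(rid),
                    "area_px": int(area),
                    "plants_in_region": int((lab_at_plant == rid).sum()),
                })
    state["timepoints"] = pd.DataFrame(rows)
    state["regions"] = pd.DataFrame(region_rows)
    _write_csv(state["timepoints"], out / "timepoint_features.csv", manifest)
    _write_csv(state["regions"], out / "watershed_regions.csv", manifest)


def _stage_traits(cfg, out, state, manifest, resume):
    tp = state["timepoints"]
    truth = state["truth"]
    g = cfg["traits"]["gs30"]
    schema = [f"mvGC{i}" for i in range(10, 101, 10)]

    # GS30: train on this trial's percentile/ΔGDD pairs, predict, zero-cross
    feats = tp[schema]
    resp = tp["delta_gdd_true"].to_numpy()
    genos = tp["plot_id"].map(truth.plots.set_index("plot_id")["genotype"])
    try:
        model = trait_extraction.train_gs30(
            feats, resp, window=g["window"], cost=g["cost"], gamma=g["gamma"],
            genotype=genos.to_numpy(), min_samples=10,
        )
        est = trait_extraction.predict_gs30_index(model, feats)
    except ValueError as e:
        manifest.warnings.append(f"gs30: {e}")
        model, est = None, np.full(len(tp), np.nan)
    gs_df = pd.DataFrame({
        "plot_id": tp["plot_id"], "campaign": tp["campaign"],
        "gdd": tp["gdd"], "estimate": est,
    }).dropna()
    if model is not None:
        # drop estimates sitting on the no-extrapolation clamp: they carry no
        # information about where the trajectory crosses zero
        lo, hi = model.response_range
        eps = 1e-9 * max(abs(lo), abs(hi), 1.0)
        gs_df = gs_df[(gs_df["estimate"] > lo + eps) & (gs_df["estimate"] < hi - eps)]
    gs30 = trait_extraction.gs30_timepoint(gs_df, window=g["window"])
    _write_csv(gs30, out / "gs30.csv", manifest)

    # plant count: calibrate on region truth from the 5-15 days-before-GS30
    # window (sparser canopies; later campaigns merge into unresolvable mats)
    regions = state["regions"].merge(
        tp[["plot_id", "campaign", "delta_gdd_true"]], on=["plot_id", "campaign"]
    )
    early = regions[regions["delta_gdd_true"] <= -5 * synthetic_field.GDD_PER_DAY]
    if len(early) < 10:
        early = regions
    a_w, b_w, diag = trait_extraction.calibrate_watershed(
        early["area_px"].to_numpy(), early["plants_in_region"].to_numpy()
    )
    counts = (
        early.groupby(["plot_id", "campaign"])["area_px"]
        .apply(lambda A: trait_extraction.predict_plant_count(A.to_numpy(), a_w, b_w))
        .rename("plant_count_est")
        .reset_index()
    )
    plant_trait = (
        counts.groupby("plot_id")["plant_count_est"]
        .apply(lambda s: trait_extraction.plant_count_trait(s.to_numpy()))
        .rename("plant_count")
        .reset_index()
    )
    _write_csv(counts, out / "plant_count_timepoints.csv", manifest)
    _write_csv(plant_trait, out / "plant_count.csv", manifest)

    # shoots: LA->shoots logistic anchored at GS30, then dynamics
    sh = cfg["traits"]["shoots"]
    merged = tp.merge(
        truth.shoot_series, left_on=["plot_id", "gdd"], right_on=["plot_id", "gdd"]
    )
    n_unmasked = np.prod([
        int(round(cfg["render"]["plot_w_mm"] / cfg["render"]["effective_gsd_mm"])),
        int(round(cfg["render"]["plot_l_mm"] / cfg["render"]["effective_gsd_mm"])),
    ])
    asym = sh["max_cover"] * n_unmasked
    pre = merged[merged["delta_gdd_true"] < 0]
    try:
        la_model = trait_extraction.fit_la_shoot_model(
            pre["la_px"].to_numpy(), pre["shoots"].to_numpy(),
            pre["delta_gdd_true"].to_numpy(), asym=asym,
            window=sh["aggregation_window"], min_group_size=5, seed=cfg["seed"],
        )
    except ValueError as e:
        manifest.warnings.append(f"shoots: {e}")
        la_model = None
    shoot_rows = []
    if la_model is not None:
        est_shoots = trait_extraction.shoots_from_la(
            merged["la_px"].to_numpy(), merged["delta_gdd_true"].to_numpy(), la_model
        )
        merged = merged.assign(shoots_est=est_shoots)
        for plot_id, grp in merged.groupby("plot_id"):
            dyn = trait_extraction.fit_shoot_dynamics(
                grp["shoots_est"].to_numpy(), grp["delta_gdd_true"].to_numpy(),
                seed=cfg["seed"],
            )
            shoot_rows.append({
                "plot_id": plot_id, "final_shoots": dyn.n_s,
                "tillering_rate": dyn.a if dyn.a is not None else np.nan,
                "fallback": dyn.fallback, "n_points": dyn.n_points,
            })
        _write_csv(merged[["plot_id", "campaign", "gdd", "la_px", "shoots", "shoots_est"]],
                   out / "shoot_timepoints.csv", manifest)
    shoots = pd.DataFrame(shoot_rows)
    if len(shoots):
        _write_csv(shoots, out / "shoots.csv", manifest)
    state["traits"] = {"gs30": gs30, "plant_count": plant_trait, "shoots": shoots,
                       "plant_counts_tp": counts}


def _stage_stats(cfg, out, state, manifest, resume):
    truth = state["truth"]
    traits = state["traits"]
    design = truth.plots.rename(columns={"range": "range"})[
        ["plot_id", "x", "y", "row", "range", "genotype", "rep", "year_site"]
    ]
    results = {}
    for name, df, col in (
        ("plant_count", traits["plant_count"], "plant_count"),
        ("gs30", traits["gs30"].query("flag == 'ok'"), "gs30_gdd"),
        ("final_shoots", traits["shoots"], "final_shoots"),
    ):
        if df is None or not len(df):
            continue
        merged = design.merge(df[["plot_id", col]], on="plot_id").dropna(subset=[col])
        if merged["rep"].nunique() < 2 or len(merged) < 4:
            manifest.warnings.append(f"stats: {name} lacks replication; skipped")
            continue
        corrected_parts, per_site = [], {}
        for ys, grp in merged.groupby("year_site", sort=True):
            try:
                corr = stat_genetics.spatial_correct(
                    grp[col].to_numpy(), grp,
                    knots_factor=cfg["statgen"]["knots_factor"],
                )
            except ValueError as e:
                manifest.warnings.append(f"stats: {name}/{ys}: {e}")
                continue
            corrected_parts.append(corr.corrected.assign(year_site=ys))
            per_site[str(ys)] = {
                "repeatability": corr.repeatability,
                "sigma2_g": corr.sigma2_g,
                "sigma2_e": corr.sigma2_e,
            }
        if not corrected_parts:
            continue
        corrected = pd.concat(corrected_parts, ignore_index=True)
        results[name] = {"per_year_site": per_site, "n_plots": len(merged)}
        if merged["year_site"].nunique() >= 2:
            full = merged.merge(
                corrected[["plot_id", "year_site", "corrected"]],
                on=["plot_id", "year_site"],
            )
            h = stat_genetics.heritability_multi(
                full["corrected"].to_numpy(), full,
                reps_to_use=cfg["statgen"]["reps_to_use"], seed=cfg["seed"],
            )
            results[name]["heritability"] = {"h2": h.h2, "model": h.model}
        _write_csv(corrected, out / f"corrected_{name}.csv", manifest)
    path = out / "stats.json"
    path.write_text(json.dumps(results, indent=1))
    manifest.record(path)
    state["stats"] = results


_STAGES = {
    "simulate": _stage_simulate,
    "multiview": _stage_multiview,
    "traits": _stage_traits,
    "stats": _stage_stats,
}


def write_fixture_config(path, output_dir="mvgc_fixture_run", seed: int = 1) -> None:
    """Emit the miniature 4-genotype × 2-rep × 12-campaign trial config."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    cfg["seed"] = seed
    cfg["output_dir"] = str(output_dir)
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
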