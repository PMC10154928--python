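"""End-to-end orchestration: synthetic inputs -> wake -> metabolic -> curves
-> efficiency -> meta, with a provenance manifest.

The pipeline exists to exercise every stage on data with known ground truth
and to audit attrition: every record dropped by a filter is logged with the
filter that removed it.  Stages write tidy CSV/JSON outputs into the run
directory plus ``manifest.json`` (config hash, seed, package versions, row
counts per stage).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aero import Environment, Morphology, STUDY_MORPHOLOGY
from .curves import fit_power_curve
from .efficiency import (efficiency_individual_pairs, efficiency_mean,
                         efficiency_model_ratio)
from .exceptions import InvalidInputError
from .io import save_records, save_fit, save_species, sequence_results_frame
from .metabolic import (GLYCOGEN, MetabolicResult, filter_flights, fit_washout,
                        flight_vco2, power_from_vco2)
from .meta import fit_scaling_model, metabolic_ump, species_efficiency_table
from .synth import (EQ_MECH_RAW, EQ_MET_RAW, gen_power_records,
                    gen_species_table, gen_vortex_wake, gen_washout_trace)
from .wake import process_sequence, select_sequences

__all__ = ["RunConfig", "run_pipeline", "report_tables", "DEFAULT_STAGES",
           "PipelineStageError"]

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; names the stage and carries the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage

DEFAULT_STAGES = ("wake", "metabolic", "curves", "efficiency", "meta")

_ALLOWED_KEYS = {"stages", "seed", "output_dir", "morphology", "environment",
                 "thresholds", "synth"}
_ALLOWED_THRESHOLDS = {"vorticity_factor", "pairing_tolerance", "z_cutoff",
                       "flight_fraction_cutoff", "weight_tolerance"}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    stages: tuple = DEFAULT_STAGES
    seed: int = 0
    output_dir: str = "flightpower_run"
    morphology: Morphology = field(default_factory=lambda: STUDY_MORPHOLOGY)
    environment: Environment = field(default_factory=Environment)
    thresholds: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        thresholds = raw.get("thresholds", {}) or {}
        bad = set(thresholds) - _ALLOWED_THRESHOLDS
        if bad:
            raise InvalidInputError(f"unknown threshold keys: {sorted(bad)}")
        kwargs: dict = {"thresholds": thresholds}
        if "stages" in raw:
            bad_stages = set(raw["stages"]) - set(DEFAULT_STAGES)
            if bad_stages:
                raise InvalidInputError(f"unknown stages: {sorted(bad_stages)}")
            kwargs["stages"] = tuple(raw["stages"])
        for key in ("seed", "output_dir", "synth"):
            if key in raw:
                kwargs[key] = raw[key]
        if "morphology" in raw:
            kwargs["morphology"] = Morphology(**raw["morphology"])
        if "environment" in raw:
            kwargs["environment"] = Environment(**raw["environment"])
        return cls(**kwargs)

    def canonical(self) -> str:
        payload = {
            "stages": list(self.stages), "seed": self.seed,
            "morphology": vars(self.morphology).copy(),
            "environment": vars(self.environment).copy(),
            "thresholds": dict(sorted(self.thresholds.items())),
            "synth": self.synth,
        }
        return json.dumps(payload, sort_keys=True, default=float)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _stage_wake(cfg: RunConfig, out: Path, manifest: dict) -> None:
    opts = cfg.synth.get("wake", {})
    n_seq = int(opts.get("n_sequences", 6))
    speeds = opts.get("speeds", [5.0, 6.0, 7.0])
    weight = cfg.morphology.weight(cfg.environment.gravity)
    rho = cfg.environment.air_density
    results, drops = [], []
    rng = np.random.default_rng(cfg.seed)
    for i in range(n_seq):
        u_inf = float(speeds[i % len(speeds)])
        sep = 0.6 * cfg.morphology.wing_span
        # circulation sized to support weight, +/-30% scatter to exercise selection
        gamma = weight / (rho * u_inf * sep) * float(rng.uniform(0.7, 1.3))
        series, _ = gen_vortex_wake(
            gamma=gamma, separation=sep, core_radius=0.15 * sep, u_inf=u_inf,
            extent=1.2 * cfg.morphology.wing_span, n_grid=int(opts.get("n_grid", 61)),
            n_frames=int(opts.get("n_frames", 30)),
            frame_rate=100.0, wingbeat_freq=cfg.morphology.wingbeat_freq,
            noise_sd=float(opts.get("noise_sd", 0.0)),
            air_density=rho, seed=cfg.seed + 100 + i)
        results.append(process_sequence(series, air_density=rho))
    retained = select_sequences(
        results, weight,
        tolerance=float(cfg.thresholds.get("weight_tolerance", 0.20)))
    for i, r in enumerate(results):
        if not r.retained:
            reason = ("weight support" if r.n_wingbeats > 1 else "wingbeat count")
            drops.append({"sequence": i, "filter": reason,
                          "weight_ratio": r.weight_ratio})
    frame = sequence_results_frame(results)
    frame.to_csv(out / "wake_results.csv", index=False)
    manifest["stages"]["wake"] = {"n_sequences": n_seq, "n_retained": len(retained),
                                  "drops": drops}


def _stage_metabolic(cfg: RunConfig, out: Path, manifest: dict) -> None:
    opts = cfg.synth.get("metabolic", {})
    n_flights = int(opts.get("n_flights", 12))
    n_individuals = int(opts.get("n_individuals", 4))
    speeds = opts.get("speeds", [5.0, 6.0, 7.0, 8.0])
    rng = np.random.default_rng(cfg.seed + 1)
    met_curve = lambda u: EQ_MET_RAW[0] * u**3 + EQ_MET_RAW[1] / u + EQ_MET_RAW[2]
    results, drops = [], []
    rows = []
    for j in range(n_flights):
        ind = f"bat{j % n_individuals + 1:02d}"
        u = float(speeds[j % len(speeds)]) + float(rng.uniform(-0.3, 0.3))
        p_true = met_curve(u)
        vco2_true = p_true * 60.0 / GLYCOGEN.joules_per_ml_co2
        landings = ((725.0, 725.0 + float(rng.uniform(0.0, 20.0))),)
        trace, event, truth = gen_washout_trace(
            flight_vco2=vco2_true, landings=landings,
            noise_sd=float(opts.get("noise_sd", 0.01)), seed=cfg.seed + 200 + j)
        try:
            pre = fit_washout(trace, "washout_pre")
            post = fit_washout(trace, "washout_post")
            vco2 = flight_vco2(trace, event, pre, post,
                               pool_ml_co2=truth.params["pool_ml_co2"])
        except Exception as err:  # fit instability drops the flight
            drops.append({"flight": j, "filter": "washout stability", "error": str(err)})
            continue
        res = MetabolicResult(vco2_flight=vco2, p_met=power_from_vco2(vco2),
                              flight_fraction=event.flight_fraction,
                              individual_id=ind, speed=u)
        results.append(res)
    retained = filter_flights(
        results,
        min_fraction=float(cfg.thresholds.get("flight_fraction_cutoff", 0.6)),
        z_cutoff=float(cfg.thresholds.get("z_cutoff", 2.0)),
        min_flights=int(opts.get("min_flights", 2)))
    for j, r in enumerate(results):
        if not r.retained:
            which = ("flight fraction" if r.flight_fraction < 0.6 else
                     "outlier Z" if np.isfinite(r.z_score) and abs(r.z_score) > 2
                     else "individual count")
            drops.append({"flight": j, "filter": which})
    for r in retained:
        rows.append({"individual": r.individual_id, "speed_ms": r.speed,
                     "power_w": r.p_met, "type": "met",
                     "weight_n": cfg.morphology.weight(), "lift_n": np.nan})
    save_records(pd.DataFrame(rows), out / "met_records.csv")
    manifest["stages"]["metabolic"] = {
        "n_flights": n_flights, "n_retained": len(retained), "drops": drops}


def _stage_curves(cfg: RunConfig, out: Path, manifest: dict) -> None:
    opts = cfg.synth.get("records", {})
    mech, _ = gen_power_records(
        EQ_MECH_RAW, n_individuals=int(opts.get("n_individuals_mech", 4)),
        flights_per_individual=int(opts.get("flights_per_individual", 12)),
        speed_range=(5.0, 9.0), noise_sd=0.005, intercept_sd=0.004,
        power_type="mech", seed=cfg.seed + 2)
    met, _ = gen_power_records(
        EQ_MET_RAW, n_individuals=int(opts.get("n_individuals_met", 8)),
        flights_per_individual=int(opts.get("flights_per_individual_met", 6)),
        speed_range=(4.0, 9.0), noise_sd=0.1, intercept_sd=0.06,
        power_type="met", seed=cfg.seed + 3)
    save_records(mech, out / "mech_records.csv")
    save_records(met, out / "met_curve_records.csv")
    mech_fit = fit_power_curve(mech, k3_mode="fixed", u_mp_prior=4.6)
    met_fit = fit_power_curve(met, k3_mode="fixed", u_mp_prior=5.2)
    save_fit(mech_fit, out / "mech_fit.json")
    save_fit(met_fit, out / "met_fit.json")
    manifest["stages"]["curves"] = {
        "mech": {"k1": mech_fit.k1, "k2": mech_fit.k2, "k3": mech_fit.k3,
                 "n_obs": mech_fit.n_obs},
        "met": {"k1": met_fit.k1, "k2": met_fit.k2, "k3": met_fit.k3,
                "n_obs": met_fit.n_obs}}


def _stage_efficiency(cfg: RunConfig, out: Path, manifest: dict) -> None:
    from .io import load_records, load_fit
    mech = load_records(out / "mech_records.csv")
    met = load_records(out / "met_curve_records.csv")
    mech_fit = load_fit(out / "mech_fit.json")
    met_fit = load_fit(out / "met_fit.json")
    tables = [efficiency_mean(mech, met)]
    grid = np.arange(5.0, 9.5, 0.5)
    tables.append(efficiency_model_ratio(mech_fit, met_fit, grid))
    pairing = efficiency_individual_pairs(
        mech, met, tolerance=float(cfg.thresholds.get("pairing_tolerance", 0.5)))
    eff = pd.concat(tables, ignore_index=True)
    eff.to_csv(out / "efficiency.csv", index=False)
    pairing.pairs.to_csv(out / "efficiency_pairs.csv", index=False)
    manifest["stages"]["efficiency"] = {
        "n_bins": int(len(tables[0])), "n_pairs": int(len(pairing.pairs)),
        "pair_r2": None if np.isnan(pairing.r_squared) else pairing.r_squared}


def _stage_meta(cfg: RunConfig, out: Path, manifest: dict) -> None:
    opts = cfg.synth.get("species", {})
    species, _ = gen_species_table(
        n_species=int(opts.get("n_species", 24)), seed=cfg.seed + 4)
    save_species(species, out / "species.csv")
    estimates = species_efficiency_table(species, cfg.environment)
    estimates.to_csv(out / "species_efficiency.csv", index=False)
    fit = fit_scaling_model(estimates)
    (out / "scaling.json").write_text(json.dumps({
        "slope": fit.slope, "intercept": fit.intercept,
        "speed_effect": fit.speed_effect,
        "sd_species_intercept": fit.sd_species_intercept,
        "sd_speed_slope": fit.sd_speed_slope,
        "z_mass": fit.z_mass, "n_obs": fit.n_obs,
        "singular": fit.singular}, indent=2))
    manifest["stages"]["meta"] = {"n_species": len(species),
                                  "n_estimates": int(len(estimates)),
                                  "slope": fit.slope}


_STAGE_FUNCS = {"wake": _stage_wake, "metabolic": _stage_metabolic,
                "curves": _stage_curves, "efficiency": _stage_efficiency,
                "meta": _stage_meta}


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the configured stages in order; returns the manifest dict."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "seed": cfg.seed,
        "config_hash": cfg.config_hash(), "stages": {}, "completed": False,
    }
    try:
        for stage in cfg.stages:
            log.info("running stage %s", stage)
            try:
                _STAGE_FUNCS[stage](cfg, out, manifest)
            except Exception as err:
                manifest["failed_stage"] = stage
                raise PipelineStageError(stage, err) from err
        manifest["completed"] = True
    finally:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=float))
    return manifest


def report_tables(run_dir) -> dict[str, Path]:
    """Tidy figure-style CSVs from a completed run.

    power_vs_speed.csv (fitted curves on a grid), efficiency_vs_speed.csv
    and efficiency_vs_mass.csv; missing upstream outputs are skipped with a
    notice.
    """
    from .io import load_fit
    run_dir = Path(run_dir)
    written: dict[str, Path] = {}

    mech_fit_path = run_dir / "mech_fit.json"
    met_fit_path = run_dir / "met_fit.json"
    if mech_fit_path.exists() and met_fit_path.exists():
        mech_fit = load_fit(mech_fit_path)
        met_fit = load_fit(met_fit_path)
        grid = np.arange(4.0, 9.25, 0.25)
        df = pd.DataFrame({
            "speed_ms": grid,
            "p_mech_w": mech_fit(grid),
            "p_met_w": met_fit(grid)})
        path = run_dir / "power_vs_speed.csv"
        df.to_csv(path, index=False)
        written["power_vs_speed"] = path

    eff_path = run_dir / "efficiency.csv"
    if eff_path.exists():
        eff = pd.read_csv(eff_path)
        if not eff.empty:
            path = run_dir / "efficiency_vs_speed.csv"
            eff[["speed_bin", "method", "efficiency"]].to_csv(path, index=False)
            written["efficiency_vs_speed"] = path
        else:
            log.info("efficiency table empty; efficiency_vs_speed.csv not written")

    sp_path = run_dir / "species_efficiency.csv"
    if sp_path.exists():
        sp = pd.read_csv(sp_path)
        path = run_dir / "efficiency_vs_mass.csv"
        (sp.groupby(["species", "taxon", "mass_kg"])["efficiency"]
         .agg(mean="mean", low="min", high="max").reset_index()
         .to_csv(path, index=False))
        written["efficiency_vs_mass"] = path
    return written
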