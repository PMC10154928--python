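"""File formats: HDF5 wake containers, CSV/JSON tables and YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .curves import CurveCoefficients
from .exceptions import InvalidInputError
from .metabolic import BreathTrace, FlightEvent
from .meta import SpeciesRecord
from .wake import SequenceResult, WakePlaneSeries

__all__ = [
    "save_wake", "load_wake",
    "save_trace", "load_trace",
    "save_events", "load_events",
    "save_records", "load_records",
    "save_species", "load_species",
    "save_fit", "load_fit",
    "sequence_results_frame",
    "load_config",
]


def save_wake(series: WakePlaneSeries, path, air_density: float | None = None) -> None:
    """Write a wake plane series to HDF5 (/y /z /t /u /v /w /freestream)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("y", data=series.y_coords)
        fh.create_dataset("z", data=series.z_coords)
        fh.create_dataset("t", data=series.timestamps)
        for name in ("u", "v", "w"):
            fh.create_dataset(name, data=getattr(series, name), compression="gzip")
        fh.create_dataset("freestream", data=series.freestream)
        fh.attrs["wingbeat_freq"] = series.wingbeat_freq
        fh.attrs["half_wake"] = series.half_wake
        if air_density is not None:
            fh.attrs["air_density"] = air_density


def load_wake(path) -> WakePlaneSeries:
    with h5py.File(path, "r") as fh:
        return WakePlaneSeries(
            y_coords=fh["y"][:], z_coords=fh["z"][:], timestamps=fh["t"][:],
            u=fh["u"][:], v=fh["v"][:], w=fh["w"][:],
            freestream=fh["freestream"][:],
            wingbeat_freq=float(fh.attrs["wingbeat_freq"]),
            half_wake=bool(fh.attrs.get("half_wake", False)))


TRACE_COLUMNS = ["time_s", "enrichment_ape", "co2_ml_min", "phase"]


def save_trace(trace: BreathTrace, path) -> None:
    pd.DataFrame({
        "time_s": trace.time, "enrichment_ape": trace.enrichment,
        "co2_ml_min": trace.co2_production, "phase": trace.phase.astype(str),
    }).to_csv(path, index=False)


def load_trace(path) -> BreathTrace:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"trace CSV lacks columns {sorted(missing)}")
    return BreathTrace(time=df["time_s"].to_numpy(),
                       enrichment=df["enrichment_ape"].to_numpy(),
                       co2_production=df["co2_ml_min"].to_numpy(),
                       phase=df["phase"].to_numpy())


def save_events(events: list[FlightEvent], path) -> None:
    payload = [{"start": e.start, "end": e.end,
                "landings": [list(l) for l in e.landings]} for e in events]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_events(path) -> list[FlightEvent]:
    payload = json.loads(Path(path).read_text())
    return [FlightEvent(start=e["start"], end=e["end"],
                        landings=tuple(tuple(l) for l in e.get("landings", [])))
            for e in payload]


RECORD_COLUMNS = ["individual", "speed_ms", "power_w", "type", "weight_n", "lift_n"]


def save_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def load_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"individual", "speed_ms", "power_w"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"records CSV lacks columns {sorted(missing)}")
    return df


SPECIES_COLUMNS = ["species", "taxon", "mass_kg", "span_m", "area_m2",
                   "f_hz", "method", "speed_ms", "pmet_w"]


def save_species(records: list[SpeciesRecord], path) -> None:
    """Long-format species CSV: one row per (species, speed)."""
    rows = []
    for r in records:
        for u, p in zip(r.speeds, r.p_met):
            rows.append({"species": r.species, "taxon": r.taxon,
                         "mass_kg": r.body_mass, "span_m": r.wing_span,
                         "area_m2": r.wing_area, "f_hz": r.wingbeat_freq,
                         "method": r.method, "speed_ms": float(u),
                         "pmet_w": float(p)})
    pd.DataFrame(rows, columns=SPECIES_COLUMNS).to_csv(path, index=False)


def load_species(path) -> list[SpeciesRecord]:
    df = pd.read_csv(path)
    missing = set(SPECIES_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"species CSV lacks columns {sorted(missing)}")
    out = []
    for name, grp in df.groupby("species", sort=True):
        grp = grp.sort_values("speed_ms")
        out.append(SpeciesRecord(
            species=str(name), taxon=str(grp["taxon"].iloc[0]),
            body_mass=float(grp["mass_kg"].iloc[0]),
            wing_span=float(grp["span_m"].iloc[0]),
            wing_area=float(grp["area_m2"].iloc[0]),
            wingbeat_freq=float(grp["f_hz"].iloc[0]),
            method=str(grp["method"].iloc[0]),
            speeds=grp["speed_ms"].to_numpy(),
            p_met=grp["pmet_w"].to_numpy()))
    return out


def save_fit(fit: CurveCoefficients, path) -> None:
    payload = {"k1": fit.k1, "k2": fit.k2, "k3": fit.k3,
               "k3_fixed": fit.k3_fixed,
               "random_intercept_sd": fit.random_intercept_sd,
               "loglik": None if np.isnan(fit.loglik) else fit.loglik,
               "n_obs": fit.n_obs,
               "speed_min": fit.speed_min, "speed_max": fit.speed_max}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_fit(path) -> CurveCoefficients:
    payload = json.loads(Path(path).read_text())
    if payload.get("loglik") is None:
        payload["loglik"] = np.nan
    return CurveCoefficients(**payload)


def sequence_results_frame(results: list[SequenceResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "power_raw_w": r.power_raw, "net_drag_n": r.net_drag,
        "power_corrected_w": r.power_corrected,
        "vertical_force_n": r.vertical_force,
        "n_wingbeats": r.n_wingbeats, "weight_ratio": r.weight_ratio,
        "retained": r.retained,
    } for r in results])


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidInputError("config must be a YAML mapping")
    return cfg
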