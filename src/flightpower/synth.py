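"""Synthetic data with known ground truth for every pipeline stage.

Each generator emulates one class of measurement and returns, alongside the
dataset, a :class:`GroundTruth` sidecar holding the exact parameters it was
built from, so estimator tests can close the loop without external data:

* :func:`gen_vortex_wake` -- a counter-rotating Lamb-Oseen vortex pair on a
  transverse plane advected in a uniform free stream: circulation, vertical
  force (``rho U Gamma s``) and kinetic-energy flux are known in closed or
  quadrature form.
* :func:`gen_washout_trace` -- the single-pool isotope-dilution forward
  model with a step increase of CO2 production during flight.
* :func:`gen_power_records` -- per-individual flight power drawn from the
  cubic-plus-inverse power-curve family with Gaussian random intercepts.
* :func:`gen_species_table` -- a cross-species table built under a log-log
  efficiency-mass law with species-level random intercepts and speed slopes,
  metabolic power constructed as flapping-model mechanical power divided by
  the species' true efficiency.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
(seed, parameters) regenerate bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .aero import Environment, Morphology, allometric_wingbeat_freq, flap_model_power, minimum_power_speed
from .exceptions import InvalidInputError
from .metabolic import BreathTrace, FlightEvent
from .meta import SpeciesRecord
from .wake import WakePlaneSeries

__all__ = [
    "GroundTruth",
    "gen_vortex_wake",
    "gen_washout_trace",
    "gen_power_records",
    "gen_species_table",
    "EQ_MET_RAW",
    "EQ_MECH_RAW",
]

#: Reference cubic-plus-inverse coefficient triples at the study's scale
#: (mechanical and metabolic power of an ~9 g bat, W vs m/s).
EQ_MECH_RAW = (9.21e-5, 0.176, 0.0297)
EQ_MET_RAW = (3.73e-4, 2.52, 0.490)


@dataclass(frozen=True)
class GroundTruth:
    """True parameters of a generated dataset, serialized with it."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=float)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def _lamb_oseen_pair(yy, zz, gamma, separation, core_radius, y0=0.0, z0=0.0):
    """In-plane (v, w) and vorticity of a counter-rotating Lamb-Oseen pair.

    Circulation +gamma at (y0 + s/2, z0), -gamma at (y0 - s/2, z0); the
    positive-y vortex carries positive circulation so the pair supports an
    upward (lift) vorticity moment ``gamma * s``.
    """
    v = np.zeros_like(yy)
    w = np.zeros_like(yy)
    omega = np.zeros_like(yy)
    for sign, yc in ((+1.0, y0 + separation / 2.0), (-1.0, y0 - separation / 2.0)):
        dy = yy - yc
        dz = zz - z0
        r2 = dy**2 + dz**2
        with np.errstate(divide="ignore", invalid="ignore"):
            vtheta_over_r = (sign * gamma / (2.0 * np.pi * r2)
                             * (1.0 - np.exp(-r2 / core_radius**2)))
        vtheta_over_r = np.where(r2 > 0, vtheta_over_r,
                                 sign * gamma / (2.0 * np.pi * core_radius**2))
        # tangential velocity split into (v, w): v = -vtheta * dz/r, w = vtheta * dy/r
        v += -vtheta_over_r * dz
        w += vtheta_over_r * dy
        omega += sign * gamma / (np.pi * core_radius**2) * np.exp(-r2 / core_radius**2)
    return v, w, omega


def _quadrature_truth(gamma, separation, core_radius, u_inf, extent, deficits,
                      air_density, refine: int = 4, base_n: int = 101):
    """Reference wake integrals on a refined grid of the analytic fields."""
    n = base_n * refine
    y = np.linspace(-extent, extent, n)
    z = np.linspace(-extent, extent, n)
    yy, zz = np.meshgrid(y, z, indexing="ij")
    v, w, _ = _lamb_oseen_pair(yy, zz, gamma, separation, core_radius)
    u = np.zeros_like(yy)
    for depth, radius, yc, zc in deficits:
        u += depth * np.exp(-((yy - yc)**2 + (zz - zc)**2) / radius**2)
    cell = (y[1] - y[0]) * (z[1] - z[0])
    ke_flux = air_density * (0.5 * (u**2 + v**2 + w**2) * (u_inf + u)).sum() * cell
    dnet = air_density * (u * (u_inf + u)).sum() * cell
    return {"kinetic_power": float(ke_flux), "net_drag": float(dnet)}


def gen_vortex_wake(gamma: float = 0.05,
                    separation: float = 0.1,
                    core_radius: float = 0.02,
                    u_inf: float = 6.0,
                    extent: float = 0.3,
                    n_grid: int = 201,
                    n_frames: int = 40,
                    frame_rate: float = 200.0,
                    wingbeat_freq: float = 10.0,
                    noise_sd: float = 0.0,
                    deficits: tuple = (),
                    half_wake: bool = False,
                    air_density: float = 1.2,
                    seed: int = 0) -> tuple[WakePlaneSeries, GroundTruth]:
    """Synthetic vortex-pair wake with closed-form integral truths.

    ``deficits`` is a tuple of ``(depth, radius, y_centre, z_centre)``
    Gaussian patches added to the streamwise perturbation ``u`` (negative
    depth = momentum deficit).  The truth sidecar stores the analytic
    vertical force ``rho U Gamma s`` and fine-grid quadrature values of the
    kinetic-energy flux and net drag of the noise-free fields.
    """
    if not core_radius < separation / 2.0 < extent:
        raise InvalidInputError(
            "need core_radius < separation/2 < grid half-width (vortices inside grid)")
    rng = np.random.default_rng(seed)
    y = np.linspace(-extent, extent, n_grid)
    z = np.linspace(-extent, extent, n_grid)
    yy, zz = np.meshgrid(y, z, indexing="ij")
    v0, w0, _ = _lamb_oseen_pair(yy, zz, gamma, separation, core_radius)
    u0 = np.zeros_like(yy)
    for depth, radius, yc, zc in deficits:
        u0 += depth * np.exp(-((yy - yc)**2 + (zz - zc)**2) / radius**2)

    t = np.arange(n_frames) / frame_rate
    shape = (n_frames,) + yy.shape
    u = np.broadcast_to(u0, shape).copy()
    v = np.broadcast_to(v0, shape).copy()
    w = np.broadcast_to(w0, shape).copy()
    if noise_sd > 0:
        u += rng.normal(0.0, noise_sd, shape)
        v += rng.normal(0.0, noise_sd, shape)
        w += rng.normal(0.0, noise_sd, shape)
    freestream = np.full_like(yy, u_inf)

    truth_integrals = _quadrature_truth(gamma, separation, core_radius, u_inf,
                                        extent, deficits, air_density)
    truth = GroundTruth(kind="vortex_wake", seed=seed, params={
        "gamma": gamma, "separation": separation, "core_radius": core_radius,
        "u_inf": u_inf, "air_density": air_density, "noise_sd": noise_sd,
        "vertical_force": air_density * u_inf * gamma * separation,
        "circulation": gamma, "deficits": [list(d) for d in deficits],
        **truth_integrals,
    })

    if half_wake:
        keep = y >= 0.0
        series = WakePlaneSeries(
            y_coords=y[keep], z_coords=z, timestamps=t,
            u=u[:, keep, :], v=v[:, keep, :], w=w[:, keep, :],
            freestream=freestream[keep, :],
            wingbeat_freq=wingbeat_freq, half_wake=True)
    else:
        series = WakePlaneSeries(
            y_coords=y, z_coords=z, timestamps=t, u=u, v=v, w=w,
            freestream=freestream, wingbeat_freq=wingbeat_freq, half_wake=False)
    return series, truth


def gen_washout_trace(resting_vco2: float = 0.23,
                      flight_vco2: float = 2.84,
                      flight_start: float = 720.0,
                      flight_duration: float = 66.0,
                      landings: tuple = ((750.0, 757.0),),
                      pool_ml_co2: float = 1.0,
                      equilibrium_enrichment: float = 20.0,
                      baseline_duration: float = 300.0,
                      equil_duration: float = 120.0,
                      pre_duration: float = 300.0,
                      post_duration: float = 900.0,
                      sample_rate: float = 1.0,
                      noise_sd: float = 0.0,
                      seed: int = 0) -> tuple[BreathTrace, FlightEvent, GroundTruth]:
    """Forward-simulated bicarbonate washout trace with a flight interval.

    A single well-mixed pool of ``pool_ml_co2`` ml CO2 equivalents starts at
    ``equilibrium_enrichment`` APE after the equilibration phase and decays
    with instantaneous rate ``VCO2(t) / (60 pool)`` per second.  CO2
    production is ``resting_vco2`` ml/min at rest and ``flight_vco2`` during
    airborne parts of the flight window (landing intervals revert to the
    resting rate).  Multiplicative Gaussian noise of relative s.d.
    ``noise_sd`` is applied to the enrichment channel.
    """
    rng = np.random.default_rng(seed)
    t_equil_end = baseline_duration + equil_duration
    t_pre_end = t_equil_end + pre_duration
    if not flight_start >= t_pre_end:
        raise InvalidInputError("flight must start after the pre-flight washout")
    flight_end = flight_start + flight_duration
    t_end = flight_end + post_duration
    time = np.arange(0.0, t_end, 1.0 / sample_rate)

    vco2 = np.full_like(time, resting_vco2)
    in_flight = (time >= flight_start) & (time < flight_end)
    vco2[in_flight] = flight_vco2
    for a, b in landings:
        vco2[(time >= a) & (time < b)] = resting_vco2

    # piecewise-exponential decay from the equilibration plateau
    enrich = np.zeros_like(time)
    dt = 1.0 / sample_rate
    after = time >= t_equil_end
    k_inst = vco2 / (60.0 * pool_ml_co2)  # s^-1
    decay = np.cumsum(np.where(after, k_inst * dt, 0.0))
    enrich[after] = equilibrium_enrichment * np.exp(-(decay[after] - decay[after][0]))
    rising = (time >= baseline_duration) & ~after
    tau = max(equil_duration / 6.0, 1.0)
    enrich[rising] = equilibrium_enrichment * (
        1.0 - np.exp(-(time[rising] - baseline_duration) / tau))
    if noise_sd > 0:
        enrich = enrich * (1.0 + rng.normal(0.0, noise_sd, time.shape))
        enrich = np.clip(enrich, 0.0, None)

    phase = np.empty(time.shape, dtype=object)
    phase[time < baseline_duration] = "baseline"
    phase[(time >= baseline_duration) & (time < t_equil_end)] = "equilibration"
    phase[(time >= t_equil_end) & (time < flight_start)] = "washout_pre"
    phase[in_flight] = "flight"
    phase[time >= flight_end] = "washout_post"

    trace = BreathTrace(time=time, enrichment=enrich,
                        co2_production=vco2, phase=phase)
    event = FlightEvent(start=flight_start, end=flight_end,
                        landings=tuple(tuple(x) for x in landings))
    truth = GroundTruth(kind="washout", seed=seed, params={
        "resting_vco2": resting_vco2, "flight_vco2": flight_vco2,
        "pool_ml_co2": pool_ml_co2,
        "equilibrium_enrichment": equilibrium_enrichment,
        "decay_rate_rest": resting_vco2 / (60.0 * pool_ml_co2),
        "flight_fraction": event.flight_fraction,
        "flight_start": flight_start, "flight_end": flight_end,
        "noise_sd": noise_sd,
    })
    return trace, event, truth


def gen_power_records(k_triple: tuple = EQ_MET_RAW,
                      n_individuals: int = 8,
                      flights_per_individual: int = 6,
                      speed_range: tuple = (4.0, 9.0),
                      noise_sd: float = 0.12,
                      intercept_sd: float = 0.08,
                      mass_mean: float = 0.0089,
                      mass_cv: float = 0.1,
                      power_type: str = "met",
                      gravity: float = 9.81,
                      weight_scaling: bool = False,
                      seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-flight power records from the cubic-plus-inverse curve family.

    Speeds are evenly spread over ``speed_range`` per individual with small
    jitter; each individual carries a Gaussian random intercept
    (sd ``intercept_sd`` W) and each flight Gaussian noise (sd ``noise_sd``
    W).  Body masses are lognormal around ``mass_mean`` with coefficient of
    variation ``mass_cv``.  Mechanical records get a lift column equal to
    body weight (steady level flight).

    With ``weight_scaling=True`` each individual's curve is the reference
    curve stretched by its weight, ``P_i(U) = (W_i/W_ref) f(U (W_ref/W_i)^(1/6))``
    -- characteristic speeds shift with W^(1/6) and power with W, the premise
    of the U* speed normalization.
    """
    if speed_range[0] <= 0:
        raise InvalidInputError("speed range must be positive")
    rng = np.random.default_rng(seed)
    k1, k2, k3 = k_triple
    rows = []
    intercepts = rng.normal(0.0, intercept_sd, n_individuals)
    sigma_ln = np.sqrt(np.log(1.0 + mass_cv**2))
    masses = mass_mean * np.exp(rng.normal(0.0, sigma_ln, n_individuals)
                                - 0.5 * sigma_ln**2)
    for i in range(n_individuals):
        base = np.linspace(speed_range[0], speed_range[1], flights_per_individual)
        speeds = base + rng.uniform(-0.25, 0.25, flights_per_individual)
        speeds = np.clip(speeds, 0.5, None)
        w_ratio = masses[i] / mass_mean
        for u in speeds:
            if weight_scaling:
                u_star = u * w_ratio**(-1.0 / 6.0)
                base_p = w_ratio * (k1 * u_star**3 + k2 / u_star + k3)
            else:
                base_p = k1 * u**3 + k2 / u + k3
            p = base_p + intercepts[i] + rng.normal(0.0, noise_sd)
            rows.append({
                "individual": f"bat{i + 1:02d}",
                "speed_ms": float(u),
                "power_w": float(max(p, 1e-6)),
                "type": power_type,
                "weight_n": float(masses[i] * gravity),
                "lift_n": float(masses[i] * gravity) if power_type == "mech" else np.nan,
            })
    records = pd.DataFrame(rows)
    truth = GroundTruth(kind="power_records", seed=seed, params={
        "k1": k1, "k2": k2, "k3": k3,
        "u_mp": minimum_power_speed(k_triple),
        "noise_sd": noise_sd, "intercept_sd": intercept_sd,
        "individual_intercepts": intercepts.tolist(),
        "masses_kg": masses.tolist(),
        "power_type": power_type,
        "weight_scaling": weight_scaling,
    })
    return records, truth


def _species_morphology(mass: float, rng: np.random.Generator) -> dict:
    """Allometric wing morphology with mild scatter (bird/bat composite)."""
    span = 1.17 * mass**(1.0 / 3.0) * np.exp(rng.normal(0.0, 0.05))
    aspect = rng.uniform(6.0, 9.0)
    area = span**2 / aspect
    freq = allometric_wingbeat_freq(mass, span, area)
    return {"wing_span": float(span), "wing_area": float(area),
            "wingbeat_freq": float(freq)}


def gen_species_table(n_species: int = 24,
                      slope: float = 0.24,
                      intercept: float = 0.49,
                      species_sd: float = 0.29,
                      speed_slope_sd: float = 0.03,
                      n_birds: int = 16,
                      n_speeds: int = 8,
                      mass_range: tuple = (0.004, 2.6),
                      obs_noise_sd: float = 0.05,
                      seed: int = 0) -> tuple[list[SpeciesRecord], GroundTruth]:
    """Cross-species table generated under a log-log efficiency-mass law.

    True efficiency (percent) of species s at speed U:
    ``log10 eta = slope log10(M g) + intercept + a_s + b_s (U - U_mid)``
    with ``a_s ~ N(0, species_sd)`` and ``b_s ~ N(0, speed_slope_sd)``.
    Metabolic power is the flapping-model mechanical power divided by that
    efficiency times a lognormal measurement error (``obs_noise_sd`` in
    log10 units, ~12% at the 0.05 default -- typical respirometry scatter);
    with ``obs_noise_sd=0`` the efficiency estimator inverts the
    construction exactly.  Speeds straddle each species' mechanical minimum
    power speed so the meta-analysis U_mp filter acts as it does on real
    series.
    """
    if n_species < 5:
        raise InvalidInputError("need >= 5 species")
    rng = np.random.default_rng(seed)
    env = Environment()
    log_lo, log_hi = np.log(mass_range[0]), np.log(mass_range[1])
    masses = np.exp(rng.uniform(log_lo, log_hi, n_species))
    taxa = np.array(["bird"] * min(n_birds, n_species)
                    + ["bat"] * max(n_species - n_birds, 0))
    rng.shuffle(taxa)
    a_s = rng.normal(0.0, species_sd, n_species)
    b_s = rng.normal(0.0, speed_slope_sd, n_species)

    records, truths = [], []
    for i in range(n_species):
        morph_kwargs = _species_morphology(masses[i], rng)
        morph = Morphology(body_mass=float(masses[i]), **morph_kwargs)
        total = lambda u: flap_model_power(morph, env, u)[0].total
        u_mp = minimum_power_speed(total, bracket=(0.3, 60.0))
        # speeds straddle U_mp so the meta-analysis U_mp filter acts as in use
        speeds = np.linspace(max(u_mp - 1.5, 0.5), u_mp + 4.0, n_speeds)
        u_mid = speeds.mean()
        log_eta = (slope * np.log10(1000.0 * masses[i]) + intercept
                   + a_s[i] + b_s[i] * (speeds - u_mid))
        eta_pct = np.clip(10.0**log_eta, 0.3, 60.0)
        p_mech = np.array([total(float(u)) for u in speeds])
        p_met = p_mech / (eta_pct / 100.0)
        if obs_noise_sd > 0:
            p_met = p_met * 10.0 ** rng.normal(0.0, obs_noise_sd, p_met.shape)
        records.append(SpeciesRecord(
            species=f"sp{i + 1:02d}", taxon=str(taxa[i]),
            body_mass=float(masses[i]), method="respirometry",
            speeds=speeds, p_met=p_met, **morph_kwargs))
        truths.append({"species": f"sp{i + 1:02d}", "a_s": float(a_s[i]),
                       "b_s": float(b_s[i]), "u_mp_mech": float(u_mp),
                       "eta_pct": eta_pct.tolist()})
    truth = GroundTruth(kind="species_table", seed=seed, params={
        "slope": slope, "intercept": intercept, "species_sd": species_sd,
        "speed_slope_sd": speed_slope_sd, "obs_noise_sd": obs_noise_sd,
        "masses_kg": masses.tolist(),
        "taxa": taxa.tolist(), "per_species": truths,
    })
    return records, truth
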