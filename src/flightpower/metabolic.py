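"""Metabolic power from labelled-bicarbonate washout traces.

An animal injected with a bolus of 13C-labelled sodium bicarbonate carries
a body bicarbonate pool transiently enriched in 13C.  Every ml of CO2 it
produces washes label out of the pool, so breath enrichment declines
exponentially with a rate constant proportional to CO2 production:

    e(t) = e0 * exp( - integral VCO2(t') dt' / N )

for a single well-mixed pool of size ``N`` (expressed here in ml CO2
equivalents, so that ``k = VCO2 / N``).  A flight in the middle of the
washout steepens the decline; comparing the resting decay fitted before and
after the flight with the total label lost across it yields the in-flight
CO2 production rate, and a fuel-specific conversion factor (J per ml CO2)
turns that into metabolic power in watts.

The same forward model drives :func:`flightpower.synth.gen_washout_trace`,
so parameter recovery is exactly testable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import FitQualityError, InsufficientDataError, InvalidInputError

__all__ = [
    "PHASES",
    "BreathTrace",
    "FlightEvent",
    "MetabolicResult",
    "FuelModel",
    "GLYCOGEN",
    "MIXED_FUEL",
    "WashoutFit",
    "fit_washout",
    "pool_from_dose",
    "flight_vco2",
    "power_from_vco2",
    "filter_flights",
    "bmr_from_respirometry",
]

PHASES = ("baseline", "equilibration", "washout_pre", "flight", "washout_post")

#: Energy yield per ml CO2 for pure glycogen oxidation (J/ml).
GLYCOGEN_J_PER_ML = 21.1
#: Energy yield per ml CO2 for a 80/20 carbohydrate/lipid mix, RQ 0.88 (J/ml).
MIXED_J_PER_ML = 23.7
#: Oxyjoule equivalent for O2-based respirometry (J/ml O2).
OXYJOULE_J_PER_ML_O2 = 20.1


@dataclass(frozen=True)
class FuelModel:
    name: str
    joules_per_ml_co2: float


GLYCOGEN = FuelModel("glycogen", GLYCOGEN_J_PER_ML)
MIXED_FUEL = FuelModel("mixed", MIXED_J_PER_ML)


@dataclass
class BreathTrace:
    """Breath 13C enrichment time series with phase labels.

    ``time`` in s (strictly increasing), ``enrichment`` in atom-percent
    excess (>= 0), ``co2_production`` in ml/min STP, ``phase`` an array of
    labels from :data:`PHASES`.
    """

    time: np.ndarray
    enrichment: np.ndarray
    co2_production: np.ndarray
    phase: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.enrichment = np.asarray(self.enrichment, dtype=float)
        self.co2_production = np.asarray(self.co2_production, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        n = self.time.size
        if any(a.size != n for a in (self.enrichment, self.co2_production, self.phase)):
            raise InvalidInputError("trace channels must share length")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidInputError("time must be strictly increasing")
        if np.any(self.enrichment < 0):
            raise InvalidInputError("enrichment must be non-negative")
        unknown = set(np.unique(self.phase.astype(str))) - set(PHASES)
        if unknown:
            raise InvalidInputError(f"unknown phase labels: {sorted(unknown)}")

    def select(self, phase: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.phase.astype(str) == phase
        return self.time[sel], self.enrichment[sel]


@dataclass(frozen=True)
class FlightEvent:
    """Flight timing: start/end of the tunnel period plus landing intervals."""

    start: float
    end: float
    landings: tuple = ()

    def __post_init__(self):
        if not self.end > self.start:
            raise InvalidInputError("flight end must be after start")
        for a, b in self.landings:
            if not (self.start <= a < b <= self.end):
                raise InvalidInputError("landings must nest within [start, end]")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def flight_fraction(self) -> float:
        landed = sum(b - a for a, b in self.landings)
        frac = 1.0 - landed / self.duration
        return min(max(frac, 0.0), 1.0)


@dataclass
class MetabolicResult:
    """Per-flight metabolic estimate plus filter bookkeeping."""

    vco2_flight: float  # ml/min
    p_met: float        # W
    flight_fraction: float
    individual_id: str = ""
    speed: float = np.nan
    z_score: float = np.nan
    retained: bool = False


@dataclass(frozen=True)
class WashoutFit:
    """Exponential washout fit e(t) = baseline + amplitude*exp(-k (t - t_ref))."""

    amplitude: float
    decay_rate: float  # k, s^-1
    baseline: float
    t_ref: float
    residual_sd: float

    def excess(self, t: float) -> float:
        """Enrichment above baseline extrapolated to absolute time ``t``."""
        return self.amplitude * math.exp(-self.decay_rate * (t - self.t_ref))


def fit_washout(trace: BreathTrace, phase: str = "washout_pre") -> WashoutFit:
    """Nonlinear least-squares fit of the exponential washout in one phase.

    Raises :class:`FitQualityError` for non-decaying traces (the selection
    rule that washout curves must be stable before and after flight).
    """
    t, e = trace.select(phase)
    if t.size < 10:
        raise InsufficientDataError(f"phase {phase!r} has {t.size} samples, need >= 10")
    t0 = float(t[0])
    base0 = float(min(e.min(), 0.0) if e.min() < 0 else 0.0)
    amp0 = max(float(e[0] - e[-1]), 1e-9)
    span = max(float(t[-1] - t0), 1.0)
    with np.errstate(over="ignore"):
        k0 = max(math.log(max(e[0], 1e-12) / max(e[-1], 1e-12)) / span, 1e-6)

    def model(tt, amp, k, base):
        return base + amp * np.exp(-k * (tt - t0))

    try:
        popt, _ = curve_fit(
            model, t, e, p0=(max(amp0, float(e[0])), k0, base0),
            bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except (RuntimeError, ValueError) as err:
        raise FitQualityError(f"washout fit failed in phase {phase!r}: {err}") from err
    amp, k, base = (float(x) for x in popt)
    resid = e - model(t, *popt)
    sd = float(np.sqrt(np.mean(resid**2)))
    total_decay = amp * (1.0 - math.exp(-k * span))
    floor = max(3.0 * sd, 1e-6 * max(1.0, float(np.mean(np.abs(e)))))
    if amp <= 0 or k <= 1e-9 or total_decay < floor:
        raise FitQualityError(
            f"phase {phase!r} does not decay (amp={amp:.3g}, k={k:.3g}, "
            f"decay/noise={total_decay / max(sd, 1e-300):.2f})")
    return WashoutFit(amplitude=amp, decay_rate=k, baseline=base,
                      t_ref=t0, residual_sd=sd)


def pool_from_dose(dose_ml_co2: float, equilibrium_enrichment: float) -> float:
    """Bicarbonate pool size (ml CO2 equivalents) from dose and plateau enrichment.

    A label dose equivalent to ``dose_ml_co2`` ml of CO2 mixed into a pool
    N produces a plateau excess enrichment ``e_eq = dose / N``.
    """
    if dose_ml_co2 <= 0 or equilibrium_enrichment <= 0:
        raise InvalidInputError("dose and equilibrium enrichment must be positive")
    return dose_ml_co2 / equilibrium_enrichment


def flight_vco2(trace: BreathTrace, event: FlightEvent,
                pre_fit: WashoutFit, post_fit: WashoutFit,
                pool_ml_co2: float,
                consistency_tol: float = 0.5) -> float:
    """Whole-flight CO2 production rate (ml/min) by isotope dilution.

    The label lost across the tunnel period (pre-fit extrapolated forward to
    ``event.start``, post-fit back to ``event.end``) is partitioned between
    resting production and an elevated contiguous flight interval of length
    ``flight_fraction * duration`` centred at the event midpoint:

        VCO2_flight = (60 N dln - VCO2_rest (T - T_f)) / T_f

    with ``dln`` the log-enrichment drop, ``N`` the pool size and
    ``VCO2_rest`` the mean of the pre/post resting rates.
    """
    if pool_ml_co2 <= 0:
        raise InvalidInputError("pool size must be positive")
    k_pre, k_post = pre_fit.decay_rate, post_fit.decay_rate
    k_mean = 0.5 * (k_pre + k_post)
    if abs(k_pre - k_post) > consistency_tol * k_mean:
        raise FitQualityError(
            f"pre/post washout rates inconsistent: {k_pre:.3g} vs {k_post:.3g} s^-1")
    vco2_rest = 60.0 * k_mean * pool_ml_co2  # ml/min
    t_total = event.duration
    t_flight = event.flight_fraction * t_total
    if t_flight <= 0:
        return vco2_rest
    e1 = pre_fit.excess(event.start)
    e2 = post_fit.excess(event.end)
    if e1 <= 0 or e2 <= 0 or e2 >= e1:
        raise FitQualityError("enrichment did not decline across the flight period")
    dln = math.log(e1 / e2)
    total_ml = pool_ml_co2 * dln  # ml of CO2 produced across the period
    return (60.0 * total_ml - vco2_rest * (t_total - t_flight)) / t_flight


def power_from_vco2(vco2: float, fuel: FuelModel = GLYCOGEN) -> float:
    """Metabolic power (W) from CO2 production (ml/min): ``vco2/60 * J_per_ml``."""
    if vco2 < 0:
        raise InvalidInputError("vco2 must be non-negative")
    return vco2 / 60.0 * fuel.joules_per_ml_co2


def filter_flights(results: list[MetabolicResult],
                   min_fraction: float = 0.6,
                   z_cutoff: float = 2.0,
                   min_flights: int = 4,
                   speed_bin: float = 1.0) -> list[MetabolicResult]:
    """Apply the flight-fraction, outlier and individual selection filters.

    Order: (1) drop flights with ``flight_fraction < min_fraction``;
    (2) drop flights whose power Z-score within the speed bin (speed rounded
    to the nearest ``speed_bin``) strictly exceeds ``z_cutoff`` in absolute
    value (population s.d.; a bin of one flight has undefined Z and is
    retained); (3) drop individuals with fewer than ``min_flights``
    surviving flights.  Returns the retained subset; ``z_score`` and
    ``retained`` are filled on every result.
    """
    for res in results:
        res.retained = False
        res.z_score = np.nan
    stage1 = [r for r in results if r.flight_fraction >= min_fraction]

    bins: dict[float, list[MetabolicResult]] = {}
    for r in stage1:
        key = round(r.speed / speed_bin) * speed_bin if np.isfinite(r.speed) else np.inf
        bins.setdefault(key, []).append(r)
    stage2 = []
    for group in bins.values():
        powers = np.array([r.p_met for r in group])
        sd = powers.std()  # population s.d., matching the hand rule
        for r in group:
            if len(group) < 2 or sd == 0:
                r.z_score = np.nan
                stage2.append(r)
                continue
            r.z_score = float((r.p_met - powers.mean()) / sd)
            if abs(r.z_score) <= z_cutoff:  # strictly "exceeding" is dropped
                stage2.append(r)

    counts: dict[str, int] = {}
    for r in stage2:
        counts[r.individual_id] = counts.get(r.individual_id, 0) + 1
    retained = [r for r in stage2 if counts[r.individual_id] >= min_flights]
    for r in retained:
        r.retained = True
    return retained


def bmr_from_respirometry(rate_ml_min: float, mode: str = "o2",
                          temperature_c: float | None = None) -> float:
    """Basal metabolic rate (W) from resting gas exchange (ml/min).

    ``mode='o2'`` uses the oxyjoule equivalent 20.1 J/ml O2; ``mode='co2'``
    the glycogen factor 21.1 J/ml CO2.  Measurements outside thermoneutrality
    (28-35 C) trigger a warning, not an error.
    """
    if rate_ml_min < 0:
        raise InvalidInputError("gas exchange rate must be non-negative")
    if temperature_c is not None and not (28.0 <= temperature_c <= 35.0):
        warnings.warn(
            f"respirometry at {temperature_c} C is outside thermoneutrality (28-35 C)",
            stacklevel=2)
    if mode == "o2":
        factor = OXYJOULE_J_PER_ML_O2
    elif mode == "co2":
        factor = GLYCOGEN_J_PER_ML
    else:
        raise InvalidInputError("mode must be 'o2' or 'co2'")
    return rate_ml_min / 60.0 * factor
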