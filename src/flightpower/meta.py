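"""Cross-species conversion-efficiency estimation and mass scaling.

For species with published metabolic power across wind-tunnel speeds,
conversion efficiency is estimated as the flapping-model mechanical power
divided by the measured metabolic power, after two quality filters: speeds
below the species' metabolic minimum power speed are excluded (aerodynamic
models are unreliable below U_mp), and so are model outputs carrying a red
flag.  The resulting efficiencies follow a strong allometric trend,
modelled on the log-log scale as

    log10(eta%) = slope * log10(M g) + intercept  (+ taxon + speed terms),

with a random intercept and random speed slope per species.  Units are a
documented convention throughout: mass in grams, efficiency in percent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .aero import Environment, Morphology, flap_model_power, minimum_power_speed
from .exceptions import InsufficientDataError, InvalidInputError

__all__ = [
    "SpeciesRecord",
    "ScalingFit",
    "vo2_to_watts",
    "species_efficiency",
    "fit_scaling_model",
    "mass_correct",
    "near_ump_comparison",
    "predict_efficiency",
]

log = logging.getLogger(__name__)

OXYJOULE = 20.1  # J per ml O2

MASS_RANGE_KG = (0.004, 2.6)


@dataclass
class SpeciesRecord:
    """Morphology plus a metabolic-power-by-speed series for one species."""

    species: str
    taxon: str  # 'bird' | 'bat'
    body_mass: float  # kg
    wing_span: float
    wing_area: float
    wingbeat_freq: float
    method: str = "respirometry"
    speeds: np.ndarray = field(default_factory=lambda: np.array([]))
    p_met: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        if self.taxon not in ("bird", "bat"):
            raise InvalidInputError("taxon must be 'bird' or 'bat'")
        if not (MASS_RANGE_KG[0] <= self.body_mass <= MASS_RANGE_KG[1]):
            raise InvalidInputError(
                f"body mass {self.body_mass} kg outside supported range {MASS_RANGE_KG}")
        self.speeds = np.asarray(self.speeds, dtype=float)
        self.p_met = np.asarray(self.p_met, dtype=float)
        if self.speeds.size != self.p_met.size:
            raise InvalidInputError("speeds and p_met must have equal length")
        if self.speeds.size < 2:
            raise InsufficientDataError("need >= 2 speeds per species")

    @property
    def morphology(self) -> Morphology:
        return Morphology(body_mass=self.body_mass, wing_span=self.wing_span,
                          wing_area=self.wing_area, wingbeat_freq=self.wingbeat_freq)


@dataclass(frozen=True)
class ScalingFit:
    """Mixed-model fit of log10 efficiency (percent) against log10 mass (g)."""

    slope: float
    intercept: float
    taxon_effect: float
    speed_effect: float
    sd_species_intercept: float
    sd_speed_slope: float
    z_mass: float
    p_mass: float
    slope_se: float
    n_obs: int
    singular: bool = False
    taxon_z: float = np.nan
    taxon_p: float = np.nan

    def predict_log10(self, mass_g, speed: float = 0.0, taxon_is_bird: bool = False):
        out = self.slope * np.log10(mass_g) + self.intercept
        out = out + self.speed_effect * speed
        if taxon_is_bird:
            out = out + self.taxon_effect
        return out


def vo2_to_watts(vo2_ml_min: float) -> float:
    """Oxygen consumption (ml/min) to watts via the 20.1 J/ml oxyjoule factor."""
    if np.any(np.asarray(vo2_ml_min) < 0):
        raise InvalidInputError("vo2 must be non-negative")
    return vo2_ml_min / 60.0 * OXYJOULE


def metabolic_ump(speeds: np.ndarray, p_met: np.ndarray) -> float:
    """Minimum power speed of a metabolic series via the cubic-plus-inverse fit.

    Ordinary least squares on (U^3, 1/U, 1); when the fitted curve is not
    U-shaped (k1 or k2 <= 0, possible with few noisy points) the speed of
    the observed minimum is used instead.
    """
    speeds = np.asarray(speeds, dtype=float)
    p_met = np.asarray(p_met, dtype=float)
    if speeds.size >= 3:
        X = np.column_stack([speeds**3, 1.0 / speeds, np.ones_like(speeds)])
        beta, *_ = np.linalg.lstsq(X, p_met, rcond=None)
        if beta[0] > 0 and beta[1] > 0:
            return minimum_power_speed((beta[0], beta[1], beta[2]))
    return float(speeds[np.argmin(p_met)])


def species_efficiency(record: SpeciesRecord,
                       env: Environment | None = None,
                       apply_ump_filter: bool = True,
                       apply_flag_filter: bool = True,
                       u_mp_threshold: float | None = None) -> pd.DataFrame:
    """Estimated conversion efficiency per speed for one species.

    eta(U) = P_mech_model(U) / P_met(U) for speeds at or above the species'
    metabolic minimum power speed and with no model red flag.  Returns a
    table (species, taxon, mass_kg, speed, p_mech, p_met, efficiency); empty
    (with a log notice) when every speed is filtered.
    """
    env = env or Environment()
    morph = record.morphology
    u_mp_met = (u_mp_threshold if u_mp_threshold is not None
                else metabolic_ump(record.speeds, record.p_met))
    rows = []
    for u, pm in zip(record.speeds, record.p_met):
        if apply_ump_filter and u < u_mp_met:
            continue
        comps, flags = flap_model_power(morph, env, float(u))
        if apply_flag_filter and flags.any_flag:
            continue
        rows.append({"species": record.species, "taxon": record.taxon,
                     "mass_kg": record.body_mass, "speed": float(u),
                     "p_mech": comps.total, "p_met": float(pm),
                     "efficiency": comps.total / float(pm)})
    if not rows:
        log.info("species %s: every speed filtered (U_mp,met=%.2f)",
                 record.species, u_mp_met)
    return pd.DataFrame(rows, columns=["species", "taxon", "mass_kg", "speed",
                                       "p_mech", "p_met", "efficiency"])


def species_efficiency_table(records: list[SpeciesRecord],
                             env: Environment | None = None) -> pd.DataFrame:
    """Concatenated :func:`species_efficiency` across species."""
    frames = [species_efficiency(r, env) for r in records]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=["species", "taxon", "mass_kg", "speed",
                                     "p_mech", "p_met", "efficiency"])
    return pd.concat(frames, ignore_index=True)


def fit_scaling_model(estimates: pd.DataFrame,
                      include_taxon: bool = False,
                      random_speed_slope: bool = True) -> ScalingFit:
    """Mixed model of log10 efficiency (percent) on log10 mass (grams).

    Fixed effects: log10 mass, speed (centred within species, so the mass
    slope is a pure between-species contrast), and optionally taxon; random
    intercept per species and (by default) a random speed slope per species.
    A singular random-slope fit falls back to the intercept-only random
    structure, and degenerate (noise-free) data to plain least squares, both
    flagged on the result.  The pooled (taxon-free) model is the default,
    matching how a single published scaling line is reported; the intercept
    refers to a species flying at its own mean measured speed.
    """
    req = {"species", "taxon", "mass_kg", "speed", "efficiency"}
    if not req.issubset(estimates.columns):
        raise InvalidInputError(f"estimates table needs columns {sorted(req)}")
    df = estimates.copy()
    if df["species"].nunique() < 5:
        raise InsufficientDataError("need >= 5 species for the scaling fit")
    if include_taxon and df["taxon"].nunique() < 2:
        raise InsufficientDataError("taxon term needs both taxa present")
    df["log_eff"] = np.log10(100.0 * df["efficiency"])
    df["log_mass"] = np.log10(1000.0 * df["mass_kg"])  # grams
    df["is_bird"] = (df["taxon"] == "bird").astype(float)
    # speed centred within species: absolute speed ranges scale with body
    # size, so an uncentred speed term would leak mass signal into itself
    df["speed"] = df.groupby("species")["speed"].transform(lambda s: s - s.mean())

    cols = ["log_mass", "speed"] + (["is_bird"] if include_taxon else [])
    X = sm.add_constant(df[cols])

    def _fit(re_formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(df["log_eff"], X, groups=df["species"],
                               exog_re=(df[["speed"]].assign(const=1.0)[["const", "speed"]]
                                        if re_formula == "slope" else None))
            return model.fit(reml=True, method=["lbfgs", "powell"])

    singular = False
    fit = None
    if random_speed_slope:
        try:
            fit = _fit("slope")
            cov_re = np.asarray(fit.cov_re)
            if (not np.all(np.isfinite(cov_re))
                    or np.linalg.det(cov_re) <= 1e-12
                    or not np.all(np.isfinite(np.asarray(fit.bse_fe)))):
                raise np.linalg.LinAlgError("singular random-effects covariance")
            sd_int = float(np.sqrt(max(cov_re[0, 0], 0.0)))
            sd_slope = float(np.sqrt(max(cov_re[1, 1], 0.0)))
        except Exception:
            singular = True
            fit = None
    if fit is None:
        try:
            fit = _fit("intercept")
            sd_int = float(np.sqrt(max(float(np.asarray(fit.cov_re).ravel()[0]), 0.0)))
            sd_slope = 0.0
            if not np.all(np.isfinite(np.asarray(fit.fe_params))):
                raise ValueError("non-finite mixed fit")
        except Exception:
            # degenerate (e.g. noise-free) data: plain least squares, flagged
            singular = True
            fit = sm.OLS(df["log_eff"], X).fit()
            sd_int = 0.0
            sd_slope = 0.0

    params = fit.params if hasattr(fit, "params") and not hasattr(fit, "fe_params") \
        else fit.fe_params
    bse = fit.bse if not hasattr(fit, "bse_fe") else fit.bse_fe
    slope = float(params["log_mass"])
    slope_se = float(bse["log_mass"])
    taxon_z = taxon_p = np.nan
    if include_taxon:
        tz = float(params["is_bird"]) / float(bse["is_bird"]) \
            if float(bse["is_bird"]) > 0 else np.inf
        taxon_z = tz
        taxon_p = float(2.0 * (1.0 - _norm_cdf(abs(tz))))
    return ScalingFit(
        slope=slope,
        intercept=float(params["const"]),
        taxon_effect=float(params["is_bird"]) if include_taxon else 0.0,
        speed_effect=float(params["speed"]),
        sd_species_intercept=sd_int,
        sd_speed_slope=sd_slope,
        z_mass=slope / slope_se if slope_se > 0 else np.inf,
        p_mass=float(2.0 * (1.0 - _norm_cdf(abs(slope / slope_se))))
        if slope_se > 0 else 0.0,
        slope_se=slope_se,
        n_obs=len(df),
        singular=singular,
        taxon_z=taxon_z,
        taxon_p=taxon_p,
    )


def _norm_cdf(x: float) -> float:
    from math import erf, sqrt
    return 0.5 * (1.0 + erf(x / sqrt(2.0)))


def mass_correct(efficiency, mass_g, exponent: float = 0.24):
    """Mass-corrected efficiency: ``eta / mass_g**exponent`` (mass in grams)."""
    mass_g = np.asarray(mass_g, dtype=float)
    if np.any(mass_g <= 0):
        raise InvalidInputError("mass must be positive")
    out = np.asarray(efficiency, dtype=float) / mass_g**exponent
    return float(out) if out.ndim == 0 else out


def predict_efficiency(mass_g: float, fit: ScalingFit) -> float:
    """Predicted efficiency in percent at mass ``mass_g`` grams from the fit."""
    if mass_g <= 0:
        raise InvalidInputError("mass must be positive")
    return float(10.0 ** (fit.slope * np.log10(mass_g) + fit.intercept))


def near_ump_comparison(estimates: pd.DataFrame,
                        u_mp_met: dict[str, float],
                        window: float = 1.0) -> dict:
    """Bird-vs-bat contrast of efficiency near the minimum power speed.

    Per-species mean efficiency within ``+/- window`` m/s of that species'
    metabolic minimum power speed, then a linear model with a log10-mass by
    taxon interaction.  Species with an empty window are dropped with a
    notice.  With a single taxon only the group summary is returned.
    """
    rows = []
    for sp, grp in estimates.groupby("species"):
        if sp not in u_mp_met:
            log.info("species %s lacks a U_mp,met; dropped", sp)
            continue
        sel = grp[np.abs(grp["speed"] - u_mp_met[sp]) <= window]
        if sel.empty:
            log.info("species %s: empty +/-%.1f m/s window; dropped", sp, window)
            continue
        rows.append({"species": sp, "taxon": grp["taxon"].iloc[0],
                     "mass_kg": grp["mass_kg"].iloc[0],
                     "efficiency": float(sel["efficiency"].mean()),
                     "n": int(len(sel))})
    table = pd.DataFrame(rows)
    out = {"species_means": table, "group_summary": None, "taxon_t": np.nan,
           "taxon_p": np.nan}
    if table.empty:
        return out
    summary = (table.groupby("taxon")["efficiency"]
               .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x))
                    if len(x) > 1 else np.nan, n="size").reset_index())
    out["group_summary"] = summary
    if table["taxon"].nunique() == 2 and len(table) >= 4:
        log_mass = np.log10(1000.0 * table["mass_kg"])
        # centred so the taxon coefficient is the contrast at the mean mass
        table = table.assign(log_mass=log_mass - log_mass.mean())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols("efficiency ~ log_mass * taxon", data=table).fit()
        term = [t for t in ols.params.index if t.startswith("taxon[")][0]
        out["taxon_t"] = float(ols.tvalues[term])
        out["taxon_p"] = float(ols.pvalues[term])
    return out
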