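"""Aerodynamic flight-power models and characteristic-speed solvers.

Two steady-state models of the mechanical power required for level flapping
flight at air speed ``U``:

* :func:`pennycuick_power` -- the classic fixed-wing decomposition of
  Pennycuick's *Flight* program: induced power ``k W^2 / (2 rho S_d U)``
  (momentum-jet theory on the wing disc), parasite power
  ``1/2 rho U^3 S_b C_db`` from body drag, and a profile power that is
  constant with speed, ``(C_pro / AR) * P_am`` with ``P_am`` the absolute
  minimum of induced + parasite power.

* :func:`flap_model_power` -- a quasi-steady flapping-flight model in the
  spirit of the animal flight performance tool (afpt): the induced-power
  factor grows with the span-based Strouhal number ``St = f b / U`` (slow
  flight with vigorous flapping sheds a less efficient wake), and profile
  power carries both a steady ``U^3`` term and a flapping term set by the
  wingtip speed scale ``f b``.  The two flapping calibration constants are
  frozen in :data:`FLAP_CALIBRATION`; see ``docs/methods.md``.

Both models yield U-shaped power curves whose minimum defines the minimum
power speed ``U_mp`` and whose tangent from the origin defines the maximum
range speed ``U_mr`` (the cost-of-transport optimum).  For the
cubic-plus-inverse family ``P = k1 U^3 + k2/U + k3`` the minimum is
analytic: ``U_mp = (k2 / (3 k1))^(1/4)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Union

from scipy.optimize import minimize_scalar

from .exceptions import InvalidInputError, NoMinimumError

__all__ = [
    "Morphology",
    "Environment",
    "PowerComponents",
    "CharacteristicSpeeds",
    "ModelFlags",
    "STUDY_MORPHOLOGY",
    "FLAP_CALIBRATION",
    "pennycuick_power",
    "flap_model_power",
    "minimum_power_speed",
    "maximum_range_speed",
    "characteristic_speeds",
    "predict_met_from_mech",
    "allometric_frontal_area",
    "allometric_wingbeat_freq",
]

#: Coefficient and exponent of the allometric body frontal area
#: S_b = 0.00813 M^0.666 (m^2, M in kg), the Flight-program default.
FRONTAL_AREA_COEF = 0.00813
FRONTAL_AREA_EXP = 0.666

#: Default induced-power factor (ideal actuator disc would be 1.0).
INDUCED_POWER_FACTOR = 1.2

#: Profile-power constant: profile power = (C_PRO / aspect ratio) * P_am.
C_PRO = 8.4

#: Flapping-model constants.  ``k_ind0`` and ``cd_pro0`` are conventional
#: (quasi-steady induced factor, wing profile drag coefficient); the two
#: flapping corrections ``k_ind_st`` (Strouhal-squared induced amplification)
#: and ``c_flap`` (flapping profile power, wingtip-speed cubed scale) are
#: calibration constants of this implementation, frozen so that the model
#: reproduces published reference predictions for a 8.9 g, 0.23 m span bat
#: (U_mp = 4.6, U_mr = 6.0 m/s).  Closed-form derivation in docs/methods.md.
FLAP_CALIBRATION = {
    "k_ind0": 1.2,
    "k_ind_st": 2.7565368049,
    "cd_pro0": 0.02,
    "c_flap": 0.5015982098,
}

#: Validity envelope of the flapping model (red flags outside it).
FLAP_ENVELOPE = {
    "strouhal_min": 0.05,
    "strouhal_max": 1.0,
    "thrust_ratio_max": 0.5,
    "freq_ratio_band": (0.5, 2.0),
}


def allometric_frontal_area(body_mass: float) -> float:
    """Body frontal area (m^2) from mass (kg): ``0.00813 M^0.666``."""
    return FRONTAL_AREA_COEF * body_mass**FRONTAL_AREA_EXP


def allometric_wingbeat_freq(
    body_mass: float, wing_span: float, wing_area: float,
    air_density: float = 1.225, gravity: float = 9.81,
) -> float:
    """Allometric cruising wingbeat frequency (Hz).

    ``f = m^(3/8) g^(1/2) b^(-23/24) S^(-1/3) rho^(-3/8)`` -- used both to
    fill missing morphology and as the reference for the frequency red flag.
    """
    return (
        body_mass**0.375 * gravity**0.5 * wing_span**(-23.0 / 24.0)
        * wing_area**(-1.0 / 3.0) * air_density**(-0.375)
    )


@dataclass(frozen=True)
class Morphology:
    """Morphology of a flying animal.

    Parameters
    ----------
    body_mass : float
        Body mass in kg.
    wing_span : float
        Wingtip-to-wingtip span b in m.
    wing_area : float
        Planform area S of both wings including the body strip, m^2.
    wingbeat_freq : float
        Cruising wingbeat frequency in Hz.
    body_drag_coeff : float
        Body drag coefficient C_db referred to frontal area.
    body_frontal_area : float, optional
        Frontal area S_b in m^2; allometric default when omitted.
    """

    body_mass: float
    wing_span: float
    wing_area: float
    wingbeat_freq: float
    body_drag_coeff: float = 0.4
    body_frontal_area: float | None = None

    def __post_init__(self):
        for name in ("body_mass", "wing_span", "wing_area", "wingbeat_freq",
                     "body_drag_coeff"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise InvalidInputError(f"{name} must be strictly positive, got {value!r}")
        if self.body_frontal_area is not None and not self.body_frontal_area > 0:
            raise InvalidInputError("body_frontal_area must be strictly positive")

    @property
    def aspect_ratio(self) -> float:
        return self.wing_span**2 / self.wing_area

    @property
    def disc_area(self) -> float:
        """Wing disc area pi b^2 / 4 used by momentum-jet induced power."""
        return math.pi * self.wing_span**2 / 4.0

    @property
    def frontal_area(self) -> float:
        if self.body_frontal_area is not None:
            return self.body_frontal_area
        return allometric_frontal_area(self.body_mass)

    def weight(self, gravity: float = 9.81) -> float:
        return self.body_mass * gravity


@dataclass(frozen=True)
class Environment:
    """Ambient air: density (kg m^-3) and gravitational acceleration (m s^-2)."""

    air_density: float = 1.225
    gravity: float = 9.81

    def __post_init__(self):
        if not 0.8 < self.air_density < 1.5:
            raise InvalidInputError(
                f"air_density {self.air_density} outside plausible (0.8, 1.5) kg/m^3")
        if not self.gravity > 0:
            raise InvalidInputError("gravity must be positive")


#: The wind-tunnel study animal: a 8.9 g Nathusius' pipistrelle.
STUDY_MORPHOLOGY = Morphology(
    body_mass=0.0089,
    wing_span=0.23,
    wing_area=0.0077,
    wingbeat_freq=9.9,
    body_drag_coeff=0.4,
)


@dataclass(frozen=True)
class PowerComponents:
    """Mechanical power split into induced, parasite and profile parts (W)."""

    speed: float
    induced: float
    parasite: float
    profile: float
    total: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        summed = self.induced + self.parasite + self.profile
        if self.total is None:
            object.__setattr__(self, "total", summed)
        elif abs(self.total - summed) > 1e-9 * max(1.0, abs(summed)):
            raise InvalidInputError("total does not equal induced+parasite+profile")
        if min(self.induced, self.parasite, self.profile) < 0:
            raise InvalidInputError("power components must be non-negative")


@dataclass(frozen=True)
class CharacteristicSpeeds:
    """Minimum power speed and maximum range speed (m/s), u_mr >= u_mp."""

    u_mp: float
    u_mr: float

    def __post_init__(self):
        if self.u_mr < self.u_mp - 1e-6:
            raise InvalidInputError("u_mr cannot be below u_mp")


@dataclass(frozen=True)
class ModelFlags:
    """Validity red flags of the flapping model."""

    speed_flag: bool = False
    thrust_flag: bool = False
    frequency_flag: bool = False

    @property
    def any_flag(self) -> bool:
        return self.speed_flag or self.thrust_flag or self.frequency_flag


def _check_speed(speed: float) -> None:
    if not (speed > 0 and math.isfinite(speed)):
        raise InvalidInputError(f"speed must be strictly positive, got {speed!r}")


def pennycuick_power(morph: Morphology, env: Environment, speed: float) -> PowerComponents:
    """Mechanical power components from the fixed-wing (Flight-style) model.

    induced = k W^2 / (2 rho S_d U); parasite = 1/2 rho U^3 S_b C_db;
    profile = (8.4 / AR) * P_am, constant with speed, where P_am is the
    absolute minimum of induced + parasite power.
    """
    _check_speed(speed)
    W = morph.weight(env.gravity)
    A = INDUCED_POWER_FACTOR * W**2 / (2.0 * env.air_density * morph.disc_area)
    B = 0.5 * env.air_density * morph.frontal_area * morph.body_drag_coeff
    induced = A / speed
    parasite = B * speed**3
    u_mp = (A / (3.0 * B)) ** 0.25
    p_am = A / u_mp + B * u_mp**3
    profile = (C_PRO / morph.aspect_ratio) * p_am
    return PowerComponents(speed=speed, induced=induced, parasite=parasite, profile=profile)


def _flap_terms(morph: Morphology, env: Environment):
    cal = FLAP_CALIBRATION
    W = morph.weight(env.gravity)
    w_tilde = W**2 / (2.0 * env.air_density * morph.disc_area)
    fb = morph.wingbeat_freq * morph.wing_span
    a0 = cal["k_ind0"] * w_tilde
    a1 = cal["k_ind_st"] * fb**2 * w_tilde          # coefficient of U^-3
    b_par = 0.5 * env.air_density * morph.frontal_area * morph.body_drag_coeff
    b_pro = 0.5 * env.air_density * morph.wing_area * cal["cd_pro0"]
    c_pro = cal["c_flap"] * 0.5 * env.air_density * morph.wing_area * fb**3
    return a0, a1, b_par, b_pro, c_pro


def flap_model_power(
    morph: Morphology, env: Environment, speed: float
) -> tuple[PowerComponents, ModelFlags]:
    """Mechanical power from the quasi-steady flapping-flight model.

    induced = (k0 + k_st St^2) W^2 / (2 rho S_d U) with St = f b / U;
    parasite = 1/2 rho U^3 S_b C_db;
    profile  = 1/2 rho U^3 S cd0  +  c_flap * 1/2 rho S (f b)^3.

    Returns the components plus red flags marking inputs outside the
    model's validated envelope (Strouhal number, thrust-to-lift ratio,
    wingbeat frequency relative to the allometric expectation).
    """
    _check_speed(speed)
    a0, a1, b_par, b_pro, c_pro = _flap_terms(morph, env)
    induced = a0 / speed + a1 / speed**3
    parasite = b_par * speed**3
    profile = b_pro * speed**3 + c_pro
    comps = PowerComponents(speed=speed, induced=induced, parasite=parasite, profile=profile)

    st = morph.wingbeat_freq * morph.wing_span / speed
    env_lim = FLAP_ENVELOPE
    speed_flag = not (env_lim["strouhal_min"] <= st <= env_lim["strouhal_max"])
    thrust_ratio = comps.total / (speed * morph.weight(env.gravity))
    thrust_flag = thrust_ratio > env_lim["thrust_ratio_max"]
    f_ref = allometric_wingbeat_freq(
        morph.body_mass, morph.wing_span, morph.wing_area,
        env.air_density, env.gravity)
    lo, hi = env_lim["freq_ratio_band"]
    frequency_flag = not (lo <= morph.wingbeat_freq / f_ref <= hi)
    return comps, ModelFlags(speed_flag, thrust_flag, frequency_flag)


PowerCurve = Union[Callable[[float], float], tuple, "CurveCoefficients"]  # noqa: F821


def _as_callable(power_curve) -> tuple[Callable[[float], float], tuple | None]:
    """Normalize a power-curve argument to (callable, coeff-triple-or-None)."""
    if callable(power_curve):
        return power_curve, None
    if hasattr(power_curve, "k1"):  # CurveCoefficients duck type
        triple = (power_curve.k1, power_curve.k2, power_curve.k3)
    else:
        triple = tuple(power_curve)
    if len(triple) != 3:
        raise InvalidInputError("coefficient form must be (k1, k2, k3)")
    k1, k2, k3 = triple
    return (lambda u: k1 * u**3 + k2 / u + k3), triple


def minimum_power_speed(power_curve, bracket: tuple[float, float] = (0.1, 40.0),
                        xatol: float = 1e-3) -> float:
    """Speed minimizing the power curve.

    Analytic ``(k2/(3 k1))**0.25`` for a (k1, k2, k3) coefficient triple;
    bounded numerical minimization for a callable.
    """
    func, triple = _as_callable(power_curve)
    if triple is not None:
        k1, k2, _ = triple
        if k1 <= 0 or k2 <= 0:
            raise NoMinimumError("cubic-plus-inverse curve needs k1, k2 > 0 for a minimum")
        return (k2 / (3.0 * k1)) ** 0.25
    res = minimize_scalar(func, bounds=bracket, method="bounded",
                          options={"xatol": xatol})
    lo, hi = bracket
    margin = 10 * xatol
    if not (lo + margin < res.x < hi - margin):
        raise NoMinimumError(
            f"no interior power minimum on ({lo}, {hi}); minimizer at {res.x:.3f}")
    return float(res.x)


def maximum_range_speed(power_curve, bracket: tuple[float, float] = (0.1, 40.0),
                        xatol: float = 1e-3) -> float:
    """Speed minimizing power per unit distance, P(U)/U (tangent from origin)."""
    func, triple = _as_callable(power_curve)
    lo, hi = bracket
    if triple is not None:
        # the tangent speed of the cubic-plus-inverse family lies within a
        # factor ~1.9 of u_mp; widen the bracket so it is always interior
        u_mp = minimum_power_speed(power_curve)
        hi = max(hi, 5.0 * u_mp)
        lo = min(lo, 0.2 * u_mp)
    res = minimize_scalar(lambda u: func(u) / u, bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    margin = 10 * xatol
    if not (lo + margin < res.x < hi - margin):
        raise NoMinimumError(
            f"no interior cost-of-transport minimum on ({lo}, {hi}); minimizer at {res.x:.3f}")
    return float(res.x)


def characteristic_speeds(power_curve, **kwargs) -> CharacteristicSpeeds:
    """Both characteristic speeds of a power curve."""
    u_mp = minimum_power_speed(power_curve, **kwargs)
    u_mr = maximum_range_speed(power_curve, **kwargs)
    return CharacteristicSpeeds(u_mp=u_mp, u_mr=max(u_mr, u_mp))


def predict_met_from_mech(p_mech: float, bmr: float, efficiency: float = 0.23) -> float:
    """Metabolic power predicted from mechanical power.

    ``P_met = 1.1 (P_mech / eta + BMR)``: whole-animal conversion efficiency
    eta plus a 1.1 respiratory/circulatory overhead on top of basal rate.
    """
    if not 0.0 < efficiency <= 1.0:
        raise InvalidInputError(f"efficiency must be in (0, 1], got {efficiency!r}")
    if p_mech < 0 or bmr < 0:
        raise InvalidInputError("p_mech and bmr must be non-negative")
    return 1.1 * (p_mech / efficiency + bmr)
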