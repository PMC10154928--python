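"""Constrained U-shaped power-curve fits with individual random effects.

Flight power against air speed is modelled by the cubic-plus-inverse family

    P(U) = k1 U^3 + k2 / U + k3 + b_i + eps,

where k1 carries parasite power (U^3), k2 induced power (1/U), k3 the
speed-independent profile power, and b_i a Gaussian random intercept per
individual.  Because the family is linear in (k1, k2, k3) the mixed model is
fitted with a linear mixed-effects solver on the basis (U^3, 1/U, 1).

In ``k3_mode='fixed'`` the profile term follows the convention that profile
power is half of total power at the minimum power speed: k3 is pinned to
0.5 times the mean observed power in the 1 m/s bin at a prior U_mp (from an
aerodynamic model) before k1 and k2 are fitted -- a two-step procedure, not
a joint constrained fit.

Speeds can be normalized across individuals of different weight by
``U* = U (W_ref / W)^(1/6)``, the expected weight scaling of characteristic
speeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .exceptions import IdentifiabilityError, InsufficientDataError, InvalidInputError

__all__ = [
    "CurveCoefficients",
    "LinearComparison",
    "normalize_speed",
    "fit_power_curve",
    "compare_to_linear",
    "specific_power",
    "REQUIRED_COLUMNS",
]

#: Column conventions for flight-power record tables.
REQUIRED_COLUMNS = ("individual", "speed_ms", "power_w")


@dataclass(frozen=True)
class CurveCoefficients:
    """Fitted coefficients of ``P = k1 U^3 + k2/U + k3`` plus fit metadata."""

    k1: float
    k2: float
    k3: float
    k3_fixed: bool = False
    random_intercept_sd: float = 0.0
    loglik: float = np.nan
    n_obs: int = 0
    speed_min: float = np.nan
    speed_max: float = np.nan

    def __call__(self, speed):
        speed = np.asarray(speed, dtype=float)
        if np.any(speed <= 0):
            raise InvalidInputError("speed must be positive")
        out = self.k1 * speed**3 + self.k2 / speed + self.k3
        return float(out) if out.ndim == 0 else out

    @property
    def u_mp(self) -> float:
        """Analytic minimum power speed (k2 / 3 k1)^(1/4)."""
        return (self.k2 / (3.0 * self.k1)) ** 0.25


@dataclass(frozen=True)
class LinearComparison:
    """Likelihood-ratio comparison of the U-shaped and linear mixed models."""

    likelihood_ratio: float
    df: int
    p_value: float
    aic_ucurve: float
    aic_linear: float
    non_nested: bool = True  # the two families are not nested; LRT is approximate


def normalize_speed(speed, weight, reference_weight):
    """Weight-normalized air speed ``U* = U (W_ref / W)^(1/6)``."""
    speed = np.asarray(speed, dtype=float)
    weight = np.asarray(weight, dtype=float)
    if np.any(weight <= 0) or np.any(np.asarray(reference_weight) <= 0):
        raise InvalidInputError("weights must be positive")
    out = speed * (reference_weight / weight) ** (1.0 / 6.0)
    return float(out) if out.ndim == 0 else out


def _validate_records(records: pd.DataFrame, speed_col: str) -> pd.DataFrame:
    for col in ("individual", speed_col, "power_w"):
        if col not in records.columns:
            raise InvalidInputError(f"records table lacks column {col!r}")
    if np.any(records[speed_col] <= 0) or np.any(records["power_w"] <= 0):
        raise InvalidInputError("speeds and powers must be positive")
    return records


def _mixed_or_ols(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Fit y = X beta + random intercept by group; OLS fallback for one group.

    Returns (beta, random intercept sd, loglik, aic).
    """
    ols = sm.OLS(y, X).fit()
    ols_out = (np.asarray(ols.params, dtype=float), 0.0, float(ols.llf),
               float(-2.0 * ols.llf + 2.0 * (X.shape[1] + 1)))
    if len(np.unique(groups)) < 2:
        return ols_out
    # scale columns to unit RMS: the raw basis (U^3 vs 1/U) is badly enough
    # conditioned that the mixed-model optimizer can otherwise return garbage
    scale = np.sqrt(np.mean(X**2, axis=0))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X / scale, groups=groups)
            fit = model.fit(reml=False, method=["lbfgs", "powell"])
        beta = np.asarray(fit.fe_params, dtype=float) / scale
        re_sd = float(np.sqrt(max(float(np.asarray(fit.cov_re).ravel()[0]), 0.0)))
        loglik = float(fit.llf)
    except (np.linalg.LinAlgError, ValueError):
        return ols_out
    # OLS is the zero-variance special case: a mixed fit that collapses to
    # the boundary, scores worse than OLS, or returns non-finite quantities
    # has failed, and the boundary solution is used instead
    if (not np.all(np.isfinite(beta)) or not np.isfinite(loglik)
            or re_sd <= 1e-10 or loglik < ols_out[2] - 1e-8):
        return ols_out
    return beta, re_sd, loglik, float(-2.0 * loglik + 2.0 * (X.shape[1] + 2))


def fit_power_curve(records: pd.DataFrame,
                    k3_mode: str = "fixed",
                    u_mp_prior: float = 4.6,
                    k3_value: float | None = None,
                    speed_col: str = "speed_ms") -> CurveCoefficients:
    """Fit the cubic-plus-inverse power curve with individual random intercepts.

    Parameters
    ----------
    records : DataFrame
        Columns ``individual``, ``speed_ms`` (or ``speed_col``), ``power_w``.
    k3_mode : {'fixed', 'free'}
        ``'fixed'`` pins k3 to half the mean observed power in the 1 m/s bin
        centred on ``round(u_mp_prior)`` before fitting k1, k2;
        ``'free'`` estimates all three coefficients.
    u_mp_prior : float
        Minimum power speed prior from an aerodynamic model (m/s); only used
        in fixed mode.
    k3_value : float, optional
        Pin k3 at this value directly instead of the binned-data estimate.
    """
    records = _validate_records(records, speed_col)
    speeds = records[speed_col].to_numpy(dtype=float)
    power = records["power_w"].to_numpy(dtype=float)
    groups = records["individual"].to_numpy()
    if np.ptp(speeds) < 1e-9:
        raise IdentifiabilityError("all speeds identical; k1 and k2 not identifiable")

    if k3_mode == "fixed":
        if k3_value is not None:
            k3 = float(k3_value)
        else:
            centre = round(float(u_mp_prior))
            in_bin = np.abs(speeds - centre) <= 0.5
            if not in_bin.any():
                raise InsufficientDataError(
                    f"no records in the 1 m/s bin at {centre} m/s to pin k3")
            k3 = 0.5 * float(power[in_bin].mean())
        X = np.column_stack([speeds**3, 1.0 / speeds])
        beta, re_sd, loglik, _ = _mixed_or_ols(power - k3, X, groups)
        k1, k2 = float(beta[0]), float(beta[1])
    elif k3_mode == "free":
        X = np.column_stack([speeds**3, 1.0 / speeds, np.ones_like(speeds)])
        if np.linalg.matrix_rank(X) < 3:
            raise IdentifiabilityError("design matrix rank deficient")
        beta, re_sd, loglik, _ = _mixed_or_ols(power, X, groups)
        k1, k2, k3 = (float(b) for b in beta)
    else:
        raise InvalidInputError("k3_mode must be 'fixed' or 'free'")

    if k1 <= 0 or k2 <= 0:
        warnings.warn(
            f"fitted curve is not U-shaped (k1={k1:.3g}, k2={k2:.3g}); "
            "characteristic speeds undefined", stacklevel=2)
    return CurveCoefficients(
        k1=k1, k2=k2, k3=k3, k3_fixed=(k3_mode == "fixed"),
        random_intercept_sd=re_sd, loglik=loglik, n_obs=len(records),
        speed_min=float(speeds.min()), speed_max=float(speeds.max()))


def compare_to_linear(records: pd.DataFrame,
                      speed_col: str = "speed_ms") -> LinearComparison:
    """Likelihood-ratio comparison of the U-shaped model against a linear one.

    Both mixed models (random intercept per individual) are fitted by
    maximum likelihood on identical records; the statistic ``2 dlogLik`` is
    referred to a chi-squared with df equal to the fixed-parameter
    difference (1).  The families are not nested, so the test is heuristic;
    AICs are reported alongside and a non-nestedness flag is always set.
    """
    records = _validate_records(records, speed_col)
    speeds = records[speed_col].to_numpy(dtype=float)
    power = records["power_w"].to_numpy(dtype=float)
    groups = records["individual"].to_numpy()

    Xu = np.column_stack([speeds**3, 1.0 / speeds, np.ones_like(speeds)])
    Xl = np.column_stack([speeds, np.ones_like(speeds)])
    _, _, ll_u, aic_u = _mixed_or_ols(power, Xu, groups)
    _, _, ll_l, aic_l = _mixed_or_ols(power, Xl, groups)
    lr = max(2.0 * (ll_u - ll_l), 0.0)
    df = Xu.shape[1] - Xl.shape[1]
    warnings.warn("U-shaped vs linear models are not nested; "
                  "treat the LRT p-value as approximate (see AICs)", stacklevel=2)
    return LinearComparison(
        likelihood_ratio=lr, df=df, p_value=float(stats.chi2.sf(lr, df)),
        aic_ucurve=aic_u, aic_linear=aic_l)


def specific_power(records: pd.DataFrame, mode: str = "weight") -> pd.DataFrame:
    """Power per newton of weight (metabolic) or lift (mechanical).

    ``mode='weight'`` divides ``power_w`` by ``weight_n``; ``mode='lift'``
    by ``lift_n``.  Returns a copy with a ``specific_power_w_per_n`` column.
    """
    out = records.copy()
    if mode == "weight":
        col = "weight_n"
    elif mode == "lift":
        col = "lift_n"
    else:
        raise InvalidInputError("mode must be 'weight' or 'lift'")
    if col not in out.columns or out[col].isna().any():
        raise InvalidInputError(f"records lack a complete {col!r} column")
    if np.any(out[col] <= 0):
        raise InvalidInputError(f"{col} must be positive")
    out["specific_power_w_per_n"] = out["power_w"] / out[col]
    return out
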