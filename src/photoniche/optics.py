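"""Water-column optics and logger-environment summaries.

Downwelling irradiance in a homogeneous water column decays exponentially
with depth, ``E_z = E_0 * exp(-K_d * z)``, where ``K_d`` (m^-1) is the
diffuse attenuation coefficient for downwelling irradiance. This module
estimates ``K_d`` from a light-depth profile by ordinary least squares on
log-transformed irradiance, converts depths to percent-of-surface
irradiance (and back), translates a depth response measured in one water
type into the equivalent depth change in clearer or murkier water, and
summarises temperature/light logger time series into the site-level
statistics used to contrast shallow and deep habitats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, DomainError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "LightProfile",
    "OpticalModel",
    "EnvironmentSummary",
    "fit_kd",
    "percent_surface_irradiance",
    "depth_for_irradiance",
    "equivalent_depth_increase",
    "summarize_loggers",
]


@dataclass(frozen=True)
class LightProfile:
    """Paired depth (m, positive downward) and irradiance readings.

    Irradiance may be in any fixed instrument unit; only ratios matter for
    the attenuation fit. At least three readings at three distinct depths
    are required, and every irradiance must be strictly positive (the fit
    is on a log scale).
    """

    depth_m: np.ndarray
    irradiance: np.ndarray

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth_m, dtype=float)
        irr = np.asarray(self.irradiance, dtype=float)
        object.__setattr__(self, "depth_m", depth)
        object.__setattr__(self, "irradiance", irr)
        if depth.ndim != 1 or irr.ndim != 1 or depth.size != irr.size:
            raise SchemaError("depth_m and irradiance must be 1-d and equal length")
        if depth.size < 3:
            raise DegenerateDataError("light profile needs at least 3 readings")
        if np.unique(depth).size < 3:
            raise DegenerateDataError("light profile needs at least 3 distinct depths")
        if np.any(depth < 0) or not np.all(np.isfinite(depth)):
            raise DomainError("depths must be finite and non-negative (positive downward)")
        if np.any(irr <= 0) or not np.all(np.isfinite(irr)):
            raise DomainError("irradiance must be finite and strictly positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LightProfile":
        missing = {"depth_m", "irradiance"} - set(df.columns)
        if missing:
            raise SchemaError(f"light profile table missing column(s): {sorted(missing)}")
        return cls(df["depth_m"].to_numpy(float), df["irradiance"].to_numpy(float))

    def __len__(self) -> int:
        return int(self.depth_m.size)


@dataclass(frozen=True)
class OpticalModel:
    """Fitted exponential attenuation law for one water column.

    Attributes
    ----------
    kd : float
        Diffuse attenuation coefficient for downwelling irradiance (m^-1).
    e0 : float
        Fitted surface irradiance (instrument units, or 100 when relative).
    r_squared : float or None
        Coefficient of determination of the log-linear regression; ``None``
        when the model was built from stated coefficients rather than fit.
    """

    kd: float
    e0: float
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.kd):
            raise DomainError("kd must be finite")
        if not (self.e0 > 0):
            raise DomainError("e0 must be positive")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise DomainError("r_squared must lie in [0, 1]")

    def predict(self, depth_m):
        """Irradiance at depth in the fitted units: ``e0 * exp(-kd * z)``."""
        z = np.asarray(depth_m, dtype=float)
        if np.any(z < 0):
            raise DomainError("depth must be non-negative")
        return self.e0 * np.exp(-self.kd * z)


@dataclass(frozen=True)
class EnvironmentSummary:
    """Shallow-vs-deep summary of logger time series (daily aggregation)."""

    site_labels: tuple[str, str]
    shallow_temp_mean: float
    shallow_temp_sd: float
    deep_temp_mean: float
    deep_temp_sd: float
    shallow_light_cv: float
    deep_light_cv: float
    variability_ratio: float
    t_statistic: float
    df: float
    p_value: float
    n_days: tuple[int, int]

    def __post_init__(self) -> None:
        if self.shallow_temp_sd < 0 or self.deep_temp_sd < 0:
            raise DomainError("standard deviations must be non-negative")
        if not (self.variability_ratio > 0):
            raise DomainError("variability_ratio must be positive")
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError("p_value must lie in [0, 1]")


def fit_kd(profile: LightProfile) -> OpticalModel:
    """Estimate K_d and E_0 by OLS of ln(irradiance) on depth.

    The attenuation law is linear on a log scale: ``ln E_z = ln E_0 - K_d z``.
    K_d is minus the fitted slope, E_0 the exponentiated intercept, and
    r_squared the coefficient of determination of the log-linear regression.
    """
    if not isinstance(profile, LightProfile):
        profile = LightProfile.from_dataframe(profile)
    res = stats.linregress(profile.depth_m, np.log(profile.irradiance))
    return OpticalModel(kd=-res.slope, e0=float(np.exp(res.intercept)),
                        r_squared=float(res.rvalue**2))


def percent_surface_irradiance(model: OpticalModel, depth_m):
    """Percent of surface irradiance reaching ``depth_m``: 100*exp(-kd*z).

    Strictly decreasing in depth (for kd > 0) and equal to 100 at z = 0.
    Accepts scalars or arrays of depth.
    """
    z = np.asarray(depth_m, dtype=float)
    if np.any(z < 0):
        raise DomainError("depth must be non-negative")
    out = 100.0 * np.exp(-model.kd * z)
    return float(out) if np.isscalar(depth_m) else out


def depth_for_irradiance(model: OpticalModel, percent: float) -> float:
    """Depth (m) at which irradiance falls to ``percent`` of the surface value.

    Inverse of :func:`percent_surface_irradiance`; requires an attenuating
    water column (kd > 0) and percent in (0, 100].
    """
    if model.kd <= 0:
        raise DomainError("depth inversion requires kd > 0")
    if not (0.0 < percent <= 100.0):
        raise DomainError("percent must lie in (0, 100]")
    return float(-np.log(percent / 100.0) / model.kd)


def equivalent_depth_increase(kd_reference: float, delta_z_reference: float,
                              kd_target: float) -> float:
    """Depth increase in target water matching a reference attenuation change.

    A depth increase dz in water with attenuation kd reduces irradiance by the
    factor exp(-kd*dz); the same optical response in water of attenuation
    ``kd_target`` occurs over ``kd_reference * delta_z_reference / kd_target``
    metres, conserving the product kd*dz.
    """
    for name, val in (("kd_reference", kd_reference),
                      ("delta_z_reference", delta_z_reference),
                      ("kd_target", kd_target)):
        if not (val > 0):
            raise DomainError(f"{name} must be positive")
    return kd_reference * delta_z_reference / kd_target


def _daily_means(series: pd.DataFrame, label: str) -> pd.DataFrame:
    """Aggregate raw logger readings to calendar-day means."""
    required = {"timestamp", "temperature_c", "relative_light"}
    missing = required - set(series.columns)
    if missing:
        raise SchemaError(f"{label} logger table missing column(s): {sorted(missing)}")
    if len(series) == 0:
        raise DegenerateDataError(f"{label} logger series is empty")
    try:
        ts = pd.to_datetime(series["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{label} logger timestamps are not parseable ISO-8601: {exc}") from exc
    daily = (
        series.assign(_date=ts.dt.normalize())
        .groupby("_date")[["temperature_c", "relative_light"]]
        .mean()
        .dropna()
    )
    if len(daily) < 2:
        raise DegenerateDataError(f"{label} logger series covers fewer than 2 days")
    logger.info("%s loggers: %d readings aggregated to %d days", label, len(series), len(daily))
    return daily


def summarize_loggers(shallow_series: pd.DataFrame, deep_series: pd.DataFrame,
                      equal_var: bool = True) -> EnvironmentSummary:
    """Contrast shallow vs deep logger series on daily aggregates.

    Raw 30-min (or any cadence) readings are averaged to calendar-day means
    first; the temperature contrast is a two-sample t-test on daily means
    (Student's pooled-variance test by default, Welch with
    ``equal_var=False``), and light variability is the coefficient of
    variation of daily mean relative light, reported as the shallow/deep
    ratio. Daily aggregation damps the diel light cycle so the CV reflects
    day-to-day (weather-driven) variability.
    """
    daily_s = _daily_means(shallow_series, "shallow")
    daily_d = _daily_means(deep_series, "deep")
    ts = daily_s["temperature_c"].to_numpy()
    td = daily_d["temperature_c"].to_numpy()
    res = stats.ttest_ind(ts, td, equal_var=equal_var)
    if np.isnan(res.statistic):  # zero variance in both groups
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    ls = daily_s["relative_light"].to_numpy()
    ld = daily_d["relative_light"].to_numpy()
    cv_s = float(np.std(ls, ddof=1) / np.mean(ls))
    cv_d = float(np.std(ld, ddof=1) / np.mean(ld))
    if cv_d == 0.0 and cv_s == 0.0:
        ratio = 1.0
    elif cv_d == 0.0:
        raise DegenerateDataError("deep light series has zero variability; CV ratio undefined")
    else:
        ratio = cv_s / cv_d
    return EnvironmentSummary(
        site_labels=("shallow", "deep"),
        shallow_temp_mean=float(np.mean(ts)),
        shallow_temp_sd=float(np.std(ts, ddof=1)),
        deep_temp_mean=float(np.mean(td)),
        deep_temp_sd=float(np.std(td, ddof=1)),
        shallow_light_cv=cv_s,
        deep_light_cv=cv_d,
        variability_ratio=ratio,
        t_statistic=t_stat,
        df=float(getattr(res, "df", len(ts) + len(td) - 2)),
        p_value=p_val,
        n_days=(len(daily_s), len(daily_d)),
    )


def compare_daily_temperatures(shallow_daily: Sequence[float],
                               deep_daily: Sequence[float],
                               equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t statistic and p-value on pre-aggregated daily means."""
    a = np.asarray(shallow_daily, float)
    b = np.asarray(deep_daily, float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("each site needs at least 2 daily means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
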