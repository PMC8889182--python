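"""PAM chlorophyll-fluorescence statistics: Q_m and F_v/F_m calibration.

The maximum excitation pressure over photosystem II is

    Q_m = 1 - (dF/Fm') / (Fv/Fm)

where dF/Fm' is the effective quantum yield measured at noon (peak light)
and Fv/Fm the maximum quantum yield measured at dusk on the same colony.
Q_m near 1 indicates chronic light stress; Q_m near 0 indicates
light-limited photochemistry. For survey colonies measured only at noon,
Fv/Fm is predicted from a per-species linear calibration of Fv/Fm against
depth, and the provenance of each Q_m value (measured vs predicted Fv/Fm)
is recorded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateDataError, DomainError

logger = logging.getLogger(__name__)

TREATMENTS = ("S-S", "S-D", "D-S", "D-D")

#: smallest admissible Fv/Fm prediction; yields are truncated into (0, 1]
_FVFM_FLOOR = 1e-6

__all__ = [
    "DepthCalibration",
    "TTestResult",
    "compute_qm",
    "calibrate_fvfm_depth",
    "predict_fvfm",
    "estimate_survey_qm",
    "compare_treatments",
]


@dataclass(frozen=True)
class DepthCalibration:
    """Linear calibration of dusk Fv/Fm against depth for one species."""

    species: str
    slope: float      # Fv/Fm units per metre
    intercept: float
    r_squared: float
    n: int
    slope_se: float
    depth_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n < 3:
            raise DegenerateDataError("calibration needs n >= 3")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise DomainError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class TTestResult:
    """Two-sample comparison of a fluorometry variable between groups."""

    labels: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    t_statistic: float
    df: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError("p_value must lie in [0, 1]")
        if not (self.df > 0):
            raise DomainError("degrees of freedom must be positive")

    def summary(self) -> str:
        (la, lb), (ma, mb), (sa, sb) = self.labels, self.means, self.sds
        return (f"{la}: {ma:.3f} ± {sa:.3f} vs {lb}: {mb:.3f} ± {sb:.3f} "
                f"(t-value = {self.t_statistic:.2f}, p = {self.p_value:.3g})")


def compute_qm(delta_f_fm_prime, fv_fm):
    """Excitation pressure ``Q_m = 1 - (dF/Fm') / (Fv/Fm)``.

    Vectorised over array inputs. Negative results (noon yield above the
    dusk yield, i.e. measurement noise under light limitation) are
    preserved, not clamped. NaN in either yield propagates to NaN.
    """
    dff = np.asarray(delta_f_fm_prime, dtype=float)
    fvfm = np.asarray(fv_fm, dtype=float)
    if np.any(fvfm[~np.isnan(fvfm)] <= 0):
        raise DomainError("Fv/Fm must be positive")
    if np.any(dff[~np.isnan(dff)] < 0):
        raise DomainError("dF/Fm' must be non-negative")
    out = 1.0 - dff / fvfm
    if out.ndim == 0:
        return float(out)
    return out


def calibrate_fvfm_depth(records: pd.DataFrame, species: str | None = None) -> DepthCalibration:
    """OLS calibration of measured dusk Fv/Fm on depth for one species.

    ``records`` needs columns ``depth_m`` and ``fv_fm`` (rows with missing
    ``fv_fm`` are dropped and counted); if a ``species`` column is present
    it must be homogeneous unless ``species`` selects one.
    """
    df = records
    if "species" in df.columns:
        if species is not None:
            df = df[df["species"] == species]
        else:
            uniq = df["species"].unique()
            if len(uniq) > 1:
                raise ConfigError(f"records contain multiple species {list(uniq)}; pass species=")
            species = str(uniq[0]) if len(uniq) else None
    n_dropped = int(df["fv_fm"].isna().sum())
    if n_dropped:
        logger.info("calibration: dropped %d records without measured Fv/Fm", n_dropped)
    df = df.dropna(subset=["fv_fm"])
    depth = df["depth_m"].to_numpy(float)
    fvfm = df["fv_fm"].to_numpy(float)
    if depth.size < 3 or np.unique(depth).size < 3:
        raise DegenerateDataError("calibration needs >= 3 records at >= 3 distinct depths")
    res = stats.linregress(depth, fvfm)
    return DepthCalibration(
        species=species or "",
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(depth.size),
        slope_se=float(res.stderr),
        depth_range=(float(depth.min()), float(depth.max())),
    )


def predict_fvfm(calibration: DepthCalibration, depth_m):
    """Predicted dusk Fv/Fm at depth from the linear calibration.

    Predictions are truncated into (0, 1] — the calibration line itself is
    unconstrained — with a logged warning on truncation; depths outside the
    calibration range trigger an extrapolation warning but are evaluated.
    """
    z = np.asarray(depth_m, dtype=float)
    lo, hi = calibration.depth_range
    if np.any(z < lo) or np.any(z > hi):
        warnings.warn(
            f"predicting Fv/Fm outside the calibration depth range [{lo}, {hi}] m",
            UserWarning, stacklevel=2)
    pred = calibration.intercept + calibration.slope * z
    n_trunc = int(np.sum((pred > 1.0) | (pred < _FVFM_FLOOR)))
    if n_trunc:
        warnings.warn(
            f"{n_trunc} Fv/Fm prediction(s) truncated into (0, 1]",
            UserWarning, stacklevel=2)
        logger.warning("predict_fvfm: %d prediction(s) truncated into (0, 1]", n_trunc)
    pred = np.clip(pred, _FVFM_FLOOR, 1.0)
    return float(pred) if np.isscalar(depth_m) else pred


def estimate_survey_qm(records: pd.DataFrame, calibration: DepthCalibration,
                       prefer_measured: bool = True) -> pd.DataFrame:
    """Q_m for survey colonies, predicting Fv/Fm from depth where unmeasured.

    Returns a table ``species, colony_id, depth_m, qm, source`` with
    ``source`` in {"measured", "fvfm_predicted"}. Records missing the noon
    yield are skipped with a logged count. Colonies that do carry a dusk
    measurement use it directly when ``prefer_measured`` (default); set
    False to force the calibration prediction for all colonies.
    """
    if "species" in records.columns:
        mismatched = records["species"] != calibration.species
        if mismatched.any():
            raise ConfigError(
                f"records species {sorted(records.loc[mismatched, 'species'].unique())} "
                f"do not match calibration species {calibration.species!r}")
    df = records.copy()
    n_missing = int(df["delta_f_fm_prime"].isna().sum())
    if n_missing:
        logger.info("estimate_survey_qm: skipped %d records missing dF/Fm'", n_missing)
        df = df.dropna(subset=["delta_f_fm_prime"])
    if len(df) == 0:
        raise DegenerateDataError("no survey records carry a noon yield")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # range warnings handled per-call sites
        predicted = predict_fvfm(calibration, df["depth_m"].to_numpy(float))
    measured = df["fv_fm"].to_numpy(float) if "fv_fm" in df.columns else np.full(len(df), np.nan)
    use_measured = prefer_measured & ~np.isnan(measured)
    fvfm = np.where(use_measured, measured, predicted)
    qm = compute_qm(df["delta_f_fm_prime"].to_numpy(float), fvfm)
    return pd.DataFrame({
        "species": calibration.species,
        "colony_id": df["colony_id"].to_numpy() if "colony_id" in df.columns else np.arange(len(df)),
        "depth_m": df["depth_m"].to_numpy(float),
        "qm": qm,
        "source": np.where(use_measured, "measured", "fvfm_predicted"),
    })


def _extract(group, variable: str) -> np.ndarray:
    if isinstance(group, pd.DataFrame):
        vals = group[variable].dropna().to_numpy(float)
    else:
        vals = np.asarray(group, dtype=float)
        vals = vals[~np.isnan(vals)]
    return vals


def compare_treatments(group_a, group_b, variable: str = "qm",
                       labels: tuple[str, str] = ("group_a", "group_b"),
                       equal_var: bool = False) -> TTestResult:
    """Two-sample t-test on a yield variable between two treatment groups.

    Groups may be DataFrames (``variable`` selects the column, one of
    ``fv_fm``/``qm``/``delta_f_fm_prime``) or plain sequences. Welch's
    unequal-variance test is the default.
    """
    a = _extract(group_a, variable)
    b = _extract(group_b, variable)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(res.statistic):  # both groups constant and equal
        t_stat, p_val, dof = 0.0, 1.0, float(a.size + b.size - 2)
    else:
        t_stat, p_val, dof = float(res.statistic), float(res.pvalue), float(res.df)
    return TTestResult(
        labels=labels,
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        t_statistic=t_stat,
        df=dof,
        p_value=p_val,
    )
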