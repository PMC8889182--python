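"""Photic-niche depth limits from Q_m ~ depth regressions.

Across a species' vertical range, excitation pressure Q_m declines roughly
linearly with depth: colonies near the surface run their photosystems under
excess light (high Q_m), colonies at depth under light limitation (Q_m near
0). The x-intercept of the fitted line — the depth where Q_m reaches the
theoretical minimum of 0 — is interpreted as the bioenergetic lower
boundary of the species' photic niche. This module fits the per-species
lines, attaches a case-resampling bootstrap confidence interval to the
x-intercept, contrasts slopes between species by ANCOVA (extra
sum-of-squares F-test for the species-by-depth interaction), and reports
slope ratios.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateDataError, DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "NicheLimitModel",
    "DepthLimitEstimate",
    "AncovaResult",
    "fit_qm_depth",
    "depth_limit",
    "ancova_interaction",
    "slope_ratio",
]


@dataclass(frozen=True)
class NicheLimitModel:
    """Per-species linear model of Q_m against depth.

    Holds the fitted coefficients plus (optionally) the underlying records,
    which are needed for the bootstrap interval and the pointwise
    confidence band. Models built from stated coefficients via
    :meth:`from_coefficients` carry no data.
    """

    species: str
    slope: float       # Q_m units per metre
    intercept: float
    r_squared: float | None
    n: int
    residual_sd: float | None = None
    slope_se: float | None = None
    depth_m: np.ndarray | None = field(default=None, repr=False)
    qm: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise DomainError("r_squared must lie in [0, 1]")
        if self.depth_m is not None and self.n < 3:
            raise DegenerateDataError("fitted model needs n >= 3")

    @classmethod
    def from_coefficients(cls, intercept: float, slope: float,
                          species: str = "") -> "NicheLimitModel":
        """Build a coefficient-only model, e.g. from a published regression."""
        return cls(species=species, slope=float(slope), intercept=float(intercept),
                   r_squared=None, n=0)

    def predict(self, depth_m):
        z = np.asarray(depth_m, dtype=float)
        out = self.intercept + self.slope * z
        return float(out) if np.isscalar(depth_m) else out

    def confidence_band(self, depth_grid, level: float = 0.95):
        """Pointwise CI for the mean response on a depth grid.

        Classical OLS band: ``yhat ± t * s * sqrt(1/n + (z - zbar)^2/Sxx)``.
        Requires the fitted records.
        """
        if self.depth_m is None or self.residual_sd is None:
            raise DegenerateDataError("confidence band requires the fitted records")
        z = np.asarray(depth_grid, dtype=float)
        x = self.depth_m
        sxx = float(np.sum((x - x.mean()) ** 2))
        se = self.residual_sd * np.sqrt(1.0 / self.n + (z - x.mean()) ** 2 / sxx)
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        yhat = self.predict(z)
        return yhat - tcrit * se, yhat + tcrit * se


@dataclass(frozen=True)
class DepthLimitEstimate:
    """x-intercept of the Q_m line: the theoretical depth limit z*."""

    species: str
    z_star: float
    ci_low: float | None
    ci_high: float | None
    bootstrap_reps: int
    n_discarded: int
    seed: int | None

    @property
    def z_star_rounded(self) -> float:
        """Depth limit rounded to 0.1 m, the reporting convention."""
        return round(self.z_star, 1)


@dataclass(frozen=True)
class AncovaResult:
    """Extra-sum-of-squares F-test for the species-by-depth interaction."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    slopes: dict

    def __post_init__(self) -> None:
        if self.f_statistic < 0:
            raise DomainError("F statistic must be non-negative")
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError("p_value must lie in [0, 1]")


def fit_qm_depth(records: pd.DataFrame, species: str | None = None) -> NicheLimitModel:
    """OLS of Q_m on depth for one species' records.

    ``records`` needs columns ``depth_m`` and ``qm``; an optional
    ``species`` column must be homogeneous (or selected via ``species``).
    """
    df = records
    if "species" in df.columns:
        if species is not None:
            df = df[df["species"] == species]
        else:
            uniq = df["species"].unique()
            if len(uniq) > 1:
                raise DegenerateDataError(
                    f"records contain multiple species {list(uniq)}; pass species=")
            species = str(uniq[0]) if len(uniq) else None
    df = df.dropna(subset=["qm", "depth_m"])
    depth = df["depth_m"].to_numpy(float)
    qm = df["qm"].to_numpy(float)
    if depth.size < 3 or np.unique(depth).size < 3:
        raise DegenerateDataError("Q_m fit needs >= 3 records at >= 3 distinct depths")
    X = sm.add_constant(depth)
    res = sm.OLS(qm, X).fit()
    return NicheLimitModel(
        species=species or "",
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n=int(depth.size),
        residual_sd=float(np.sqrt(res.mse_resid)),
        slope_se=float(res.bse[1]),
        depth_m=depth.copy(),
        qm=qm.copy(),
    )


def _bootstrap_intercepts(depth: np.ndarray, qm: np.ndarray, reps: int,
                          rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Case-resampling bootstrap x-intercepts, vectorised closed-form OLS."""
    n = depth.size
    idx = rng.integers(0, n, size=(reps, n))
    x = depth[idx]
    y = qm[idx]
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = np.sum((x - xm) ** 2, axis=1)
    sxy = np.sum((x - xm) * (y - ym), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = sxy / sxx
    intercepts = ym.ravel() - slopes * xm.ravel()
    valid = np.isfinite(slopes) & (slopes < 0)
    z = -intercepts[valid] / slopes[valid]
    return z, int(reps - valid.sum())


def depth_limit(model: NicheLimitModel, bootstrap_reps: int = 2000,
                seed: int | None = None) -> DepthLimitEstimate:
    """Depth z* at which the fitted Q_m line reaches 0, with bootstrap CI.

    z* = -intercept/slope, defined only for a declining line (slope < 0).
    When the model carries its records, a case-resampling bootstrap of the
    regression yields a percentile 95% interval; replicates whose
    resampled slope is non-negative have no finite limit and are discarded
    (warned about above 10%). Coefficient-only models get a point estimate
    with no interval.
    """
    if model.slope >= 0:
        raise DomainError("no finite depth limit: Q_m does not decline with depth")
    z_star = -model.intercept / model.slope
    ci_low = ci_high = None
    n_discarded = 0
    reps_done = 0
    if model.depth_m is not None and bootstrap_reps > 0:
        if seed is None:
            raise DomainError("a seed is required for the bootstrap interval")
        rng = np.random.default_rng(seed)
        z_boot, n_discarded = _bootstrap_intercepts(model.depth_m, model.qm,
                                                    bootstrap_reps, rng)
        reps_done = bootstrap_reps
        if n_discarded > 0.10 * bootstrap_reps:
            warnings.warn(
                f"{n_discarded}/{bootstrap_reps} bootstrap replicates had a "
                "non-negative slope and were discarded; the interval may be unstable",
                UserWarning, stacklevel=2)
        if z_boot.size < 2:
            raise DegenerateDataError("too few valid bootstrap replicates for an interval")
        ci_low, ci_high = (float(v) for v in np.percentile(z_boot, [2.5, 97.5]))
    return DepthLimitEstimate(
        species=model.species,
        z_star=float(z_star),
        ci_low=ci_low,
        ci_high=ci_high,
        bootstrap_reps=reps_done,
        n_discarded=n_discarded,
        seed=seed,
    )


def ancova_interaction(records: pd.DataFrame) -> AncovaResult:
    """Test whether the Q_m ~ depth slope differs between two species.

    Fits the full model ``qm ~ depth + species + depth:species`` and the
    no-interaction model, and compares them by the extra-sum-of-squares
    F-test: ``F = ((RSS0 - RSS1)/1) / (RSS1/(N - 4))`` on 1 and N-4 df.
    """
    df = records.dropna(subset=["qm", "depth_m", "species"])
    species = sorted(df["species"].unique())
    if len(species) != 2:
        raise DegenerateDataError(f"ANCOVA needs exactly 2 species, got {species}")
    for sp in species:
        sub = df[df["species"] == sp]
        if len(sub) < 3 or sub["depth_m"].nunique() < 2:
            raise DegenerateDataError(
                f"species {sp!r} needs >= 3 records at >= 2 distinct depths")
    y = df["qm"].to_numpy(float)
    z = df["depth_m"].to_numpy(float)
    g = (df["species"] == species[1]).to_numpy(float)
    n_obs = y.size
    X_full = np.column_stack([np.ones(n_obs), z, g, z * g])
    X_red = X_full[:, :3]
    if np.linalg.matrix_rank(X_full) < 4:
        raise DegenerateDataError("rank-deficient ANCOVA design")
    full = sm.OLS(y, X_full).fit()
    reduced = sm.OLS(y, X_red).fit()
    df_den = n_obs - 4
    ssr_diff = float(reduced.ssr - full.ssr)
    if full.ssr <= 0.0:  # exact fit: F degenerates to 0 or infinity
        f_stat = 0.0 if ssr_diff <= 0.0 else float("inf")
    else:
        f_stat = max(ssr_diff / (float(full.ssr) / df_den), 0.0)
    p_val = float(stats.f.sf(f_stat, 1, df_den))
    slopes = {
        species[0]: float(full.params[1]),
        species[1]: float(full.params[1] + full.params[3]),
    }
    return AncovaResult(f_statistic=f_stat, df_num=1, df_den=int(df_den),
                        p_value=p_val, slopes=slopes)


def slope_ratio(model_a: NicheLimitModel, model_b: NicheLimitModel) -> float:
    """Ratio of absolute Q_m-decline rates, |slope_a| / |slope_b|."""
    if model_b.slope == 0:
        raise DomainError("reference model has zero slope")
    return abs(model_a.slope) / abs(model_b.slope)
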