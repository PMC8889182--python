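"""Synthetic field-campaign data with the structure the analysis assumes.

Every analysis stage consumes one of four tables: a light-depth profile,
shallow/deep logger time series, PAM fluorometry records and transplant
outcomes. The generators here emulate those tables under a single
:class:`SimulationConfig` whose defaults are the study conditions reported
for the Bocas del Toro transplant site: K_d = 0.40 m^-1; daily
temperatures 28.85 +/- 0.96 C (shallow) vs 28.46 +/- 0.88 C (deep) over
176 logger days with shallow light five times more day-to-day variable;
per-species Q_m-depth lines 0.735 - 0.133 z (O. annularis) and
0.422 - 0.054 z (O. franksi); and per-treatment six-month death
probabilities (S-S 0.00, S-D 0.27, D-S 0.02, D-D 0.04) at the post-census
group sizes (27, 29, 44, 28).

All generators are pure functions of (config, seed): the same seed yields
byte-identical tables. dF/Fm' is derived from a simulated "true" Q_m via
the inverse of the Q_m formula, so downstream estimation exercises the
formula as an inverse problem.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .optics import LightProfile

__all__ = [
    "SpeciesConfig",
    "TreatmentConfig",
    "SimulationConfig",
    "gen_light_profile",
    "gen_daily_temperatures",
    "gen_logger_series",
    "gen_fluorometry_survey",
    "gen_transplant_experiment",
]


@dataclass(frozen=True)
class SpeciesConfig:
    """Generating lines and survey design for one species.

    The Q_m line gives each colony's expected excitation pressure at its
    depth; the Fv/Fm line is the dusk-yield depth calibration (positive
    slope: deeper colonies convert light more efficiently). Residual
    standard deviations are chosen so the lines reproduce the field-survey
    R^2 values over the species' depth range.
    """

    name: str
    depth_min: float
    depth_max: float
    survey_n: int
    calibration_n: int
    qm_slope: float
    qm_intercept: float
    qm_noise_sd: float
    fvfm_slope: float = 0.02
    fvfm_intercept: float = 0.48
    fvfm_noise_sd: float = 0.01
    dff_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.survey_n < 1 or self.calibration_n < 0:
            raise ConfigError("survey_n must be >= 1 and calibration_n >= 0")
        if self.calibration_n > self.survey_n:
            raise ConfigError("calibration subsample cannot exceed the survey size")
        if min(self.qm_noise_sd, self.fvfm_noise_sd, self.dff_noise_sd) < 0:
            raise ConfigError("noise standard deviations must be non-negative")
        if not (0 < self.depth_min < self.depth_max):
            raise ConfigError("depth range must satisfy 0 < depth_min < depth_max")


@dataclass(frozen=True)
class TreatmentConfig:
    """One transplant arm: origin-destination code, size and death risk."""

    treatment: str
    species: str
    n: int
    death_prob: float
    discard_n: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.death_prob <= 1.0):
            raise ConfigError("death_prob must lie in [0, 1]")
        if self.n < 1 or self.discard_n < 0 or self.discard_n >= self.n:
            raise ConfigError("need n >= 1 and 0 <= discard_n < n")


def _default_species() -> tuple[SpeciesConfig, ...]:
    return (
        SpeciesConfig(name="O. annularis", depth_min=2.5, depth_max=6.0,
                      survey_n=38, calibration_n=10,
                      qm_slope=-0.133, qm_intercept=0.735, qm_noise_sd=0.09),
        SpeciesConfig(name="O. franksi", depth_min=3.0, depth_max=8.0,
                      survey_n=67, calibration_n=21,
                      qm_slope=-0.054, qm_intercept=0.422, qm_noise_sd=0.08),
    )


def _default_treatments() -> tuple[TreatmentConfig, ...]:
    return (
        TreatmentConfig("S-S", "O. annularis", n=27, death_prob=0.00),
        TreatmentConfig("S-D", "O. annularis", n=29, death_prob=0.27),
        TreatmentConfig("D-S", "O. franksi", n=44, death_prob=0.02),
        TreatmentConfig("D-D", "O. franksi", n=28, death_prob=0.04),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the synthetic campaign; defaults are the study conditions."""

    seed: int = 0
    # light-depth profile
    kd: float = 0.40                      # m^-1
    surface_irradiance: float = 100.0     # relative units (100 = surface)
    profile_depth_max: float = 10.0       # m
    profile_n_depths: int = 21
    profile_log_noise_sd: float = 0.05    # multiplicative (log-normal) sensor error
    # loggers
    logger_start: str = "2014-09-26"
    logger_days: int = 176
    readings_per_day: int = 48            # 30-min cadence
    shallow_temp_mean: float = 28.85      # deg C, daily-mean level
    shallow_temp_sd: float = 0.96
    deep_temp_mean: float = 28.46
    deep_temp_sd: float = 0.88
    temp_diel_amplitude: float = 0.20     # deg C within-day swing
    temp_sensor_sd: float = 0.05
    shallow_light_mean: float = 600.0     # relative-light units at 3.5 m
    deep_light_mean: float = 55.0         # at 9.5 m
    shallow_light_cv: float = 0.50        # day-to-day CV; shallow/deep ratio ~ 5
    deep_light_cv: float = 0.10
    # biology
    species: tuple[SpeciesConfig, ...] = field(default_factory=_default_species)
    treatments: tuple[TreatmentConfig, ...] = field(default_factory=_default_treatments)

    def __post_init__(self) -> None:
        if self.profile_n_depths < 3:
            raise ConfigError("profile needs at least 3 depths")
        if self.logger_days < 2:
            raise ConfigError("logger series needs at least 2 days")
        if min(self.profile_log_noise_sd, self.shallow_temp_sd, self.deep_temp_sd,
               self.shallow_light_cv, self.deep_light_cv) < 0:
            raise ConfigError("noise parameters must be non-negative")

    def species_config(self, name: str) -> SpeciesConfig:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise ConfigError(f"no species named {name!r} in the configuration")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "species" in data:
            data["species"] = tuple(
                sp if isinstance(sp, SpeciesConfig) else SpeciesConfig(**sp)
                for sp in data["species"])
        if "treatments" in data:
            data["treatments"] = tuple(
                t if isinstance(t, TreatmentConfig) else TreatmentConfig(**t)
                for t in data["treatments"])
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown simulation config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(config_seed, seed):
    return np.random.default_rng(config_seed if seed is None else seed)


def gen_light_profile(config: SimulationConfig, seed=None) -> LightProfile:
    """Noisy exponential light-depth profile.

    ``E(z) = E0 * exp(-kd z) * exp(eps)`` with eps ~ Normal(0, sigma_log):
    multiplicative log-normal sensor error, so irradiance stays positive
    and the log-linear fit sees homoscedastic residuals.
    """
    rng = _rng(config.seed, seed)
    z = np.linspace(0.0, config.profile_depth_max, config.profile_n_depths)
    eps = rng.normal(0.0, config.profile_log_noise_sd, size=z.size)
    irr = config.surface_irradiance * np.exp(-config.kd * z) * np.exp(eps)
    return LightProfile(depth_m=z, irradiance=irr)


def gen_daily_temperatures(config: SimulationConfig, seed=None) -> dict[str, np.ndarray]:
    """Daily mean temperatures per site, Normal(mu_site, sd_site)."""
    rng = _rng(config.seed, seed)
    return {
        "shallow": rng.normal(config.shallow_temp_mean, config.shallow_temp_sd,
                              config.logger_days),
        "deep": rng.normal(config.deep_temp_mean, config.deep_temp_sd,
                           config.logger_days),
    }


def _diel_light_profile(hours: np.ndarray) -> np.ndarray:
    """Relative within-day light shape: daylight sin^2 hump, zero at night."""
    frac = np.clip(np.sin(np.pi * (hours - 6.0) / 12.0), 0.0, None)
    return frac**2


def gen_logger_series(config: SimulationConfig, seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shallow and deep 30-min logger tables (timestamp, temp, light).

    Each day draws a daily mean temperature Normal(mu, sd) and a daily
    light level (log-normal with the site's day-to-day CV); within-day
    readings add a diel sinusoid plus sensor noise to temperature and scale
    light by a fixed daylight profile, so calendar-day means recover the
    daily draws.
    """
    rng = _rng(config.seed, seed)
    temps = {
        "shallow": rng.normal(config.shallow_temp_mean, config.shallow_temp_sd,
                              config.logger_days),
        "deep": rng.normal(config.deep_temp_mean, config.deep_temp_sd,
                           config.logger_days),
    }
    frames = []
    n_per_day = config.readings_per_day
    hours = np.arange(n_per_day) * 24.0 / n_per_day
    diel_t = np.sin(2.0 * np.pi * (hours - 9.0) / 24.0)  # peak mid-afternoon
    diel_l = _diel_light_profile(hours)
    start = pd.Timestamp(config.logger_start)
    timestamps = pd.date_range(start, periods=config.logger_days * n_per_day,
                               freq=pd.Timedelta(hours=24.0 / n_per_day))
    for site, light_mean, light_cv in (
            ("shallow", config.shallow_light_mean, config.shallow_light_cv),
            ("deep", config.deep_light_mean, config.deep_light_cv)):
        sigma = np.sqrt(np.log1p(light_cv**2))
        daily_light = light_mean * np.exp(
            rng.normal(0.0, 1.0, config.logger_days) * sigma - sigma**2 / 2.0)
        temp = (np.repeat(temps[site], n_per_day)
                + config.temp_diel_amplitude * np.tile(diel_t, config.logger_days)
                + rng.normal(0.0, config.temp_sensor_sd, config.logger_days * n_per_day))
        light = np.repeat(daily_light, n_per_day) * np.tile(diel_l, config.logger_days)
        frames.append(pd.DataFrame({
            "timestamp": timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "site": site,
            "temperature_c": temp,
            "relative_light": light,
        }))
    return frames[0], frames[1]


def gen_fluorometry_survey(config: SimulationConfig, species: str,
                           seed=None) -> pd.DataFrame:
    """In-situ PAM survey for one species along its depth range.

    Depths are uniform over the species range. Each colony gets a dusk
    yield from the Fv/Fm calibration line plus noise (truncated into
    (0, 1]) and a true excitation pressure from the Q_m line plus residual
    (truncated at 1); its noon yield is back-computed as
    ``dF/Fm' = Fv/Fm * (1 - Q_m_true)``. Only the calibration subsample
    (the first ``calibration_n`` colonies) reports Fv/Fm; the rest carry
    the noon yield alone, as in a single-dive survey.
    """
    sp = config.species_config(species)
    rng = _rng(config.seed, seed)
    z = rng.uniform(sp.depth_min, sp.depth_max, sp.survey_n)
    fvfm = sp.fvfm_intercept + sp.fvfm_slope * z
    if sp.fvfm_noise_sd > 0:
        fvfm = fvfm + rng.normal(0.0, sp.fvfm_noise_sd, sp.survey_n)
    fvfm = np.clip(fvfm, 1e-6, 1.0)
    qm_true = sp.qm_intercept + sp.qm_slope * z
    if sp.qm_noise_sd > 0:
        qm_true = qm_true + rng.normal(0.0, sp.qm_noise_sd, sp.survey_n)
    qm_true = np.minimum(qm_true, 1.0)
    dff = fvfm * (1.0 - qm_true)
    if sp.dff_noise_sd > 0:
        dff = dff + rng.normal(0.0, sp.dff_noise_sd, sp.survey_n)
    dff = np.clip(dff, 0.0, 1.0)
    is_calib = np.arange(sp.survey_n) < sp.calibration_n
    tag = species.split()[-1][:3]
    return pd.DataFrame({
        "species": species,
        "colony_id": [f"{tag}-{i + 1:03d}" for i in range(sp.survey_n)],
        "depth_m": z,
        "treatment": "survey",
        "timepoint_d": np.nan,
        "delta_f_fm_prime": dff,
        "fv_fm": np.where(is_calib, fvfm, np.nan),
    })


def gen_transplant_experiment(config: SimulationConfig, seed=None) -> pd.DataFrame:
    """Six-month transplant census: one alive/dead/discarded row per genotype.

    Deaths are independent Bernoulli draws at the treatment's death
    probability; ``discard_n`` genotypes per arm (default 0) are marked
    discarded (e.g. detached fragments) regardless of their draw.
    """
    rng = _rng(config.seed, seed)
    rows = []
    for trt in config.treatments:
        dead = rng.random(trt.n) < trt.death_prob
        status = np.where(dead, "dead", "alive").astype(object)
        if trt.discard_n:
            drop = rng.choice(trt.n, size=trt.discard_n, replace=False)
            status[drop] = "discarded"
        for i in range(trt.n):
            rows.append({
                "species": trt.species,
                "treatment": trt.treatment,
                "genotype_id": f"{trt.treatment}-{i + 1:03d}",
                "status": status[i],
            })
    return pd.DataFrame(rows)


def write_campaign(config: SimulationConfig, out_dir, seed=None) -> dict[str, str]:
    """Emit the four CSVs a full analysis run reads; returns their paths.

    Per-table seeds are spawned from one root so each table is individually
    reproducible and independent of the others.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    children = root.spawn(3 + len(config.species))
    s_profile, s_logger, s_transplant = children[:3]
    species_seeds = children[3:]
    paths = {}

    profile = gen_light_profile(config, seed=s_profile)
    paths["profile"] = os.path.join(out_dir, "light_profile.csv")
    pd.DataFrame({"depth_m": profile.depth_m,
                  "irradiance": profile.irradiance}).to_csv(paths["profile"], index=False)

    shallow, deep = gen_logger_series(config, seed=s_logger)
    paths["loggers"] = os.path.join(out_dir, "loggers.csv")
    pd.concat([shallow, deep], ignore_index=True).to_csv(paths["loggers"], index=False)

    surveys = [gen_fluorometry_survey(config, sp.name, seed=s)
               for sp, s in zip(config.species, species_seeds)]
    paths["pam"] = os.path.join(out_dir, "pam.csv")
    pd.concat(surveys, ignore_index=True).to_csv(paths["pam"], index=False)

    paths["outcomes"] = os.path.join(out_dir, "outcomes.csv")
    gen_transplant_experiment(config, seed=s_transplant).to_csv(paths["outcomes"], index=False)
    return paths
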