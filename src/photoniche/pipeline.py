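"""Full-campaign orchestration: optics -> fluorometry -> niche -> fitness.

:func:`run_pipeline` ties the analysis stages together over the four input
tables and renders a single :class:`AnalysisReport` that serialises
losslessly to JSON. All randomness (the depth-limit bootstrap) flows from
one top-level seed split into per-stage streams, so identical inputs and
seed produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .errors import PipelineError
from . import fitness as fitness_mod
from . import fluorometry as fluoro
from . import io as io_mod
from . import niche
from . import optics

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs for one full analysis run.

    Any input path may be None to skip its stage. ``report_depths`` are the
    depths (m) at which the optics block quotes percent surface irradiance
    (default: the two transplant-site depths).
    """

    seed: int
    profile_path: str | None = None
    loggers_path: str | None = None
    pam_path: str | None = None
    outcomes_path: str | None = None
    contrasts: tuple = fitness_mod.DEFAULT_CONTRASTS
    bootstrap_reps: int = 2000
    report_depths: tuple = (3.5, 9.5)
    out_dir: str | None = None

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)


@dataclass
class AnalysisReport:
    """JSON-serialisable report with one block per analysis stage."""

    optics: dict = field(default_factory=dict)
    environment: dict = field(default_factory=dict)
    niche: dict = field(default_factory=dict)
    fitness: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "optics": self.optics,
            "environment": self.environment,
            "niche": self.niche,
            "fitness": self.fitness,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))

    def to_text(self) -> str:
        lines = ["photoniche analysis report", "=" * 27]
        if self.optics:
            lines.append(f"K_d = {self.optics['kd_per_m']:.2f} m^-1 "
                         f"(R^2 = {self.optics['r_squared']:.3f})")
            for depth, pct in self.optics["percent_surface_irradiance"].items():
                lines.append(f"  {depth} m: {pct:.1f}% surface irradiance")
        if self.environment:
            env = self.environment
            lines.append(
                f"Daily temperature: shallow {env['shallow_temp_mean_c']:.2f} ± "
                f"{env['shallow_temp_sd_c']:.2f} °C vs deep {env['deep_temp_mean_c']:.2f} ± "
                f"{env['deep_temp_sd_c']:.2f} °C (t-value = {env['t_statistic']:.2f}, "
                f"p = {env['p_value']:.3g})")
            lines.append(f"Light variability ratio (shallow/deep CV): "
                         f"{env['variability_ratio']:.1f}")
        for sp, block in self.niche.get("species", {}).items():
            fit = block["fit"]
            lim = block["depth_limit"]
            ci = (f" (95% CI {lim['ci_low_m']:.1f}-{lim['ci_high_m']:.1f} m)"
                  if lim.get("ci_low_m") is not None else "")
            lines.append(
                f"{sp}: Q_m = {fit['intercept']:.3f} {fit['slope']:+.3f} * depth "
                f"(R^2 = {fit['r_squared']:.2f}, n = {fit['n']}); "
                f"depth limit = {lim['z_star_rounded_m']:.1f} m{ci}")
        if "ancova" in self.niche:
            an = self.niche["ancova"]
            lines.append(
                f"Species x depth interaction: F_{an['df_num']},{an['df_den']} = "
                f"{an['f_statistic']:.2f}, p = {an['p_value']:.3g}; "
                f"slope ratio = {self.niche['slope_ratio']:.2f}")
        if self.fitness:
            lines.append(self.fitness["text"])
        return "\n".join(lines)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return inner
    return wrap


@_stage("optics")
def _optics_block(profile_df, report_depths) -> dict:
    model = optics.fit_kd(optics.LightProfile.from_dataframe(profile_df))
    return {
        "kd_per_m": model.kd,
        "e0": model.e0,
        "r_squared": model.r_squared,
        "percent_surface_irradiance": {
            str(z): optics.percent_surface_irradiance(model, z) for z in report_depths
        },
        "units": {"kd_per_m": "m^-1", "percent_surface_irradiance": "%"},
    }


@_stage("environment")
def _environment_block(loggers_df) -> dict:
    shallow = loggers_df[loggers_df["site"] == "shallow"]
    deep = loggers_df[loggers_df["site"] == "deep"]
    summ = optics.summarize_loggers(shallow, deep)
    return {
        "shallow_temp_mean_c": summ.shallow_temp_mean,
        "shallow_temp_sd_c": summ.shallow_temp_sd,
        "deep_temp_mean_c": summ.deep_temp_mean,
        "deep_temp_sd_c": summ.deep_temp_sd,
        "shallow_light_cv": summ.shallow_light_cv,
        "deep_light_cv": summ.deep_light_cv,
        "variability_ratio": summ.variability_ratio,
        "t_statistic": summ.t_statistic,
        "df": summ.df,
        "p_value": summ.p_value,
        "n_days": list(summ.n_days),
        "units": {"temperature": "degC", "variability_ratio": "shallow CV / deep CV"},
    }


@_stage("niche")
def _niche_block(pam_df, bootstrap_reps, seed_seq) -> dict:
    species = sorted(pam_df["species"].unique())
    seeds = seed_seq.spawn(len(species))
    block: dict = {"species": {}}
    models = {}
    qm_frames = []
    for sp, sp_seed in zip(species, seeds):
        sub = pam_df[pam_df["species"] == sp]
        calib = fluoro.calibrate_fvfm_depth(sub, species=sp)
        qm_records = fluoro.estimate_survey_qm(sub, calib)
        qm_frames.append(qm_records)
        model = niche.fit_qm_depth(qm_records, species=sp)
        models[sp] = model
        boot_seed = int(sp_seed.generate_state(1)[0] % (2**31))
        limit = niche.depth_limit(model, bootstrap_reps=bootstrap_reps, seed=boot_seed)
        block["species"][sp] = {
            "calibration": {
                "slope_per_m": calib.slope,
                "intercept": calib.intercept,
                "r_squared": calib.r_squared,
                "n": calib.n,
            },
            "fit": {
                "slope": model.slope,
                "intercept": model.intercept,
                "r_squared": model.r_squared,
                "n": model.n,
                "residual_sd": model.residual_sd,
            },
            "depth_limit": {
                "z_star_m": limit.z_star,
                "z_star_rounded_m": limit.z_star_rounded,
                "ci_low_m": limit.ci_low,
                "ci_high_m": limit.ci_high,
                "bootstrap_reps": limit.bootstrap_reps,
                "bootstrap_discarded": limit.n_discarded,
                "seed": limit.seed,
            },
        }
    if len(species) == 2:
        import pandas as pd

        pooled = pd.concat(qm_frames, ignore_index=True)
        an = niche.ancova_interaction(pooled)
        block["ancova"] = {
            "f_statistic": an.f_statistic,
            "df_num": an.df_num,
            "df_den": an.df_den,
            "p_value": an.p_value,
            "slopes": an.slopes,
        }
        steep = min(models, key=lambda sp: models[sp].slope)
        other = next(sp for sp in models if sp != steep)
        block["slope_ratio"] = niche.slope_ratio(models[steep], models[other])
        block["slope_ratio_order"] = [steep, other]
    block["units"] = {"slope": "Q_m per m", "z_star_m": "m"}
    return block


@_stage("fitness")
def _fitness_block(outcomes_df, contrasts) -> dict:
    report = fitness_mod.survivorship_report(outcomes_df, contrasts=contrasts)
    out = report.to_dict()
    out["text"] = report.to_text()
    return out


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Run every stage whose input table is configured and render the report.

    Stage errors abort the run with a stage-labelled
    :class:`~photoniche.errors.PipelineError`; nothing is written to
    ``out_dir`` unless all configured stages succeed.
    """
    paths = {name: p for name, p in (
        ("profile", config.profile_path),
        ("loggers", config.loggers_path),
        ("pam", config.pam_path),
        ("outcomes", config.outcomes_path)) if p is not None}
    tables = io_mod.read_tables(paths)
    report = AnalysisReport()
    seed_seq = np.random.SeedSequence(config.seed)
    optics_seq, env_seq, niche_seq, fitness_seq = seed_seq.spawn(4)
    if "profile" in tables:
        report.optics = _optics_block(tables["profile"], config.report_depths)
    if "loggers" in tables:
        report.environment = _environment_block(tables["loggers"])
    if "pam" in tables:
        report.niche = _niche_block(tables["pam"], config.bootstrap_reps, niche_seq)
    if "outcomes" in tables:
        report.fitness = _fitness_block(tables["outcomes"], config.contrasts)
    report.provenance = {
        "package": "photoniche",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
    }
    if config.out_dir is not None:
        os.makedirs(config.out_dir, exist_ok=True)
        json_path = os.path.join(config.out_dir, "report.json")
        text_path = os.path.join(config.out_dir, "report.txt")
        with open(json_path, "w") as fh:
            fh.write(report.to_json() + "\n")
        with open(text_path, "w") as fh:
            fh.write(report.to_text() + "\n")
        logger.info("wrote %s and %s", json_path, text_path)
    return report
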