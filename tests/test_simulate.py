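"""Generator determinism, invariants, and parameter recovery round-trips."""

import numpy as np
import pandas as pd
import pytest

from photoniche import (
    ConfigError,
    SimulationConfig,
    calibrate_fvfm_depth,
    compute_qm,
    depth_limit,
    estimate_survey_qm,
    fit_kd,
    fit_qm_depth,
    gen_fluorometry_survey,
    gen_light_profile,
    gen_logger_series,
    gen_transplant_experiment,
)
from photoniche.simulate import SpeciesConfig, TreatmentConfig, write_campaign


class TestConfig:
    def test_defaults_are_the_study_conditions(self, default_config):
        assert default_config.kd == 0.40
        assert default_config.logger_days == 176
        names = [sp.name for sp in default_config.species]
        assert names == ["O. annularis", "O. franksi"]
        trts = {t.treatment: t for t in default_config.treatments}
        assert trts["S-D"].death_prob == 0.27
        assert (trts["S-S"].n, trts["S-D"].n, trts["D-S"].n, trts["D-D"].n) == (27, 29, 44, 28)

    def test_round_trips_through_dict(self, default_config):
        rebuilt = SimulationConfig.from_dict(default_config.to_dict())
        assert rebuilt == default_config

    def test_yaml_round_trip(self, default_config, tmp_path):
        import yaml

        path = tmp_path / "sim.yaml"
        path.write_text(yaml.safe_dump(default_config.to_dict()))
        assert SimulationConfig.from_yaml(path) == default_config

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(profile_n_depths=2)
        with pytest.raises(ConfigError):
            TreatmentConfig("S-S", "A", n=10, death_prob=1.5)
        with pytest.raises(ConfigError):
            SpeciesConfig(name="A", depth_min=5.0, depth_max=2.0, survey_n=10,
                          calibration_n=3, qm_slope=-0.1, qm_intercept=0.6,
                          qm_noise_sd=0.05)
        with pytest.raises(ConfigError):
            SimulationConfig().species_config("O. nonexistens")


class TestDeterminism:
    def test_same_seed_same_tables(self, default_config):
        for gen in (gen_light_profile, gen_transplant_experiment):
            a, b = gen(default_config, seed=9), gen(default_config, seed=9)
            if isinstance(a, pd.DataFrame):
                pd.testing.assert_frame_equal(a, b)
            else:
                np.testing.assert_array_equal(a.irradiance, b.irradiance)
        s1, d1 = gen_logger_series(default_config, seed=9)
        s2, d2 = gen_logger_series(default_config, seed=9)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(d1, d2)
        f1 = gen_fluorometry_survey(default_config, "O. annularis", seed=9)
        f2 = gen_fluorometry_survey(default_config, "O. annularis", seed=9)
        pd.testing.assert_frame_equal(f1, f2)

    def test_different_seed_different_draws(self, default_config):
        a = gen_light_profile(default_config, seed=1)
        b = gen_light_profile(default_config, seed=2)
        assert not np.allclose(a.irradiance, b.irradiance)

    def test_campaign_csvs_are_byte_identical_across_runs(self, default_config, tmp_path):
        p1 = write_campaign(default_config, tmp_path / "a", seed=4)
        p2 = write_campaign(default_config, tmp_path / "b", seed=4)
        for name in p1:
            assert open(p1[name], "rb").read() == open(p2[name], "rb").read()


class TestLightProfileGenerator:
    def test_zero_noise_profile_is_exactly_exponential(self, default_config):
        from dataclasses import replace

        config = replace(default_config, profile_log_noise_sd=0.0)
        model = fit_kd(gen_light_profile(config, seed=0))
        assert model.kd == pytest.approx(0.40, rel=1e-12)
        assert model.e0 == pytest.approx(100.0, rel=1e-12)

    def test_default_noise_keeps_kd_near_the_field_estimate(self, default_config):
        model = fit_kd(gen_light_profile(default_config, seed=8))
        assert abs(model.kd - 0.40) < 0.03


class TestLoggerGenerator:
    def test_yields_30_min_cadence_iso_timestamps(self, default_config):
        shallow, deep = gen_logger_series(default_config, seed=2)
        assert len(shallow) == 176 * 48
        ts = pd.to_datetime(shallow["timestamp"], format="ISO8601")
        assert (ts.diff().dropna() == pd.Timedelta(minutes=30)).all()
        assert set(shallow["site"]) == {"shallow"} and set(deep["site"]) == {"deep"}

    def test_unit_cv_ratio_config(self, default_config):
        from dataclasses import replace

        from photoniche import summarize_loggers

        config = replace(default_config, shallow_light_cv=0.2, deep_light_cv=0.2,
                         logger_days=150)
        shallow, deep = gen_logger_series(config, seed=6)
        assert summarize_loggers(shallow, deep).variability_ratio == pytest.approx(1.0, abs=0.4)


class TestFluorometryGenerator:
    def test_zero_noise_round_trips_the_generating_qm_line(self, default_config):
        from dataclasses import replace

        quiet = tuple(replace(sp, qm_noise_sd=0.0, fvfm_noise_sd=0.0)
                      for sp in default_config.species)
        config = replace(default_config, species=quiet)
        df = gen_fluorometry_survey(config, "O. annularis", seed=3)
        calib = calibrate_fvfm_depth(df, species="O. annularis")
        model = fit_qm_depth(estimate_survey_qm(df, calib), species="O. annularis")
        assert model.slope == pytest.approx(-0.133, abs=1e-9)
        assert model.intercept == pytest.approx(0.735, abs=1e-9)

    def test_back_computation_identity(self, default_config):
        # with no extra noise on the noon yield, Q_m is exactly recoverable
        df = gen_fluorometry_survey(default_config, "O. franksi", seed=13)
        measured = df.dropna(subset=["fv_fm"])
        qm = compute_qm(measured["delta_f_fm_prime"].to_numpy(),
                        measured["fv_fm"].to_numpy())
        sp = default_config.species_config("O. franksi")
        line = sp.qm_intercept + sp.qm_slope * measured["depth_m"].to_numpy()
        # residuals around the line have the configured spread
        assert np.all(qm <= 1.0 + 1e-12)
        assert np.std(qm - line) < 4 * sp.qm_noise_sd

    def test_survey_structure_and_invariants(self, default_config):
        df = gen_fluorometry_survey(default_config, "O. annularis", seed=17)
        sp = default_config.species_config("O. annularis")
        assert len(df) == sp.survey_n
        assert df["fv_fm"].notna().sum() == sp.calibration_n
        assert df["depth_m"].between(sp.depth_min, sp.depth_max).all()
        assert df["delta_f_fm_prime"].between(0.0, 1.0).all()
        assert df["fv_fm"].dropna().between(0.0, 1.0).all()
        assert df["colony_id"].is_unique

    def test_depth_limit_recovery_rate(self, default_config):
        # recovered z* within 5.5 +/- 1.0 m in >= 90% of seeds
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            df = gen_fluorometry_survey(default_config, "O. annularis", seed=seed)
            calib = calibrate_fvfm_depth(df, species="O. annularis")
            model = fit_qm_depth(estimate_survey_qm(df, calib), species="O. annularis")
            if model.slope < 0:
                z_star = depth_limit(model, bootstrap_reps=0).z_star
                hits += abs(z_star - 5.5) <= 1.0
        assert hits / n_rep >= 0.90


class TestTransplantGenerator:
    def test_zero_death_probability_means_no_deaths(self, default_config):
        from dataclasses import replace

        safe = tuple(replace(t, death_prob=0.0) for t in default_config.treatments)
        df = gen_transplant_experiment(replace(default_config, treatments=safe), seed=1)
        assert (df["status"] == "alive").all()

    def test_discards_marked_not_dead(self, default_config):
        from dataclasses import replace

        trts = tuple(replace(t, discard_n=1) for t in default_config.treatments)
        df = gen_transplant_experiment(replace(default_config, treatments=trts), seed=1)
        assert (df["status"] == "discarded").sum() == len(trts)

    def test_native_vs_transplant_contrast_is_usually_detectable(self, default_config):
        # power of the one-sided exact test at the generating rates
        from photoniche import fisher_one_tailed, tally_outcomes

        hits = 0
        n_rep = 500
        for seed in range(n_rep):
            df = gen_transplant_experiment(default_config, seed=seed)
            p = fisher_one_tailed(tally_outcomes(df, "S-D", "S-S")).p_value
            hits += p < 0.05
        assert hits / n_rep >= 0.80
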