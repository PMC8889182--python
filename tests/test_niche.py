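"""Q_m ~ depth fits, depth limits with bootstrap CIs, ANCOVA, slope ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oracles import ancova_f_from_rss
from photoniche import (
    DegenerateDataError,
    DomainError,
    NicheLimitModel,
    ancova_interaction,
    depth_limit,
    fit_qm_depth,
    slope_ratio,
)


def qm_frame(depth, qm, species="O. annularis"):
    return pd.DataFrame({"species": species, "depth_m": depth, "qm": qm})


def synthetic_survey(rng, slope=-0.133, intercept=0.735, noise_sd=0.09, n=38,
                     depth_range=(2.5, 6.0), species="O. annularis"):
    z = rng.uniform(*depth_range, n)
    qm = intercept + slope * z + rng.normal(0, noise_sd, n)
    return qm_frame(z, qm, species)


class TestFitQmDepth:
    def test_exact_line_recovered(self):
        z = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        model = fit_qm_depth(qm_frame(z, 0.6 - 0.1 * z))
        assert model.slope == pytest.approx(-0.1, abs=1e-12)
        assert model.intercept == pytest.approx(0.6, abs=1e-12)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_generating_slope_inside_fitted_ci(self):
        rng = np.random.default_rng(42)
        model = fit_qm_depth(synthetic_survey(rng))
        tcrit = 2.028  # t_{0.975, 36}
        assert abs(model.slope - (-0.133)) < tcrit * model.slope_se

    def test_permutation_invariance_of_the_fit(self, rng):
        df = synthetic_survey(rng)
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a, b = fit_qm_depth(df), fit_qm_depth(shuffled)
        assert a.slope == pytest.approx(b.slope, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_confidence_band_brackets_the_fit_and_narrows_at_centre(self, rng):
        df = synthetic_survey(rng)
        model = fit_qm_depth(df)
        grid = np.linspace(2.5, 6.0, 8)
        lo, hi = model.confidence_band(grid)
        assert np.all(lo < model.predict(grid)) and np.all(model.predict(grid) < hi)
        widths = hi - lo
        centre_idx = np.argmin(np.abs(grid - df["depth_m"].mean()))
        assert widths[centre_idx] == pytest.approx(widths.min(), rel=1e-6)

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_qm_depth(qm_frame([3.0, 3.0, 3.0], [0.3, 0.2, 0.1]))


class TestDepthLimit:
    @pytest.mark.parametrize("intercept,slope,expected", [
        (0.735, -0.133, 5.5),   # shallow specialist line
        (0.422, -0.054, 7.8),   # deep specialist line
        (0.6, -0.1, 6.0),
    ])
    def test_published_style_coefficients(self, intercept, slope, expected):
        model = NicheLimitModel.from_coefficients(intercept, slope)
        est = depth_limit(model, bootstrap_reps=0)
        assert est.z_star_rounded == pytest.approx(expected)
        assert est.ci_low is None and est.ci_high is None

    def test_fitted_line_crosses_zero_at_z_star(self, rng):
        model = fit_qm_depth(synthetic_survey(rng))
        est = depth_limit(model, bootstrap_reps=0)
        assert abs(model.intercept + model.slope * est.z_star) < 1e-12

    def test_non_declining_line_has_no_limit(self):
        with pytest.raises(DomainError):
            depth_limit(NicheLimitModel.from_coefficients(0.2, 0.01), bootstrap_reps=0)

    def test_bootstrap_interval_brackets_estimate_and_is_seeded(self, rng):
        model = fit_qm_depth(synthetic_survey(rng))
        a = depth_limit(model, bootstrap_reps=500, seed=11)
        b = depth_limit(model, bootstrap_reps=500, seed=11)
        c = depth_limit(model, bootstrap_reps=500, seed=12)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)
        assert a.ci_low <= a.z_star <= a.ci_high

    def test_bootstrap_requires_seed(self, rng):
        model = fit_qm_depth(synthetic_survey(rng))
        with pytest.raises(DomainError):
            depth_limit(model, bootstrap_reps=100, seed=None)

    def test_flat_noisy_line_warns_about_discarded_replicates(self):
        rng = np.random.default_rng(5)
        z = rng.uniform(2, 8, 20)
        qm = 0.3 - 0.001 * z + rng.normal(0, 0.2, 20)
        model = fit_qm_depth(qm_frame(z, qm))
        if model.slope < 0:
            with pytest.warns(UserWarning, match="discarded"):
                depth_limit(model, bootstrap_reps=400, seed=1)


class TestAncova:
    def test_collinear_hand_dataset_separates_perfectly(self):
        # each group lies exactly on its own line, so the interaction F is
        # analytically unbounded: implementation and RSS oracle agree it is huge
        df = pd.concat([
            qm_frame([1, 2, 3, 4], [0.5, 0.4, 0.3, 0.2], species="A"),
            qm_frame([1, 2, 3, 4], [0.45, 0.42, 0.39, 0.36], species="B"),
        ], ignore_index=True)
        res = ancova_interaction(df)
        f_oracle = ancova_f_from_rss(df["depth_m"], df["qm"],
                                     (df["species"] == "B").astype(float))
        assert res.f_statistic > 1e10 and f_oracle > 1e10
        assert res.p_value < 1e-10
        assert res.df_num == 1 and res.df_den == 4
        assert res.slopes["A"] == pytest.approx(-0.1)
        assert res.slopes["B"] == pytest.approx(-0.03)

    def test_hand_dataset_matches_rss_oracle(self):
        df = pd.concat([
            qm_frame([1, 2, 3, 4], [0.50, 0.41, 0.30, 0.20], species="A"),
            qm_frame([1, 2, 3, 4], [0.45, 0.41, 0.40, 0.36], species="B"),
        ], ignore_index=True)
        res = ancova_interaction(df)
        f_oracle = ancova_f_from_rss(df["depth_m"], df["qm"],
                                     (df["species"] == "B").astype(float))
        assert res.f_statistic == pytest.approx(f_oracle, rel=1e-9)
        assert res.df_num == 1 and res.df_den == 4

    def test_matches_rss_oracle_on_noisy_surveys(self, rng):
        df = pd.concat([
            synthetic_survey(rng),
            synthetic_survey(rng, slope=-0.054, intercept=0.422, noise_sd=0.08,
                             n=67, depth_range=(3.0, 8.0), species="O. franksi"),
        ], ignore_index=True)
        res = ancova_interaction(df)
        f_oracle = ancova_f_from_rss(df["depth_m"], df["qm"],
                                     (df["species"] == "O. franksi").astype(float))
        assert res.f_statistic == pytest.approx(f_oracle, rel=1e-9)
        assert res.df_den == len(df) - 4
        assert res.p_value < 0.01  # the two lines genuinely differ in slope

    def test_null_calibration_rarely_rejects(self):
        # same generating line for both groups: interaction should look null
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            df = pd.concat([
                synthetic_survey(rng, species="A", n=20),
                synthetic_survey(rng, species="B", n=20),
            ], ignore_index=True)
            rejections += ancova_interaction(df).p_value <= 0.05
        assert rejections / n_rep <= 0.10

    def test_exact_lines_with_different_slopes_give_huge_f(self):
        z = np.array([1.0, 2.0, 3.0, 4.0])
        df = pd.concat([
            qm_frame(z, 0.6 - 0.10 * z, species="A"),
            qm_frame(z, 0.6 - 0.05 * z, species="B"),
        ], ignore_index=True)
        res = ancova_interaction(df)
        assert res.f_statistic > 1e10
        assert res.p_value < 1e-10

    def test_needs_exactly_two_species(self, rng):
        with pytest.raises(DegenerateDataError):
            ancova_interaction(synthetic_survey(rng))


class TestSlopeRatio:
    def test_published_style_slopes_are_more_than_twice_as_steep(self):
        a = NicheLimitModel.from_coefficients(0.735, -0.133)
        b = NicheLimitModel.from_coefficients(0.422, -0.054)
        assert slope_ratio(a, b) == pytest.approx(2.463, abs=1e-3)
        assert slope_ratio(a, b) > 2.0

    def test_identity_and_reciprocal_symmetry(self):
        a = NicheLimitModel.from_coefficients(0.6, -0.1)
        b = NicheLimitModel.from_coefficients(0.4, -0.2)
        assert slope_ratio(a, a) == pytest.approx(1.0)
        assert slope_ratio(a, b) == pytest.approx(0.5)
        assert slope_ratio(a, b) * slope_ratio(b, a) == pytest.approx(1.0)

    @given(sa=st.floats(-0.5, -0.01), sb=st.floats(-0.5, -0.01))
    def test_reciprocal_property(self, sa, sb):
        a = NicheLimitModel.from_coefficients(0.5, sa)
        b = NicheLimitModel.from_coefficients(0.5, sb)
        assert slope_ratio(a, b) * slope_ratio(b, a) == pytest.approx(1.0, rel=1e-9)

    def test_zero_denominator_rejected(self):
        a = NicheLimitModel.from_coefficients(0.5, -0.1)
        b = NicheLimitModel.from_coefficients(0.5, 0.0)
        with pytest.raises(DomainError):
            slope_ratio(a, b)
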