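import numpy as np
import pandas as pd
import pytest

from mvgc.multiview_core import MultiviewImage
from mvgc.trait_extraction import (
    Gs30Model,
    LAShootModel,
    WatershedConfig,
    calibrate_watershed,
    error_metrics,
    fit_la_shoot_model,
    fit_shoot_dynamics,
    gs30_timepoint,
    logistic_la,
    plant_count_trait,
    predict_gs30_index,
    predict_plant_count,
    shoots_from_la,
    train_gs30,
    watershed_labels,
    watershed_regions,
)

SCHEMA = [f"mvGC{i}" for i in range(10, 101, 10)]


def _percentile_features(delta_gdd, noise_sd, seed):
    from mvgc.synthetic_field import percentile_trajectories

    return percentile_trajectories(np.asarray(delta_gdd, float), noise_sd, seed)


class TestGs30Svr:
    def test_noiseless_trajectories_recovered_below_noise_floor(self):
        """Monotone percentile trajectories with known ΔGDD train an SVR whose
        grouped-CV RMSE stays under 5 GDD."""
        rng = np.random.default_rng(5)
        dg = rng.uniform(-20, 20, 300)
        X = _percentile_features(dg, 0.0, 1)
        geno = np.repeat(np.arange(30), 10)
        model = train_gs30(X, dg, genotype=geno)
        assert model.cv_report["genotype"]["rmse"] <= 5.0

    def test_constant_response_predicts_within_eps_tube(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.random((40, 10)), columns=SCHEMA)
        model = train_gs30(X, np.zeros(40))
        pred = predict_gs30_index(model, X)
        assert np.all(np.abs(pred) <= 0.11)  # SVR epsilon default 0.1

    def test_window_filter_error_reports_range(self):
        X = pd.DataFrame(np.random.default_rng(0).random((30, 10)), columns=SCHEMA)
        with pytest.raises(ValueError, match="window"):
            train_gs30(X, np.full(30, 500.0))

    def test_training_rows_memorized_within_tube(self):
        rng = np.random.default_rng(3)
        dg = rng.uniform(-20, 20, 120)
        X = _percentile_features(dg, 0.001, 2)
        model = train_gs30(X, dg)
        pred = predict_gs30_index(model, X)
        # most points inside the epsilon tube plus slack for the RBF fit
        assert np.median(np.abs(pred - np.clip(dg, *model.response_range))) < 2.0

    def test_bare_soil_prediction_clamped_to_training_range(self):
        rng = np.random.default_rng(4)
        dg = rng.uniform(-20, 20, 100)
        model = train_gs30(_percentile_features(dg, 0.0, 3), dg)
        zero = pd.DataFrame(np.zeros((1, 10)), columns=SCHEMA)
        pred = predict_gs30_index(model, zero)
        lo, hi = model.response_range
        assert lo <= pred[0] <= hi

    def test_permuted_feature_columns_rejected(self):
        rng = np.random.default_rng(6)
        dg = rng.uniform(-20, 20, 60)
        model = train_gs30(_percentile_features(dg, 0.0, 4), dg)
        bad = _percentile_features(dg, 0.0, 4)[SCHEMA[::-1]]
        with pytest.raises(ValueError, match="schema"):
            predict_gs30_index(model, bad)

    def test_genotype_blocked_cv_partitions_disjoint(self):
        from sklearn.model_selection import GroupKFold

        groups = np.repeat(np.arange(10), 5)
        seen = []
        for _, te in GroupKFold(n_splits=10).split(np.zeros((50, 1)), groups=groups):
            seen.extend(groups[te])
        assert sorted(set(seen)) == list(range(10))


class TestGs30Timepoint:
    def _estimates(self, slope_offset=612.0, noise=0.0, n=6, seed=0, plot="p1"):
        rng = np.random.default_rng(seed)
        gdd = np.linspace(592, 632, n)
        est = gdd - slope_offset + rng.normal(0, noise, n)
        return pd.DataFrame(
            {"plot_id": plot, "campaign": np.arange(n), "gdd": gdd, "estimate": est}
        )

    def test_exact_linear_crossing(self):
        res = gs30_timepoint(self._estimates())
        assert res.loc[0, "gs30_gdd"] == pytest.approx(612.0)
        assert res.loc[0, "flag"] == "ok"

    def test_noisy_crossing_within_monte_carlo_band(self):
        """GDD − 612 + N(0,5) over 6 campaigns recovers 612 within ±6 GDD in
        at least 95% of runs."""
        hits = 0
        for s in range(100):
            res = gs30_timepoint(self._estimates(noise=5.0, seed=s), window=None)
            if abs(res.loc[0, "gs30_gdd"] - 612.0) <= 6.0:
                hits += 1
        assert hits >= 90

    def test_low_repeatability_campaign_removed(self):
        df = self._estimates()
        df.loc[df.campaign == 2, "estimate"] = 100.0  # corrupted campaign
        reps = {c: (0.2 if c == 2 else 0.9) for c in df.campaign}
        res = gs30_timepoint(df, repeatability_by_campaign=reps, window=None)
        assert res.loc[0, "n_campaigns"] == 5
        assert res.loc[0, "gs30_gdd"] == pytest.approx(612.0)

    def test_too_few_campaigns_flagged_missing(self):
        res = gs30_timepoint(self._estimates(n=1))
        assert np.isnan(res.loc[0, "gs30_gdd"])
        assert res.loc[0, "flag"] == "too_few_campaigns"

    def test_nonpositive_slope_flagged(self):
        df = self._estimates()
        df["estimate"] = -df["estimate"]
        res = gs30_timepoint(df, window=None)
        assert res.loc[0, "flag"] == "nonpositive_slope"


def _gaussian_blob_image(centers, sigma=3.0, shape=(80, 80), amp=0.9):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.zeros(shape)
    for cx, cy in centers:
        img = np.maximum(img, amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)))
    return MultiviewImage(values=img, n_views=10)


class TestWatershed:
    def test_two_blobs_give_two_regions_with_superlevel_areas(self):
        """Two σ=3 px Gaussian blobs 30 px apart split into two regions whose
        areas match the analytic superlevel-set area π·2σ²·ln(amp/i_thresh)."""
        mv = _gaussian_blob_image([(25, 40), (55, 40)])
        cfg = WatershedConfig(i_thresh=0.1, i_peak=0.3, d_min=10)
        areas = watershed_regions(mv, cfg)
        assert len(areas) == 2
        analytic = np.pi * 2 * 9.0 * np.log(0.9 / 0.1)
        for a in areas:
            assert a == pytest.approx(analytic, rel=0.10)

    def test_bare_soil_zero_regions(self):
        mv = MultiviewImage(values=np.zeros((40, 40)), n_views=5)
        assert len(watershed_regions(mv, WatershedConfig())) == 0

    def test_close_duplicate_peak_suppressed(self):
        mv = _gaussian_blob_image([(40, 40), (44, 40)])
        cfg = WatershedConfig(i_thresh=0.1, i_peak=0.3, d_min=10)
        assert len(watershed_regions(mv, cfg)) == 1

    def test_region_areas_cover_support(self):
        mv = _gaussian_blob_image([(20, 20), (60, 60), (20, 60)])
        cfg = WatershedConfig(i_thresh=0.1, i_peak=0.3, d_min=10)
        labels = watershed_labels(mv, cfg)
        areas = watershed_regions(mv, cfg)
        assert areas.sum() == (labels > 0).sum()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            WatershedConfig(i_thresh=0.5, i_peak=0.3)


class TestWatershedCalibration:
    def test_exact_linear_truth_recovered(self):
        A = np.linspace(50, 500, 20)
        a_w, b_w, diag = calibrate_watershed(A, 0.01 * A)
        assert a_w == pytest.approx(0.01, abs=1e-12)
        assert b_w == pytest.approx(0.0, abs=1e-9)
        assert diag["r2"] == pytest.approx(1.0)

    def test_noisy_truth_within_two_se(self, rng):
        A = rng.uniform(50, 500, 200)
        y = 0.01 * A + 0.5 + rng.normal(0, 0.2, 200)
        a_w, b_w, diag = calibrate_watershed(A, y)
        assert abs(a_w - 0.01) <= 2 * diag["se_a"]
        assert abs(b_w - 0.5) <= 2 * diag["se_b"]

    def test_single_region_rejected(self):
        with pytest.raises(ValueError):
            calibrate_watershed(np.array([100.0]), np.array([1.0]))

    def test_zero_area_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            calibrate_watershed(np.full(12, 100.0), np.arange(12.0))


class TestPlantCount:
    def test_empty_region_list_zero_plants(self):
        assert predict_plant_count(np.array([]), 0.02, 0.5) == 0.0

    def test_arithmetic(self):
        assert predict_plant_count(np.array([100.0] * 3), 0.02, 0.5) == pytest.approx(7.5)

    def test_intercept_once_diagnostic(self):
        a = predict_plant_count(np.array([100.0] * 3), 0.02, 0.5, intercept_once=True)
        assert a == pytest.approx(6.5)

    def test_median_trait(self):
        assert plant_count_trait([100, 104, 98]) == 100
        assert plant_count_trait([77]) == 77
        assert 98 <= plant_count_trait([100, 1e6, 98]) <= 100


class TestLAShootModel:
    TRUE = dict(asym=50_000.0, a_xmid=-0.004, b_xmid=5.2, a_scal=0.0015, b_scal=0.9)

    def _model(self):
        return LAShootModel(**self.TRUE)

    def _triplets(self, rng, n_per_group=30, noise=0.01):
        model = self._model()
        dgs, las, shoots = [], [], []
        for center in (-150, -125, -100, -75, -50, -25):
            dg = center + rng.uniform(-10, 10, n_per_group)
            n_s = rng.uniform(30, 600, n_per_group)
            la = logistic_la(n_s, dg, model) * (1 + rng.normal(0, noise, n_per_group))
            dgs.append(dg), las.append(la), shoots.append(n_s)
        return np.concatenate(las), np.concatenate(shoots), np.concatenate(dgs)

    def test_generate_and_refit_recovers_coefficients(self, rng):
        la, n_s, dg = self._triplets(rng)
        fit = fit_la_shoot_model(la, n_s, dg, asym=self.TRUE["asym"], seed=11)
        for name in ("a_xmid", "b_xmid", "a_scal", "b_scal"):
            assert getattr(fit, name) == pytest.approx(self.TRUE[name], rel=0.05)

    def test_constant_shoot_group_dropped(self, rng):
        la, n_s, dg = self._triplets(rng)
        n_s[np.abs(dg + 150) < 15] = 100.0
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = fit_la_shoot_model(la, n_s, dg, asym=self.TRUE["asym"], seed=11)
        assert not np.any(np.isclose(fit.diagnostics["groups"]["delta_gdd"], -150))

    def test_midpoint_gives_half_asymptote(self):
        model = self._model()
        n_mid = np.expm1(model.xmid(-100.0))
        assert logistic_la(n_mid, -100.0, model) == pytest.approx(model.asym / 2)

    def test_inversion_roundtrip_exact(self, rng):
        model = self._model()
        la = rng.uniform(0.05, 0.95, 50) * model.asym
        dg = rng.uniform(-180, -20, 50)
        back = logistic_la(shoots_from_la(la, dg, model), dg, model)
        np.testing.assert_allclose(back, la, rtol=1e-9)

    def test_midpoint_inversion(self):
        model = self._model()
        n = shoots_from_la(model.asym / 2, -80.0, model)
        assert n == pytest.approx(np.expm1(model.xmid(-80.0)), rel=1e-9)

    def test_la_above_asym_clamped_with_warning(self):
        model = self._model()
        with pytest.warns(UserWarning, match="clamp"):
            n = shoots_from_la(model.asym * 1.1, -80.0, model)
        assert np.isfinite(n)

    def test_nonpositive_la_gives_zero_shoots(self):
        assert shoots_from_la(0.0, -80.0, self._model()) == 0.0

    def test_strictly_increasing_in_la(self):
        model = self._model()
        la = np.linspace(0.01, 0.99, 200) * model.asym
        n = shoots_from_la(la, -100.0, model)
        assert np.all(np.diff(n) > 0)


class TestShootDynamics:
    def test_noiseless_exact_recovery(self):
        dg = np.arange(-200.0, -9.0, 10.0)
        y = 120.0 - np.exp(-0.015 * dg)
        fit = fit_shoot_dynamics(y, dg, seed=1)
        assert fit.n_s == pytest.approx(120.0, rel=1e-6)
        assert fit.a == pytest.approx(0.015, rel=1e-6)
        assert not fit.fallback

    def test_two_points_fall_back_to_median(self):
        fit = fit_shoot_dynamics(np.array([90.0, 110.0]), np.array([-50.0, -20.0]))
        assert fit.fallback and fit.a is None
        assert fit.n_s == pytest.approx(100.0)

    def test_out_of_window_points_filtered(self):
        dg = np.array([-300.0, -150.0, -100.0, -50.0, 10.0])
        y = 120.0 - np.exp(-0.015 * dg)
        fit = fit_shoot_dynamics(y, dg, seed=1)
        assert fit.n_points == 3

    def test_constant_series_matches_grid_search_oracle(self):
        """For a flat series the best inverse-exponential fit approaches
        N_S ≈ c + 1 as ΔGDD→0⁻ (brute-force grid oracle)."""
        dg = np.linspace(-150, -10, 8)
        y = np.full(8, 95.0)
        fit = fit_shoot_dynamics(y, dg, seed=1)
        # oracle: dense grid over (n_s, a)
        best = (np.inf, None, None)
        for n_s in np.linspace(90, 110, 81):
            for a in np.logspace(-4, 0, 120):
                sse = np.sum((n_s - np.exp(-a * dg) - y) ** 2)
                if sse < best[0]:
                    best = (sse, n_s, a)
        sse_fit = np.sum((fit.n_s - np.exp(-fit.a * dg) - y) ** 2)
        assert sse_fit <= best[0] * 1.01

    def test_campaign_order_invariance(self):
        dg = np.arange(-200.0, -9.0, 25.0)
        y = 110.0 - np.exp(-0.02 * dg) + np.sin(dg) * 0.5
        f1 = fit_shoot_dynamics(y, dg, seed=2)
        perm = np.random.default_rng(0).permutation(len(dg))
        f2 = fit_shoot_dynamics(y[perm], dg[perm], seed=2)
        assert f1.n_s == pytest.approx(f2.n_s, rel=1e-6)


class TestErrorMetrics:
    def test_perfect_prediction(self):
        m = error_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["rmse"] == 0.0 and m["r2"] == pytest.approx(1.0)

    def test_constant_offset_bias_sign_convention(self):
        ref = np.array([10.0, 20.0, 30.0])
        m = error_metrics(ref, ref + 2.0)
        assert m["bias"] == pytest.approx(-2.0)  # reference − estimate
        assert m["rmse"] == pytest.approx(2.0)
        assert m["r2"] == pytest.approx(1.0)

    def test_matches_textbook_formulas(self, rng):
        ref = rng.normal(50, 10, 200)
        est = ref + rng.normal(0, 5, 200)
        m = error_metrics(ref, est)
        err = ref - est
        assert m["rmse"] == pytest.approx(np.sqrt(np.mean(err**2)), abs=1e-12)
        assert m["rrmse"] == pytest.approx(m["rmse"] / ref.mean(), abs=1e-12)
        r = np.corrcoef(ref, est)[0, 1]
        assert m["pearson_r"] == pytest.approx(r, abs=1e-12)
        assert m["r2"] == pytest.approx(r**2, abs=1e-12)

    def test_zero_reference_mean_flagged(self):
        m = error_metrics([-1.0, 1.0], [0.0, 1.0])
        assert np.isnan(m["rrmse"]) and m["rrmse_flag"]
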