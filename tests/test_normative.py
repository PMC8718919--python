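"""Penalized-spline normative model: basis, penalty, GCV, prediction, persistence."""

import json

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from qeegnorm import normative as nm
from qeegnorm import synthetic as syn


class TestSplineBasis:
    def test_partition_of_unity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(4.5, 81.0, 200)
        knots = nm.make_knots(x, n_interior=10)
        B = nm.spline_basis(x, knots)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_degree_one_no_interior_knots_is_linear_interpolation(self):
        knots = np.array([0.0, 0.0, 10.0, 10.0])
        x = np.linspace(0, 10, 23)
        B = nm.spline_basis(x, knots, degree=1)
        y_ends = np.array([3.0, -5.0])
        np.testing.assert_allclose(B @ y_ends, np.interp(x, [0, 10], y_ends), atol=1e-12)

    def test_evaluation_is_reproducible_at_knots(self):
        x = np.linspace(4.5, 81, 50)
        knots = nm.make_knots(x)
        np.testing.assert_array_equal(
            nm.spline_basis(knots[5:8], knots), nm.spline_basis(knots[5:8], knots)
        )

    def test_out_of_span_ages_rejected(self):
        knots = nm.make_knots(np.linspace(10, 20, 30))
        with pytest.raises(ValueError, match="knot span"):
            nm.spline_basis([25.0], knots)


class TestPenalizedFit:
    def _xy(self, n=80, seed=1):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(0, 50, n))
        return rng, x

    def test_linear_trend_fitted_exactly_at_any_lambda(self):
        _, x = self._xy()
        y = 2.0 - 0.3 * x
        for lam in (0.01, 10.0, 1e6):
            fit = nm.fit_penalized_spline(x, y, lam)
            B = nm.spline_basis(x, fit["knots"])
            np.testing.assert_allclose(B @ fit["coef"], y, atol=1e-6)

    def test_huge_lambda_approaches_ols_line(self):
        rng, x = self._xy()
        y = 1.0 + 0.2 * x + rng.normal(0, 0.5, len(x))
        fit = nm.fit_penalized_spline(x, y, 1e10)
        B = nm.spline_basis(x, fit["knots"])
        slope, intercept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(B @ fit["coef"], intercept + slope * x, atol=1e-3)

    def test_small_instance_matches_dense_normal_equations(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0, 10, 12))
        y = rng.normal(0, 1, 12)
        lam = 2.5
        fit = nm.fit_penalized_spline(x, y, lam, n_knots=2)  # 6 basis functions
        B = nm.spline_basis(x, fit["knots"])
        assert B.shape[1] == 6
        # independent construction: second divided differences over knot averages
        knots, k = fit["knots"], 3
        g = np.array([knots[j + 1 : j + k + 1].mean() for j in range(6)])
        D = np.zeros((4, 6))
        for j in range(4):
            D[j, j : j + 3] = [
                1 / (g[j + 1] - g[j]),
                -1 / (g[j + 1] - g[j]) - 1 / (g[j + 2] - g[j + 1]),
                1 / (g[j + 2] - g[j + 1]),
            ]
        D *= np.mean(np.diff(g)) ** 2
        coef_direct = np.linalg.solve(B.T @ B + lam * D.T @ D, B.T @ y)
        np.testing.assert_allclose(fit["coef"], coef_direct, atol=1e-10)

    def test_effective_dof_nonincreasing_in_lambda(self):
        rng, x = self._xy(n=150)
        y = np.sin(x / 5) + rng.normal(0, 0.2, len(x))
        edfs = [nm.fit_penalized_spline(x, y, lam)["edf"]
                for lam in np.logspace(-3, 6, 12)]
        assert all(a >= b - 1e-9 for a, b in zip(edfs, edfs[1:]))

    def test_singularity_at_zero_lambda_advises_larger(self):
        x = np.linspace(0, 1, 8)
        with pytest.raises(ValueError, match="lam"):
            nm.fit_penalized_spline(x, np.zeros(8), 0.0, n_knots=10)


class TestGCV:
    def test_pure_noise_prefers_smoothest_fit(self):
        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(0, 10, 200))
        y = 5 + rng.normal(0, 1, 200)
        lam = nm.select_lambda_gcv(x, y)
        grid = list(nm.DEFAULT_LAM_GRID)
        assert grid.index(lam) >= len(grid) // 2
        # the selected fit is essentially the penalty's smoothest (linear) fit
        assert nm.fit_penalized_spline(x, y, lam)["edf"] <= 3.0

    def test_curved_noiseless_data_prefers_roughest_fit(self):
        x = np.sort(np.random.default_rng(5).uniform(0, 10, 200))
        lam = nm.select_lambda_gcv(x, np.sin(2 * x))
        assert list(nm.DEFAULT_LAM_GRID).index(lam) <= 1

    def test_selected_lambda_is_the_grid_argmin(self):
        rng = np.random.default_rng(6)
        x = np.sort(rng.uniform(0, 10, 100))
        y = np.cos(x) + rng.normal(0, 0.3, 100)
        grid = [0.1, 1.0, 10.0, 100.0]
        lam_star = nm.select_lambda_gcv(x, y, grid)
        def gcv(lam):
            fit = nm.fit_penalized_spline(x, y, lam)
            return len(y) * fit["rss"] / (len(y) - fit["edf"]) ** 2
        assert gcv(lam_star) <= min(gcv(l) for l in grid) + 1e-12

    def test_estimator_is_cloneable_sklearn_style(self):
        est = nm.PenalizedSplineRegressor(lam=3.0, n_knots=5)
        est2 = clone(est)
        assert est2.get_params()["lam"] == 3.0
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 10, 60))
        y = x * 0.5 + rng.normal(0, 0.1, 60)
        est.fit(x.reshape(-1, 1), y)
        assert est.predict([[5.0]]).shape == (1,)
        assert est.sigma_ > 0 and est.edf_ > 0


class TestNormativeDB:
    def test_stratified_model_ignores_other_sex_rows(self, small_tables):
        bp, demo = small_tables
        m_all = nm.NormativeDB(sex_mode="male").fit(bp, demo)
        males = demo[demo.sex == "male"]
        m_only = nm.NormativeDB(sex_mode="male").fit(
            bp[bp.subject_id.isin(set(males.subject_id))], males
        )
        grid = np.linspace(*m_all.age_range_, 50)
        np.testing.assert_allclose(
            m_all.predict_mean(grid, "theta", "Cz"),
            m_only.predict_mean(grid, "theta", "Cz"),
            atol=1e-12,
        )

    def test_predictions_continuous_in_age(self, fitted_models):
        m = fitted_models["male"]
        assert abs(m.predict_mean(30.0, "alpha", "O1") - m.predict_mean(30.001, "alpha", "O1")) < 1e-3
        assert abs(m.predict_sd(30.0, "alpha", "O1") - m.predict_sd(30.001, "alpha", "O1")) < 1e-3

    def test_sd_approaches_sigma_when_leverage_vanishes(self, fitted_models):
        m = fitted_models["male"]
        comp = m.components_[("theta", "Cz")]
        mid = float(np.mean(m.age_range_))
        sd = m.predict_sd(mid, "theta", "Cz")
        assert comp["sigma"] < sd < comp["sigma"] * 1.05

    def test_zscore_center_and_linearity(self, fitted_models):
        m = fitted_models["male"]
        mean = m.predict_mean(40.0, "beta", "P3")
        sd = m.predict_sd(40.0, "beta", "P3")
        bp = pd.DataFrame(
            {
                "subject_id": ["A", "B"],
                "channel": ["P3", "P3"],
                "band": ["beta", "beta"],
                "log_power": [mean, mean + 2 * sd],
            }
        )
        demo = pd.DataFrame(
            {"subject_id": ["A", "B"], "age": [40.0, 40.0], "sex": ["male", "male"]}
        )
        z = m.zscore(bp, demo).set_index("subject_id")["z"]
        assert z["A"] == pytest.approx(0.0, abs=1e-10)
        assert z["B"] == pytest.approx(2.0, abs=1e-10)

    def test_out_of_range_age_is_clamped_and_flagged(self, fitted_models):
        m = fitted_models["male"]
        bp = pd.DataFrame(
            {"subject_id": ["OLD"], "channel": ["Cz"], "band": ["theta"],
             "log_power": [1.0]}
        )
        demo = pd.DataFrame({"subject_id": ["OLD"], "age": [90.0], "sex": ["male"]})
        z = m.zscore(bp, demo)
        assert bool(z.age_clamped.iloc[0])
        assert np.isfinite(z.z.iloc[0])

    def test_nonpositive_power_flagged_not_zeroed(self, fitted_models):
        m = fitted_models["male"]
        bp = pd.DataFrame(
            {"subject_id": ["N", "N"], "channel": ["Cz", "Pz"], "band": ["theta", "theta"],
             "log_power": [np.nan, 1.5]}
        )
        demo = pd.DataFrame({"subject_id": ["N"], "age": [30.0], "sex": ["male"]})
        z = m.zscore(bp, demo).set_index("channel")
        assert bool(z.loc["Cz", "undefined"]) and not np.isfinite(z.loc["Cz", "z"])
        assert np.isfinite(z.loc["Pz", "z"])

    def test_sex_mismatch_rejected(self, fitted_models):
        bp = pd.DataFrame(
            {"subject_id": ["X"], "channel": ["Cz"], "band": ["theta"], "log_power": [1.0]}
        )
        demo = pd.DataFrame({"subject_id": ["X"], "age": [30.0], "sex": ["female"]})
        with pytest.raises(ValueError, match="sex_mode"):
            fitted_models["male"].zscore(bp, demo)

    def test_cohort_below_minimum_size_rejected(self, small_tables):
        bp, demo = small_tables
        with pytest.raises(ValueError, match="at least"):
            nm.NormativeDB(sex_mode="male", min_n=10_000).fit(bp, demo)


class TestPersistence:
    def test_json_round_trip_reproduces_predictions(self, fitted_models, tmp_path):
        m = fitted_models["female"]
        path = tmp_path / "model.json"
        m.save(path)
        m2 = nm.NormativeDB.load(path)
        grid = np.linspace(*m.age_range_, 100)
        for key in [("theta", "Cz"), ("gamma", "O2")]:
            np.testing.assert_allclose(
                m.predict_mean(grid, *key), m2.predict_mean(grid, *key), rtol=1e-12
            )
            np.testing.assert_allclose(
                m.predict_sd(grid, *key), m2.predict_sd(grid, *key), rtol=1e-12
            )

    def test_truncated_file_gives_schema_error(self, fitted_models, tmp_path):
        path = tmp_path / "model.json"
        fitted_models["male"].save(path)
        path.write_text(path.read_text()[:200])
        with pytest.raises(nm.ModelSchemaError):
            nm.NormativeDB.load(path)

    def test_wrong_document_gives_schema_error(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text(json.dumps({"model": "something-else"}))
        with pytest.raises(nm.ModelSchemaError, match="not a qeegnorm"):
            nm.NormativeDB.load(path)

    def test_hand_edited_lambda_reloads_as_consistent_refit(
        self, fitted_models, train_cohort, tmp_path
    ):
        m = fitted_models["male"]
        path = tmp_path / "model.json"
        m.save(path)
        doc = json.loads(path.read_text())
        target = next(
            c for c in doc["components"] if c["band"] == "theta" and c["channel"] == "Cz"
        )
        new_lam = 1e4 if target["lam"] < 1e3 else 1e-3
        target["lam"] = new_lam
        path.write_text(json.dumps(doc))
        edited = nm.NormativeDB.load(path)
        # oracle: refit on the same training rows with the grid pinned to new_lam
        bp, demo = train_cohort.band_power_table(), train_cohort.demographics()
        refit = nm.NormativeDB(sex_mode="male", lam_grid=(new_lam, new_lam)).fit(bp, demo)
        grid = np.linspace(*m.age_range_, 60)
        np.testing.assert_allclose(
            edited.predict_mean(grid, "theta", "Cz"),
            refit.predict_mean(grid, "theta", "Cz"),
            atol=1e-8,
        )


class TestAgeBandBaseline:
    def test_identical_log_powers_give_zero_z_everywhere(self):
        rng = np.random.default_rng(8)
        ids = [f"C{i}" for i in range(80)]
        bp = pd.DataFrame(
            {"subject_id": np.repeat(ids, 2),
             "channel": ["Cz", "Pz"] * 80,
             "band": ["theta", "theta"] * 80,
             "log_power": 1.7}
        )
        demo = pd.DataFrame(
            {"subject_id": ids, "age": rng.uniform(5, 80, 80), "sex": "male"}
        )
        model = nm.AgeBandNormativeDB(min_n=10).fit(bp, demo)
        z = model.zscore(bp, demo)
        np.testing.assert_array_equal(z.z, 0.0)

    def test_window_stats_match_brute_force(self, small_tables):
        bp, demo = small_tables
        model = nm.AgeBandNormativeDB(sex_mode="pooled", half_width=5.0).fit(bp, demo)
        ages = demo.set_index("subject_id")["age"]
        lo = model.age_range_[0]
        w = 2  # probe one interior window
        in_window = ages[(ages >= lo + w * 10.0) & (ages < lo + (w + 1) * 10.0)]
        if len(in_window) >= model.min_n:
            vals = bp[(bp.subject_id.isin(in_window.index))
                      & (bp.channel == "Cz") & (bp.band == "alpha")]["log_power"]
            assert model.window_means_.loc[w, ("alpha", "Cz")] == pytest.approx(vals.mean())
            assert model.window_sds_.loc[w, ("alpha", "Cz")] == pytest.approx(vals.std(ddof=1))

    def test_thin_windows_are_widened_to_minimum_n(self, small_tables):
        bp, demo = small_tables
        model = nm.AgeBandNormativeDB(sex_mode="pooled", half_width=1.0, min_n=30).fit(bp, demo)
        assert (model.window_counts_ >= 30).all()

    def test_age_band_jumps_exceed_spline_jumps_at_boundary(
        self, small_tables, fitted_models
    ):
        bp, demo = small_tables
        band_model = nm.AgeBandNormativeDB(sex_mode="pooled", half_width=5.0).fit(bp, demo)
        spline = fitted_models["pooled"]
        boundary = band_model.age_range_[0] + 10.0 * 3  # interior window edge
        probes = pd.DataFrame(
            {"subject_id": ["P1", "P2"], "age": [boundary - 0.1, boundary + 0.1],
             "sex": ["male", "male"]}
        )
        cells = bp[bp.subject_id == bp.subject_id.iloc[0]][["channel", "band"]]
        probe_bp = pd.concat(
            [cells.assign(subject_id=sid, log_power=1.0) for sid in ("P1", "P2")],
            ignore_index=True,
        )
        zb = band_model.zscore(probe_bp, probes).pivot_table(
            index=["channel", "band"], columns="subject_id", values="z"
        )
        zs = spline.zscore(probe_bp, probes.assign(sex="male")).pivot_table(
            index=["channel", "band"], columns="subject_id", values="z"
        )
        jump_band = (zb["P1"] - zb["P2"]).abs().mean()
        jump_spline = (zs["P1"] - zs["P2"]).abs().mean()
        assert jump_band > jump_spline
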