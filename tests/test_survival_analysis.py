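import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiaging.experiments import rep_seed
from epiaging.survival_analysis import (
    FULL_COVARIATES,
    bicor,
    breslow_baseline_cumhaz,
    breslow_partial_loglik,
    cox_fit,
    kruskal_wallis,
    landmark_exclusion,
    logistic_sensitivity,
    make_design,
    person_years_from_days,
    predict_incidence,
    stratified_analysis,
)
from epiaging.synthetic_cohort import SimulationConfig, simulate_events, simulate_subjects


# ---------------------------------------------------------------------------
# person-time

class TestPersonYears:
    @pytest.mark.parametrize(
        "days, years",
        [(0, 0.0), (365, 0.9993), (7305, 20.0), (1, 0.0027), (36525, 100.0)],
    )
    def test_four_decimal_conversion(self, days, years):
        assert person_years_from_days(days) == pytest.approx(years, abs=1e-12)

    def test_negative_days_rejected(self):
        with pytest.raises(ValueError):
            person_years_from_days(-1)


# ---------------------------------------------------------------------------
# Kruskal-Wallis

class TestKruskalWallis:
    def test_hand_computed_toy_partition(self):
        # groups {1,2,3} and {4,5,6}: H = 12/(6*7)*(6^2/3+15^2/3) - 3*7
        res = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert res.statistic == pytest.approx(3.857, abs=5e-4)
        assert res.group_sizes == [3, 3]

    def test_label_relabeling_invariance(self, rng):
        x = rng.normal(size=30)
        g = rng.choice(["u", "v", "w"], size=30)
        relabel = {"u": "B", "v": "C", "w": "A"}
        a = kruskal_wallis(x, g)
        b = kruskal_wallis(x, np.vectorize(relabel.get)(g))
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_chi_square_p_matches_permutation_oracle(self, rng):
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.9, 1, 20)])
        g = np.array(["a"] * 20 + ["b"] * 20)
        res = kruskal_wallis(x, g)
        n_shuffles = 10_000
        count = 0
        for _ in range(n_shuffles):
            count += kruskal_wallis(x, rng.permutation(g)).statistic >= res.statistic
        p_perm = (count + 1) / (n_shuffles + 1)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_shuffles)
        assert abs(p_perm - res.p_value) < max(mc_err, 0.01)

    def test_degenerate_identical_values(self):
        with pytest.raises(ValueError, match="degenerate"):
            kruskal_wallis([1, 1, 1, 1], ["a", "a", "b", "b"])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two"):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])


# ---------------------------------------------------------------------------
# biweight midcorrelation

class TestBicor:
    def test_linear_self_maps(self, rng):
        x = rng.normal(size=50)
        assert bicor(x, x).statistic == pytest.approx(1.0, abs=1e-12)
        assert bicor(x, -2 * x + 3).statistic == pytest.approx(-1.0, abs=1e-12)

    def test_agrees_with_pearson_on_clean_gaussian(self, rng):
        cov = [[1, 0.5], [0.5, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=10_000)
        r_bi = bicor(xy[:, 0], xy[:, 1]).statistic
        r_pe = stats.pearsonr(xy[:, 0], xy[:, 1])[0]
        assert abs(r_bi - r_pe) < 0.03

    def test_downweights_outliers(self, rng):
        x = rng.normal(size=200)
        y = x + rng.normal(0, 0.1, 200)
        y[:5] += 50  # gross outliers
        assert bicor(x, y).statistic > stats.pearsonr(x, y)[0]

    def test_zero_mad_fallback_and_error(self):
        x = np.array([1.0, 1, 1, 1, 1, 1, 9])  # MAD 0
        y = np.arange(7.0)
        with pytest.warns(UserWarning, match="zero MAD"):
            res = bicor(x, y)
        assert res.method == "pearson-fallback"
        with pytest.raises(ValueError, match="absolute deviation"):
            bicor(x, y, fallback_to_pearson=False)


# ---------------------------------------------------------------------------
# Cox model

def _toy_single_covariate():
    # 6 subjects, distinct event times, binary covariate
    return pd.DataFrame(
        {
            "x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 1, 1],
        }
    )


def _grid_oracle_loglik(df, covariates, grid):
    """Hand-written Breslow partial likelihood evaluated on a beta grid."""
    X = df[covariates].to_numpy()
    t = df["time"].to_numpy()
    e = df["event"].to_numpy()
    best, best_ll = None, -np.inf
    for beta in grid:
        beta = np.atleast_1d(beta)
        eta = X @ beta
        ll = 0.0
        for i in np.flatnonzero(e):
            ll += eta[i] - np.log(np.exp(eta[t >= t[i]]).sum())
        if ll > best_ll:
            best, best_ll = beta, ll
    return np.asarray(best), best_ll


class TestCoxFit:
    def test_log_hr_matches_dense_grid_search(self):
        df = _toy_single_covariate()
        fit = cox_fit(df, ["x"])
        grid = np.arange(-5, 5, 1e-4)
        beta_star, _ = _grid_oracle_loglik(df, ["x"], grid[:, None])
        assert fit.summary.loc["x", "log_hr"] == pytest.approx(beta_star[0], abs=1e-3)

    def test_optimum_dominates_surrounding_grid(self, rng):
        n = 40
        df = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.binomial(1, 0.5, n).astype(float),
                "time": rng.exponential(5, n).round(3) + 0.001,
                "event": rng.binomial(1, 0.6, n),
            }
        )
        fit = cox_fit(df, ["x1", "x2"])
        b = fit.summary["log_hr"].to_numpy()
        X, t, e = df[["x1", "x2"]].to_numpy(), df["time"].to_numpy(), df["event"].to_numpy()
        ll_hat = breslow_partial_loglik(X, b, t, e)
        for d1 in (-0.05, 0, 0.05):
            for d2 in (-0.05, 0, 0.05):
                assert ll_hat >= breslow_partial_loglik(
                    X, b + np.array([d1, d2]), t, e
                ) - 1e-9

    def test_breslow_jump_count_equals_distinct_event_times(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "time": rng.integers(1, 10, n).astype(float),  # forces ties
                "event": rng.binomial(1, 0.7, n),
            }
        )
        fit = cox_fit(df, ["x"])
        distinct = np.unique(df.loc[df["event"] == 1, "time"]).size
        assert len(fit.baseline_cumhaz) == distinct
        assert (np.diff(fit.baseline_cumhaz.to_numpy()) > 0).all()
        assert fit.baseline_cumhaz.iloc[0] > 0

    def test_zero_events_rejected(self):
        df = _toy_single_covariate().assign(event=0)
        with pytest.raises(ValueError, match="no events"):
            cox_fit(df, ["x"])

    def test_constant_covariate_rejected(self):
        df = _toy_single_covariate().assign(x=1.0)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["x"])

    def test_row_order_invariance(self, rng):
        df = _toy_single_covariate()
        a = cox_fit(df, ["x"]).summary
        b = cox_fit(df.sample(frac=1, random_state=3), ["x"]).summary
        pd.testing.assert_frame_equal(a, b)

    def test_r_squared_definition(self):
        df = _toy_single_covariate()
        fit = cox_fit(df, ["x"])
        expected = 1 - np.exp(
            2 * (fit.null_log_likelihood - fit.log_likelihood) / fit.n
        )
        assert fit.r_squared == pytest.approx(expected, abs=1e-12)
        assert fit.total_person_years == pytest.approx(df["time"].sum())


# ---------------------------------------------------------------------------
# stratified models

def _simulated_design(seed=1, n=3000, baseline_rate=2.6e-3, log_hr=np.log(1.5)):
    cfg = SimulationConfig(
        n_subjects=n, baseline_rate=baseline_rate,
        true_log_hr_per_sd=log_hr, seed=seed,
    )
    ph, truth = simulate_subjects(cfg)
    ph, truth = simulate_events(ph, truth, cfg)
    ieaa = (truth["true_acceleration"] / cfg.acceleration_sd).rename("ieaa")
    return ph, ieaa, truth


class TestStratifiedAnalysis:
    def test_age_boundary_convention(self):
        ph, ieaa, _ = _simulated_design(seed=2)
        ph = ph.copy()
        ph.iloc[0, ph.columns.get_loc("age")] = 59.99
        ph.iloc[1, ph.columns.get_loc("age")] = 60.0
        ph.iloc[2, ph.columns.get_loc("age")] = 79.0
        res = {s.name: s for s in stratified_analysis(ph, ieaa, "age")}
        labels = pd.cut(
            ph["age"], [0, 60, 70, np.inf], right=False,
            labels=["50-59", "60-69", "70+"],
        )
        for name in ("50-59", "60-69", "70+"):
            assert res[name].n == (labels == name).sum()

    def test_event_partition_conservation(self):
        ph, ieaa, _ = _simulated_design(seed=3)
        res = stratified_analysis(ph, ieaa, "age")
        assert sum(s.n_events for s in res) == ph["event"].sum()
        assert sum(s.n for s in res) == len(ph)

    def test_smoking_strata_drop_pack_years_for_never(self):
        ph, ieaa, _ = _simulated_design(seed=4)
        res = {s.name: s for s in stratified_analysis(ph, ieaa, "smoking")}
        assert "pack_years" not in res["never"].fit.covariate_names
        assert "pack_years" in res["current"].fit.covariate_names
        for s in res.values():  # smoking dummies never enter their own strata
            assert "former" not in (s.fit.covariate_names if s.fit else [])

    def test_empty_stratum_reported_not_dropped(self):
        ph, ieaa, _ = _simulated_design(seed=5, n=300)
        ph = ph[ph["age"] < 70]  # empty the oldest stratum
        res = {s.name: s for s in stratified_analysis(ph, ieaa, "age")}
        assert res["70+"].fit is None
        assert res["70+"].error == "no subjects"

    def test_effect_planted_only_in_oldest_group_is_detected(self):
        """Simulate an acceleration effect only at ages 70+; the stratified
        estimate in that group should be the largest in most replicates."""
        hits = 0
        n_reps = 50
        for i in range(n_reps):
            seed = rep_seed(60, i)
            young_cfg = SimulationConfig(
                n_subjects=1400, age_range=(50.0, 69.99), baseline_rate=2.6e-3,
                true_log_hr_per_sd=0.0, seed=seed,
            )
            old_cfg = SimulationConfig(
                n_subjects=600, age_range=(70.0, 79.0), baseline_rate=2.6e-3,
                true_log_hr_per_sd=np.log(2.5), seed=seed + 1,
            )
            parts = []
            for tag, cfg in (("y", young_cfg), ("o", old_cfg)):
                ph, truth = simulate_subjects(cfg)
                ph, truth = simulate_events(ph, truth, cfg)
                ph = ph.set_index(tag + ph.index.astype(str))
                truth = truth.set_index(ph.index)
                z = (truth["true_acceleration"] / cfg.acceleration_sd).rename("ieaa")
                parts.append((ph, z))
            ph = pd.concat([p for p, _ in parts])
            ieaa = pd.concat([z for _, z in parts])
            res = {s.name: s for s in stratified_analysis(ph, ieaa, "age")}
            hrs = {
                k: s.fit.summary.loc["ieaa", "hr"]
                for k, s in res.items() if s.fit is not None
            }
            if "70+" in hrs and hrs["70+"] == max(hrs.values()):
                hits += 1
        assert hits >= 45


# ---------------------------------------------------------------------------
# incidence curves

class TestPredictIncidence:
    @pytest.fixture()
    def fit(self):
        ph, ieaa, _ = _simulated_design(seed=6)
        design = make_design(ph, ieaa)
        return cox_fit(design, FULL_COVARIATES)

    def test_zero_profile_is_baseline_curve(self, fit):
        profile = {c: 0.0 for c in fit.covariate_names}
        times = np.array([0.0, 5.0, 10.0, 19.0])
        inc = predict_incidence(fit, profile, times)
        jump_t = fit.baseline_cumhaz.index.to_numpy()
        for t, v in inc.items():
            h0 = fit.baseline_cumhaz.to_numpy()[jump_t <= t][-1] if (jump_t <= t).any() else 0.0
            assert v == pytest.approx(1 - np.exp(-h0), abs=1e-12)

    def test_incidence_zero_at_time_zero_and_nondecreasing(self, fit):
        profile = {c: 0.0 for c in fit.covariate_names}
        profile.update(age=75.0, current=1.0, pack_years=30.0)
        times = np.linspace(0, 20, 41)
        inc = predict_incidence(fit, profile, times)
        assert inc.iloc[0] == 0.0
        assert (np.diff(inc.to_numpy()) >= 0).all()

    def test_higher_ieaa_profile_dominates(self, fit):
        times = np.linspace(0, 20, 21)
        base = {c: 0.0 for c in fit.covariate_names}
        base.update(age=75.0, current=1.0, pack_years=30.0)
        assert fit.summary.loc["ieaa", "log_hr"] > 0
        hi = predict_incidence(fit, {**base, "ieaa": 1.0}, times)
        lo = predict_incidence(fit, {**base, "ieaa": -1.0}, times)
        assert (hi.to_numpy()[1:] > lo.to_numpy()[1:]).all()

    def test_extension_beyond_followup_warns_and_is_flat(self, fit):
        profile = {c: 0.0 for c in fit.covariate_names}
        with pytest.warns(UserWarning, match="extended flat"):
            inc = predict_incidence(fit, profile, [19.0, 25.0, 40.0])
        assert inc.iloc[1] == inc.iloc[2]

    def test_missing_profile_covariate_rejected(self, fit):
        with pytest.raises(ValueError, match="missing"):
            predict_incidence(fit, {"ieaa": 0.0}, [1.0])


# ---------------------------------------------------------------------------
# sensitivity analyses

class TestLandmarkExclusion:
    def _toy(self):
        return pd.DataFrame(
            {
                "event": [1, 1, 1, 0, 0],
                "time": [0.5, 2.0, 4.0, 0.3, 6.0],
            },
            index=[f"s{i}" for i in range(5)],
        )

    @pytest.mark.parametrize("within, removed", [(0, 0), (1, 1), (5, 3)])
    def test_toy_counts(self, within, removed):
        filtered, n = landmark_exclusion(self._toy(), within)
        assert n == removed
        assert len(filtered) == 5 - removed
        # censored subjects retained regardless of time
        assert "s3" in filtered.index and "s4" in filtered.index


class TestLogisticSensitivity:
    def test_null_covariate_has_near_zero_log_or(self):
        ph, _, truth = _simulated_design(seed=7, n=50_000, log_hr=0.0)
        ieaa = (truth["true_acceleration"] / 5.0).rename("ieaa")
        out = logistic_sensitivity(ph, ieaa)
        assert abs(out.loc["ieaa", "log_or"]) <= 0.05

    def test_rare_outcome_or_approximates_cox_hr(self):
        ph, ieaa, _ = _simulated_design(
            seed=8, n=50_000, baseline_rate=2.5e-4, log_hr=np.log(1.5)
        )
        assert ph["event"].mean() < 0.04  # rare outcome regime
        design = make_design(ph, ieaa)
        hr = cox_fit(design, FULL_COVARIATES).summary.loc["ieaa", "hr"]
        orr = logistic_sensitivity(ph, ieaa).loc["ieaa", "odds_ratio"]
        assert abs(orr - hr) <= 0.1

    def test_row_duplication_leaves_estimates_unchanged(self):
        ph, ieaa, _ = _simulated_design(seed=9, n=2000)
        a = logistic_sensitivity(ph, ieaa)
        ph2 = pd.concat([ph, ph.set_axis(ph.index + "_dup")])
        ieaa2 = pd.concat([ieaa, ieaa.set_axis(ieaa.index + "_dup")])
        b = logistic_sensitivity(ph2, ieaa2)
        np.testing.assert_allclose(a["log_or"], b["log_or"], atol=1e-6)

    def test_single_class_rejected(self):
        ph, ieaa, _ = _simulated_design(seed=10, n=300, baseline_rate=0.0)
        with pytest.raises(ValueError, match="outcome classes"):
            logistic_sensitivity(ph, ieaa)
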