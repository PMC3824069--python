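"""Estimators and specification tests against independent oracles."""

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from prefiv.estimators import (
    fe_tsls,
    first_stage_diagnostics,
    hausman_dwh,
    lm_added_instruments,
    ols_cluster,
    ps_match_rd,
    tsls,
    wald_ratio,
)
from prefiv.experiments import CONFOUNDED_STUDY_CONFIG, simulate_cohort


def _brute_force_cluster_se(y, X, clusters):
    """Independent oracle: loop-over-clusters sandwich for OLS, Stata factor."""
    n, k = X.shape
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    u = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((k, k))
    for g in np.unique(clusters):
        Xg, ug = X[clusters == g], u[clusters == g]
        s = Xg.T @ ug
        meat += np.outer(s, s)
    G = len(np.unique(clusters))
    V = (G / (G - 1)) * ((n - 1) / (n - k)) * bread @ meat @ bread
    return beta, np.sqrt(np.diag(V))


@pytest.fixture(scope="module")
def clustered_data():
    rng = np.random.default_rng(15)
    n, G = 1500, 50
    cl = rng.integers(0, G, n)
    effect = rng.normal(0, 0.3, G)[cl]
    x = (rng.random(n) < 0.5).astype(float)
    y = 0.2 + 0.1 * x + effect + rng.normal(0, 0.5, n)
    year = rng.integers(2000, 2005, n)
    return y, x, cl, year


class TestOlsCluster:
    def test_matches_brute_force_and_statsmodels(self, clustered_data):
        y, x, cl, _ = clustered_data
        res = ols_cluster(y, x, None, cl)
        X = np.column_stack([x, np.ones_like(x)])
        beta, se = _brute_force_cluster_se(y, X, cl)
        assert res.rd_per_100 == pytest.approx(100 * beta[0], rel=1e-10)
        assert res.se == pytest.approx(100 * se[0], rel=1e-10)
        sm_res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": cl})
        assert res.se == pytest.approx(100 * sm_res.bse[0], rel=1e-6)

    def test_singleton_clusters_reduce_to_hc1(self, clustered_data):
        y, x, _, _ = clustered_data
        res = ols_cluster(y, x, None, np.arange(len(y)))
        X = np.column_stack([x, np.ones_like(x)])
        hc1 = sm.OLS(y, X).fit(cov_type="HC1")
        assert res.se == pytest.approx(100 * hc1.bse[0], rel=1e-8)

    def test_constant_outcome_gives_zero_coef_and_se(self):
        y = np.full(40, 0.5)
        x = np.tile([0.0, 1.0], 20)
        res = ols_cluster(y, x, None, np.repeat(np.arange(10), 4))
        assert res.rd_per_100 == pytest.approx(0.0, abs=1e-10)
        assert res.se == pytest.approx(0.0, abs=1e-10)

    def test_few_clusters_and_rank_deficiency_rejected(self):
        y, x = np.array([1.0, 0.0]), np.array([1.0, 0.0])
        with pytest.raises(ValueError, match="cluster"):
            ols_cluster(y, x, None, np.array([1, 1]))
        with pytest.raises(ValueError, match="rank"):
            ols_cluster(
                np.arange(4.0), np.ones(4), np.ones((4, 1)), np.array([0, 0, 1, 1])
            )

    def test_unbiased_without_confounding(self):
        cfg = dataclasses.replace(
            CONFOUNDED_STUDY_CONFIG,
            n_physicians=150,
            patients_per_physician=60,
            confounder_effect_rx=0.0,
            confounder_effect_y=0.0,
            seed=33,
        )
        cohort, truth, _ = simulate_cohort(cfg)
        res = ols_cluster(
            cohort["Y"].to_numpy(float),
            cohort["X"].to_numpy(float),
            None,
            cohort["physician_id"].to_numpy(),
        )
        assert abs(res.rd_per_100 - truth.true_effect) < 2 * res.se


class TestWaldRatio:
    def test_hand_example_zero_numerator(self):
        z = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        assert wald_ratio(y, x, z) == pytest.approx(0.0)

    def test_hand_example_50_per_100(self):
        z = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        y = np.array([1, 1, 0, 0, 0, 0, 1, 0])
        assert wald_ratio(y, x, z) == pytest.approx(50.0)

    def test_y_equal_x_gives_100(self):
        z = np.array([1, 1, 0, 0])
        x = np.array([1, 0, 0, 0])
        assert wald_ratio(x.astype(float), x, z) == pytest.approx(100.0)

    def test_zero_first_stage_rejected(self):
        z = np.array([1, 1, 0, 0])
        x = np.array([1, 0, 1, 0])
        with pytest.raises(ValueError, match="first-stage"):
            wald_ratio(x, x, z)  # means equal across z


class TestTsls:
    def test_instrumenting_x_with_itself_equals_ols(self, clustered_data):
        y, x, cl, year = clustered_data
        ols = ols_cluster(y, x, None, cl)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            iv, _ = tsls(y, x, x, None, cl)
        assert iv.rd_per_100 == pytest.approx(ols.rd_per_100, rel=1e-10)
        assert iv.se == pytest.approx(ols.se, rel=1e-10)

    def test_equals_wald_ratio_just_identified(self):
        rng = np.random.default_rng(16)
        for _ in range(50):
            n = int(rng.integers(10, 50))
            z = (rng.random(n) < 0.5).astype(float)
            x = (rng.random(n) < 0.3 + 0.4 * z).astype(float)
            y = (rng.random(n) < 0.2 + 0.3 * x).astype(float)
            if z.min() == z.max() or x[z == 1].mean() == x[z == 0].mean():
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est, _ = tsls(y, x, z, None, np.arange(n))
            assert est.rd_per_100 == pytest.approx(wald_ratio(y, x, z), abs=1e-10)

    def test_indirect_least_squares_identity(self, clustered_data):
        """Just-identified 2SLS equals reduced-form over first-stage, even
        with controls in both equations."""
        y, x, cl, year = clustered_data
        rng = np.random.default_rng(17)
        z = np.round(np.clip(x * 0.6 + rng.random(len(x)) * 0.8, 0, 1))
        ctrl = pd.get_dummies(year, dtype=float).iloc[:, 1:].to_numpy()
        est, _ = tsls(y, x, z, ctrl, cl)
        Zm = np.column_stack([z, ctrl, np.ones_like(z)])
        rf = np.linalg.lstsq(Zm, y, rcond=None)[0][0]
        fs = np.linalg.lstsq(Zm, x, rcond=None)[0][0]
        assert est.rd_per_100 == pytest.approx(100 * rf / fs, rel=1e-9)

    def test_removes_unmeasured_confounding_where_ols_fails(self):
        """The core validity property: with strong unmeasured confounding and
        a preference-driven instrument, 2SLS recovers the true risk
        difference while plain least squares does not."""
        cfg = dataclasses.replace(CONFOUNDED_STUDY_CONFIG, seed=44)
        cohort, truth, _ = simulate_cohort(cfg, instruments=("Z1", "ind7"))
        y = cohort["Y"].to_numpy(float)
        x = cohort["X"].to_numpy(float)
        cl = cohort["physician_id"].to_numpy()
        iv, fs = tsls(y, x, cohort["Z1"].to_numpy(float), None, cl)
        ols = ols_cluster(y, x, None, cl)
        assert fs.partial_f > 100
        assert abs(iv.rd_per_100 - truth.true_effect) < 3 * iv.se
        assert abs(ols.rd_per_100 - truth.true_effect) > 10 * ols.se
        # precision ordering: deeper instruments are at least as precise
        Z7 = cohort[[f"Z_ind7_{j}" for j in range(1, 8)]].to_numpy(float)
        iv7, _ = tsls(y, x, Z7, None, cl)
        assert iv7.se <= iv.se

    def test_weak_instrument_warns(self):
        rng = np.random.default_rng(18)
        n = 400
        z = (rng.random(n) < 0.5).astype(float)
        x = (rng.random(n) < 0.5).astype(float)  # unrelated to z
        y = rng.random(n)
        with pytest.warns(UserWarning, match="weak first stage"):
            tsls(y, x, z, None, rng.integers(0, 40, n))


class TestFirstStage:
    def test_single_instrument_f_is_squared_t(self, cohort_z1):
        fs = first_stage_diagnostics(
            cohort_z1["X"].to_numpy(float),
            cohort_z1["Z1"].to_numpy(float),
            None,
            cohort_z1["physician_id"].to_numpy(),
        )
        # recompute t from an OLS of x on z with the same variance
        res = ols_cluster(
            cohort_z1["X"].to_numpy(float),
            cohort_z1["Z1"].to_numpy(float),
            None,
            cohort_z1["physician_id"].to_numpy(),
        )
        assert fs.partial_f == pytest.approx((res.rd_per_100 / res.se) ** 2, rel=1e-9)
        assert fs.first_stage_rd == pytest.approx(res.rd_per_100, rel=1e-12)
        assert 0 <= fs.partial_r2 <= 1

    def test_irrelevant_instrument_mean_f_near_one(self):
        rng = np.random.default_rng(19)
        fs_vals = []
        for _ in range(300):
            n = 600
            cl = rng.integers(0, 30, n)
            z = (rng.random(n) < 0.5).astype(float)
            x = (rng.random(n) < 0.5).astype(float)
            fs_vals.append(first_stage_diagnostics(x, z, None, cl).partial_f)
        mean_f = np.mean(fs_vals)
        assert abs(mean_f - 1.0) < 3 * np.std(fs_vals, ddof=1) / math.sqrt(len(fs_vals))


class TestLmAddedInstruments:
    def test_duplicate_instrument_adds_nothing(self):
        rng = np.random.default_rng(20)
        n = 500
        z = (rng.random(n) < 0.5).astype(float)
        x = (rng.random(n) < 0.3 + 0.3 * z).astype(float)
        # an affine copy of the base instrument carries no new variance
        stat, df, p = lm_added_instruments(x, z, np.column_stack([1 - z]), None)
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert df == 1 and p == pytest.approx(1.0)

    def test_exact_overlap_rejected(self):
        z = np.array([0.0, 1.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="overlap"):
            lm_added_instruments(z, z, z, None)

    def test_deeper_history_explains_extra_exposure_variance(self):
        """With persistent physician preferences, indicators for older prior
        prescriptions add first-stage information beyond the most recent one."""
        cfg = dataclasses.replace(
            CONFOUNDED_STUDY_CONFIG, n_physicians=150, patients_per_physician=60, seed=55
        )
        cohort, _, _ = simulate_cohort(cfg, instruments=("Z1", "ind7"))
        added = cohort[[f"Z_ind7_{j}" for j in range(2, 8)]].to_numpy(float)
        stat, df, p = lm_added_instruments(
            cohort["X"].to_numpy(float), cohort["Z1"].to_numpy(float), added, None
        )
        assert df == 6
        assert stat > stats.chi2.ppf(0.95, 6)
        assert p < 0.05


class TestHausman:
    def test_degenerate_residual_signalled(self):
        z = np.tile([0.0, 1.0], 50)
        y = np.random.default_rng(1).random(100)
        with pytest.raises(ValueError, match="degenerate"):
            hausman_dwh(y, z, z, None, np.repeat(np.arange(10), 10))

    def test_detects_strong_confounding(self):
        cfg = dataclasses.replace(
            CONFOUNDED_STUDY_CONFIG,
            n_physicians=300,
            patients_per_physician=80,
            preference_sd=2.5,
            confounder_effect_y=60.0,
            seed=66,
        )
        cohort, _, _ = simulate_cohort(cfg)
        stat, p = hausman_dwh(
            cohort["Y"].to_numpy(float),
            cohort["X"].to_numpy(float),
            cohort["Z1"].to_numpy(float),
            None,
            cohort["physician_id"].to_numpy(),
        )
        assert p < 0.01

    def test_accepts_exogenous_exposure(self):
        cfg = dataclasses.replace(
            CONFOUNDED_STUDY_CONFIG,
            n_physicians=200,
            patients_per_physician=60,
            confounder_effect_rx=0.0,
            confounder_effect_y=0.0,
            seed=67,
        )
        cohort, _, _ = simulate_cohort(cfg)
        _, p = hausman_dwh(
            cohort["Y"].to_numpy(float),
            cohort["X"].to_numpy(float),
            cohort["Z1"].to_numpy(float),
            None,
            cohort["physician_id"].to_numpy(),
        )
        assert p > 0.01


def _fe_world(delta, seed=0, G=300, m=30, tau=-10.0):
    """Physician-level direct outcome effect delta violates the exclusion
    restriction for plain 2SLS but not for the fixed-effects variant."""
    rng = np.random.default_rng(seed)
    alpha = rng.normal(0, 1.2, G)
    cl = np.repeat(np.arange(G), m)
    x = (rng.random(G * m) < 1 / (1 + np.exp(-alpha[cl]))).astype(float)
    # instrument: physician's previous patient's prescription
    z = pd.Series(x).groupby(cl).shift(1).to_numpy()
    keep = ~np.isnan(z)
    y = (20 + tau * x + delta * alpha[cl] + rng.normal(0, 30, G * m)) / 100
    return y[keep], x[keep], z[keep], cl[keep]


class TestFixedEffectsIv:
    def test_constant_instrument_physician_contributes_nothing(self):
        y, x, z, cl = _fe_world(delta=0.0, seed=5, G=80, m=20)
        est = fe_tsls(y, x, z, None, cl)
        const = [g for g in np.unique(cl) if z[cl == g].min() == z[cl == g].max()]
        assert const, "test needs at least one constant-instrument physician"
        drop = cl != const[0]
        est2 = fe_tsls(y[drop], x[drop], z[drop], None, cl[drop])
        assert est.rd_per_100 == pytest.approx(est2.rd_per_100, abs=1e-9)

    def test_removes_direct_physician_effect(self):
        y, x, z, cl = _fe_world(delta=20.0, seed=6)
        fe = fe_tsls(y, x, z, None, cl)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plain, _ = tsls(y, x, z, None, cl)
        assert abs(fe.rd_per_100 - (-10.0)) < 3 * fe.se
        assert abs(plain.rd_per_100 - (-10.0)) > 3 * plain.se

    def test_agrees_with_tsls_without_physician_effects(self):
        y, x, z, cl = _fe_world(delta=0.0, seed=7)
        fe = fe_tsls(y, x, z, None, cl)
        plain, _ = tsls(y, x, z, None, cl)
        assert abs(fe.rd_per_100 - plain.rd_per_100) < 2 * max(fe.se, plain.se)

    def test_no_within_variation_rejected(self):
        y = np.random.default_rng(2).random(40)
        x = np.tile([0.0, 1.0], 20)
        cl = np.repeat(np.arange(4), 10)
        z = np.repeat([0.0, 1.0, 0.0, 1.0], 10)  # constant within physician
        with pytest.raises(ValueError, match="within-physician"):
            fe_tsls(y, x, z, None, cl)


def _psm_world(n, seed, confounded, k=8):
    rng = np.random.default_rng(seed)
    C = (rng.random((n, k)) < 0.4).astype(float)
    lin = C @ np.linspace(1.4, 0.4, k) if confounded else np.zeros(n)
    x = (rng.random(n) < 1 / (1 + np.exp(-(lin - 1.5)))).astype(int)
    bias = C @ np.full(k, 15.0) if confounded else np.zeros(n)
    y = (-10.0 * x + bias + rng.normal(0, 15, n)) / 100
    return y, x, C


class TestPsMatching:
    def test_independent_covariates_match_crude(self):
        y, x, C = _psm_world(6000, seed=8, confounded=False)
        res = ps_match_rd(y, x, C)
        crude = 100 * (y[x == 1].mean() - y[x == 0].mean())
        assert abs(res.rd_per_100 - crude) < 3 * res.se

    def test_recovers_effect_under_observed_confounding(self):
        y, x, C = _psm_world(20000, seed=9, confounded=True)
        res = ps_match_rd(y, x, C)
        crude = 100 * (y[x == 1].mean() - y[x == 0].mean())
        assert abs(res.rd_per_100 - (-10.0)) < 3 * res.se
        assert abs(crude - (-10.0)) > 5 * res.se

    def test_zero_caliper_requires_exact_scores(self):
        # continuous covariate: exact propensity-score ties have probability 0
        rng = np.random.default_rng(12)
        C = rng.normal(size=(300, 1))
        x = (rng.random(300) < 1 / (1 + np.exp(-C[:, 0]))).astype(int)
        y = rng.random(300)
        with pytest.raises(ValueError, match="caliper"):
            ps_match_rd(y, x, C, caliper=0.0)

    def test_zero_caliper_exact_match_runs(self):
        rng = np.random.default_rng(11)
        C = (rng.random((400, 1)) < 0.5).astype(float)
        x = (rng.random(400) < 0.5).astype(int)
        y = rng.random(400)
        res = ps_match_rd(y, x, C, caliper=0.0)
        assert res.diagnostics["n_matched_exposed"] == int(x.sum())
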