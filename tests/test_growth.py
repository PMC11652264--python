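import numpy as np
import pandas as pd
import pytest

from twingrowth.errors import SpecError
from twingrowth import growth, simulate as sim, twin
from twingrowth.growth import (
    FACTORS,
    WAVES,
    build_piecewise_lgc,
    build_outcome_spec,
    make_sem_data,
    piecewise_loading_matrix,
    prune_nonsignificant_covariances,
    slope_loadings,
    standardized_betas,
)


class TestLoadings:
    def test_default_childhood_slope(self):
        child, adol = slope_loadings()
        assert child == (0.0, 3.0, 5.0)

    def test_default_adolescence_slope(self):
        child, adol = slope_loadings()
        assert adol == (0.0, 2.0, 7.0)

    def test_each_wave_loads_on_own_trait_only(self):
        lam = piecewise_loading_matrix()
        assert np.all(lam[:6, 4:] == 0)     # emotional waves, conduct factors
        assert np.all(lam[6:, :4] == 0)

    def test_one_intercept_one_slope_per_wave(self):
        lam = piecewise_loading_matrix()
        for row in lam:
            assert np.sum(row == 1.0) == 1
            assert np.count_nonzero(row) <= 2

    def test_anchor_must_match_a_wave_age(self):
        with pytest.raises(SpecError, match="anchor"):
            piecewise_loading_matrix(anchors=(5.0, 9.0))

    def test_custom_ages(self):
        child, adol = slope_loadings(
            wave_ages=(4.5, 7.2, 9.1, 9.3, 11.4, 16.3), anchors=(4.5, 9.3))
        assert child == (0.0, pytest.approx(2.7), pytest.approx(4.6))
        assert adol == (pytest.approx(0.0), pytest.approx(2.1),
                        pytest.approx(7.0))


class TestSpecStructure:
    def test_parameter_count_63(self):
        # 8 means + 36 factor (co)variances + 12 residual variances
        # + 7 residual covariances (parent-self age-9 tied across traits)
        spec = build_piecewise_lgc()
        assert spec.n_free == 63

    def test_no_cross_segment_equalities(self):
        # the age-9 knot is a rater switch: parent and self age-9 means and
        # factors stay free of each other (discontinuity allowed)
        spec = build_piecewise_lgc()
        assert spec.aliases == {}
        labels = set(spec.free_labels)
        assert "mean_em_ic" in labels and "mean_em_ip" in labels

    def test_outcome_spec_adds_regression_block(self):
        spec = build_outcome_spec("audit_total", ["ses"])
        labels = set(spec.free_labels)
        assert {"b_em_ip", "b_cd_sa", "g_ses", "int_audit_total",
                "resvar_audit_total"} <= labels
        # covariate correlates freely with every factor (auxiliary role)
        assert {f"psi_x_ses_{f}" for f in FACTORS} <= labels

    def test_multi_group_labels_suffixed(self):
        spec = build_piecewise_lgc(groups=["F", "M"])
        assert spec.n_free == 126
        assert "mean_em_ic@F" in spec.free_labels


class TestGrowthFit:
    def test_mean_trajectory_recovery(self, small_long, small_cohort):
        ds, truth, cfg = small_cohort
        gfit = growth.fit_growth(small_long)
        assert gfit.converged
        mu_hat, _ = gfit.model.implied_moments(gfit.theta, "all")
        X = small_long[list(WAVES)].to_numpy(float)
        emp = np.nanmean(X, axis=0)
        se = np.nanstd(X, axis=0) / np.sqrt(len(X))
        assert np.all(np.abs(mu_hat - emp) < 3 * se + 1e-6)

    def test_factor_means_near_truth(self, small_long, small_cohort):
        ds, truth, cfg = small_cohort
        gfit = growth.fit_growth(small_long)
        est = gfit.estimates()
        for f, tv in zip(FACTORS, cfg.factor_means):
            assert est[f"mean_{f}"] == pytest.approx(tv, abs=0.15)


class TestPruning:
    def _diag_cfg(self, seed):
        cfg = sim.default_config(n_mz=1000, n_dzss=1000, seed=seed)
        total = np.diag(np.diag(cfg.ace_a + cfg.ace_c + cfg.ace_e))
        cfg.ace_a, cfg.ace_c, cfg.ace_e = 0.5 * total, 0.2 * total, 0.3 * total
        cfg.residual_corr_cross_trait = 0.0
        cfg.residual_corr_parent_self9 = 0.25
        cfg.validate()
        return cfg

    def test_true_zero_covariances_pruned(self):
        hits = reps = 0
        for rep in range(5):
            cfg = self._diag_cfg(300 + rep)
            ds, _ = sim.simulate_dataset(cfg)
            long_df = ds.to_individual_long()
            gfit = growth.fit_growth(long_df)
            data = make_sem_data(long_df, list(WAVES))
            pr = prune_nonsignificant_covariances(gfit, data)
            reps += 1
            hits += "psi_em_ic_cd_sa" in pr.pruned
            # the genuinely nonzero parent-self covariance must survive
            assert "rescov_p9_s9" not in pr.pruned
            # acceptance of the pruned model cannot raise AIC
            assert pr.fit.aic <= gfit.aic + 1e-6
        assert hits / reps >= 0.8

    def test_all_significant_unchanged(self, small_long):
        # default config has correlated factors: nothing major gets pruned
        gfit = growth.fit_growth(small_long)
        data = make_sem_data(small_long, list(WAVES))
        pr = prune_nonsignificant_covariances(gfit, data)
        assert pr.lr[2] >= 0.05      # retained reduction never degrades fit


class TestOutcomeModel:
    def test_standardization_identity(self, small_long):
        ofit = growth.fit_outcome_model(small_long, "audit_total")
        spec, res = ofit.spec, ofit.fit
        _, sig = spec.implied_moments(res.theta, "all")
        psi = spec.materialize(res.theta, "all")["psi"]
        sd_y = np.sqrt(sig[spec.var_index("audit_total"),
                           spec.var_index("audit_total")])
        for _, row in ofit.betas.iterrows():
            j = FACTORS.index(row["predictor"])
            expect = row["beta_raw"] * np.sqrt(psi[j, j]) / sd_y
            assert row["beta_std"] == pytest.approx(expect, abs=1e-8)

    def test_null_effects_covered(self, small_long):
        # generating model has b = 0 for all but em_ip and cd_sa
        ofit = growth.fit_outcome_model(small_long, "audit_total")
        V = ofit.fit.robust_vcov()
        null_factors = [f for f in FACTORS if f not in ("em_ip", "cd_sa")]
        misses = 0
        for f in null_factors:
            i = ofit.fit.labels.index(f"b_{f}")
            se = np.sqrt(V[i, i])
            misses += abs(ofit.fit.theta[i]) > 1.96 * se
        assert misses <= 2

    def test_conduct_effect_recovered(self, small_long):
        ofit = growth.fit_outcome_model(small_long, "audit_total")
        row = ofit.betas.set_index("predictor").loc["cd_sa"]
        assert row["beta_std"] == pytest.approx(0.30, abs=0.08)

    def test_outcome_all_missing_rejected(self, small_long):
        df = small_long.copy()
        df["audit_total"] = np.nan
        with pytest.raises(Exception, match="missing"):
            growth.fit_outcome_model(df, "audit_total")

    def test_one_step_two_step_agreement(self):
        # well-separated design: low residual noise -> reliable factor scores
        cfg = sim.default_config(n_mz=1500, n_dzss=1500, seed=77)
        cfg.residual_vars = (0.05,) * 12
        cfg.validate()
        ds, _ = sim.simulate_dataset(cfg)
        long_df = ds.to_individual_long()
        ofit = growth.fit_outcome_model(long_df, "audit_total")
        one_step = ofit.betas.set_index("predictor")["beta_std"]
        gfit = growth.fit_growth(long_df)
        scored = twin.compute_factor_scores(gfit, long_df)
        cols = [f"fs_{f}" for f in FACTORS]
        Z = scored[cols + ["audit_total"]].dropna()
        X = np.column_stack([np.ones(len(Z))] + [Z[c] for c in cols])
        coef, *_ = np.linalg.lstsq(X, Z["audit_total"], rcond=None)
        sd_y = Z["audit_total"].std()
        for j, f in enumerate(("em_ip", "cd_sa")):
            two_step = coef[1 + FACTORS.index(f)] * Z[f"fs_{f}"].std() / sd_y
            one = one_step[f]
            assert np.sign(two_step) == np.sign(one)
            assert abs(two_step - one) / abs(one) < 0.2


class TestSexPipelineStructure:
    def test_step_order_and_report(self):
        cfg = sim.default_config(n_mz=300, n_dzss=300, seed=5)
        ds, _ = sim.simulate_dataset(cfg)
        long_df = ds.to_individual_long()
        rep = growth.sex_difference_pipeline(long_df, "audit_total",
                                            covariates=["ses"])
        assert [s.name for s in rep.steps] == list(growth.STEP_NAMES)
        assert set(rep.wald["coefficient"]).issubset(
            {f"b_{f}" for f in FACTORS} | {"g_ses"})
        d = rep.to_json_dict()
        assert len(d["steps"]) == 5

    def test_group_without_outcome_rejected(self):
        cfg = sim.default_config(n_mz=100, n_dzss=100, seed=6)
        ds, _ = sim.simulate_dataset(cfg)
        long_df = ds.to_individual_long()
        long_df.loc[long_df["sex"] == "M", "audit_total"] = np.nan
        with pytest.raises(Exception, match="no outcome data"):
            growth.sex_difference_pipeline(long_df, "audit_total")
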