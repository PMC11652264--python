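import numpy as np
import pytest

from twingrowth.errors import SpecError
from twingrowth import io as tio, simulate as sim
from twingrowth.growth import WAVES


class TestAceComponents:
    def test_mz_a_identical(self):
        rng = np.random.default_rng(1)
        A = np.array([[0.5]])
        comp = sim.simulate_ace_components(100, "MZ", A, A * 0.6, A * 0.4, rng)
        np.testing.assert_array_equal(comp["A1"], comp["A2"])

    def test_c_shared_everywhere(self):
        rng = np.random.default_rng(2)
        A = np.eye(2)
        comp = sim.simulate_ace_components(50, "DZss", A, A, A, rng)
        np.testing.assert_array_equal(comp["C1"], comp["C2"])

    def test_e_only_independence(self):
        rng = np.random.default_rng(3)
        Z = np.zeros((1, 1))
        comp = sim.simulate_ace_components(20000, "MZ", Z, Z, np.eye(1), rng)
        p1 = comp["E1"][:, 0]
        p2 = comp["E2"][:, 0]
        r = np.corrcoef(p1, p2)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(20000)

    def test_dz_cross_twin_covariance_closed_form(self):
        # univariate A=0.5, C=0.3, E=0.2 -> cross-twin cov 0.5*0.5+0.3 = 0.55
        rng = np.random.default_rng(4)
        n = 20000
        comp = sim.simulate_ace_components(
            n, "DZss", np.array([[0.5]]), np.array([[0.3]]),
            np.array([[0.2]]), rng)
        p1 = (comp["A1"] + comp["C1"] + comp["E1"])[:, 0]
        p2 = (comp["A2"] + comp["C2"] + comp["E2"])[:, 0]
        cov = np.cov(p1, p2)[0, 1]
        # var of a product-moment cov estimate ~ (v1*v2 + c^2)/n
        se = np.sqrt((1.0 * 1.0 + 0.55 ** 2) / n)
        assert abs(cov - 0.55) < 3 * se

    def test_non_psd_rejected_before_sampling(self):
        rng = np.random.default_rng(5)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(SpecError, match="positive semi-definite"):
            sim.simulate_ace_components(10, "MZ", bad, np.eye(2), np.eye(2), rng)


class TestSimulateDataset:
    def test_seed_determinism_on_disk(self, tmp_path):
        cfg = sim.default_config(n_mz=50, n_dzss=50, n_dzos=20, seed=9)
        cfg.missingness = sim.default_missingness()
        for name in ("a.csv", "b.csv"):
            ds, _ = sim.simulate_dataset(cfg)
            tio.write_twin_table(ds, tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_mz_pairs_same_sex_os_mixed(self):
        cfg = sim.default_config(n_mz=200, n_dzss=100, n_dzos=100, seed=1)
        ds, _ = sim.simulate_dataset(cfg)
        t = ds.table
        mz = t[t.zyg == "MZ"]
        assert (mz.sex_t1 == mz.sex_t2).all()
        os_ = t[t.zyg == "DZos"]
        assert (os_.sex_t1 != os_.sex_t2).all()

    def test_complete_when_no_missingness(self):
        cfg = sim.default_config(n_mz=100, n_dzss=100, seed=2)
        ds, _ = sim.simulate_dataset(cfg)
        cols = [f"{w}_t{t}" for w in WAVES for t in (1, 2)]
        assert not ds.table[cols].isna().any().any()

    def test_deterministic_chain_with_zero_noise(self):
        # E = C = residuals = 0: observed scores are exact linear maps of A draws
        cfg = sim.default_config(n_mz=30, n_dzss=0, seed=3)
        cfg.ace_c = np.zeros((8, 8))
        cfg.ace_e = np.zeros((8, 8))
        cfg.residual_vars = (1e-12,) * 12
        cfg.outcomes = {"audit_total": sim.OutcomeSpec(
            mean=0.0, direct_b=(1.0,) + (0.0,) * 7, ace_var=(0, 0, 0))}
        cfg.validate()
        ds, _ = sim.simulate_dataset(cfg)
        t = ds.table
        # MZ co-twins must then be bit-near-identical
        np.testing.assert_allclose(t["em_p4_t1"], t["em_p4_t2"], atol=1e-5)
        # outcome = em_ic factor = em_p4 observed (loading 1, zero residual)
        np.testing.assert_allclose(t["audit_total_t1"], t["em_p4_t1"], atol=1e-5)

    def test_mz_composite_correlation_exceeds_dz(self):
        cfg = sim.default_config(n_mz=4000, n_dzss=4000, seed=6)
        ds, truth = sim.simulate_dataset(cfg)
        t = ds.table

        def pair_corr(zyg, col):
            sub = t[t.zyg == zyg]
            return np.corrcoef(sub[f"{col}_t1"], sub[f"{col}_t2"])[0, 1]

        # age-9 parent report is a clean composite of intercept+slope factors
        assert pair_corr("MZ", "em_p9") > pair_corr("DZss", "em_p9") + 0.03

    def test_both_outcome_blocks_empty_rejected(self):
        with pytest.raises(SpecError, match="neither"):
            sim.OutcomeSpec(direct_b=(0.0,) * 8, ace_var=(0, 0, 0)).validate()


class TestImpliedMoments:
    def test_zero_loadings_limit(self):
        # zero out the factor signal: observed covariance = residual covariance
        cfg = sim.default_config(n_mz=10, n_dzss=10, seed=0)
        cfg.ace_a = np.zeros((8, 8))
        cfg.ace_c = np.zeros((8, 8))
        cfg.ace_e = np.eye(8) * 1e-12
        cols, mu, within, cmz, cdz = sim.implied_observed_moments(cfg)
        np.testing.assert_allclose(within[:12, :12], cfg.residual_cov(),
                                   atol=1e-10)

    def test_e_only_outcome_cross_twin_zero(self):
        cfg = sim.default_config(n_mz=10, n_dzss=10, seed=0)
        cfg.ace_a = np.zeros((8, 8))
        cfg.ace_c = np.zeros((8, 8))
        cfg.ace_e = np.eye(8)
        cfg.outcomes = {"audit_total": sim.OutcomeSpec(
            direct_b=(0.0,) * 8, ace_var=(0.0, 0.0, 1.0),
            cross_e=(0.2,) * 8)}
        cfg.validate()
        cols, mu, within, cmz, cdz = sim.implied_observed_moments(cfg)
        y = cols.index("audit_total")
        np.testing.assert_allclose(cmz[y], 0.0, atol=1e-12)
        np.testing.assert_allclose(cdz[y], 0.0, atol=1e-12)

    def test_empirical_moments_match_implied(self):
        # Monte-Carlo agreement of generated data with the analytic oracle
        n = 50000
        cfg = sim.default_config(n_mz=n // 2, n_dzss=n // 2, seed=13)
        ds, truth = sim.simulate_dataset(cfg)
        cols, mu, within, cmz, cdz = sim.implied_observed_moments(cfg)
        t = ds.table
        X = np.vstack([t[[f"{c}_t1" for c in cols]].to_numpy(float),
                       t[[f"{c}_t2" for c in cols]].to_numpy(float)])
        emp_mu = X.mean(axis=0)
        se_mu = np.sqrt(np.diag(within) / X.shape[0])
        assert np.all(np.abs(emp_mu - mu) < 4 * se_mu)
        emp_cov = np.cov(X, rowvar=False)
        v = np.diag(within)
        se_cov = np.sqrt((np.outer(v, v) + within ** 2) / X.shape[0])
        assert np.all(np.abs(emp_cov - within) < 4 * se_cov)
        # cross-twin blocks per zygosity
        for zyg, cross in (("MZ", cmz), ("DZss", cdz)):
            sub = t[t.zyg == zyg]
            X1 = sub[[f"{c}_t1" for c in cols]].to_numpy(float)
            X2 = sub[[f"{c}_t2" for c in cols]].to_numpy(float)
            nzy = len(sub)
            d1 = X1 - X1.mean(axis=0)
            d2 = X2 - X2.mean(axis=0)
            emp_cross = d1.T @ d2 / (nzy - 1)
            se_cross = np.sqrt((np.outer(v, v) + cross ** 2) / nzy)
            assert np.all(np.abs(emp_cross - cross) < 4.5 * se_cross)

    def test_manifest_psd_and_json(self, tmp_path):
        cfg = sim.default_config(n_mz=20, n_dzss=20, seed=5)
        _, truth = sim.simulate_dataset(cfg)
        W = np.array(truth.implied_within_cov)
        assert np.linalg.eigvalsh(W).min() > -1e-8
        truth.to_json(tmp_path / "truth.json")
        assert (tmp_path / "truth.json").stat().st_size > 100


class TestMARProperty:
    def test_missingness_independent_of_value_given_strata(self):
        # logistic regression of the missing flag on the *pre-deletion* value
        # within sex x SES strata: coefficient on the value ~ 0
        cfg = sim.default_config(n_mz=8000, n_dzss=8000, seed=21)
        cfg.missingness = {"em_s11": sim.MissingnessSpec(
            intercept=-0.5, b_sex=0.5, b_ses=-0.8)}
        rng_state = cfg.seed
        ds, _ = sim.simulate_dataset(cfg)
        cfg2 = sim.default_config(n_mz=8000, n_dzss=8000, seed=rng_state)
        ds_full, _ = sim.simulate_dataset(cfg2)   # same seed, no deletion
        miss = ds.table["em_s11_t1"].isna().to_numpy()
        value = ds_full.table["em_s11_t1"].to_numpy(float)
        male = (ds.table["sex_t1"] == "M").to_numpy(float)
        ses = ds.table["ses"].to_numpy(float)
        assert 0.05 < miss.mean() < 0.95
        import statsmodels.api as sm
        X = sm.add_constant(np.column_stack([male, ses, value]))
        res = sm.Logit(miss.astype(float), X).fit(disp=0)
        coef_value = res.params[3]
        se_value = res.bse[3]
        assert abs(coef_value) < 3 * se_value
        # while the SES driver is decisively detected
        assert abs(res.params[2] / res.bse[2]) > 5
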