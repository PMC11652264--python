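import numpy as np
import pandas as pd
import pytest

from twingrowth.errors import IdentificationError
from twingrowth import growth, simulate as sim, twin
from twingrowth.growth import FACTORS, WAVES, build_piecewise_lgc
from twingrowth.sem.fit import FitResult

from tests.conftest import make_ace_params


def oracle_pair_cov(p1: twin.AceParams, r: float,
                    p2: twin.AceParams | None = None) -> np.ndarray:
    """Independent oracle: explicit linear map of both twins' variables onto
    a stacked vector of independent standard-normal latent sources, then
    T T'. Shared genetic sources enter with weight sqrt(r) (plus twin-
    specific remainders with weight sqrt(1-r)), shared environment fully,
    nonshared environment per twin.
    """
    p2 = p2 or p1
    v = p1.v
    # source order: a_shared, a1, a2, c, e1, e2 (each v-dimensional)
    n_src = 6 * v

    def pre_structural(par, a_sh, a_own, c, e):
        # loading of each twin's pre-structural vector on the sources
        T = np.zeros((v, n_src))
        T[:, a_sh * v:(a_sh + 1) * v] += np.sqrt(r) * par.L_a
        T[:, a_own * v:(a_own + 1) * v] += np.sqrt(1 - r) * par.L_a
        T[:, c * v:(c + 1) * v] += par.L_c
        T[:, e * v:(e + 1) * v] += par.L_e
        return T

    def structural(par, T):
        B = np.zeros((v, v))
        B[v - 1, : v - 1] = par.b
        return np.linalg.solve(np.eye(v) - B, T)

    T1 = structural(p1, pre_structural(p1, 0, 1, 3, 4))
    T2 = structural(p2, pre_structural(p2, 0, 2, 3, 5))
    T = np.vstack([T1, T2])
    return T @ T.T


class TestImpliedPairCov:
    def test_univariate_closed_form(self):
        pars = twin.AceParams(
            np.array([[np.sqrt(0.5)]]), np.array([[np.sqrt(0.3)]]),
            np.array([[np.sqrt(0.2)]]), b=np.zeros(0), means=np.zeros(1))
        mz = twin.implied_pair_cov(pars, 1.0)
        dz = twin.implied_pair_cov(pars, 0.5)
        assert mz[0, 1] == pytest.approx(0.8)
        assert dz[0, 1] == pytest.approx(0.55)
        assert mz[0, 0] == pytest.approx(1.0)

    def test_e_only_direct_path_no_cross_transmission(self):
        # all influence on the predictor is nonshared: a direct path cannot
        # produce any cross-twin predictor-outcome covariance
        v = 2
        Le = np.eye(v) * np.sqrt(0.9)
        pars = twin.AceParams(np.zeros((v, v)), np.zeros((v, v)), Le,
                              b=np.array([0.7]), means=np.zeros(v))
        for r in (1.0, 0.5):
            S = twin.implied_pair_cov(pars, r)
            assert S[0, v + 1] == pytest.approx(0.0, abs=1e-12)  # P1 vs y2
            assert S[1, v] == pytest.approx(0.0, abs=1e-12)      # y1 vs P2

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_path_tracing_oracle_all_structures(self, k):
        rng = np.random.default_rng(10 + k)
        v = k + 1
        import itertools
        for rep in range(3):
            L = [np.tril(rng.normal(size=(v, v))) * 0.4 + 0.5 * np.eye(v)
                 for _ in range(3)]
            for rset in range(k + 1):
                for combo in itertools.combinations(range(k), rset):
                    b = np.zeros(k)
                    La, Lc, Le = (M.copy() for M in L)
                    for j in range(k):
                        if j in combo:
                            b[j] = rng.normal() * 0.5
                            La[v - 1, j] = Lc[v - 1, j] = Le[v - 1, j] = 0.0
                    pars = twin.AceParams(La, Lc, Le, b=b, means=np.zeros(v))
                    for r in (1.0, 0.5):
                        got = twin.implied_pair_cov(pars, r)
                        want = oracle_pair_cov(pars, r)
                        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_opposite_sex_oracle(self):
        pm = make_ace_params(b=(-0.3, 0.2))
        pf = make_ace_params(b=(-0.1, 0.2))
        got = twin.implied_pair_cov(pm, 0.5, pf)
        want = oracle_pair_cov(pm, 0.5, pf)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_mz_dominates_dz_elementwise_positive(self):
        pars = make_ace_params(b=(0.2, 0.3))
        mz = twin.implied_pair_cov(pars, 1.0)
        dz = twin.implied_pair_cov(pars, 0.5)
        v = pars.v
        cross_mz, cross_dz = mz[:v, v:], dz[:v, v:]
        pos = cross_mz > 0
        assert np.all(cross_mz[pos] >= cross_dz[pos] - 1e-12)


class TestFactorScores:
    def _truth_fit(self, theta_overrides=None):
        spec = build_piecewise_lgc()
        est = dict(zip(spec.free_labels, spec.start_vector()))
        cfg = sim.default_config(n_mz=10, n_dzss=10)
        total = cfg.ace_a + cfg.ace_c + cfg.ace_e
        for j, f in enumerate(FACTORS):
            est[f"mean_{f}"] = cfg.factor_means[j]
            est[f"psi_{f}_{f}"] = total[j, j]
            for j2 in range(j + 1, 8):
                est[f"psi_{f}_{FACTORS[j2]}"] = total[j, j2]
        for w in WAVES:
            est[f"res_{w}"] = 1e-6
        if theta_overrides:
            est.update(theta_overrides)
        theta = np.array([est[l] for l in spec.free_labels])
        return FitResult(model=spec, data=None, labels=spec.free_labels,
                         theta=theta, loglik=0.0, converged=True,
                         grad_norm=0.0, n_iter=0), cfg, total

    def test_noiseless_limit_reproduces_factors(self):
        fitres, cfg, total = self._truth_fit()
        rng = np.random.default_rng(3)
        n = 200
        eta = rng.multivariate_normal(cfg.factor_means, total, size=n)
        lam = growth.piecewise_loading_matrix()
        X = eta @ lam.T
        df = pd.DataFrame(X, columns=list(WAVES))
        scored = twin.compute_factor_scores(fitres, df)
        for j, f in enumerate(FACTORS):
            np.testing.assert_allclose(scored[f"fs_{f}"], eta[:, j], atol=1e-3)

    def test_formula_oracle_with_missing_pattern(self):
        fitres, cfg, total = self._truth_fit(
            {f"res_{w}": 0.8 for w in WAVES})
        row = {w: np.nan for w in WAVES}
        row.update({"em_p4": 3.0, "em_p7": 2.0, "cd_s11": 1.0, "cd_s16": 4.0})
        df = pd.DataFrame([row])
        scored = twin.compute_factor_scores(fitres, df)
        # hand evaluation of score = alpha + psi lam_o' sigma_o^-1 (y - mu_o)
        spec = fitres.model
        mu, sig = spec.implied_moments(fitres.theta, "all")
        mats = spec.materialize(fitres.theta, "all")
        obs = [list(WAVES).index(w) for w in
               ("em_p4", "em_p7", "cd_s11", "cd_s16")]
        y = np.array([3.0, 2.0, 1.0, 4.0])
        K = mats["psi"] @ mats["lam"][obs].T @ np.linalg.inv(
            sig[np.ix_(obs, obs)])
        want = mats["alpha"] + K @ (y - mu[obs])
        got = scored[[f"fs_{f}" for f in FACTORS]].iloc[0].to_numpy()
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_unscorable_trait_missing(self):
        fitres, *_ = self._truth_fit({f"res_{w}": 0.8 for w in WAVES})
        row = {w: np.nan for w in WAVES}
        row.update({"em_p4": 2.0})            # no conduct indicators at all
        scored = twin.compute_factor_scores(fitres, pd.DataFrame([row]))
        assert not np.isnan(scored["fs_em_ic"].iloc[0])
        assert np.isnan(scored["fs_cd_ic"].iloc[0])

    def test_score_truth_correlation_default_config(self):
        # reliability threshold fixed from the default configuration
        fitres, cfg, total = self._truth_fit(
            {f"res_{w}": 1.0 for w in WAVES})
        rng = np.random.default_rng(8)
        n = 8000
        eta = rng.multivariate_normal(cfg.factor_means, total, size=n)
        lam = growth.piecewise_loading_matrix()
        X = eta @ lam.T + rng.standard_normal((n, 12))
        scored = twin.compute_factor_scores(
            fitres, pd.DataFrame(X, columns=list(WAVES)))
        for f in ("em_ip", "cd_sa"):
            j = FACTORS.index(f)
            r = np.corrcoef(scored[f"fs_{f}"], eta[:, j])[0, 1]
            assert r > 0.7, (f, r)

    def test_residualize_on_sex(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "sex": rng.choice(["M", "F"], 500),
            "v": rng.normal(size=500)})
        df["v"] += 0.8 * (df["sex"] == "M")
        out = twin.residualize_on_sex(df, ["v"])
        male = (df["sex"] == "M").to_numpy(float)
        assert abs(np.corrcoef(out["v"], male)[0, 1]) < 1e-10


class TestFitAce:
    def test_recovery_direct_paths(self):
        pars = make_ace_params(b=(-0.08, 0.30))
        pair = twin.simulate_pair_data(pars, 4000, 4000, seed=1,
                                       var_names=["p1", "p2", "y"])
        st = twin.AceStructure.all_direct(("p1", "p2"), "y")
        res = twin.fit_ace(st, pair)
        assert res.converged
        V = res.vcov
        for lab, tv in (("b_p1", -0.08), ("b_p2", 0.30)):
            i = res.labels.index(lab)
            assert abs(res.theta[i] - tv) < 3 * np.sqrt(V[i, i])

    def test_standardized_shares_sum_to_one(self):
        pars = make_ace_params(b=(-0.2, 0.1))
        pair = twin.simulate_pair_data(pars, 1500, 1500, seed=2,
                                       var_names=["p1", "p2", "y"])
        st = twin.AceStructure.all_direct(("p1", "p2"), "y")
        res = twin.fit_ace(st, pair)
        sol = twin.standardized_solution(res)
        np.testing.assert_allclose(
            sol[["a2", "c2", "e2"]].sum(axis=1), 1.0, atol=1e-8)

    def test_direct_nested_in_cholesky(self):
        pars = make_ace_params(b=(0.25, -0.15))
        pair = twin.simulate_pair_data(pars, 1000, 1000, seed=3,
                                       var_names=["p1", "p2", "y"])
        ll_direct = twin.fit_ace(
            twin.AceStructure.all_direct(("p1", "p2"), "y"), pair).loglik
        ll_chol = twin.fit_ace(
            twin.AceStructure.cholesky(("p1", "p2"), "y"), pair).loglik
        assert ll_direct <= ll_chol + 1e-6

    def test_zero_a_boundary_pileup(self):
        pars = make_ace_params(shares=(0.0, 0.45, 0.55),
                               y_shares=(0.0, 0.4, 0.6))
        pair = twin.simulate_pair_data(pars, 1500, 1500, seed=4,
                                       var_names=["p1", "p2", "y"])
        st = twin.AceStructure.cholesky(("p1", "p2"), "y")
        res = twin.fit_ace(st, pair)
        sol = twin.standardized_solution(res).set_index("variable")
        assert (sol["a2"] < 0.08).all()
        assert any(lab.startswith("a_") for lab in res.boundary)

    def test_saturated_cholesky_reproduces_sample_cov(self):
        pars = make_ace_params(b=(0.0, 0.0), cross_a=(0.15, 0.0))
        pair = twin.simulate_pair_data(pars, 3000, 3000, seed=5,
                                       var_names=["p1", "p2", "y"])
        st = twin.AceStructure.cholesky(("p1", "p2"), "y")
        res = twin.fit_ace(st, pair)
        moms = res.model.moments(res.theta)
        for zyg in ("MZ", "DZ"):
            sub = pair[pair.zyg == ("MZ" if zyg == "MZ" else "DZss")]
            cols = [f"{v}_t1" for v in ("p1", "p2", "y")] + \
                   [f"{v}_t2" for v in ("p1", "p2", "y")]
            S = np.cov(sub[cols].to_numpy(float), rowvar=False)
            _, implied = moms[zyg]
            vdiag = np.diag(S)
            se = np.sqrt((np.outer(vdiag, vdiag) + S ** 2) / len(sub))
            assert np.all(np.abs(implied - S) < 4 * se)

    def test_single_zygosity_unidentified(self):
        pars = make_ace_params()
        pair = twin.simulate_pair_data(pars, 500, 500, seed=6,
                                       var_names=["p1", "p2", "y"])
        with pytest.raises(IdentificationError):
            twin.fit_ace(twin.AceStructure.cholesky(("p1", "p2"), "y"),
                         pair[pair.zyg == "MZ"])

    def test_missing_cotwin_allowed(self):
        pars = make_ace_params(b=(0.2, 0.1))
        pair = twin.simulate_pair_data(pars, 800, 800, seed=7,
                                       var_names=["p1", "p2", "y"])
        pair.loc[pair.index[:100], "y_t2"] = np.nan
        st = twin.AceStructure.all_direct(("p1", "p2"), "y")
        res = twin.fit_ace(st, pair)
        assert res.converged


class TestFullChainRecovery:
    def test_sign_and_magnitude_through_pipeline(self, small_long,
                                                 small_cohort):
        ds, truth, cfg = small_cohort
        gfit = growth.fit_growth(small_long)
        scored = twin.compute_factor_scores(gfit, small_long)
        keep = ["fs_em_ip", "fs_cd_sa", "audit_total"]
        scored = twin.residualize_on_sex(scored, keep)
        pair_df = twin.make_pair_table(scored, keep)
        st = twin.AceStructure.all_direct(("fs_em_ip", "fs_cd_sa"),
                                          "audit_total")
        res = twin.fit_ace(st, pair_df)
        b_true = np.asarray(cfg.outcomes["audit_total"].direct_b)
        b_ip = res.estimate("b_fs_em_ip")
        b_sa = res.estimate("b_fs_cd_sa")
        # attenuated by factor-score noise but sign-preserving
        assert np.sign(b_ip) == np.sign(b_true[FACTORS.index("em_ip")])
        assert np.sign(b_sa) == np.sign(b_true[FACTORS.index("cd_sa")])
        assert abs(b_sa) > 0.3 * abs(b_true[FACTORS.index("cd_sa")])
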