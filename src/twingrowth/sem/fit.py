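"""FIML estimation: optimization, information matrices, sandwich covariance."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from twingrowth.sem.fiml import PatternData
from twingrowth.sem.model import MomentModel

_BIG = 1e12


class SemData:
    """Per-group data with optional row-level cluster ids.

    ``data`` maps group label -> raw matrix (rows x modelled variables,
    NaN = missing) or a prebuilt :class:`PatternData`. ``clusters`` maps
    group label -> array of cluster ids aligned with the rows; clusters may
    span groups (ids are pooled when forming the sandwich meat).
    """

    def __init__(self, data: dict, clusters: dict | None = None):
        self.patterns: dict[str, PatternData] = {}
        for g, X in data.items():
            self.patterns[g] = X if isinstance(X, PatternData) else PatternData(
                np.asarray(X, dtype=float))
        self.clusters = clusters or {}
        self.n_rows = sum(p.n_rows for p in self.patterns.values())

    def group(self, g: str) -> PatternData:
        return self.patterns[g]


def total_loglik(model: MomentModel, data: SemData, theta) -> float:
    theta = np.asarray(theta, dtype=float)
    try:
        moms = model.moments(theta)
    except np.linalg.LinAlgError:
        return -np.inf
    total = 0.0
    for g, pat in data.patterns.items():
        mu, sig = moms[g]
        ll = pat.loglik(mu, sig)
        if not np.isfinite(ll):
            return -np.inf
        total += ll
    return total


def _moment_jacobian(model: MomentModel, theta, rel_step: float = 1e-6):
    """Jacobian of (mu_g, sigma_g) w.r.t. theta: analytic when the model
    provides one, central differences otherwise."""
    theta = np.asarray(theta, dtype=float)
    analytic = getattr(model, "moment_jacobian", None)
    if analytic is not None:
        jac = analytic(theta)
        if jac is not None:
            return jac
    k = theta.size
    base = model.moments(theta)
    jac = {g: (np.zeros((mu.size, k)), np.zeros((sig.shape[0], sig.shape[1], k)))
           for g, (mu, sig) in base.items()}
    for t in range(k):
        h = rel_step * max(1.0, abs(theta[t]))
        up, dn = theta.copy(), theta.copy()
        up[t] += h
        dn[t] -= h
        mom_up = model.moments(up)
        mom_dn = model.moments(dn)
        for g in base:
            dmu, dsig = jac[g]
            dmu[:, t] = (mom_up[g][0] - mom_dn[g][0]) / (2 * h)
            dsig[:, :, t] = (mom_up[g][1] - mom_dn[g][1]) / (2 * h)
    return jac


def gradient(model: MomentModel, data: SemData, theta) -> np.ndarray:
    """Gradient of the total FIML log-likelihood (chain rule through moments)."""
    theta = np.asarray(theta, dtype=float)
    jac = _moment_jacobian(model, theta)
    moms = model.moments(theta)
    g_out = np.zeros(theta.size)
    for g, pat in data.patterns.items():
        mu, sig = moms[g]
        gmu, gsig = pat.moment_gradient(mu, sig)
        dmu, dsig = jac[g]
        g_out += dmu.T @ gmu + np.einsum("ij,ijt->t", gsig, dsig)
    return g_out


def expected_information(model: MomentModel, data: SemData, theta) -> np.ndarray:
    """Fisher (expected) information at theta, summed over groups/patterns.

    Used to drive scoring iterations; the sandwich A-matrix uses the
    observed information instead.
    """
    theta = np.asarray(theta, dtype=float)
    jac = _moment_jacobian(model, theta)
    moms = model.moments(theta)
    k = theta.size
    H = np.zeros((k, k))
    for g, pat in data.patterns.items():
        mu, sig = moms[g]
        dmu, dsig = jac[g]
        for p in pat.patterns:
            so = sig[np.ix_(p.obs, p.obs)]
            sinv = np.linalg.inv(so)
            DM = dmu[p.obs, :]
            H += p.n * (DM.T @ sinv @ DM)
            T = dsig[np.ix_(p.obs, p.obs)]
            M = np.einsum("ab,bct->act", sinv, T)
            H += 0.5 * p.n * np.einsum("act,cas->ts", M, M)
    return 0.5 * (H + H.T)


def _fisher_scoring(model, data, theta0, bounds, *, maxiter=300, gtol=1e-5):
    """Expected-information Newton ascent with step halving and box clipping."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    th = np.clip(np.asarray(theta0, float), lo, hi)
    ll = total_loglik(model, data, th)
    if not np.isfinite(ll):
        return th, ll, 0, False
    it = 0
    for it in range(1, maxiter + 1):
        g = gradient(model, data, th)
        sg = _scaled_grad_norm(-g, th, -ll, bounds)
        if sg < gtol:
            return th, ll, it, True
        H = expected_information(model, data, th)
        ridge = 1e-8 * max(1.0, float(np.trace(H)) / max(H.shape[0], 1))
        try:
            step = np.linalg.solve(H + ridge * np.eye(H.shape[0]), g)
        except np.linalg.LinAlgError:
            step = g / np.maximum(np.diag(H), 1e-8)
        t, improved = 1.0, False
        while t > 1e-12:
            cand = np.clip(th + t * step, lo, hi)
            llc = total_loglik(model, data, cand)
            if np.isfinite(llc) and llc > ll + 1e-12:
                th, ll = cand, llc
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    g = gradient(model, data, th)
    sg = _scaled_grad_norm(-g, th, -ll, bounds)
    return th, ll, it, sg < gtol


def observed_information(model: MomentModel, data: SemData, theta,
                         rel_step: float = 1e-5) -> np.ndarray:
    """Negative Hessian of the total log-likelihood (central differences)."""
    theta = np.asarray(theta, dtype=float)
    k = theta.size
    H = np.zeros((k, k))
    for t in range(k):
        h = rel_step * max(1.0, abs(theta[t]))
        up, dn = theta.copy(), theta.copy()
        up[t] += h
        dn[t] -= h
        H[:, t] = (gradient(model, data, up) - gradient(model, data, dn)) / (2 * h)
    H = 0.5 * (H + H.T)
    return -H


@dataclass
class FitResult:
    """Estimates plus likelihood bookkeeping for one fitted model."""

    model: MomentModel
    data: SemData
    labels: list[str]
    theta: np.ndarray
    loglik: float
    converged: bool
    grad_norm: float
    n_iter: int
    message: str = ""
    boundary: list[str] = field(default_factory=list)
    n_starts_used: int = 1
    _vcov: np.ndarray | None = None
    _robust: np.ndarray | None = None
    _info: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def estimate(self, label: str) -> float:
        return float(self.theta[self.labels.index(label)])

    def estimates(self) -> dict[str, float]:
        return dict(zip(self.labels, self.theta))

    # -- covariance of the estimates ---------------------------------------

    def information(self) -> np.ndarray:
        if self._info is None:
            self._info = observed_information(self.model, self.data, self.theta)
        return self._info

    @property
    def vcov(self) -> np.ndarray:
        """Naive covariance: inverse observed information (pseudo-inverse)."""
        if self._vcov is None:
            V = np.linalg.pinv(self.information())
            self._vcov = _nearest_psd(0.5 * (V + V.T))
        return self._vcov

    def robust_vcov(self, clusters: dict | None = None) -> np.ndarray:
        if self._robust is None or clusters is not None:
            rb = cluster_robust_vcov(self, clusters)
            if clusters is not None:
                return rb
            self._robust = rb
        return self._robust

    def se(self, label: str, robust: bool = False) -> float:
        V = self.robust_vcov() if robust else self.vcov
        i = self.labels.index(label)
        return float(np.sqrt(max(V[i, i], 0.0)))

    def param_table(self, robust: bool = False) -> pd.DataFrame:
        V = self.robust_vcov() if robust else self.vcov
        se = np.sqrt(np.clip(np.diag(V), 0.0, None))
        z = np.divide(self.theta, se, out=np.full_like(self.theta, np.nan),
                      where=se > 0)
        from scipy.stats import norm
        p = 2 * norm.sf(np.abs(z))
        return pd.DataFrame({
            "label": self.labels, "estimate": self.theta, "se": se,
            "z": z, "p": p,
            "ci_lo": self.theta - 1.959963984540054 * se,
            "ci_hi": self.theta + 1.959963984540054 * se,
        })

    def to_json_dict(self) -> dict:
        return {
            "labels": self.labels,
            "estimates": [float(v) for v in self.theta],
            "loglik": float(self.loglik),
            "k": self.k,
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "grad_norm": float(self.grad_norm),
            "n_iter": int(self.n_iter),
            "boundary": list(self.boundary),
            "message": self.message,
        }


def _nearest_psd(V: np.ndarray) -> np.ndarray:
    w, Q = np.linalg.eigh(V)
    if w.min(initial=0.0) >= 0:
        return V
    return (Q * np.clip(w, 0.0, None)) @ Q.T


def _scaled_grad_norm(g, theta, f, bounds):
    """Inf-norm of the projected gradient, scaled by parameter and loglik size."""
    pg = g.copy()
    for i, (lo, hi) in enumerate(bounds):
        at_lo = np.isfinite(lo) and theta[i] - lo < 1e-9
        at_hi = np.isfinite(hi) and hi - theta[i] < 1e-9
        if (at_lo and pg[i] > 0) or (at_hi and pg[i] < 0):
            pg[i] = 0.0
    scale = np.maximum(1.0, np.abs(theta))
    return float(np.max(np.abs(pg * scale))) / max(1.0, abs(f))


def fit(model: MomentModel, data: SemData, *,
        start: np.ndarray | None = None,
        n_starts: int = 1,
        retry_on_failure: bool = True,
        seed: int | None = None,
        gtol: float = 1e-5,
        maxiter: int = 3000) -> FitResult:
    """Maximize the FIML log-likelihood with bounded quasi-Newton (L-BFGS-B).

    Convergence requires a finite optimum with scaled projected-gradient
    norm below ``gtol``. If the first start fails and ``retry_on_failure``
    is set, up to two jittered restarts are attempted; with ``n_starts > 1``
    that many jittered starts are always run and the best optimum kept.
    """
    labels = model.free_labels
    x0 = np.asarray(start, float) if start is not None else model.start_vector()
    bnds = model.bounds()
    lo = [b[0] for b in bnds]
    hi = [b[1] for b in bnds]
    x0 = np.clip(x0, lo, hi)
    rng = np.random.default_rng(seed)

    def fun(th):
        ll = total_loglik(model, data, th)
        if not np.isfinite(ll):
            return _BIG, np.zeros_like(th)
        return -ll, -gradient(model, data, th)

    def run_one(x_init):
        th, ll, nit, conv = _fisher_scoring(model, data, x_init, bnds,
                                            gtol=gtol, maxiter=min(maxiter, 300))
        msg = "fisher-scoring"
        if not conv:
            x_polish = th if np.isfinite(ll) else x_init
            res = minimize(fun, x_polish, jac=True, method="L-BFGS-B",
                           bounds=bnds, options={"maxiter": maxiter,
                                                 "ftol": 1e-13, "gtol": 1e-9,
                                                 "maxcor": 40})
            th = res.x
            ll = -res.fun if res.fun < _BIG / 2 else -np.inf
            nit += res.nit
            msg = f"fisher-scoring+lbfgsb: {res.message}"
        g = gradient(model, data, th) if np.isfinite(ll) else np.zeros_like(th)
        sg = _scaled_grad_norm(-g, th, -ll if np.isfinite(ll) else _BIG, bnds)
        conv = np.isfinite(ll) and sg < gtol
        return {"x": th, "f": -ll, "sg": sg, "converged": conv,
                "nit": nit, "msg": msg}

    def jittered():
        j = rng.normal(scale=0.2 * (1.0 + np.abs(x0)))
        return np.clip(x0 + j, lo, hi)

    best = None
    n_used = 0
    planned = [x0] + [jittered() for _ in range(max(n_starts - 1, 0))]
    retries_left = 2 if retry_on_failure else 0
    while planned:
        cand = run_one(planned.pop(0))
        n_used += 1
        if best is None or cand["f"] < best["f"] - 1e-10 or (
                cand["converged"] and not best["converged"]
                and cand["f"] < best["f"] + 1e-8):
            best = cand
        if not planned and not best["converged"] and retries_left > 0:
            planned.append(jittered())
            retries_left -= 1

    boundary = [labels[i] for i, (lo, hi) in enumerate(bnds)
                if np.isfinite(lo) and best["x"][i] - lo < 1e-7]
    return FitResult(
        model=model, data=data, labels=labels, theta=best["x"],
        loglik=-best["f"] if best["f"] < _BIG / 2 else -np.inf,
        converged=bool(best["converged"]), grad_norm=best["sg"],
        n_iter=int(best["nit"]), message=best["msg"], boundary=boundary,
        n_starts_used=n_used,
    )


def cluster_robust_vcov(fitres: FitResult, clusters: dict | None = None
                        ) -> np.ndarray:
    """Sandwich A^-1 B A^-1 over cluster-level score outer products.

    ``clusters`` maps group label -> per-row cluster ids; defaults to the
    ids stored on the fit's :class:`SemData` (rows lacking ids become
    singleton clusters).
    """
    model, data, theta = fitres.model, fitres.data, fitres.theta
    clusters = clusters if clusters is not None else data.clusters
    jac = _moment_jacobian(model, theta)
    moms = model.moments(theta)
    k = theta.size
    sums: dict = {}
    for g, pat in data.patterns.items():
        mu, sig = moms[g]
        rows, gmu, gsig = pat.row_moment_scores(mu, sig)
        dmu, dsig = jac[g]
        scores = gmu @ dmu + np.einsum("rij,ijt->rt", gsig, dsig)
        ids = clusters.get(g)
        for r, row_idx in enumerate(rows):
            cid = (g, int(row_idx)) if ids is None else ("c", ids[row_idx])
            if cid in sums:
                sums[cid] += scores[r]
            else:
                sums[cid] = scores[r].copy()
    n_clusters = len(sums)
    if n_clusters < k:
        warnings.warn(
            f"only {n_clusters} clusters for {k} free parameters; "
            "sandwich meat is rank deficient", stacklevel=2)
    B = np.zeros((k, k))
    for s in sums.values():
        B += np.outer(s, s)
    A_inv = np.linalg.pinv(fitres.information())
    V = A_inv @ B @ A_inv
    return _nearest_psd(0.5 * (V + V.T))
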