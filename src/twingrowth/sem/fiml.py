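"""Pattern-wise full-information maximum likelihood over missing data.

Rows are grouped by missingness pattern; each pattern stores sufficient
statistics (n, mean, centred scatter) so a likelihood evaluation costs
O(number of patterns), independent of the number of rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class Pattern:
    obs: np.ndarray          # indices of observed columns
    n: int
    mean: np.ndarray         # sample mean of observed subvector
    scatter: np.ndarray      # sum of (y - mean)(y - mean)'
    rows: np.ndarray         # row indices into the source matrix
    data: np.ndarray         # observed values, n x len(obs)


class PatternData:
    """Missing-data layout of one group's data matrix (NaN = missing)."""

    def __init__(self, X: np.ndarray, columns: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("data must be a 2-d array")
        self.n_rows, self.n_vars = X.shape
        self.columns = columns
        self.X = X
        obs_mask = ~np.isnan(X)
        self.patterns: list[Pattern] = []
        keys = {}
        for i in range(self.n_rows):
            key = obs_mask[i].tobytes()
            keys.setdefault(key, []).append(i)
        for key, rows in keys.items():
            mask = np.frombuffer(key, dtype=bool)
            obs = np.flatnonzero(mask)
            if obs.size == 0:
                continue                       # fully missing rows contribute 0
            rows = np.asarray(rows)
            sub = X[np.ix_(rows, obs)]
            m = sub.mean(axis=0)
            c = sub - m
            self.patterns.append(Pattern(obs, len(rows), m, c.T @ c, rows, sub))
        # deterministic order: by first row index
        self.patterns.sort(key=lambda p: p.rows[0])
        self.n_obs_values = int(obs_mask.sum())

    # -- likelihood ---------------------------------------------------------

    def loglik(self, mu: np.ndarray, sigma: np.ndarray) -> float:
        """FIML log-likelihood of all rows under N(mu, sigma).

        Returns -inf when any observed sub-covariance is not positive
        definite; never raises mid-optimization.
        """
        total = 0.0
        for p in self.patterns:
            so = sigma[np.ix_(p.obs, p.obs)]
            try:
                c, low = cho_factor(so, lower=True, check_finite=False)
            except np.linalg.LinAlgError:
                return -np.inf
            except ValueError:
                return -np.inf
            diag = np.diag(c)
            if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
                return -np.inf
            logdet = 2.0 * float(np.sum(np.log(diag)))
            d = p.mean - mu[p.obs]
            sinv_d = cho_solve((c, low), d, check_finite=False)
            tr = float(np.sum(cho_solve((c, low), p.scatter, check_finite=False)
                              .diagonal()))
            quad = p.n * float(d @ sinv_d)
            k = p.obs.size
            total += -0.5 * (p.n * k * _LOG2PI + p.n * logdet + tr + quad)
        return total

    def moment_gradient(self, mu, sigma):
        """Gradient of loglik w.r.t. the full mean vector and covariance.

        Covariance derivative uses the independent-entry convention, so a
        chain rule through d(sigma)/d(theta) as a full (symmetric) matrix
        inner product is exact.
        """
        g_mu = np.zeros(self.n_vars)
        g_sig = np.zeros((self.n_vars, self.n_vars))
        for p in self.patterns:
            so = sigma[np.ix_(p.obs, p.obs)]
            c, low = cho_factor(so, lower=True, check_finite=False)
            sinv = cho_solve((c, low), np.eye(p.obs.size), check_finite=False)
            d = p.mean - mu[p.obs]
            sinv_d = sinv @ d
            g_mu[p.obs] += p.n * sinv_d
            inner = p.scatter + p.n * np.outer(d, d)
            g_sig[np.ix_(p.obs, p.obs)] += 0.5 * (sinv @ inner @ sinv - p.n * sinv)
        return g_mu, g_sig

    def row_moment_scores(self, mu, sigma):
        """Per-row gradients in (mu, sigma) space for sandwich estimation.

        Returns ``(rows, g_mu, g_sig)`` with one entry per usable row:
        g_mu is (m, p) and g_sig is (m, p, p) with zeros off-pattern.
        """
        rows_all, gmu_all, gsig_all = [], [], []
        for p in self.patterns:
            so = sigma[np.ix_(p.obs, p.obs)]
            c, low = cho_factor(so, lower=True, check_finite=False)
            sinv = cho_solve((c, low), np.eye(p.obs.size), check_finite=False)
            dev = p.data - mu[p.obs]          # n x k
            sd = dev @ sinv                   # n x k
            gmu = np.zeros((p.n, self.n_vars))
            gmu[:, p.obs] = sd
            gsig = np.zeros((p.n, self.n_vars, self.n_vars))
            outer = 0.5 * (sd[:, :, None] * sd[:, None, :] - sinv[None, :, :])
            gsig[np.ix_(np.arange(p.n), p.obs, p.obs)] = outer
            rows_all.append(p.rows)
            gmu_all.append(gmu)
            gsig_all.append(gsig)
        if not rows_all:
            z = np.zeros((0, self.n_vars))
            return np.zeros(0, dtype=int), z, np.zeros((0, self.n_vars, self.n_vars))
        return (np.concatenate(rows_all), np.concatenate(gmu_all),
                np.concatenate(gsig_all))

    # -- saturated reference ------------------------------------------------

    def complete_case_moments(self):
        """Pooled pairwise-available mean and covariance (start-value heuristic)."""
        X = self.X
        mu = np.nanmean(X, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        dfX = np.where(np.isnan(X), np.nan, X - mu)
        cov = np.zeros((self.n_vars, self.n_vars))
        for i in range(self.n_vars):
            for j in range(i, self.n_vars):
                prod = dfX[:, i] * dfX[:, j]
                ok = ~np.isnan(prod)
                cov[i, j] = cov[j, i] = prod[ok].mean() if ok.any() else 0.0
        # guard against wildly non-PD pairwise estimates
        w, V = np.linalg.eigh(cov)
        floor = max(1e-6, 1e-6 * float(w.max(initial=1.0)))
        cov = (V * np.maximum(w, floor)) @ V.T
        return mu, cov


def fiml_loglik(mu, sigma, data) -> float:
    """Convenience wrapper: FIML log-likelihood of a raw data matrix."""
    if not isinstance(data, PatternData):
        data = PatternData(np.asarray(data, dtype=float))
    return data.loglik(np.asarray(mu, float), np.asarray(sigma, float))


def saturated_loglik(data: PatternData) -> float:
    """Closed-form maximum of the complete-data likelihood (ML, denominator n).

    Only valid when the data have no missing values.
    """
    if len(data.patterns) != 1 or data.patterns[0].obs.size != data.n_vars:
        raise ValueError("saturated closed form requires complete data")
    p = data.patterns[0]
    sig = p.scatter / p.n
    sign, logdet = np.linalg.slogdet(sig)
    if sign <= 0:
        raise ValueError("singular sample covariance")
    k = data.n_vars
    return -0.5 * p.n * (k * _LOG2PI + logdet + k)
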