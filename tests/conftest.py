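import numpy as np
import pandas as pd
import pytest

from twingrowth import simulate as sim
from twingrowth import twin


@pytest.fixture(scope="session")
def small_cohort():
    """Complete-data cohort used by several growth/twin tests."""
    cfg = sim.default_config(n_mz=800, n_dzss=800, seed=42)
    ds, truth = sim.simulate_dataset(cfg)
    return ds, truth, cfg


@pytest.fixture(scope="session")
def small_long(small_cohort):
    ds, truth, cfg = small_cohort
    return ds.to_individual_long()


def make_ace_params(b=(0.0, 0.0), shares=(0.5, 0.2, 0.3),
                    y_shares=(0.35, 0.10, 0.55), pred_corr=0.3,
                    cross_a=None, cross_c=None, cross_e=None,
                    means=None) -> twin.AceParams:
    """Standardized-scale twin generating parameters for k = 2 predictors."""
    R = np.array([[1.0, pred_corr], [pred_corr, 1.0]])
    v = 3

    def emb(L, own, cross):
        M = np.zeros((v, v))
        M[:2, :2] = L
        M[2, 2] = own
        if cross is not None:
            M[2, :2] = cross
        return M

    def safe_chol(M):
        return np.linalg.cholesky(M + 1e-14 * np.eye(len(M))) \
            if np.any(M) else np.zeros_like(M)

    La = safe_chol(shares[0] * R)
    Lc = safe_chol(shares[1] * R)
    Le = safe_chol(shares[2] * R)
    pars = twin.AceParams(
        emb(La, np.sqrt(y_shares[0]), cross_a),
        emb(Lc, np.sqrt(y_shares[1]), cross_c),
        emb(Le, np.sqrt(y_shares[2]), cross_e),
        b=np.asarray(b, float),
        means=np.zeros(3) if means is None else np.asarray(means, float))
    return pars
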