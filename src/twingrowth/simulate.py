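"""Synthetic twin cohorts with the statistical structure the analyses assume.

The generator draws ACE-decomposed latent growth factors (MZ genetic
correlation 1, DZ 0.5), maps them to observed waves through the piecewise
loading scheme, produces alcohol outcomes under direct phenotypic paths
and/or correlated ACE influences, and imposes MAR missingness driven by
sex and a simulated family-level SES covariate. Every run is reproducible
from (config, seed) and ships with a ground-truth manifest that includes
closed-form implied moments, the analytic oracle for all recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from twingrowth.errors import SpecError
from twingrowth.growth import (
    DEFAULT_ANCHORS,
    DEFAULT_WAVE_AGES,
    FACTORS,
    WAVES,
    piecewise_loading_matrix,
)
from twingrowth.io import DZOS, DZSS, FEMALE, MALE, MZ, TwinDataset, default_schema

N_FACTORS = 8
N_WAVES = 12


def _psd_check(name: str, M: np.ndarray, tol: float = 1e-8) -> None:
    M = np.asarray(M, float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-10):
        raise SpecError(f"{name} must be square symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() < -tol * max(1.0, w.max(initial=1.0)):
        raise SpecError(f"{name} is not positive semi-definite "
                        f"(min eigenvalue {w.min():.3g})")


@dataclass
class OutcomeSpec:
    """Generating model for one alcohol outcome.

    ``direct_b`` are raw regression weights of the outcome on the 8 growth
    factors (phenotypic transmission); ``cross_a/c/e`` are covariances of
    the outcome's own A/C/E component with the factors' A/C/E components
    (correlated-influence route). ``ace_var`` decomposes the outcome's own
    residual variance.
    """

    mean: float = 0.0
    direct_b: tuple = (0.0,) * N_FACTORS
    direct_b_male: tuple | None = None
    direct_b_female: tuple | None = None
    ace_var: tuple = (0.3, 0.1, 0.6)
    cross_a: tuple = (0.0,) * N_FACTORS
    cross_c: tuple = (0.0,) * N_FACTORS
    cross_e: tuple = (0.0,) * N_FACTORS
    sex_shift: float = 0.0

    def b_for_sex(self, sex: str) -> np.ndarray:
        if sex == MALE and self.direct_b_male is not None:
            return np.asarray(self.direct_b_male, float)
        if sex == FEMALE and self.direct_b_female is not None:
            return np.asarray(self.direct_b_female, float)
        return np.asarray(self.direct_b, float)

    def validate(self) -> None:
        if len(self.direct_b) != N_FACTORS:
            raise SpecError("direct_b must have 8 entries")
        if any(v < 0 for v in self.ace_var):
            raise SpecError("outcome ACE variances must be non-negative")
        has_direct = any(np.any(np.asarray(b) != 0) for b in
                         (self.direct_b, self.direct_b_male or (0,),
                          self.direct_b_female or (0,)))
        has_corr = any(np.any(np.asarray(v) != 0) for v in
                       (self.cross_a, self.cross_c, self.cross_e))
        if not has_direct and not has_corr and sum(self.ace_var) == 0:
            raise SpecError("outcome model has neither direct paths nor "
                            "correlated ACE influences nor residual variance")


@dataclass
class MissingnessSpec:
    """Per-column logistic missingness: logit p = intercept + b_sex*male + b_ses*ses."""

    intercept: float = -30.0     # effectively no missingness
    b_sex: float = 0.0
    b_ses: float = 0.0

    def prob(self, male: np.ndarray, ses: np.ndarray) -> np.ndarray:
        eta = self.intercept + self.b_sex * male + self.b_ses * ses
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class SimulationConfig:
    n_mz: int = 1000
    n_dzss: int = 1000
    n_dzos: int = 0
    factor_means: tuple = (2.1, -0.02, 3.0, -0.08, 2.1, -0.06, 2.2, -0.04)
    ace_a: np.ndarray | None = None      # 8x8; defaults built in __post_init__
    ace_c: np.ndarray | None = None
    ace_e: np.ndarray | None = None
    wave_ages: tuple = DEFAULT_WAVE_AGES
    anchors: tuple = DEFAULT_ANCHORS
    residual_vars: tuple = (1.0,) * N_WAVES
    residual_corr_cross_trait: float = 0.3
    residual_corr_parent_self9: float = 0.2
    outcomes: dict = field(default_factory=dict)
    factor_sex_shift: tuple = (0.0,) * N_FACTORS
    missingness: dict = field(default_factory=dict)   # column -> MissingnessSpec
    age_mean: float = 22.85
    age_sd: float = 0.88
    round_scores: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.ace_a is None or self.ace_c is None or self.ace_e is None:
            total = _default_factor_cov()
            self.ace_a = 0.5 * total
            self.ace_c = 0.2 * total
            self.ace_e = 0.3 * total
        self.ace_a = np.asarray(self.ace_a, float)
        self.ace_c = np.asarray(self.ace_c, float)
        self.ace_e = np.asarray(self.ace_e, float)
        if not self.outcomes:
            self.outcomes = {"audit_total": OutcomeSpec(
                mean=8.2, ace_var=(6.0, 1.5, 10.0))}
        self.validate()

    def validate(self) -> None:
        for name, M in (("A", self.ace_a), ("C", self.ace_c), ("E", self.ace_e)):
            if M.shape != (N_FACTORS, N_FACTORS):
                raise SpecError(f"{name} must be 8x8")
            _psd_check(name, M)
        tot = np.diag(self.ace_a + self.ace_c + self.ace_e)
        if np.any(tot <= 0):
            raise SpecError("every factor must have positive total variance")
        for o in self.outcomes.values():
            o.validate()
        _psd_check("residual covariance", self.residual_cov())
        for j, (ja, jc, je) in enumerate(self.joint_ace()):
            _psd_check(f"joint A (outcome block {j})", ja)
            _psd_check(f"joint C (outcome block {j})", jc)
            _psd_check(f"joint E (outcome block {j})", je)

    # -- derived structures -------------------------------------------------

    def residual_cov(self) -> np.ndarray:
        sd = np.sqrt(np.asarray(self.residual_vars, float))
        R = np.eye(N_WAVES)
        for w in range(6):
            R[w, 6 + w] = R[6 + w, w] = self.residual_corr_cross_trait
        for a, b in ((2, 3), (8, 9)):          # parent/self age-9, both traits
            R[a, b] = R[b, a] = self.residual_corr_parent_self9
        return R * np.outer(sd, sd)

    def joint_ace(self):
        """Per outcome: (A, C, E) over (8 factors + outcome own component)."""
        out = []
        for o in self.outcomes.values():
            blocks = []
            for M, cross, var in ((self.ace_a, o.cross_a, o.ace_var[0]),
                                  (self.ace_c, o.cross_c, o.ace_var[1]),
                                  (self.ace_e, o.cross_e, o.ace_var[2])):
                J = np.zeros((N_FACTORS + 1, N_FACTORS + 1))
                J[:N_FACTORS, :N_FACTORS] = M
                J[:N_FACTORS, -1] = J[-1, :N_FACTORS] = np.asarray(cross, float)
                J[-1, -1] = var
                blocks.append(J)
            out.append(tuple(blocks))
        return out

    def latent_dim(self) -> int:
        return N_FACTORS + len(self.outcomes)

    def stacked_ace(self):
        """A, C, E over (factors, outcome components...) with outcome own
        components mutually independent."""
        d = self.latent_dim()
        A = np.zeros((d, d))
        C = np.zeros((d, d))
        E = np.zeros((d, d))
        A[:N_FACTORS, :N_FACTORS] = self.ace_a
        C[:N_FACTORS, :N_FACTORS] = self.ace_c
        E[:N_FACTORS, :N_FACTORS] = self.ace_e
        for i, o in enumerate(self.outcomes.values()):
            j = N_FACTORS + i
            A[:N_FACTORS, j] = A[j, :N_FACTORS] = np.asarray(o.cross_a, float)
            C[:N_FACTORS, j] = C[j, :N_FACTORS] = np.asarray(o.cross_c, float)
            E[:N_FACTORS, j] = E[j, :N_FACTORS] = np.asarray(o.cross_e, float)
            A[j, j], C[j, j], E[j, j] = o.ace_var
        return A, C, E

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("ace_a", "ace_c", "ace_e"):
            d[key] = np.asarray(d[key]).tolist()
        d["outcomes"] = {k: asdict(v) for k, v in self.outcomes.items()}
        d["missingness"] = {k: asdict(v) for k, v in self.missingness.items()}
        return d


def _default_factor_cov() -> np.ndarray:
    """Compound-symmetric factor covariance (corr 0.3) at plausible scales."""
    sds = np.array([1.0, 0.15, 1.2, 0.2, 0.9, 0.15, 1.0, 0.18])
    R = np.full((N_FACTORS, N_FACTORS), 0.3)
    np.fill_diagonal(R, 1.0)
    return R * np.outer(sds, sds)


def default_config(**overrides) -> SimulationConfig:
    """Default cohort: one AUDIT-Total-like outcome with a direct path of
    standardized size -0.08 from the emotional preadolescence intercept and
    0.3 from the conduct adolescence slope."""
    cfg = SimulationConfig(**{k: v for k, v in overrides.items()
                              if k != "outcomes"})
    if "outcomes" in overrides:
        cfg.outcomes = overrides["outcomes"]
        cfg.validate()
        return cfg
    total = cfg.ace_a + cfg.ace_c + cfg.ace_e
    b = np.zeros(N_FACTORS)
    sd_y = 4.5
    b[FACTORS.index("em_ip")] = -0.08 * sd_y / np.sqrt(total[2, 2])
    b[FACTORS.index("cd_sa")] = 0.30 * sd_y / np.sqrt(total[7, 7])
    explained = float(b @ total @ b)
    resid = max(sd_y ** 2 - explained, 1.0)
    cfg.outcomes = {"audit_total": OutcomeSpec(
        mean=8.2, direct_b=tuple(b),
        ace_var=(0.35 * resid, 0.10 * resid, 0.55 * resid))}
    cfg.validate()
    return cfg


def default_missingness() -> dict:
    """Moderate MAR missingness on later waves and the outcome."""
    out = {}
    for w in WAVES:
        if w.endswith(("p9", "s9", "s11", "s16")):
            out[w] = MissingnessSpec(intercept=-1.3, b_sex=-0.3, b_ses=-0.4)
    out["audit_total"] = MissingnessSpec(intercept=-0.9, b_sex=0.4, b_ses=-0.5)
    return out


# ---------------------------------------------------------------------------
# component simulation
# ---------------------------------------------------------------------------

def simulate_ace_components(n_pairs: int, zygosity: str, A, C, E, rng):
    """Latent A/C/E component draws for both twins of ``n_pairs`` pairs.

    A components are identical within MZ pairs; for DZ pairs the co-twin's
    component is 0.5 * twin1 + sqrt(0.75) * an independent draw with the
    same covariance (exactly the conditional-normal construction for a
    within-pair genetic correlation of 0.5). C is shared, E independent.
    """
    A = np.asarray(A, float)
    C = np.asarray(C, float)
    E = np.asarray(E, float)
    for name, M in (("A", A), ("C", C), ("E", E)):
        _psd_check(name, M)
    d = A.shape[0]

    def draw(cov, n):
        w, V = np.linalg.eigh(cov)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        return rng.standard_normal((n, d)) @ L.T

    a1 = draw(A, n_pairs)
    if zygosity == MZ:
        a2 = a1.copy()
    elif zygosity in (DZSS, DZOS):
        a2 = 0.5 * a1 + np.sqrt(0.75) * draw(A, n_pairs)
    else:
        raise SpecError(f"unknown zygosity {zygosity!r}")
    c = draw(C, n_pairs)
    return {"A1": a1, "A2": a2, "C1": c, "C2": c.copy(),
            "E1": draw(E, n_pairs), "E2": draw(E, n_pairs)}


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthManifest:
    config: dict
    columns: list
    implied_mean: list
    implied_within_cov: list
    implied_cross_mz: list
    implied_cross_dz: list

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def implied_observed_moments(config: SimulationConfig):
    """Closed-form moments of the generated per-twin observed vector
    (12 waves then the outcomes, in configuration order), exact when sex
    effects are zero (the default).

    Returns ``(columns, mu, within_cov, cross_mz, cross_dz)``.
    """
    lam_w = piecewise_loading_matrix(config.wave_ages, config.anchors)
    A, C, E = config.stacked_ace()
    d = config.latent_dim()
    n_out = len(config.outcomes)
    p = N_WAVES + n_out
    M = np.zeros((p, d))
    M[:N_WAVES, :N_FACTORS] = lam_w
    mu = np.zeros(p)
    means = np.asarray(config.factor_means, float)
    mu[:N_WAVES] = lam_w @ means
    for i, (name, o) in enumerate(config.outcomes.items()):
        r = N_WAVES + i
        b = np.asarray(o.direct_b, float)
        M[r, :N_FACTORS] = b
        M[r, N_FACTORS + i] = 1.0
        mu[r] = o.mean + float(b @ means)
    T = A + C + E
    within = M @ T @ M.T
    within[:N_WAVES, :N_WAVES] += config.residual_cov()
    cross_mz = M @ (A + C) @ M.T
    cross_dz = M @ (0.5 * A + C) @ M.T
    columns = list(WAVES) + list(config.outcomes)
    return columns, mu, 0.5 * (within + within.T), \
        0.5 * (cross_mz + cross_mz.T), 0.5 * (cross_dz + cross_dz.T)


def simulate_dataset(config: SimulationConfig, seed: int | None = None):
    """Generate a wide twin table plus its ground-truth manifest.

    Identical (config, seed) yields identical output, including on-disk
    bytes when written through :func:`twingrowth.io.write_twin_table`.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lam_w = piecewise_loading_matrix(config.wave_ages, config.anchors)
    A, C, E = config.stacked_ace()
    res_cov = config.residual_cov()
    w_res, V_res = np.linalg.eigh(res_cov)
    L_res = V_res * np.sqrt(np.clip(w_res, 0.0, None))
    means = np.asarray(config.factor_means, float)
    shift = np.asarray(config.factor_sex_shift, float)
    out_names = list(config.outcomes)

    frames = []
    fam0 = 0
    for zyg, n in ((MZ, config.n_mz), (DZSS, config.n_dzss),
                   (DZOS, config.n_dzos)):
        if n == 0:
            continue
        comp = simulate_ace_components(n, zyg, A, C, E, rng)
        if zyg == DZOS:
            sex1 = np.full(n, MALE, dtype=object)
            sex2 = np.full(n, FEMALE, dtype=object)
        else:
            fam_sex = rng.random(n) < 0.5
            sex1 = np.where(fam_sex, MALE, FEMALE).astype(object)
            sex2 = sex1.copy()
        ses = rng.standard_normal(n)
        age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, None)
        cols = {"family_id": np.arange(fam0, fam0 + n), "zyg": zyg,
                "sex_t1": sex1, "sex_t2": sex2, "ses": ses}
        fam0 += n
        for t, (a, c, e, sex) in enumerate(
                ((comp["A1"], comp["C1"], comp["E1"], sex1),
                 (comp["A2"], comp["C2"], comp["E2"], sex2)), start=1):
            male = (sex == MALE).astype(float)
            latent = a + c + e
            eta = means + latent[:, :N_FACTORS] + np.outer(male, shift)
            waves = eta @ lam_w.T + rng.standard_normal((n, N_WAVES)) @ L_res.T
            if config.round_scores:
                waves = np.clip(np.round(waves), 0.0, 10.0)
            for wi, w in enumerate(WAVES):
                cols[f"{w}_t{t}"] = waves[:, wi]
            for oi, name in enumerate(out_names):
                o = config.outcomes[name]
                bmat = np.where(male[:, None] > 0,
                                o.b_for_sex(MALE), o.b_for_sex(FEMALE))
                y = (o.mean + o.sex_shift * male
                     + np.sum(bmat * eta, axis=1)
                     + latent[:, N_FACTORS + oi])
                cols[f"{name}_t{t}"] = y
            cols[f"age22_t{t}"] = age
        frames.append(pd.DataFrame(cols))
    if not frames:
        raise SpecError("no pairs requested")
    table = pd.concat(frames, ignore_index=True)

    # MAR missingness after generation
    for col, ms in config.missingness.items():
        for t in (1, 2):
            name = f"{col}_t{t}"
            if name not in table.columns:
                continue
            male = (table[f"sex_t{t}"] == MALE).to_numpy(float)
            pmis = ms.prob(male, table["ses"].to_numpy(float))
            drop = rng.random(len(table)) < pmis
            table.loc[drop, name] = np.nan

    columns, mu, within, cmz, cdz = implied_observed_moments(config)
    manifest = GroundTruthManifest(
        config=config.to_dict(), columns=columns,
        implied_mean=mu.tolist(), implied_within_cov=within.tolist(),
        implied_cross_mz=cmz.tolist(), implied_cross_dz=cdz.tolist())
    dataset = TwinDataset(table, default_schema())
    return dataset, manifest
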