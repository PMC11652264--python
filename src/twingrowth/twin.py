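"""Twin ACE model family: Cholesky correlated-factor, direct-path, hybrids.

Variables are factor scores of retained growth-factor predictors plus one
outcome, all sex-residualized. Each variable's variance decomposes into
additive-genetic (A), shared-environment (C) and nonshared-environment (E)
parts via triangular (Cholesky) factors; the outcome receives influence
from each predictor either through a direct phenotypic path or through
correlated A/C/E cross-loadings. MZ pairs share A fully, DZ pairs half; C
is fully shared and E never crosses twins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from twingrowth.errors import IdentificationError, SpecError, ValidationError
from twingrowth.growth import FACTORS, WAVES
from twingrowth.io import DZOS, DZSS, FEMALE, MALE, MZ
from twingrowth.sem.fit import FitResult, SemData, _moment_jacobian, fit
from twingrowth.sem.infer import lr_test, wald_equality
from twingrowth.sem.model import MomentModel, Parameter

COMPONENTS = ("a", "c", "e")


# ---------------------------------------------------------------------------
# structure and implied covariance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AceStructure:
    """Which predictors transmit via a direct path (the rest via correlated
    A/C/E cross-loadings to the outcome)."""

    predictors: tuple
    outcome: str
    direct: frozenset

    def __post_init__(self):
        if not set(self.direct) <= set(self.predictors):
            raise SpecError("direct set must be a subset of the predictors")

    @property
    def code(self) -> str:
        d = ",".join(p for p in self.predictors if p in self.direct) or "-"
        c = ",".join(p for p in self.predictors if p not in self.direct) or "-"
        return f"direct[{d}]|correlated[{c}]"

    @classmethod
    def cholesky(cls, predictors, outcome):
        return cls(tuple(predictors), outcome, frozenset())

    @classmethod
    def all_direct(cls, predictors, outcome):
        return cls(tuple(predictors), outcome, frozenset(predictors))


@dataclass
class AceParams:
    """Numeric parameter set for one sex: triangular component loadings over
    (predictors..., outcome) and direct paths b (zero where not in the
    direct set)."""

    L_a: np.ndarray
    L_c: np.ndarray
    L_e: np.ndarray
    b: np.ndarray          # length k, outcome row of the structural matrix
    means: np.ndarray      # length v

    @property
    def v(self) -> int:
        return self.L_a.shape[0]

    def component_cov(self, comp: str) -> np.ndarray:
        """(I-B)^-1 L L' (I-B)^-T for one component, i.e. the component's
        contribution to the within-person covariance including transmission
        through the direct paths."""
        L = {"a": self.L_a, "c": self.L_c, "e": self.L_e}[comp]
        inv = self._inv_imb()
        return inv @ (L @ L.T) @ inv.T

    def _inv_imb(self) -> np.ndarray:
        v = self.v
        B = np.zeros((v, v))
        B[v - 1, : v - 1] = self.b
        return np.linalg.solve(np.eye(v) - B, np.eye(v))


def implied_pair_cov(params1: AceParams, r: float,
                     params2: AceParams | None = None) -> np.ndarray:
    """2v x 2v covariance of a twin pair with genetic correlation ``r``.

    Cross-twin block carries r * A-implied + C-implied; E stays within
    twins. ``params2`` allows sex-specific parameters for opposite-sex
    pairs (twin 1 male, twin 2 female by convention).
    """
    p2 = params2 or params1
    inv1, inv2 = params1._inv_imb(), p2._inv_imb()
    A1 = params1.L_a @ params1.L_a.T
    C1 = params1.L_c @ params1.L_c.T
    A2 = p2.L_a @ p2.L_a.T
    C2 = p2.L_c @ p2.L_c.T
    # components are the same latent sources; cross-twin uses the geometric
    # pairing of the two twins' loadings
    La1, La2 = params1.L_a, p2.L_a
    Lc1, Lc2 = params1.L_c, p2.L_c
    within1 = inv1 @ (A1 + C1 + params1.L_e @ params1.L_e.T) @ inv1.T
    within2 = inv2 @ (A2 + C2 + p2.L_e @ p2.L_e.T) @ inv2.T
    cross = inv1 @ (r * (La1 @ La2.T) + Lc1 @ Lc2.T) @ inv2.T
    v = params1.v
    S = np.zeros((2 * v, 2 * v))
    S[:v, :v] = within1
    S[v:, v:] = within2
    S[:v, v:] = cross
    S[v:, :v] = cross.T
    return S


def simulate_pair_data(params: AceParams, n_mz: int, n_dz: int,
                       seed: int | None = None,
                       params_female: AceParams | None = None,
                       var_names: list[str] | None = None) -> pd.DataFrame:
    """Pair-level draws from the implied twin-pair distribution.

    With ``params_female`` given, pairs are split into the five sex-by-
    zygosity groups (DZ pairs half same-sex, half opposite-sex; twin 1
    male in opposite-sex pairs).
    """
    rng = np.random.default_rng(seed)
    v = params.v
    names = var_names or [f"v{i}" for i in range(v - 1)] + ["y"]

    def draw(cov, mu, n):
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(2 * v))
        return mu + rng.standard_normal((n, 2 * v)) @ L.T

    frames = []
    fam = 0

    def add(zyg, sex1, sex2, cov, mu, n):
        nonlocal fam
        if n == 0:
            return
        Z = draw(cov, mu, n)
        cols = {"family_id": np.arange(fam, fam + n), "zyg": zyg}
        fam += n
        for t, off in ((1, 0), (2, v)):
            for i, nm in enumerate(names):
                cols[f"{nm}_t{t}"] = Z[:, off + i]
        cols["sex_t1"], cols["sex_t2"] = sex1, sex2
        frames.append(pd.DataFrame(cols))

    if params_female is None:
        mu = np.concatenate([params.means, params.means])
        add(MZ, MALE, MALE, implied_pair_cov(params, 1.0), mu, n_mz)
        add(DZSS, MALE, MALE, implied_pair_cov(params, 0.5), mu, n_dz)
    else:
        pm, pf = params, params_female
        mu_m = np.concatenate([pm.means, pm.means])
        mu_f = np.concatenate([pf.means, pf.means])
        mu_os = np.concatenate([pm.means, pf.means])
        add(MZ, MALE, MALE, implied_pair_cov(pm, 1.0), mu_m, n_mz // 2)
        add(MZ, FEMALE, FEMALE, implied_pair_cov(pf, 1.0), mu_f,
            n_mz - n_mz // 2)
        n_ss = n_dz // 2
        add(DZSS, MALE, MALE, implied_pair_cov(pm, 0.5), mu_m, n_ss // 2)
        add(DZSS, FEMALE, FEMALE, implied_pair_cov(pf, 0.5), mu_f,
            n_ss - n_ss // 2)
        add(DZOS, MALE, FEMALE, implied_pair_cov(pm, 0.5, pf), mu_os,
            n_dz - n_ss)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# the fitted model
# ---------------------------------------------------------------------------

class AceModel(MomentModel):
    """Pair-level moment model for one :class:`AceStructure`.

    Standard mode fits two groups (MZ, pooled DZ). With
    ``sex_specific=True`` the direct paths are sex-indexed and five groups
    are used (MZ-M, MZ-F, DZss-M, DZss-F, DZos); A/C/E parameters stay
    equal across sexes (sex is residualized out upstream).
    """

    R = {"MZ": 1.0, "DZ": 0.5}

    def __init__(self, structure: AceStructure, *, sex_specific: bool = False,
                 start_cov: np.ndarray | None = None,
                 start_mean: np.ndarray | None = None,
                 start_b: dict | None = None):
        self.structure = structure
        self.sex_specific = sex_specific
        self.vars = list(structure.predictors) + [structure.outcome]
        self.v = len(self.vars)
        self._labels: list[str] = []
        self._params: dict[str, Parameter] = {}
        self._build_labels(start_cov, start_mean, start_b or {})

    # -- label table --------------------------------------------------------

    def _add(self, label, start=0.1, lower=-np.inf, upper=np.inf):
        self._labels.append(label)
        self._params[label] = Parameter(label, float(start), lower, upper)

    def _build_labels(self, start_cov, start_mean, start_b):
        v, S = self.v, start_cov
        for i, name in enumerate(self.vars):
            m0 = 0.0 if start_mean is None else float(start_mean[i])
            self._add(f"mean_{name}", m0)
        chol0 = None
        if S is not None:
            chol0 = np.linalg.cholesky(S / 3.0 + 1e-6 * np.eye(v))
        for comp in COMPONENTS:
            for i in range(v):
                for j in range(i + 1):
                    st = 0.3 if chol0 is None else chol0[i, j]
                    if i < v - 1 or j == v - 1:
                        # predictor block and the outcome's own loading
                        if i == j:
                            self._add(f"{comp}_{self.vars[i]}", max(st, 0.05),
                                      lower=0.0)
                        else:
                            self._add(f"{comp}_{self.vars[i]}_{self.vars[j]}", st)
                    else:
                        # outcome row, predictor column j
                        if self.vars[j] in self.structure.direct:
                            continue  # fixed 0: transmission is via b
                        self._add(f"{comp}_y_{self.vars[j]}", st)
        sexes = (MALE, FEMALE) if self.sex_specific else (None,)
        for p in self.structure.predictors:
            if p in self.structure.direct:
                for s in sexes:
                    lab = f"b_{p}" if s is None else f"b_{p}@{s}"
                    self._add(lab, float(start_b.get(p, 0.0)))

    @property
    def groups(self):
        if self.sex_specific:
            return ["MZ-M", "MZ-F", "DZ-M", "DZ-F", "DZ-OS"]
        return ["MZ", "DZ"]

    @property
    def free_labels(self):
        return list(self._labels)

    def parameter(self, label):
        return self._params[label]

    # -- evaluation ---------------------------------------------------------

    def params_for(self, theta, sex: str | None = None) -> AceParams:
        th = self.theta_dict(theta)
        v = self.v
        mats = {}
        for comp in COMPONENTS:
            L = np.zeros((v, v))
            for i in range(v):
                for j in range(i + 1):
                    if i == j:
                        L[i, i] = th[f"{comp}_{self.vars[i]}"]
                    elif i < v - 1:
                        L[i, j] = th[f"{comp}_{self.vars[i]}_{self.vars[j]}"]
                    elif self.vars[j] not in self.structure.direct:
                        L[i, j] = th[f"{comp}_y_{self.vars[j]}"]
            mats[comp] = L
        b = np.zeros(v - 1)
        for j, p in enumerate(self.structure.predictors):
            if p in self.structure.direct:
                lab = f"b_{p}" if not self.sex_specific else f"b_{p}@{sex}"
                b[j] = th[lab]
        means = np.array([th[f"mean_{n}"] for n in self.vars])
        return AceParams(mats["a"], mats["c"], mats["e"], b, means)

    def moments(self, theta):
        out = {}
        if not self.sex_specific:
            pars = self.params_for(theta)
            mu = np.concatenate([pars.means, pars.means])
            for g in self.groups:
                out[g] = (mu, implied_pair_cov(pars, self.R[g.split("-")[0]]))
            return out
        pm = self.params_for(theta, MALE)
        pf = self.params_for(theta, FEMALE)
        mu_mm = np.concatenate([pm.means, pm.means])
        for g in self.groups:
            zyg, sex = g.split("-")
            r = self.R[zyg]
            if sex == "OS":
                out[g] = (mu_mm, implied_pair_cov(pm, r, pf))
            else:
                pars = pm if sex == "M" else pf
                out[g] = (mu_mm, implied_pair_cov(pars, r))
        return out


# ---------------------------------------------------------------------------
# factor scores
# ---------------------------------------------------------------------------

def compute_factor_scores(growth_fit: FitResult, long_df: pd.DataFrame,
                          group_col: str | None = None) -> pd.DataFrame:
    """Regression-method factor scores from a fitted growth model.

    score = alpha + psi lam' sigma^-1 (y_obs - mu) over each row's observed
    sub-pattern; rows with no observed indicator for a trait get NaN for
    that trait's factors.
    """
    spec = growth_fit.model
    out = long_df.copy()
    score_cols = [f"fs_{f}" for f in FACTORS]
    for c in score_cols:
        out[c] = np.nan
    X = long_df[list(WAVES)].to_numpy(float)
    if group_col is not None:
        grp = long_df[group_col].astype(str).to_numpy()
    else:
        grp = np.full(len(long_df), spec.groups[0])
    for g in np.unique(grp):
        mu, sig = spec.implied_moments(growth_fit.theta, g)
        mats = spec.materialize(growth_fit.theta, g)
        lam, psi, alpha = mats["lam"], mats["psi"], mats["alpha"]
        rows = np.flatnonzero(grp == g)
        masks = ~np.isnan(X[rows])
        for key in {m.tobytes() for m in masks}:
            mask = np.frombuffer(key, dtype=bool)
            obs = np.flatnonzero(mask)
            sel = rows[np.flatnonzero((masks == mask).all(axis=1))]
            if obs.size == 0:
                continue
            K = psi @ lam[obs].T @ np.linalg.inv(sig[np.ix_(obs, obs)])
            dev = X[np.ix_(sel, obs)] - mu[obs]
            scores = alpha + dev @ K.T
            # a trait with no observed indicator is unscorable
            for ti, tcode in enumerate(("em", "cd")):
                has = np.any(lam[obs, 4 * ti:4 * ti + 4] != 0)
                cols_t = score_cols[4 * ti:4 * ti + 4]
                if has:
                    for fj, c in enumerate(cols_t):
                        out.loc[out.index[sel], c] = scores[:, 4 * ti + fj]
    return out


def residualize_on_sex(df: pd.DataFrame, columns: list[str],
                       sex_col: str = "sex") -> pd.DataFrame:
    """Regress a male indicator out of each column (complete pairs only)."""
    out = df.copy()
    male = (df[sex_col] == MALE).to_numpy(float)
    for c in columns:
        y = out[c].to_numpy(float)
        ok = ~np.isnan(y)
        if ok.sum() < 2 or np.ptp(male[ok]) == 0:
            out[c] = y - np.nanmean(y)
            continue
        Xd = np.column_stack([np.ones(ok.sum()), male[ok]])
        beta, *_ = np.linalg.lstsq(Xd, y[ok], rcond=None)
        res = np.full_like(y, np.nan)
        res[ok] = y[ok] - Xd @ beta
        out[c] = res
    return out


def make_pair_table(long_df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Pivot individual rows to pairs: <col>_t1/_t2 keyed by family."""
    need = ["family_id", "zyg", "twin"] + columns
    missing = [c for c in need if c not in long_df.columns]
    if missing:
        raise ValidationError(f"long table lacks columns {missing}")
    wide = long_df.pivot(index="family_id", columns="twin", values=columns)
    wide.columns = [f"{c}_t{t}" for c, t in wide.columns]
    meta_cols = ["family_id", "zyg"]
    if "sex" in long_df.columns:
        sx = long_df.pivot(index="family_id", columns="twin", values="sex")
        sx.columns = [f"sex_t{t}" for t in sx.columns]
        wide = wide.join(sx)
    meta = long_df[meta_cols].drop_duplicates("family_id").set_index("family_id")
    return meta.join(wide).reset_index()


def _pair_matrix(pair_df: pd.DataFrame, vars_: list[str]) -> np.ndarray:
    cols = [f"{v}_t1" for v in vars_] + [f"{v}_t2" for v in vars_]
    return pair_df[cols].to_numpy(float)


def _orient_os_male_first(pair_df: pd.DataFrame, vars_: list[str]) -> pd.DataFrame:
    """Ensure twin 1 is male within opposite-sex pairs (model convention)."""
    df = pair_df.copy()
    if "sex_t1" not in df.columns:
        return df
    flip = (df["zyg"] == DZOS) & (df["sex_t1"] == FEMALE)
    if flip.any():
        for v in list(vars_) + ["sex"]:
            c1, c2 = f"{v}_t1", f"{v}_t2"
            if c1 in df.columns and c2 in df.columns:
                df.loc[flip, [c1, c2]] = df.loc[flip, [c2, c1]].to_numpy()
    return df


def ace_sem_data(pair_df: pd.DataFrame, structure: AceStructure, *,
                 sex_specific: bool = False,
                 include_os: bool = True) -> SemData:
    """Group pair rows by zygosity (and sex for the 5-group mode)."""
    vars_ = list(structure.predictors) + [structure.outcome]
    df = _orient_os_male_first(pair_df, vars_)
    data = {}
    if not sex_specific:
        mz = df[df["zyg"] == MZ]
        dz_mask = df["zyg"].isin([DZSS, DZOS] if include_os else [DZSS])
        dz = df[dz_mask]
        if len(mz) == 0 or len(dz) == 0:
            raise IdentificationError(
                "both MZ and DZ pairs are required to separate A from C")
        data["MZ"] = _pair_matrix(mz, vars_)
        data["DZ"] = _pair_matrix(dz, vars_)
        return SemData(data)
    for g, sel in (
        ("MZ-M", (df["zyg"] == MZ) & (df["sex_t1"] == MALE)),
        ("MZ-F", (df["zyg"] == MZ) & (df["sex_t1"] == FEMALE)),
        ("DZ-M", (df["zyg"] == DZSS) & (df["sex_t1"] == MALE)),
        ("DZ-F", (df["zyg"] == DZSS) & (df["sex_t1"] == FEMALE)),
        ("DZ-OS", df["zyg"] == DZOS),
    ):
        sub = df[sel]
        if len(sub):
            data[g] = _pair_matrix(sub, vars_)
    return SemData(data)


def _check_identification(model: AceModel, data: SemData) -> None:
    """Local rank check of the moment Jacobian at the start values."""
    theta = model.start_vector()
    jac = _moment_jacobian(model, theta)
    blocks = []
    for g in data.patterns:
        dmu, dsig = jac[g]
        p = dmu.shape[0]
        iu = np.triu_indices(p)
        blocks.append(dmu)
        blocks.append(dsig[iu[0], iu[1], :])
    J = np.vstack(blocks)
    rank = np.linalg.matrix_rank(J, tol=1e-8)
    if rank < model.n_free:
        raise IdentificationError(
            f"structure locally unidentified: moment Jacobian rank {rank} "
            f"< {model.n_free} free parameters")


def fit_ace(structure: AceStructure, pair_df: pd.DataFrame, *,
            sex_specific: bool = False, include_os: bool = True,
            check_identification: bool = True, **fit_kwargs) -> FitResult:
    """FIML fit of one ACE structure over zygosity groups of twin pairs."""
    vars_ = list(structure.predictors) + [structure.outcome]
    data = ace_sem_data(pair_df, structure, sex_specific=sex_specific,
                        include_os=include_os)
    # moment-matched starts from the pooled within-person covariance
    persons = pd.concat([
        pair_df[[f"{v}_t{t}" for v in vars_]].set_axis(vars_, axis=1)
        for t in (1, 2)], ignore_index=True)
    S = np.cov(persons.dropna().to_numpy(float), rowvar=False)
    m0 = persons.mean().to_numpy(float)
    ols_b = {}
    comp_df = persons.dropna()
    if len(comp_df) > len(vars_) + 1 and structure.direct:
        Xd = np.column_stack([np.ones(len(comp_df))]
                             + [comp_df[p] for p in structure.predictors])
        coef, *_ = np.linalg.lstsq(Xd, comp_df[structure.outcome], rcond=None)
        for j, p in enumerate(structure.predictors, start=1):
            if p in structure.direct:
                ols_b[p] = coef[j]
    model = AceModel(structure, sex_specific=sex_specific,
                     start_cov=S, start_mean=m0, start_b=ols_b)
    if check_identification:
        _check_identification(model, data)
    return fit(model, data, **fit_kwargs)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardized_solution(fitres: FitResult, sex: str | None = None
                          ) -> pd.DataFrame:
    """Per-variable standardized variance shares and direct paths.

    Shares a2 + c2 + e2 = 1 for every variable (outcome shares include the
    variance transmitted through direct paths).
    """
    model: AceModel = fitres.model
    pars = model.params_for(fitres.theta,
                            sex if model.sex_specific else None)
    covs = {comp: pars.component_cov(comp) for comp in COMPONENTS}
    total = sum(covs.values())
    rows = []
    for i, name in enumerate(model.vars):
        tv = total[i, i]
        row = {"variable": name, "total_var": tv}
        for comp in COMPONENTS:
            row[f"{comp}2"] = covs[comp][i, i] / tv if tv > 0 else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    sd = np.sqrt(np.diag(total))
    for j, p in enumerate(model.structure.predictors):
        if p in model.structure.direct:
            df.loc[df["variable"] == p, "b_std"] = (
                pars.b[j] * sd[j] / sd[-1] if sd[-1] > 0 else np.nan)
    return df


# ---------------------------------------------------------------------------
# structure search and sex differences
# ---------------------------------------------------------------------------

@dataclass
class StructureSearchResult:
    table: pd.DataFrame
    selected: AceStructure
    selected_fit: FitResult
    fits: dict = field(default_factory=dict)
    excluded: dict = field(default_factory=dict)

    def delta_aic(self, code: str) -> float:
        row = self.table[self.table["code"] == code]
        return float(row["delta_aic_vs_cholesky"].iloc[0])


def structure_search(pair_df: pd.DataFrame, predictors, outcome: str, *,
                     include_os: bool = True, **fit_kwargs
                     ) -> StructureSearchResult:
    """AIC comparison of the Cholesky, all-direct, and hybrid structures.

    The all-direct model is accepted outright when it beats the Cholesky on
    AIC; otherwise the full lattice of direct/correlated assignments is
    fitted (exhaustive for the small predictor counts used here).
    Deterministic tie-break: lower AIC, then fewer parameters, then
    lexicographic structure code.
    """
    predictors = tuple(predictors)
    if len(predictors) < 1:
        raise SpecError("need at least one predictor")
    if len(predictors) > 4:
        raise SpecError("exhaustive hybrid search supports at most 4 predictors")
    chol = AceStructure.cholesky(predictors, outcome)
    direct = AceStructure.all_direct(predictors, outcome)
    fits: dict[str, tuple[AceStructure, FitResult]] = {}
    excluded: dict[str, str] = {}

    def try_fit(st: AceStructure):
        try:
            fr = fit_ace(st, pair_df, include_os=include_os, **fit_kwargs)
        except (IdentificationError, np.linalg.LinAlgError) as exc:
            excluded[st.code] = str(exc)
            return
        if not fr.converged:
            excluded[st.code] = f"non-convergence: {fr.message}"
            return
        fits[st.code] = (st, fr)

    try_fit(chol)
    try_fit(direct)
    chol_ok = chol.code in fits
    direct_best = (direct.code in fits and chol_ok
                   and fits[direct.code][1].aic <= fits[chol.code][1].aic)
    if not direct_best:
        for rset in range(1, len(predictors)):
            for combo in itertools.combinations(predictors, rset):
                st = AceStructure(predictors, outcome, frozenset(combo))
                try_fit(st)
    if not fits:
        raise SpecError("no candidate structure converged")
    ref_aic = fits[chol.code][1].aic if chol_ok else min(
        f.aic for _, f in fits.values())
    rows = []
    for code, (st, fr) in fits.items():
        rows.append({"code": code, "n_direct": len(st.direct), "k": fr.k,
                     "loglik": fr.loglik, "aic": fr.aic,
                     "delta_aic_vs_cholesky": fr.aic - ref_aic})
    table = pd.DataFrame(rows).sort_values(
        ["aic", "k", "code"], kind="stable").reset_index(drop=True)
    sel_code = table.iloc[0]["code"]
    st, fr = fits[sel_code]
    return StructureSearchResult(table, st, fr,
                                 fits={c: f for c, (s, f) in fits.items()},
                                 excluded=excluded)


@dataclass
class SexPathReport:
    table: pd.DataFrame
    joint_lr: tuple
    free_fit: FitResult | None
    equal_fit: FitResult | None


def sex_difference_direct_paths(structure: AceStructure,
                                pair_df: pd.DataFrame, *,
                                alpha: float = 0.05,
                                **fit_kwargs) -> SexPathReport:
    """Five-group refit with sex-indexed direct paths; tests whether each
    path (and all jointly, by likelihood ratio) can be equated across sexes."""
    if not structure.direct:
        return SexPathReport(pd.DataFrame(), (0.0, 0, 1.0), None, None)
    free = fit_ace(structure, pair_df, sex_specific=True,
                   check_identification=False, **fit_kwargs)
    # equal-b model: ordinary 2-group parameterization refitted on 5 groups
    # via tying the sex-indexed labels
    eq_model = AceModel(structure, sex_specific=True)
    tie = {}
    for p in structure.predictors:
        if p in structure.direct:
            tie[f"b_{p}"] = [f"b_{p}@{MALE}", f"b_{p}@{FEMALE}"]
    eq = _TiedAceModel(eq_model, tie)
    data = ace_sem_data(pair_df, structure, sex_specific=True)
    start = np.array([free.estimates().get(l.replace("b_", f"b_", 1), 0.1)
                      if not l.startswith("b_")
                      else np.mean([free.estimate(a) for a in tie.get(l, [l])])
                      for l in eq.free_labels])
    for i, l in enumerate(eq.free_labels):
        if l in free.labels:
            start[i] = free.estimate(l)
    eqfit = fit(eq, data, start=start, **fit_kwargs)
    joint = lr_test(eqfit, free, check_nesting=False)
    V = free.vcov
    rows = []
    for p in sorted(structure.direct):
        lm, lf = f"b_{p}@{MALE}", f"b_{p}@{FEMALE}"
        i, j = free.labels.index(lm), free.labels.index(lf)
        W, pw = wald_equality(free.theta[i], np.sqrt(max(V[i, i], 0)),
                              free.theta[j], np.sqrt(max(V[j, j], 0)),
                              V[i, j])
        rows.append({"path": p, "b_male": free.theta[i],
                     "b_female": free.theta[j], "W": W, "p": pw,
                     "equal_retained": pw >= alpha})
    return SexPathReport(pd.DataFrame(rows), joint, free, eqfit)


class _TiedAceModel(MomentModel):
    """AceModel with some labels tied together (equality constraints)."""

    def __init__(self, base: AceModel, ties: dict[str, list[str]]):
        self.base = base
        self.ties = ties
        atom_to_canon = {}
        for canon, atoms in ties.items():
            for a in atoms:
                atom_to_canon[a] = canon
        self._map = []          # base label -> canonical
        seen, labels = {}, []
        for l in base.free_labels:
            canon = atom_to_canon.get(l, l)
            if canon not in seen:
                seen[canon] = len(labels)
                labels.append(canon)
            self._map.append(seen[canon])
        self._labels = labels

    @property
    def groups(self):
        return self.base.groups

    @property
    def free_labels(self):
        return list(self._labels)

    def parameter(self, label):
        if label in self.ties:
            return self.base.parameter(self.ties[label][0])
        return self.base.parameter(label)

    def atoms(self):
        out = {l: {l} for l in self._labels}
        for canon, atom_list in self.ties.items():
            out[canon] = set(atom_list)
        return {k: frozenset(v) for k, v in out.items()}

    def moments(self, theta):
        theta = np.asarray(theta, float)
        full = theta[self._map]
        return self.base.moments(full)
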