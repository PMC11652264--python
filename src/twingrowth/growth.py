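"""Bivariate piecewise latent growth model and the phenotypic outcome analyses.

Two developmental segments per trait, knotted at age 9 where the rater
switches from parent to self report: a childhood intercept/slope pair over
the parent-report waves (ages 4, 7, 9) and a preadolescence intercept /
adolescence slope pair over the self-report waves (ages 9, 11, 16). Slope
loadings are wave age minus the segment anchor age, so the default loadings
are (0, 3, 5) and (0, 2, 7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from twingrowth.errors import SpecError, ValidationError
from twingrowth.sem.fit import FitResult, SemData, fit
from twingrowth.sem.infer import (
    ModificationLog,
    lr_test,
    modification_search,
    transfer_start,
    wald_equality,
)
from twingrowth.sem.model import Parameter, SemModelSpec

TRAIT_CODES = ("em", "cd")
WAVE_TEMPLATE = ("p4", "p7", "p9", "s9", "s11", "s16")
WAVES = tuple(f"{t}_{w}" for t in TRAIT_CODES for w in WAVE_TEMPLATE)
FACTORS = tuple(f"{t}_{f}" for t in TRAIT_CODES for f in ("ic", "sc", "ip", "sa"))
DEFAULT_WAVE_AGES = (4.0, 7.0, 9.0, 9.0, 11.0, 16.0)
DEFAULT_ANCHORS = (4.0, 9.0)


def piecewise_loading_matrix(wave_ages=DEFAULT_WAVE_AGES,
                             anchors=DEFAULT_ANCHORS) -> np.ndarray:
    """12 x 8 fixed loading matrix of the bivariate two-segment growth model."""
    wave_ages = tuple(float(a) for a in wave_ages)
    if len(wave_ages) != 6:
        raise SpecError("expected 6 wave ages (3 parent + 3 self)")
    a_child, a_adol = float(anchors[0]), float(anchors[1])
    if a_child not in wave_ages[:3] or a_adol not in wave_ages[3:]:
        raise SpecError(
            "each anchor must equal one wave age in its segment so the "
            "slope loadings include an exact zero")
    lam = np.zeros((12, 8))
    for ti, _ in enumerate(TRAIT_CODES):
        r0, f0 = 6 * ti, 4 * ti
        for w in range(3):                       # parent segment
            lam[r0 + w, f0 + 0] = 1.0
            lam[r0 + w, f0 + 1] = wave_ages[w] - a_child
        for w in range(3, 6):                    # self segment
            lam[r0 + w, f0 + 2] = 1.0
            lam[r0 + w, f0 + 3] = wave_ages[w] - a_adol
    return lam


def slope_loadings(wave_ages=DEFAULT_WAVE_AGES, anchors=DEFAULT_ANCHORS):
    """(childhood, adolescence) slope loading triples, e.g. (0,3,5)/(0,2,7)."""
    lam = piecewise_loading_matrix(wave_ages, anchors)
    return tuple(lam[0:3, 1]), tuple(lam[3:6, 3])


def _tag(groups):
    return (lambda lab, g: lab) if len(groups) == 1 else (
        lambda lab, g: f"{lab}@{g}")


def build_piecewise_lgc(wave_ages=DEFAULT_WAVE_AGES, anchors=DEFAULT_ANCHORS,
                        groups: list[str] | None = None) -> SemModelSpec:
    """Growth-only model: 12 observed waves, 8 latent factors, 63 parameters.

    Free parameters per group: 8 factor means, 36 factor (co)variances,
    12 residual variances, 6 cross-trait same-occasion residual covariances
    and 1 shared parent-self age-9 residual covariance (tied across traits).
    """
    groups = list(groups) if groups else ["all"]
    spec = SemModelSpec(list(WAVES), list(FACTORS), groups)
    lam = piecewise_loading_matrix(wave_ages, anchors)
    tag = _tag(groups)
    for g in groups:
        for i in range(12):
            for j in range(8):
                if lam[i, j] != 0.0:
                    spec.set_entry(g, "lam", (i, j), lam[i, j])
        for j, f in enumerate(FACTORS):
            lab = tag(f"mean_{f}", g)
            spec.set_entry(g, "alpha", j, lab)
            spec.set_param(lab, start=2.0 if f.endswith(("ic", "ip")) else 0.0)
        for j, f in enumerate(FACTORS):
            lab = tag(f"psi_{f}_{f}", g)
            spec.set_entry(g, "psi", (j, j), lab)
            spec.set_param(lab, start=0.5 if f.endswith(("ic", "ip")) else 0.05,
                           lower=0.0)
            for j2 in range(j + 1, 8):
                lab = tag(f"psi_{f}_{FACTORS[j2]}", g)
                spec.set_entry(g, "psi", (j, j2), lab)
                spec.set_param(lab, start=0.0)
        for i, w in enumerate(WAVES):
            lab = tag(f"res_{w}", g)
            spec.set_entry(g, "theta", (i, i), lab)
            spec.set_param(lab, start=1.0, lower=0.0)
        for wi, w in enumerate(WAVE_TEMPLATE):
            lab = tag(f"rescov_em_cd_{w}", g)
            spec.set_entry(g, "theta", (wi, 6 + wi), lab)
            spec.set_param(lab, start=0.0)
        # one tied parent-self age-9 residual covariance across both traits
        lab = tag("rescov_p9_s9", g)
        spec.set_entry(g, "theta", (WAVES.index("em_p9"), WAVES.index("em_s9")), lab)
        spec.set_entry(g, "theta", (WAVES.index("cd_p9"), WAVES.index("cd_s9")), lab)
        spec.set_param(lab, start=0.0)
    return spec


def build_outcome_spec(outcome: str, covariates: list[str] | None = None,
                       wave_ages=DEFAULT_WAVE_AGES, anchors=DEFAULT_ANCHORS,
                       groups: list[str] | None = None) -> SemModelSpec:
    """Growth model plus a simultaneous regression of the outcome on all
    8 factors and the covariates (covariates correlate freely with the
    factors and each other, serving as FIML auxiliary correlates)."""
    groups = list(groups) if groups else ["all"]
    covariates = list(covariates or [])
    observed = list(WAVES) + [outcome] + covariates
    latent = list(FACTORS) + [f"x_{c}" for c in covariates]
    spec = SemModelSpec(observed, latent, groups)
    base = build_piecewise_lgc(wave_ages, anchors, groups)
    for lab, par in base.params.items():
        spec.params[lab] = Parameter(lab, par.start, par.lower, par.upper)
    tag = _tag(groups)
    y = len(WAVES)
    for g in groups:
        # copy the growth block
        for mat in ("lam", "psi", "theta", "alpha"):
            src = base.mats[g][mat]
            dst = spec.mats[g][mat]
            if mat in ("lam",):
                dst[:12, :8] = src
            elif mat in ("psi", "theta"):
                dst[: src.shape[0], : src.shape[1]] = src
            else:
                dst[: src.shape[0]] = src
        # outcome regression
        for j, f in enumerate(FACTORS):
            lab = tag(f"b_{f}", g)
            spec.set_entry(g, "lam", (y, j), lab)
            spec.set_param(lab, start=0.0)
        for ci, c in enumerate(covariates):
            lj = 8 + ci
            oi = y + 1 + ci
            spec.set_entry(g, "lam", (oi, lj), 1.0)
            spec.set_entry(g, "theta", (oi, oi), 0.0)
            lab = tag(f"mean_x_{c}", g)
            spec.set_entry(g, "alpha", lj, lab)
            spec.set_param(lab, start=0.0)
            lab = tag(f"psi_x_{c}_x_{c}", g)
            spec.set_entry(g, "psi", (lj, lj), lab)
            spec.set_param(lab, start=1.0, lower=0.0)
            for j, f in enumerate(FACTORS):
                lab = tag(f"psi_x_{c}_{f}", g)
                spec.set_entry(g, "psi", (lj, j), lab)
                spec.set_param(lab, start=0.0)
            for ci2 in range(ci + 1, len(covariates)):
                lab = tag(f"psi_x_{c}_x_{covariates[ci2]}", g)
                spec.set_entry(g, "psi", (lj, 8 + ci2), lab)
                spec.set_param(lab, start=0.0)
            lab = tag(f"g_{c}", g)
            spec.set_entry(g, "lam", (y, lj), lab)
            spec.set_param(lab, start=0.0)
        lab = tag(f"int_{outcome}", g)
        spec.set_entry(g, "nu", y, lab)
        spec.set_param(lab, start=0.0)
        lab = tag(f"resvar_{outcome}", g)
        spec.set_entry(g, "theta", (y, y), lab)
        spec.set_param(lab, start=1.0, lower=0.0)
    return spec


# ---------------------------------------------------------------------------
# data preparation and start values
# ---------------------------------------------------------------------------

def long_to_matrix(long_df: pd.DataFrame, columns: list[str]):
    missing = [c for c in columns if c not in long_df.columns]
    if missing:
        raise ValidationError(f"missing columns in long table: {missing}")
    return long_df[columns].to_numpy(dtype=float)


def make_sem_data(long_df: pd.DataFrame, columns: list[str],
                  group_col: str | None = None,
                  cluster_col: str = "family_id") -> SemData:
    """Individual-level rows -> per-group pattern data with family clusters."""
    if group_col is None:
        X = long_to_matrix(long_df, columns)
        clusters = {"all": long_df[cluster_col].to_numpy()} \
            if cluster_col in long_df.columns else None
        return SemData({"all": X}, clusters)
    data, clusters = {}, {}
    for g, sub in long_df.groupby(group_col, sort=True):
        data[str(g)] = long_to_matrix(sub, columns)
        if cluster_col in sub.columns:
            clusters[str(g)] = sub[cluster_col].to_numpy()
    return SemData(data, clusters or None)


def moment_matched_start(spec: SemModelSpec, data: SemData) -> np.ndarray:
    """Start values from pooled pairwise moments: factor means by least
    squares through the loadings, variances from a rough decomposition."""
    start = spec.start_vector()
    idx = {l: i for i, l in enumerate(spec.free_labels)}
    for g in spec.groups:
        pat = data.patterns.get(g)
        if pat is None:
            continue
        mu, cov = pat.complete_case_moments()
        mats = spec.materialize(spec.start_vector(), g)
        lam = mats["lam"]
        used = [j for j in range(lam.shape[1]) if np.any(lam[:, j] != 0)]
        sol, *_ = np.linalg.lstsq(lam[:, used], mu - mats["nu"].astype(float),
                                  rcond=None)
        alpha_template = spec.mats[g]["alpha"]
        for pos, j in enumerate(used):
            lab = alpha_template[j]
            if isinstance(lab, str):
                idx_l = idx.get(spec.canonical(lab))
                if idx_l is not None:
                    start[idx_l] = sol[pos]
        theta_template = spec.mats[g]["theta"]
        for i in range(theta_template.shape[0]):
            lab = theta_template[i, i]
            if isinstance(lab, str):
                idx_l = idx.get(spec.canonical(lab))
                if idx_l is not None:
                    start[idx_l] = max(0.4 * cov[i, i], 1e-3)
        psi_template = spec.mats[g]["psi"]
        for j in range(psi_template.shape[0]):
            lab = psi_template[j, j]
            if isinstance(lab, str) and np.any(lam[:, j] == 1.0):
                anchor = int(np.argmax(lam[:, j] == 1.0))
                idx_l = idx.get(spec.canonical(lab))
                if idx_l is not None:
                    start[idx_l] = max(0.5 * cov[anchor, anchor], 1e-3)
    return start


def fit_growth(long_df: pd.DataFrame, wave_ages=DEFAULT_WAVE_AGES,
               anchors=DEFAULT_ANCHORS, group_col: str | None = None,
               **fit_kwargs) -> FitResult:
    groups = sorted(long_df[group_col].astype(str).unique()) if group_col else None
    spec = build_piecewise_lgc(wave_ages, anchors, groups)
    data = make_sem_data(long_df, list(WAVES), group_col=group_col)
    start = moment_matched_start(spec, data)
    return fit(spec, data, start=start, **fit_kwargs)


# ---------------------------------------------------------------------------
# covariance pruning (growth model)
# ---------------------------------------------------------------------------

@dataclass
class PruneResult:
    spec: SemModelSpec
    fit: FitResult
    pruned: list[str]
    restored: list[str]
    lr: tuple


def prune_nonsignificant_covariances(full_fit: FitResult, data: SemData, *,
                                     alpha: float = 0.05, robust: bool = True,
                                     fit_kwargs: dict | None = None) -> PruneResult:
    """Fix nonsignificant covariances to zero, keeping the reduction only if
    it does not significantly worsen fit; otherwise restore covariances one
    at a time by largest chi-square gain until it does not."""
    fit_kwargs = fit_kwargs or {}
    spec = full_fit.model
    if not isinstance(spec, SemModelSpec):
        raise SpecError("pruning requires a SemModelSpec-based fit")
    cand = [l for l in full_fit.labels
            if l.split("@")[0].startswith(("psi_", "rescov_"))
            and not _is_variance_label(l)]
    V = full_fit.robust_vcov() if robust else full_fit.vcov
    z = {}
    for l in cand:
        i = full_fit.labels.index(l)
        se = np.sqrt(max(V[i, i], 0.0))
        z[l] = abs(full_fit.theta[i]) / se if se > 0 else np.inf
    from scipy.stats import norm
    zcrit = norm.isf(alpha / 2)
    to_prune = sorted(l for l in cand if z[l] < zcrit)
    if not to_prune:
        return PruneResult(spec, full_fit, [], [], (0.0, 0, 1.0))
    pruned_spec = spec.fix(_expand_atoms(spec, to_prune), 0.0)
    pf = fit(pruned_spec, data, start=transfer_start(pruned_spec, full_fit),
             **fit_kwargs)
    restored: list[str] = []
    current_spec, current_fit = pruned_spec, pf
    remaining = list(to_prune)
    while True:
        stat = lr_test(current_fit, full_fit, check_nesting=False)
        if stat[2] >= alpha or not remaining:
            break
        gains, fits = {}, {}
        for l in remaining:
            trial_spec = spec.fix(_expand_atoms(
                spec, [x for x in remaining if x != l] ), 0.0)
            tf = fit(trial_spec, data,
                     start=transfer_start(trial_spec, full_fit), **fit_kwargs)
            gains[l] = tf.loglik - current_fit.loglik
            fits[l] = (trial_spec, tf)
        best = max(remaining, key=lambda l: (gains[l], -remaining.index(l)))
        restored.append(best)
        remaining.remove(best)
        current_spec, current_fit = fits[best]
    return PruneResult(current_spec, current_fit, remaining, restored,
                       lr_test(current_fit, full_fit, check_nesting=False))


def _is_variance_label(label: str) -> bool:
    stem = label.split("@")[0]
    if stem.startswith("psi_"):
        body = stem[4:]
        half = len(body) // 2
        return body[:half] == body[half + 1:]
    return False


def _expand_atoms(spec: SemModelSpec, canon_labels: list[str]) -> list[str]:
    atoms = spec.atoms()
    out = []
    for l in canon_labels:
        out.extend(sorted(atoms.get(l, {l})))
    return out


# ---------------------------------------------------------------------------
# outcome regression
# ---------------------------------------------------------------------------

@dataclass
class OutcomeFit:
    outcome: str
    covariates: list[str]
    spec: SemModelSpec
    fit: FitResult
    betas: pd.DataFrame          # raw + standardized with robust 95% CIs


def standardized_betas(fitres: FitResult, outcome: str,
                       covariates: list[str] | None = None,
                       group: str | None = None,
                       robust: bool = True) -> pd.DataFrame:
    """Standardize outcome paths: beta_std = beta_raw * sd(pred) / sd(outcome),
    using the model-implied (within-group) standard deviations."""
    spec = fitres.model
    covariates = covariates or []
    groups = [group] if group else spec.groups
    V = fitres.robust_vcov() if robust else fitres.vcov
    rows = []
    for g in groups:
        mu, sig = spec.implied_moments(fitres.theta, g)
        mats = spec.materialize(fitres.theta, g)
        psi = mats["psi"]
        y = spec.var_index(outcome)
        sd_y = float(np.sqrt(sig[y, y]))
        preds = [(f, j, f"b_{f}") for j, f in enumerate(FACTORS)] + [
            (c, 8 + ci, f"g_{c}") for ci, c in enumerate(covariates)]
        for name, j, stem in preds:
            lab = stem if len(spec.groups) == 1 else f"{stem}@{g}"
            canon = spec.canonical(lab)
            if canon not in fitres.labels:
                continue
            i = fitres.labels.index(canon)
            raw = float(fitres.theta[i])
            se = float(np.sqrt(max(V[i, i], 0.0)))
            sd_p = float(np.sqrt(max(psi[j, j], 0.0)))
            scale = sd_p / sd_y if sd_y > 0 else np.nan
            rows.append({
                "group": g, "predictor": name, "label": canon,
                "beta_raw": raw, "se_raw": se,
                "beta_std": raw * scale,
                "ci_lo_std": (raw - 1.96 * se) * scale,
                "ci_hi_std": (raw + 1.96 * se) * scale,
            })
    return pd.DataFrame(rows)


def fit_outcome_model(long_df: pd.DataFrame, outcome: str,
                      covariates: list[str] | None = None,
                      wave_ages=DEFAULT_WAVE_AGES, anchors=DEFAULT_ANCHORS,
                      group_col: str | None = None,
                      **fit_kwargs) -> OutcomeFit:
    """Joint one-step growth + outcome regression with family-cluster SEs."""
    covariates = list(covariates or [])
    if long_df[outcome].notna().sum() == 0:
        raise ValidationError(f"outcome column {outcome!r} is entirely missing")
    groups = sorted(long_df[group_col].astype(str).unique()) if group_col else None
    spec = build_outcome_spec(outcome, covariates, wave_ages, anchors, groups)
    cols = list(WAVES) + [outcome] + covariates
    data = make_sem_data(long_df, cols, group_col=group_col)
    start = moment_matched_start(spec, data)
    res = fit(spec, data, start=start, **fit_kwargs)
    betas = standardized_betas(res, outcome, covariates)
    return OutcomeFit(outcome, covariates, spec, res, betas)


# ---------------------------------------------------------------------------
# ordered multi-group sex-difference pipeline
# ---------------------------------------------------------------------------

STEP_NAMES = (
    "covariate_structure",
    "factor_means",
    "factor_variances",
    "factor_covariances",
    "residual_variances_and_covariances",
)


@dataclass
class SexStepReport:
    name: str
    constrained: list[str]
    delta_chi2: float
    df: int
    p: float
    freed: list[str]
    accepted: bool


@dataclass
class SexDifferenceReport:
    steps: list[SexStepReport]
    wald: pd.DataFrame
    equated_coefficients: list[str]
    intercept_residual_equated: bool
    intercept_residual_lr: tuple
    final_fit: FitResult

    def to_json_dict(self) -> dict:
        return {
            "steps": [{
                "name": s.name, "constrained": s.constrained,
                "delta_chi2": s.delta_chi2, "df": s.df, "p": s.p,
                "freed": s.freed, "accepted": s.accepted,
            } for s in self.steps],
            "wald": self.wald.to_dict(orient="records"),
            "equated_coefficients": self.equated_coefficients,
            "intercept_residual_equated": self.intercept_residual_equated,
            "intercept_residual_lr": list(self.intercept_residual_lr),
        }


def _step_label_stems(spec: SemModelSpec, outcome: str,
                      covariates: list[str]) -> dict[str, list[str]]:
    stems = {l.split("@")[0] for l in (spec.params)}
    cov_stems = sorted(
        s for s in stems
        if (s.startswith(("mean_x_", "psi_x_")))
    )
    return {
        "covariate_structure": cov_stems,
        "factor_means": [f"mean_{f}" for f in FACTORS],
        "factor_variances": [f"psi_{f}_{f}" for f in FACTORS],
        "factor_covariances": sorted(
            s for s in stems
            if s.startswith("psi_") and not _is_variance_label(s)
            and not s.startswith("psi_x_")),
        "residual_variances_and_covariances": sorted(
            s for s in stems if s.startswith(("res_", "rescov_"))),
    }


def sex_difference_pipeline(long_df: pd.DataFrame, outcome: str,
                            covariates: list[str] | None = None,
                            wave_ages=DEFAULT_WAVE_AGES,
                            anchors=DEFAULT_ANCHORS,
                            alpha: float = 0.05,
                            sex_col: str = "sex",
                            fit_kwargs: dict | None = None
                            ) -> SexDifferenceReport:
    """Ordered multi-group constraint sequence for sex differences.

    (1) everything involving covariates except the outcome-on-covariate
    coefficients; (2) factor means; (3) factor variances; (4) factor
    covariances; (5) residual variances and covariances. Each step is
    tested against the previously accepted model with a chi-square
    difference test and partially rolled back by exact modification search
    when rejected. Wald tests then compare every outcome coefficient across
    the groups, nonsignificant ones are equated jointly, and finally the
    outcome intercept and residual variance equality is attempted.
    """
    fit_kwargs = dict(fit_kwargs or {})
    covariates = list(covariates or [])
    df = long_df.copy()
    df["_grp"] = df[sex_col].astype(str)
    groups = sorted(df["_grp"].unique())
    if len(groups) != 2:
        raise ValidationError(f"expected two sex groups, got {groups}")
    for g in groups:
        if df.loc[df["_grp"] == g, outcome].notna().sum() == 0:
            raise ValidationError(f"group {g!r} has no outcome data")
    spec = build_outcome_spec(outcome, covariates, wave_ages, anchors, groups)
    cols = list(WAVES) + [outcome] + covariates
    data = make_sem_data(df, cols, group_col="_grp")
    start = moment_matched_start(spec, data)
    reference = fit(spec, data, start=start, **fit_kwargs)
    stems_by_step = _step_label_stems(spec, outcome, covariates)

    steps: list[SexStepReport] = []
    current = reference
    for name in STEP_NAMES:
        stems = stems_by_step[name]
        cspec = current.model
        merged = []
        for s in stems:
            atom_pair = [f"{s}@{g}" for g in groups]
            cspec = cspec.constrain_equal(atom_pair, s)
            merged.append(s)
        cfit = fit(cspec, data, start=transfer_start(cspec, current),
                   **fit_kwargs)
        delta, dff, p = lr_test(cfit, current)
        freed: list[str] = []
        if p < alpha:
            log = modification_search(cfit, merged, data, current,
                                      alpha=alpha, fit_kwargs=fit_kwargs)
            freed = log.freed
            cfit = log.final_fit
            delta, dff, p = lr_test(cfit, current)
        steps.append(SexStepReport(name, stems, delta, dff, p, freed,
                                   accepted=p >= alpha))
        current = cfit

    # Wald tests on outcome coefficients across groups
    coef_stems = [f"b_{f}" for f in FACTORS] + [f"g_{c}" for c in covariates]
    V = current.robust_vcov()
    rows = []
    for stem in coef_stems:
        l1, l2 = (current.model.canonical(f"{stem}@{g}") for g in groups)
        if l1 == l2 or l1 not in current.labels or l2 not in current.labels:
            continue
        i, j = current.labels.index(l1), current.labels.index(l2)
        b1, b2 = current.theta[i], current.theta[j]
        se1 = np.sqrt(max(V[i, i], 0.0))
        se2 = np.sqrt(max(V[j, j], 0.0))
        W, p = wald_equality(b1, se1, b2, se2, V[i, j])
        rows.append({"coefficient": stem, f"b_{groups[0]}": b1,
                     f"b_{groups[1]}": b2, f"se_{groups[0]}": se1,
                     f"se_{groups[1]}": se2, "W": W, "p": p})
    wald_df = pd.DataFrame(rows)

    to_equate = [r["coefficient"] for r in rows if r["p"] >= alpha]
    if to_equate:
        espec = current.model
        for stem in to_equate:
            espec = espec.constrain_equal([f"{stem}@{g}" for g in groups], stem)
        efit = fit(espec, data, start=transfer_start(espec, current),
                   **fit_kwargs)
        if lr_test(efit, current)[2] >= alpha:
            current = efit
        else:
            to_equate = []

    # final: outcome intercept and residual variance
    ispec = current.model
    for stem in (f"int_{outcome}", f"resvar_{outcome}"):
        ispec = ispec.constrain_equal([f"{stem}@{g}" for g in groups], stem)
    ifit = fit(ispec, data, start=transfer_start(ispec, current), **fit_kwargs)
    ilr = lr_test(ifit, current)
    equated = ilr[2] >= alpha
    final = ifit if equated else current
    return SexDifferenceReport(steps, wald_df, to_equate, equated, ilr, final)
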