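"""Likelihood-ratio and Wald tests, and the constraint-freeing search."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from twingrowth.errors import NotNestedError
from twingrowth.sem.fit import FitResult, SemData, fit


def _atom_values(fitres: FitResult) -> dict[str, float]:
    est = fitres.estimates()
    out = {}
    for canon, atoms in fitres.model.atoms().items():
        for a in atoms:
            out[a] = est[canon]
    return out


def transfer_start(new_model, old_fit: FitResult) -> np.ndarray:
    """Warm-start vector for ``new_model`` from a related fitted model."""
    vals = _atom_values(old_fit)
    atoms = new_model.atoms()
    start = new_model.start_vector()
    for i, lab in enumerate(new_model.free_labels):
        hits = [vals[a] for a in atoms[lab] if a in vals]
        if hits:
            start[i] = float(np.mean(hits))
    return start


def _is_nested(restricted, full) -> bool:
    """Restricted is nested in full iff its tie partition is coarser."""
    ra, fa = restricted.atoms(), full.atoms()
    r_union = frozenset().union(*ra.values()) if ra else frozenset()
    f_union = frozenset().union(*fa.values()) if fa else frozenset()
    if r_union != f_union:
        return False
    for f_set in fa.values():
        if not any(f_set <= r_set for r_set in ra.values()):
            return False
    return True


def lr_test(fit_restricted: FitResult, fit_full: FitResult, *,
            check_nesting: bool = True, tol: float = 1e-6):
    """Chi-square difference test of nested FIML fits.

    Returns ``(delta_chi2, df, p)``; ``p = 1`` when ``df = 0`` by convention.
    """
    if check_nesting:
        if not _is_nested(fit_restricted.model, fit_full.model):
            raise NotNestedError(
                "restricted model's parameter ties do not coarsen the full "
                "model's; pass check_nesting=False to override")
    delta = 2.0 * (fit_full.loglik - fit_restricted.loglik)
    df = fit_full.k - fit_restricted.k
    if df < 0:
        raise NotNestedError("restricted model has more free parameters than full")
    scale = max(1.0, abs(fit_full.loglik))
    if delta < -tol * scale:
        raise NotNestedError(
            f"restricted loglik exceeds full by {-delta:.3g}; refit the full "
            "model (likely a failed optimization)")
    delta = max(delta, 0.0)
    p = 1.0 if df == 0 else float(chi2.sf(delta, df))
    return float(delta), int(df), p


def wald_equality(b1: float, se1: float, b2: float, se2: float,
                  cov12: float = 0.0):
    """Wald test of b1 == b2; returns (W, p) with W ~ chi2(1) under the null."""
    denom = se1 ** 2 + se2 ** 2 - 2.0 * cov12
    if not np.isfinite(denom) or denom <= 0:
        raise ValueError("nonpositive variance of the contrast")
    W = (b1 - b2) ** 2 / denom
    return float(W), float(chi2.sf(W, 1))


@dataclass
class ModificationStep:
    iteration: int
    global_delta_chi2: float
    global_df: int
    global_p: float
    candidate_deltas: dict[str, float]
    freed: str | None


@dataclass
class ModificationLog:
    steps: list[ModificationStep] = field(default_factory=list)
    freed: list[str] = field(default_factory=list)
    final_fit: FitResult | None = None
    accepted: bool = False
    irreducible: bool = False

    def to_json_dict(self) -> dict:
        return {
            "freed": self.freed,
            "accepted": self.accepted,
            "irreducible": self.irreducible,
            "steps": [{
                "iteration": s.iteration,
                "global_delta_chi2": s.global_delta_chi2,
                "global_df": s.global_df,
                "global_p": s.global_p,
                "candidate_deltas": s.candidate_deltas,
                "freed": s.freed,
            } for s in self.steps],
        }


def modification_search(constrained_fit: FitResult, candidates: list[str],
                        data: SemData, reference_fit: FitResult, *,
                        alpha: float = 0.05, fit_kwargs: dict | None = None
                        ) -> ModificationLog:
    """Free constrained parameters one at a time until fit is acceptable.

    Each candidate is a canonical (tied) label on the constrained model.
    The improvement from freeing a candidate is measured by an exact
    free-one-and-refit chi-square difference (not a score-test
    approximation). Candidates are freed largest-improvement-first, ties
    broken by the fixed candidate order, until the global test against
    ``reference_fit`` is nonsignificant at ``alpha``.
    """
    fit_kwargs = fit_kwargs or {}
    log = ModificationLog()
    current = constrained_fit
    remaining = list(candidates)
    it = 0
    while True:
        delta, df, p = lr_test(current, reference_fit)
        if p >= alpha or df == 0:
            log.steps.append(ModificationStep(it, delta, df, p, {}, None))
            log.accepted = True
            break
        if not remaining:
            log.steps.append(ModificationStep(it, delta, df, p, {}, None))
            log.irreducible = True
            break
        spec = current.model
        atoms = spec.atoms()
        deltas, trial_fits = {}, {}
        for cand in remaining:
            released = spec.release(sorted(atoms[cand]))
            trial = fit(released, data, start=transfer_start(released, current),
                        **fit_kwargs)
            deltas[cand] = 2.0 * (trial.loglik - current.loglik)
            trial_fits[cand] = trial
        best = max(remaining, key=lambda c: (deltas[c], -remaining.index(c)))
        if deltas[best] <= 0:
            log.steps.append(ModificationStep(it, delta, df, p, deltas, None))
            log.irreducible = True
            break
        log.steps.append(ModificationStep(it, delta, df, p, deltas, best))
        log.freed.append(best)
        remaining.remove(best)
        current = trial_fits[best]
        it += 1
    log.final_fit = current
    return log
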