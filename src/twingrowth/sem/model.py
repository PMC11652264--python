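"""Parameterized mean/covariance structures.

Two layers:

* :class:`MomentModel` — the minimal contract the fitting machinery needs:
  an ordered free-parameter table and a ``moments(theta)`` map returning
  per-group implied means and covariances.

* :class:`SemModelSpec` — a concrete matrix-based model
  (``sigma = lam (I-B)^-1 psi (I-B)^-T lam' + theta_res``,
  ``mu = nu + lam (I-B)^-1 alpha``) whose entries are fixed numbers or
  labelled free parameters; equality constraints are expressed by aliasing
  labels onto a shared canonical label.
"""

from __future__ import annotations

import abc
import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

from twingrowth.errors import SpecError

_MATRIX_ORDER = ("lam", "beta", "psi", "theta", "nu", "alpha")
_SYMMETRIC = {"psi", "theta"}


@dataclass
class Parameter:
    label: str
    start: float = 0.1
    lower: float = -np.inf
    upper: float = np.inf


class MomentModel(abc.ABC):
    """Contract consumed by :func:`twingrowth.sem.fit.fit`."""

    @property
    @abc.abstractmethod
    def groups(self) -> list[str]:
        ...

    @property
    @abc.abstractmethod
    def free_labels(self) -> list[str]:
        """Canonical free-parameter labels, in a fixed deterministic order."""

    @abc.abstractmethod
    def parameter(self, label: str) -> Parameter:
        ...

    @abc.abstractmethod
    def moments(self, theta: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Implied (mu, sigma) per group at the free-parameter vector theta."""

    # -- shared helpers -----------------------------------------------------

    @property
    def n_free(self) -> int:
        return len(self.free_labels)

    def start_vector(self) -> np.ndarray:
        return np.array([self.parameter(l).start for l in self.free_labels], float)

    def bounds(self) -> list[tuple[float, float]]:
        return [(self.parameter(l).lower, self.parameter(l).upper)
                for l in self.free_labels]

    def atoms(self) -> dict[str, frozenset[str]]:
        """Expansion of each canonical label to its atomic constituents."""
        return {l: frozenset([l]) for l in self.free_labels}

    def theta_dict(self, theta) -> dict[str, float]:
        return dict(zip(self.free_labels, np.asarray(theta, float)))


class SemModelSpec(MomentModel):
    """Matrix-template structural model over one or more groups."""

    def __init__(self, observed: list[str], latent: list[str],
                 groups: list[str] | None = None):
        self.observed = list(observed)
        self.latent = list(latent)
        self._groups = list(groups) if groups else ["all"]
        p, m = len(self.observed), len(self.latent)
        self.mats: dict[str, dict[str, np.ndarray]] = {}
        for g in self._groups:
            self.mats[g] = {
                "lam": np.zeros((p, m), dtype=object),
                "beta": np.zeros((m, m), dtype=object),
                "psi": np.zeros((m, m), dtype=object),
                "theta": np.zeros((p, p), dtype=object),
                "nu": np.zeros(p, dtype=object),
                "alpha": np.zeros(m, dtype=object),
            }
        self.params: dict[str, Parameter] = {}
        self.aliases: dict[str, str] = {}    # atomic label -> canonical label
        self._compiled = None

    # -- construction -------------------------------------------------------

    def set_entry(self, group: str, mat: str, index, value) -> None:
        """Set a matrix entry to a fixed number or a free-parameter label."""
        arr = self.mats[group][mat]
        if isinstance(value, str) and value not in self.params:
            self.params[value] = Parameter(value)
        if mat in _SYMMETRIC:
            i, j = index
            arr[i, j] = value
            arr[j, i] = value
        else:
            arr[index] = value
        self._compiled = None

    def set_param(self, label: str, start: float | None = None,
                  lower: float | None = None, upper: float | None = None) -> None:
        par = self.params.setdefault(label, Parameter(label))
        if start is not None:
            par.start = float(start)
        if lower is not None:
            par.lower = float(lower)
        if upper is not None:
            par.upper = float(upper)

    def var_index(self, name: str) -> int:
        return self.observed.index(name)

    def lat_index(self, name: str) -> int:
        return self.latent.index(name)

    def copy(self) -> "SemModelSpec":
        new = copy.deepcopy(self)
        new._compiled = None
        return new

    # -- MomentModel contract -----------------------------------------------

    @property
    def groups(self) -> list[str]:
        return self._groups

    def canonical(self, label: str) -> str:
        return self.aliases.get(label, label)

    @property
    def free_labels(self) -> list[str]:
        seen, out = set(), []
        for g in self._groups:
            for mat in _MATRIX_ORDER:
                arr = self.mats[g][mat]
                for v in arr.flat:
                    if isinstance(v, str):
                        c = self.canonical(v)
                        if c not in seen:
                            seen.add(c)
                            out.append(c)
        return out

    def parameter(self, label: str) -> Parameter:
        if label in self.params:
            return self.params[label]
        # canonical label introduced by aliasing without explicit registration:
        # inherit from any atom
        for atom, canon in self.aliases.items():
            if canon == label and atom in self.params:
                p = self.params[atom]
                return Parameter(label, p.start, p.lower, p.upper)
        raise KeyError(label)

    def atoms(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {l: set() for l in self.free_labels}
        for g in self._groups:
            for mat in _MATRIX_ORDER:
                for v in self.mats[g][mat].flat:
                    if isinstance(v, str):
                        out[self.canonical(v)].add(v)
        return {k: frozenset(v) for k, v in out.items()}

    # -- equality constraints ----------------------------------------------

    def constrain_equal(self, atom_labels: list[str], new_label: str | None = None
                        ) -> "SemModelSpec":
        """Return a copy with the given atomic labels tied to one parameter."""
        if len(atom_labels) < 2:
            raise SpecError("need at least two labels to constrain equal")
        new = self.copy()
        canon = new_label or atom_labels[0]
        starts, lowers, uppers = [], [], []
        for a in atom_labels:
            if a not in new.params:
                raise SpecError(f"unknown parameter label {a!r}")
            new.aliases[a] = canon
            p = new.params[a]
            starts.append(p.start)
            lowers.append(p.lower)
            uppers.append(p.upper)
        new.params[canon] = Parameter(canon, float(np.mean(starts)),
                                      max(lowers), min(uppers))
        new._compiled = None
        return new

    def fix(self, atom_labels: list[str], value: float = 0.0) -> "SemModelSpec":
        """Return a copy with all entries bearing these labels fixed to a value."""
        targets = set(atom_labels)
        new = self.copy()
        for g in new._groups:
            for mat in _MATRIX_ORDER:
                arr = new.mats[g][mat]
                for idx, v in np.ndenumerate(arr):
                    if isinstance(v, str) and v in targets:
                        arr[idx] = float(value)
        new._compiled = None
        return new

    def release(self, atom_labels: list[str]) -> "SemModelSpec":
        """Return a copy with the given atoms freed from their alias."""
        new = self.copy()
        for a in atom_labels:
            new.aliases.pop(a, None)
        new._compiled = None
        return new

    # -- evaluation ---------------------------------------------------------

    def _compile(self):
        if self._compiled is not None:
            return self._compiled
        order = {l: i for i, l in enumerate(self.free_labels)}
        comp = {}
        for g in self._groups:
            gcomp = {}
            for mat in _MATRIX_ORDER:
                arr = self.mats[g][mat]
                base = np.zeros(arr.shape, dtype=float)
                flat_idx, theta_idx = [], []
                for fi, v in enumerate(arr.flat):
                    if isinstance(v, str):
                        flat_idx.append(fi)
                        theta_idx.append(order[self.canonical(v)])
                    else:
                        base.flat[fi] = float(v)
                gcomp[mat] = (base, np.array(flat_idx, dtype=int),
                              np.array(theta_idx, dtype=int))
            comp[g] = gcomp
        self._compiled = comp
        return comp

    def materialize(self, theta, group: str) -> dict[str, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        comp = self._compile()[group]
        out = {}
        for mat, (base, fi, ti) in comp.items():
            m = base.copy()
            if fi.size:
                m.flat[fi] = theta[ti]
            out[mat] = m
        return out

    def implied_moments(self, theta, group: str):
        """(mu, sigma) for one group; raises LinAlgError if (I-B) is singular."""
        m = self.materialize(theta, group)
        lam, beta, psi = m["lam"], m["beta"], m["psi"]
        theta_res, nu, alpha = m["theta"], m["nu"], m["alpha"]
        nlat = beta.shape[0]
        if np.any(beta):
            inv = np.linalg.solve(np.eye(nlat) - beta, np.eye(nlat))
            lam_eff = lam @ inv
        else:
            lam_eff = lam
        sigma = lam_eff @ psi @ lam_eff.T + theta_res
        sigma = 0.5 * (sigma + sigma.T)
        mu = nu + lam_eff @ alpha
        return mu, sigma

    def moments(self, theta):
        return {g: self.implied_moments(theta, g) for g in self._groups}

    def moment_jacobian(self, theta):
        """Analytic d(mu, sigma)/d(theta) per group; None if B is non-zero
        (callers then fall back to finite differences)."""
        theta = np.asarray(theta, dtype=float)
        k = theta.size
        comp = self._compile()
        out = {}
        for g in self._groups:
            mats = self.materialize(theta, g)
            if np.any(mats["beta"]):
                return None
            lam, psi, alpha = mats["lam"], mats["psi"], mats["alpha"]
            p, m = lam.shape
            lampsi = lam @ psi
            dmu = np.zeros((p, k))
            dsig = np.zeros((p, p, k))
            for mat, (base, fi, ti) in comp[g].items():
                for flat, t in zip(fi, ti):
                    if mat == "lam":
                        r, c = divmod(flat, m)
                        dsig[r, :, t] += lampsi[:, c]
                        dsig[:, r, t] += lampsi[:, c]
                        dmu[r, t] += alpha[c]
                    elif mat == "psi":
                        i, j = divmod(flat, m)
                        dsig[:, :, t] += np.outer(lam[:, i], lam[:, j])
                    elif mat == "theta":
                        i, j = divmod(flat, p)
                        dsig[i, j, t] += 1.0
                    elif mat == "nu":
                        dmu[flat, t] += 1.0
                    elif mat == "alpha":
                        dmu[:, t] += lam[:, flat]
            out[g] = (dmu, dsig)
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def enc(arr):
            out = np.empty(arr.shape, dtype=object)
            for idx, v in np.ndenumerate(arr):
                out[idx] = {"p": v} if isinstance(v, str) else float(v)
            return out.tolist()

        return {
            "observed": self.observed,
            "latent": self.latent,
            "groups": self._groups,
            "matrices": {g: {m: enc(self.mats[g][m]) for m in _MATRIX_ORDER}
                         for g in self._groups},
            "parameters": {l: {"start": p.start,
                               "lower": None if np.isinf(p.lower) else p.lower,
                               "upper": None if np.isinf(p.upper) else p.upper}
                           for l, p in self.params.items()},
            "aliases": dict(self.aliases),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SemModelSpec":
        spec = cls(d["observed"], d["latent"], d["groups"])

        def dec(x):
            if isinstance(x, dict):
                return x["p"]
            if isinstance(x, list):
                return [dec(v) for v in x]
            return float(x)

        for g in spec._groups:
            for mat in _MATRIX_ORDER:
                arr = np.array(dec(d["matrices"][g][mat]), dtype=object)
                spec.mats[g][mat] = arr.reshape(spec.mats[g][mat].shape)
        for l, pd_ in d.get("parameters", {}).items():
            spec.params[l] = Parameter(
                l, pd_.get("start", 0.1),
                -np.inf if pd_.get("lower") is None else pd_["lower"],
                np.inf if pd_.get("upper") is None else pd_["upper"])
        spec.aliases = dict(d.get("aliases", {}))
        return spec

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SemModelSpec":
        return cls.from_dict(yaml.safe_load(text))


def saturated_spec(observed: list[str], groups: list[str] | None = None,
                   start_mu: np.ndarray | None = None,
                   start_cov: np.ndarray | None = None) -> SemModelSpec:
    """Fully saturated mean/covariance model (one parameter per moment)."""
    groups = groups or ["all"]
    spec = SemModelSpec(observed, [], groups)
    p = len(observed)
    for g in groups:
        tag = "" if len(groups) == 1 else f"@{g}"
        for i in range(p):
            lab = f"mu_{observed[i]}{tag}"
            spec.set_entry(g, "nu", i, lab)
            if start_mu is not None:
                spec.set_param(lab, start=float(start_mu[i]))
        for i in range(p):
            for j in range(i, p):
                lab = f"cov_{observed[i]}_{observed[j]}{tag}"
                spec.set_entry(g, "theta", (i, j), lab)
                if i == j:
                    spec.set_param(lab, start=1.0 if start_cov is None
                                   else float(start_cov[i, i]), lower=1e-10)
                elif start_cov is not None:
                    spec.set_param(lab, start=float(start_cov[i, j]))
    return spec
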