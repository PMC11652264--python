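"""Twin-cohort tables, scale scoring, and preprocessing transforms.

Canonical layout is wide: one row per twin pair, per-twin columns suffixed
``_t1`` / ``_t2`` (e.g. ``em_p4_t1``, ``audit_total_t2``). Problem waves
follow the naming ``<trait>_<rater><age>`` with trait ``em``/``cd`` and
rater ``p`` (parent) / ``s`` (self).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from twingrowth.errors import DegenerateDesignError, ValidationError

MZ = "MZ"
DZSS = "DZss"
DZOS = "DZos"
ZYGOSITIES = (MZ, DZSS, DZOS)

MALE = "M"
FEMALE = "F"

_SEX_ALIASES = {
    "m": MALE, "male": MALE, "1": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
}


def canonical_sex(value) -> str:
    if isinstance(value, str):
        key = value.strip().lower()
        if key in _SEX_ALIASES:
            return _SEX_ALIASES[key]
    raise ValidationError(f"unrecognised sex code {value!r}")


@dataclass(frozen=True)
class Wave:
    """One measurement occasion of one trait."""

    wave_id: str
    trait: str              # emotional | conduct | alcohol
    rater: str              # parent | self
    nominal_age: float
    item_count: int
    item_max: int
    item_min: int = 0

    @property
    def score_max(self) -> float:
        return self.item_count * self.item_max

    def __post_init__(self):
        if self.item_count <= 0:
            raise ValidationError(f"wave {self.wave_id}: item_count must be positive")


def _problem_waves() -> tuple[Wave, ...]:
    waves = []
    for trait, code in (("emotional", "em"), ("conduct", "cd")):
        for rater, rcode, age in (
            ("parent", "p", 4), ("parent", "p", 7), ("parent", "p", 9),
            ("self", "s", 9), ("self", "s", 11), ("self", "s", 16),
        ):
            waves.append(Wave(f"{code}_{rcode}{age}", trait, rater, age, 5, 2))
    return tuple(waves)


@dataclass(frozen=True)
class MeasurementSchema:
    """Measurement design: problem waves plus the alcohol assessment."""

    problem_waves: tuple[Wave, ...] = field(default_factory=_problem_waves)
    alcohol_waves: tuple[Wave, ...] = (
        Wave("audit_total", "alcohol", "self", 22, 10, 4),
        Wave("audit_consumption", "alcohol", "self", 22, 3, 4),
        Wave("audit_problem", "alcohol", "self", 22, 7, 4),
    )
    age_column: str = "age22"

    @property
    def waves(self) -> tuple[Wave, ...]:
        return self.problem_waves + self.alcohol_waves

    def wave(self, wave_id: str) -> Wave:
        for w in self.waves:
            if w.wave_id == wave_id:
                return w
        raise KeyError(wave_id)

    def problem_wave_ids(self) -> list[str]:
        return [w.wave_id for w in self.problem_waves]

    def data_dictionary(self) -> pd.DataFrame:
        """Column-level documentation emitted by the ``schema`` CLI subcommand."""
        rows = [
            {"column": "family_id", "description": "pair identifier", "range": "-"},
            {"column": "zyg", "description": f"zygosity, one of {ZYGOSITIES}", "range": "-"},
        ]
        for t in ("t1", "t2"):
            rows.append({"column": f"sex_{t}", "description": f"twin {t} sex (M/F)", "range": "-"})
        for w in self.waves:
            for t in ("t1", "t2"):
                rows.append({
                    "column": f"{w.wave_id}_{t}",
                    "description": f"{w.trait} score, {w.rater}-report, age {w.nominal_age:g}",
                    "range": f"[0, {w.score_max:g}]",
                })
        for t in ("t1", "t2"):
            rows.append({"column": f"{self.age_column}_{t}",
                         "description": "exact age at alcohol assessment (years)", "range": ">0"})
        return pd.DataFrame(rows)


def default_schema() -> MeasurementSchema:
    return MeasurementSchema()


# ---------------------------------------------------------------------------
# scale scoring and transforms
# ---------------------------------------------------------------------------

def compute_scale_score(
    item_values: Sequence[float | None],
    item_count: int,
    item_max: int,
    *,
    min_items: int = 1,
    wave_id: str = "?",
) -> float:
    """Prorated scale score: mean of available items times the item count.

    Returns NaN when fewer than ``min_items`` items are available.
    """
    vals = []
    for i, v in enumerate(item_values):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if not (0 <= v <= item_max):
            raise ValidationError(
                f"wave {wave_id}: item {i} value {v} outside [0, {item_max}]"
            )
        vals.append(float(v))
    if len(item_values) != item_count:
        raise ValidationError(
            f"wave {wave_id}: got {len(item_values)} items, schema says {item_count}"
        )
    if len(vals) < max(min_items, 1):
        return float("nan")
    return float(np.mean(vals) * item_count)


def residualize_on_age(scores, ages) -> np.ndarray:
    """Residuals of score on age from an OLS fit over complete pairs.

    Rows missing either input stay missing. Raises
    :class:`DegenerateDesignError` when all fitted ages coincide.
    """
    s = np.asarray(scores, dtype=float)
    a = np.asarray(ages, dtype=float)
    if s.shape != a.shape:
        raise ValidationError("scores and ages must have equal length")
    ok = ~(np.isnan(s) | np.isnan(a))
    if ok.sum() < 2:
        raise ValidationError("need at least two complete (score, age) pairs")
    if np.ptp(a[ok]) == 0:
        raise DegenerateDesignError(
            "all ages identical; explicit mean-centering required instead"
        )
    X = np.column_stack([np.ones(ok.sum()), a[ok]])
    beta, *_ = np.linalg.lstsq(X, s[ok], rcond=None)
    out = np.full_like(s, np.nan)
    out[ok] = s[ok] - X @ beta
    return out


def log_transform_problem_score(score, *, offset: float = 1.0):
    """log(score + offset); 0 maps to 0 with the default offset of 1."""
    arr = np.asarray(score, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValidationError("problem scores must be non-negative")
    out = np.log(arr + offset)
    if np.isscalar(score) or arr.ndim == 0:
        return float(out)
    return out


def flag_hazardous(audit_total, *, cutoff: float = 8.0):
    """True iff AUDIT total >= cutoff; NaN propagates."""
    arr = np.asarray(audit_total, dtype=float)
    if np.any((arr < 0) | (arr > 40)):
        raise ValidationError("AUDIT total outside [0, 40]")
    out = np.where(np.isnan(arr), np.nan, (arr >= cutoff).astype(float))
    if np.isscalar(audit_total) or arr.ndim == 0:
        return float("nan") if np.isnan(out) else bool(out)
    return out


# ---------------------------------------------------------------------------
# TwinDataset
# ---------------------------------------------------------------------------

@dataclass
class TwinDataset:
    """Wide table: one row per twin pair, measures suffixed ``_t1``/``_t2``."""

    table: pd.DataFrame
    schema: MeasurementSchema = field(default_factory=default_schema)

    def __post_init__(self):
        self.validate(check_ranges=False)

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    def validate(self, *, check_ranges: bool = True) -> None:
        df = self.table
        for col in ("family_id", "zyg"):
            if col not in df.columns:
                raise ValidationError(f"missing required column {col!r}")
            if df[col].isna().any():
                bad = df.index[df[col].isna()][0]
                raise ValidationError(f"row {bad}: {col} may not be missing")
        bad_zyg = ~df["zyg"].isin(ZYGOSITIES)
        if bad_zyg.any():
            i = df.index[bad_zyg][0]
            raise ValidationError(f"row {i}: unknown zygosity code {df.loc[i, 'zyg']!r}")
        if df["family_id"].duplicated().any():
            raise ValidationError("duplicate family_id values")
        if {"sex_t1", "sex_t2"} <= set(df.columns) and len(df):
            s1, s2 = df["sex_t1"], df["sex_t2"]
            both = s1.notna() & s2.notna()
            mz_mixed = both & (df["zyg"] == MZ) & (s1 != s2)
            if mz_mixed.any():
                i = df.index[mz_mixed][0]
                raise ValidationError(f"row {i}: MZ pair with opposite sexes")
            os_same = both & (df["zyg"] == DZOS) & (s1 == s2)
            if os_same.any():
                i = df.index[os_same][0]
                raise ValidationError(f"row {i}: DZos pair with identical sexes")
        if check_ranges:
            for w in self.schema.waves:
                for t in ("t1", "t2"):
                    col = f"{w.wave_id}_{t}"
                    if col not in df.columns:
                        continue
                    v = df[col].astype(float)
                    bad = v.notna() & ((v < 0) | (v > w.score_max))
                    if bad.any():
                        i = df.index[bad][0]
                        raise ValidationError(
                            f"row {i}: {col}={v[i]} outside [0, {w.score_max:g}]"
                        )

    def to_individual_long(self) -> pd.DataFrame:
        """Stack twins: two rows per pair, person-level columns without suffix."""
        frames = []
        suffixed = [c for c in self.table.columns if c.endswith(("_t1", "_t2"))]
        shared = [c for c in self.table.columns if c not in suffixed]
        for pos in (1, 2):
            suf = f"_t{pos}"
            cols = [c for c in suffixed if c.endswith(suf)]
            part = self.table[shared + cols].copy()
            part.columns = shared + [c[: -len(suf)] for c in cols]
            part["twin"] = pos
            frames.append(part)
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(["family_id", "twin"], kind="stable").reset_index(drop=True)


def from_long(long_df: pd.DataFrame, schema: MeasurementSchema | None = None) -> TwinDataset:
    """Pivot a person-per-row table to the canonical wide pair layout.

    Twin position 1 is the lower within-family person index, deterministically.
    """
    schema = schema or default_schema()
    df = long_df.copy()
    if "person_id" in df.columns:
        df = df.sort_values(["family_id", "person_id"], kind="stable")
    df["twin"] = df.groupby("family_id").cumcount() + 1
    if (df["twin"] > 2).any():
        raise ValidationError("a family has more than two persons")
    shared = [c for c in ("family_id", "zyg") if c in df.columns]
    per_twin = [c for c in df.columns if c not in shared + ["twin", "person_id"]]
    wide = df.pivot(index="family_id", columns="twin", values=per_twin)
    wide.columns = [f"{c}_t{t}" for c, t in wide.columns]
    meta = df[shared].drop_duplicates("family_id").set_index("family_id")
    out = meta.join(wide).reset_index().infer_objects()
    return TwinDataset(out, schema)


def read_twin_table(
    path,
    schema: MeasurementSchema | None = None,
    *,
    check_ranges: bool = True,
) -> TwinDataset:
    """Read a wide CSV table, validating TwinDataset invariants."""
    schema = schema or default_schema()
    df = pd.read_csv(path)
    for col in ("sex_t1", "sex_t2"):
        if col in df.columns:
            df[col] = df[col].map(lambda v: canonical_sex(v) if pd.notna(v) else np.nan)
    ds = TwinDataset(df, schema)
    ds.validate(check_ranges=check_ranges)
    return ds


def write_twin_table(dataset: TwinDataset, path) -> None:
    """Write CSV; full float precision so round-trips are bit-exact."""
    dataset.table.to_csv(path, index=False, float_format="%.17g")


def residualize_outcomes_on_age(
    long_df: pd.DataFrame,
    outcome_cols: Iterable[str],
    age_col: str = "age22",
) -> pd.DataFrame:
    """Regress exact age out of each outcome column (single pooled fit)."""
    out = long_df.copy()
    for col in outcome_cols:
        if col in out.columns:
            out[col] = residualize_on_age(out[col].to_numpy(float),
                                          out[age_col].to_numpy(float))
    return out
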