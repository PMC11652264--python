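"""End-to-end orchestration: simulate -> preprocess -> growth -> phenotypic
regression -> sex tests -> twin model comparison, with per-stage artifacts
and a hash manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from twingrowth import growth, io as tio, simulate as sim, twin
from twingrowth.errors import ValidationError

log = logging.getLogger("twingrowth")


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    input_csv: str | None = None        # analyze an existing table instead
    simulate: bool = True
    n_mz: int = 1000
    n_dzss: int = 1000
    n_dzos: int = 0
    with_missingness: bool = False
    outcomes: list = field(default_factory=lambda: ["audit_total"])
    covariates: list = field(default_factory=list)
    alpha: float = 0.05
    wave_ages: list = field(default_factory=lambda: list(growth.DEFAULT_WAVE_AGES))
    anchors: list = field(default_factory=lambda: list(growth.DEFAULT_ANCHORS))
    log_problem_score: bool = True
    refit_per_outcome: bool = False
    run_sex_tests: bool = True
    run_twin: bool = True
    include_os: bool = True
    fit_maxiter: int = 3000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    raise TypeError(type(o))


def preprocess(dataset: tio.TwinDataset, outcomes: list[str],
               log_problem: bool = True) -> pd.DataFrame:
    """Pair table -> individual rows with age-residualized outcomes."""
    long_df = dataset.to_individual_long()
    if "audit_problem" in long_df.columns and log_problem:
        long_df["audit_problem"] = tio.log_transform_problem_score(
            np.clip(long_df["audit_problem"].to_numpy(float), 0, None))
    present = [o for o in outcomes if o in long_df.columns]
    missing = [o for o in outcomes if o not in long_df.columns]
    if missing:
        raise ValidationError(f"outcome columns absent from table: {missing}")
    if "age22" in long_df.columns:
        long_df = tio.residualize_outcomes_on_age(long_df, present, "age22")
    return long_df


def run_pipeline(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "config": asdict(config)}
    fit_kwargs = {"maxiter": config.fit_maxiter}
    config.to_yaml(out / "config.yaml")

    def record(stage: str, *paths: Path):
        manifest["stages"][stage] = {p.name: _sha256(p) for p in paths}
        _write_json(manifest, out / "manifest.json")

    def fail(stage: str, exc: Exception):
        (out / f"FAILED_{stage}").write_text(str(exc))
        log.error("stage %s failed: %s", stage, exc)
        raise

    # 1 -- data
    stage = "01_data"
    try:
        if config.input_csv:
            dataset = tio.read_twin_table(config.input_csv, check_ranges=False)
            truth = None
        else:
            scfg = sim.default_config(
                n_mz=config.n_mz, n_dzss=config.n_dzss, n_dzos=config.n_dzos,
                seed=config.seed)
            if config.with_missingness:
                scfg.missingness = sim.default_missingness()
            dataset, truth = sim.simulate_dataset(scfg)
        twins_csv = out / "twins.csv"
        tio.write_twin_table(dataset, twins_csv)
        arts = [twins_csv]
        if truth is not None:
            truth.to_json(out / "truth.json")
            arts.append(out / "truth.json")
        record(stage, *arts)
    except Exception as exc:            # noqa: BLE001 - stage boundary
        fail(stage, exc)

    # 2 -- preprocess
    stage = "02_preprocess"
    try:
        long_df = preprocess(dataset, config.outcomes, config.log_problem_score)
        long_csv = out / "long.csv"
        long_df.to_csv(long_csv, index=False, float_format="%.17g")
        record(stage, long_csv)
    except Exception as exc:
        fail(stage, exc)

    # 3 -- growth model (fit once, shared across outcomes by default)
    stage = "03_growth"
    try:
        gfit = growth.fit_growth(long_df, config.wave_ages, config.anchors,
                                 **fit_kwargs)
        gpath = out / "growth_fit.json"
        _write_json(gfit.to_json_dict(), gpath)
        gfit.param_table().to_csv(out / "growth_params.csv", index=False)
        record(stage, gpath, out / "growth_params.csv")
    except Exception as exc:
        fail(stage, exc)

    # 4-6 per outcome
    for outcome in config.outcomes:
        stage = f"04_outcome_{outcome}"
        try:
            ofit = growth.fit_outcome_model(
                long_df, outcome, config.covariates,
                config.wave_ages, config.anchors, **fit_kwargs)
            bpath = out / f"betas_{outcome}.csv"
            ofit.betas.to_csv(bpath, index=False)
            fpath = out / f"outcome_fit_{outcome}.json"
            _write_json(ofit.fit.to_json_dict(), fpath)
            record(stage, bpath, fpath)
        except Exception as exc:
            fail(stage, exc)

        if config.run_sex_tests:
            stage = f"05_sextest_{outcome}"
            try:
                rep = growth.sex_difference_pipeline(
                    long_df, outcome, config.covariates,
                    config.wave_ages, config.anchors, alpha=config.alpha,
                    fit_kwargs=fit_kwargs)
                rpath = out / f"sextest_{outcome}.json"
                _write_json(rep.to_json_dict(), rpath)
                record(stage, rpath)
            except Exception as exc:
                fail(stage, exc)

        if config.run_twin:
            stage = f"06_twin_{outcome}"
            try:
                res = run_twin_stage(gfit, ofit, long_df, outcome,
                                     alpha=config.alpha, out=out,
                                     include_os=config.include_os,
                                     fit_kwargs=fit_kwargs)
                if res is None:
                    (out / f"SKIPPED_{stage}").write_text(
                        "no significant predictors to decompose")
                else:
                    record(stage, *res)
            except Exception as exc:
                fail(stage, exc)

    _write_json(manifest, out / "manifest.json")
    return out


def select_predictors(betas: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Growth factors with a significant outcome path in any group."""
    crit = 1.959963984540054
    sig = betas[np.abs(betas["beta_raw"]) > crit * betas["se_raw"]]
    factors = [p for p in sig["predictor"].unique() if p in growth.FACTORS]
    return sorted(factors, key=list(growth.FACTORS).index)


def run_twin_stage(gfit, ofit, long_df, outcome, *, alpha, out: Path,
                   include_os: bool, fit_kwargs: dict):
    predictors = select_predictors(ofit.betas, alpha)[:3]
    if not predictors:
        return None
    scored = twin.compute_factor_scores(gfit, long_df)
    keep = [f"fs_{p}" for p in predictors] + [outcome]
    scored = twin.residualize_on_sex(scored, keep)
    pair_df = twin.make_pair_table(scored, keep)
    pred_cols = [f"fs_{p}" for p in predictors]
    search = twin.structure_search(pair_df, pred_cols, outcome,
                                   include_os=include_os, **fit_kwargs)
    apath = out / f"twin_aic_{outcome}.csv"
    search.table.to_csv(apath, index=False)
    sel = {
        "selected": search.selected.code,
        "predictors": predictors,
        "standardized": twin.standardized_solution(search.selected_fit)
        .to_dict(orient="records"),
        "excluded": search.excluded,
    }
    spath = out / f"twin_selected_{outcome}.json"
    _write_json(sel, spath)
    arts = [apath, spath]
    if search.selected.direct:
        rep = twin.sex_difference_direct_paths(
            search.selected, pair_df, alpha=alpha, **fit_kwargs)
        xpath = out / f"twin_sexpaths_{outcome}.json"
        _write_json({"joint_lr": list(rep.joint_lr),
                     "paths": rep.table}, xpath)
        arts.append(xpath)
    return arts
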