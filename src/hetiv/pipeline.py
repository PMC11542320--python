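"""End-to-end orchestration of the 4-stage analysis with provenance.

Stages run in a fixed order: (1) expert elicitation -> forced covariates,
(2) candidate enumeration, volume filter and post-double-selection LASSO,
(3) local-IV estimation of individual and subgroup effects with bootstrap
intervals, (4) forest-plot reporting.  Every run writes a manifest recording
the configuration, seeds, timings and a content hash of each artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import candidates as cand
from . import elicitation, lasso, liv, reporting, simulate

log = logging.getLogger("hetiv")

MANDATORY_COLUMNS = (
    "treatment",
    "outcome",
    "hospital_id",
    "period",
    "tto",
    "age_60_74",
    "age_75_plus",
    "sex",
    "frailty",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    output_dir: str = "hetiv_run"
    seed: int = 0
    # inputs: either a cohort CSV or a simulation config; ratings CSV optional
    cohort_csv: str | None = None
    ratings_csv: str | None = None
    simulation: dict = field(default_factory=dict)
    # stage toggles / options
    run_elicitation: bool = True
    forced_list: list[str] | None = None  # used when elicitation is off
    priority_threshold: float = 2.0
    min_per_arm: int = 50
    volume_rule: str = "carriers"
    lasso_c: float = 1.1
    lasso_gamma: float | None = None
    degree: int = 3
    mte_basis: str = "polynomial"
    effect_mode: str = "person"
    propensity_eps: float = 1e-3
    adjustments: list[str] | None = None  # None = all available defaults
    bootstrap_replicates: int = 200
    bootstrap_unit: str = "patient"
    bootstrap_stages: str = "stage3"
    reporting_floor: int = 10
    ordering: str = "effect"
    render_formats: tuple = ("static", "dynamic")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise StageError("config", "schema",
                             f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.cohort_csv, self.ratings_csv):
            if p is not None and not Path(p).exists():
                raise StageError("config", "schema", f"input path missing: {p}")
        if self.effect_mode not in ("person", "conditional"):
            raise StageError("config", "schema", "effect_mode invalid")
        if self.bootstrap_replicates < 1:
            raise StageError("config", "schema", "bootstrap_replicates < 1")


def validate_cohort(data: str | Path | pd.DataFrame,
                    comorbidities: list[str] | None = None) -> dict:
    """Schema and value-domain checks on an admission table.

    Checks mandatory columns, outcome in [0, 90], tto in [0, 1], death
    implying zero outcome, and the MLTC rule (>= 2 comorbidities per patient).
    Returns a report dict with per-check violation row indices.
    """
    df = pd.read_csv(data) if not isinstance(data, pd.DataFrame) else data
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise StageError("validate", "schema",
                         f"missing mandatory columns: {missing}")
    if comorbidities is None:
        comorbidities = [c for c in simulate.SimulationConfig().comorbidity_prevalences
                         if c in df.columns]
    checks: dict[str, list[int]] = {}
    out = df["outcome"]
    checks["outcome_out_of_range"] = df.index[(out < 0) | (out > 90)].tolist()
    checks["tto_out_of_range"] = df.index[
        (df["tto"] < 0) | (df["tto"] > 1)
    ].tolist()
    if "died" in df.columns:
        checks["death_nonzero_outcome"] = df.index[
            (df["died"] == 1) & (df["outcome"] != 0)
        ].tolist()
    if comorbidities:
        counts = df[comorbidities].sum(axis=1)
        checks["mltc_violation"] = df.index[counts < 2].tolist()
    checks["missing_values"] = df.index[
        df[list(MANDATORY_COLUMNS)].isna().any(axis=1)
    ].tolist()
    n_viol = sum(len(v) for v in checks.values())
    return {
        "n_rows": int(len(df)),
        "n_violations": int(n_viol),
        "violations": checks,
        "valid": n_viol == 0,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute stages 1-4 and return the run manifest.

    Any stage failure raises :class:`StageError` with the stage name and a
    machine-readable code; artifacts written before the failure are retained.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "artifacts": {},
    }
    seeds = np.random.SeedSequence(config.seed).generate_state(4)

    def _register(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    def _finish(stage: str, t0: float) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}

    # ---- input cohort -------------------------------------------------
    t0 = time.time()
    oracle = None
    if config.cohort_csv:
        cohort = simulate.read_cohort_csv(config.cohort_csv)
    else:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", int(seeds[0] % 2**31))
        sim_cfg = simulate.SimulationConfig(**sim_kwargs)
        cohort, oracle = simulate.generate_cohort(sim_cfg)
        path = outdir / "cohort.csv"
        simulate.write_cohort_csv(cohort, path)
        _register("cohort", path)
        manifest["oracle_ate"] = oracle.ate
    report = validate_cohort(cohort)
    if not report["valid"]:
        raise StageError("validate", "data",
                         f"{report['n_violations']} cohort violations")
    comorbs = [c for c in simulate.SimulationConfig().comorbidity_prevalences
               if c in cohort.columns]
    _finish("input", t0)

    # ---- stage 1: elicitation -----------------------------------------
    t0 = time.time()
    if config.run_elicitation:
        if config.ratings_csv:
            survey = elicitation.read_survey_csv(config.ratings_csv)
        else:
            survey = elicitation.simulate_survey(
                comorbs, seed=int(seeds[1] % 2**31)
            )
        priorities = elicitation.aggregate_ratings(
            survey, threshold=config.priority_threshold
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            manifest["icc"] = elicitation.interrater_icc(survey)
    else:
        if config.forced_list is None:
            raise StageError("elicit", "schema",
                             "elicitation disabled but no forced_list given")
        priorities = elicitation.PrioritySet(
            forced=sorted(config.forced_list),
            low_priority=sorted(set(comorbs) - set(config.forced_list)),
        )
    path = outdir / "priorities.json"
    priorities.to_json(path)
    _register("priorities", path)
    manifest["n_forced_stage1"] = len(priorities.forced)
    _finish("stage1_elicit", t0)

    # ---- stage 2: candidates + volume filter + PDS --------------------
    t0 = time.time()
    try:
        cand_set = cand.enumerate_candidates(priorities)
        kept, vol_report = cand.apply_volume_threshold(
            cohort, cand_set, config.min_per_arm, rule=config.volume_rule
        )
        path = outdir / "volume_report.csv"
        vol_report.to_csv(path)
        _register("volume_report", path)
        selection = lasso.pds_select(
            cohort, kept, priorities,
            c=config.lasso_c, gamma=config.lasso_gamma,
        )
    except StageError:
        raise
    except Exception as e:  # numerical failure in selection
        raise StageError("select", "numerical", str(e)) from e
    path = outdir / "selection.json"
    selection.to_json(path)
    _register("selection", path)
    manifest["n_candidates"] = len(cand_set)
    manifest["n_selected"] = len(selection.x_selected)
    _finish("stage2_select", t0)

    # ---- stage 3: LIV estimation + bootstrap --------------------------
    t0 = time.time()
    adjustments = (
        config.adjustments
        if config.adjustments is not None
        else [a for a in liv.DEFAULT_ADJUSTMENTS
              if a in cohort.columns or a == "age_sq"]
    )
    spec = liv.BootstrapSpec(
        n_replicates=config.bootstrap_replicates,
        seed=int(seeds[2] % 2**31),
        unit=config.bootstrap_unit,
        stages=config.bootstrap_stages,
    )
    try:
        estimates = liv.bootstrap_ci(
            cohort, selection, spec,
            adjustments=adjustments,
            degree=config.degree,
            mode=config.effect_mode,
            eps=config.propensity_eps,
            basis=config.mte_basis,
            reporting_floor=config.reporting_floor,
            candidates=kept,
            priorities=priorities,
            min_per_arm=config.min_per_arm,
        )
    except liv.InstrumentError as e:
        raise StageError("estimate", "instrument", str(e)) from e
    except np.linalg.LinAlgError as e:
        raise StageError("estimate", "numerical", str(e)) from e
    for ext, writer in (("csv", estimates.to_csv), ("json", estimates.to_json)):
        path = outdir / f"effects.{ext}"
        writer(path)
        _register(f"effects_{ext}", path)
    manifest["overall"] = estimates.overall
    manifest["first_stage_f"] = estimates.meta.get("first_stage_f")
    _finish("stage3_estimate", t0)

    # ---- stage 4: reporting -------------------------------------------
    t0 = time.time()
    spec4 = reporting.build_forest(estimates, ordering=config.ordering)
    path = outdir / "forest.json"
    spec4.to_json(path)
    _register("forest_spec", path)
    if "static" in config.render_formats:
        path = outdir / "forest.png"
        reporting.render_forest(spec4, str(path), format="static")
        _register("forest_png", path)
    if "dynamic" in config.render_formats:
        path = outdir / "forest.html"
        reporting.render_forest(spec4, str(path), format="dynamic")
        _register("forest_html", path)
    _finish("stage4_report", t0)

    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    log.info("pipeline complete: %s", path)
    return manifest
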