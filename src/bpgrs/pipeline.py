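"""End-to-end orchestration: cohort -> score -> models -> interaction -> risks.

One :class:`RunConfig` (YAML-friendly) drives every stage; all randomness
flows through the single seed, so a fixed config reproduces byte-identical
outputs.  Each stage's failure is re-raised with the stage name so a broken
input is attributable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .absrisk import group_absolute_risks
from .grs import (
    assign_groups,
    compute_wgrs,
    load_dosages_tsv,
    load_weights,
    standardize,
)
from .interaction import assign_joint_groups, reri_analysis, sensitivity_cuts
from .simulate import GompertzHazard, JointEffect, SimConfig, simulate_cohort
from .survival import DEFAULT_ADJUSTMENT, ExposureSpec, results_table

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run needs; see ``load_run_config`` for YAML."""

    output_dir: str = "bpgrs_run"
    seed: int = 0
    # either simulate=True (SimConfig fields under `simulation`) or input paths
    simulate: bool = True
    simulation: Mapping[str, Any] = field(default_factory=dict)
    phenotype_csv: str | None = None
    dosage_tsv: str | None = None
    weight_tsv: str | None = None
    outcomes: tuple[str, ...] = ("uc_total", "uc_nonaggressive", "uc_aggressive")
    sbp_cut: float = 140.0
    dbp_cut: float = 90.0
    sensitivity_sbp_cuts: tuple[float, ...] = (130.0, 140.0, 150.0)
    interaction_outcome: str = "uc_aggressive"
    absrisk_start_age: float = 60.0
    absrisk_horizon: float = 20.0
    adjustment: tuple[str, ...] = DEFAULT_ADJUSTMENT

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError("at least one outcome is required")
        for p in (self.phenotype_csv, self.dosage_tsv, self.weight_tsv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("outcomes", "sensitivity_sbp_cuts", "adjustment"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _build_sim_config(cfg: RunConfig) -> SimConfig:
    raw = dict(cfg.simulation)
    raw.setdefault("seed", cfg.seed)
    if "hazards" in raw:
        raw["hazards"] = {k: GompertzHazard(**v) for k, v in raw["hazards"].items()}
    if "joint_effect" in raw and raw["joint_effect"] is not None:
        raw["joint_effect"] = JointEffect(**raw["joint_effect"])
    return SimConfig(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

        return wrapper

    return deco


@_stage("input")
def _obtain_cohort(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    if cfg.simulate:
        cohort, dosages = simulate_cohort(_build_sim_config(cfg))
        return cohort, dosages
    if cfg.phenotype_csv is None:
        raise ValueError("phenotype_csv required when simulate is false")
    cohort = pd.read_csv(cfg.phenotype_csv, index_col=0)
    cohort.index = cohort.index.astype(str)
    if "exit_age" not in cohort.columns:
        if "followup_years" not in cohort.columns:
            raise ValueError("phenotype table needs exit_age or followup_years")
        cohort["exit_age"] = cohort["entry_age"] + cohort["followup_years"]
    dosages = load_dosages_tsv(cfg.dosage_tsv) if cfg.dosage_tsv else None
    return cohort, dosages


@_stage("grs")
def _score_stage(
    cfg: RunConfig, cohort: pd.DataFrame, dosages: pd.DataFrame | None
) -> tuple[pd.DataFrame, pd.DataFrame | None, int]:
    if dosages is None:
        return cohort, None, 0
    weights = load_weights(cfg.weight_tsv)
    score = assign_groups(standardize(compute_wgrs(dosages, weights)))
    n_missing = score.attrs.get("n_excluded", 0) + int(
        len(cohort) - len(score.index.intersection(cohort.index))
    )
    cohort = cohort.copy()
    cohort["wgrs"] = score["raw_score"].reindex(cohort.index)
    cohort["wgrs_z"] = score["z_score"].reindex(cohort.index)
    return cohort, score, n_missing


@_stage("fit")
def _models_stage(cfg: RunConfig, cohort: pd.DataFrame, have_grs: bool) -> pd.DataFrame:
    exposures = [ExposureSpec("sbp", "categorical"), ExposureSpec("dbp", "categorical")]
    if have_grs:
        exposures.append(ExposureSpec("wgrs", "categorical"))
    return results_table(cohort, cfg.outcomes, exposures, cfg.adjustment)


@_stage("interact")
def _interaction_stage(cfg: RunConfig, cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for bp_var, cut in (("sbp", cfg.sbp_cut), ("dbp", cfg.dbp_cut)):
        for outcome in cfg.outcomes:
            est, fit = reri_analysis(cohort, outcome, bp_var, cut, adjustment=cfg.adjustment)
            summ = fit.summary()
            for grp, term in (
                ("bp_high_only", "joint_10"),
                ("grs_high_only", "joint_01"),
                ("both_high", "joint_11"),
            ):
                rows.append(
                    {
                        "bp_variable": bp_var,
                        "outcome": outcome,
                        "group": grp,
                        "hr": summ.loc[term, "hr"],
                        "ci_lo": summ.loc[term, "ci_lo"],
                        "ci_hi": summ.loc[term, "ci_hi"],
                        "reri": est.reri,
                        "reri_se": est.se,
                        "reri_ci_lo": est.ci95[0],
                        "reri_ci_hi": est.ci95[1],
                        "p_additive": est.p_additive,
                        "p_multiplicative": est.p_multiplicative,
                    }
                )
    fig3 = pd.DataFrame(rows)
    sens = sensitivity_cuts(
        cohort, cfg.interaction_outcome, cfg.sensitivity_sbp_cuts, adjustment=cfg.adjustment
    ).reset_index()
    return fig3, sens


@_stage("absrisk")
def _absrisk_stage(cfg: RunConfig, cohort: pd.DataFrame) -> pd.DataFrame:
    cj = assign_joint_groups(cohort, "sbp", cfg.sbp_cut)
    frames = []
    for outcome in cfg.outcomes:
        tab = group_absolute_risks(
            cj, outcome, start_age=cfg.absrisk_start_age, horizon=cfg.absrisk_horizon
        ).reset_index()
        tab["outcome"] = outcome
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write CSV outputs plus a run manifest.

    Returns the manifest dict; files land in ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, dosages = _obtain_cohort(config)
    n_total = len(cohort)

    cohort, score, n_geno_missing = _score_stage(config, cohort, dosages)
    have_grs = score is not None
    if have_grs:
        score.to_csv(out / "scores.csv")

    covar_cols = [c for c in config.adjustment if c in cohort.columns]
    n_covar_missing = int(cohort[covar_cols].isna().any(axis=1).sum()) if covar_cols else 0

    table3 = _models_stage(config, cohort, have_grs)
    table3.to_csv(out / "hazard_ratios.csv", index=False)

    if have_grs:
        fig3, sens = _interaction_stage(config, cohort)
        fig3.to_csv(out / "interaction.csv", index=False)
        sens.to_csv(out / "sensitivity_cuts.csv", index=False)
        absrisk = _absrisk_stage(config, cohort)
        absrisk.to_csv(out / "absolute_risk.csv", index=False)
    else:
        logger.info("no genotype input: running blood-pressure-only models")

    events = cohort["event"].value_counts().to_dict()
    n_scored = int(cohort["wgrs"].notna().sum()) if have_grs else 0
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_cohort": n_total,
        "n_genotype_missing": int(n_total - n_scored) if have_grs else None,
        "n_covariate_missing": n_covar_missing,
        "n_entering_bp_models": n_total - n_covar_missing,
        "n_entering_genetic_models": (n_scored - n_covar_missing) if have_grs else None,
        "events": {k: int(v) for k, v in events.items()},
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
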