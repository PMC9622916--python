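"""Synthetic cohorts with the structure of a male population-based BP/GRS study.

The generator emulates a cohort of middle-aged men (baseline ages 45-73)
followed ~20 years for incident urothelial carcinoma (UC), split into
non-aggressive and aggressive disease, with death as a competing event:

* genotypes at the 18 panel SNPs drawn independently under Hardy-Weinberg
  equilibrium, dosage ~ Binomial(2, EAF);
* systolic/diastolic blood pressure from a bivariate normal
  (defaults 144/19 and 88/10 mmHg, correlation 0.7);
* lifestyle covariates (smoking 5 levels, BMI quartile, activity tertile,
  education 5 levels) drawn from the source population's category
  frequencies, independent of genotype;
* cause-specific event ages from piecewise-exponential hazards on 1-year
  bands of attained age (Gompertz-shaped defaults), so age acts as the time
  scale with delayed entry at baseline age.

Effects are injected either as per-covariate log hazard ratios or as joint
exposure-group relative risks (RR10, RR01, RR11) on one target cause, in
which case the true additive-interaction RERI = RR11 - RR10 - RR01 + 1 is
known in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grs import SnpWeight, compute_wgrs, load_weights, standardize

__all__ = ["GompertzHazard", "JointEffect", "SimConfig", "simulate_genotypes",
           "simulate_cohort", "summarize_cohort", "category_percentages"]

EVENT_CODES = ("censored", "uc_nonaggressive", "uc_aggressive", "death")

_SMOKING_LEVELS = ["never", "ex", "current_low", "current_mid", "current_high"]
#: never / ex / current smokers 28.2 / 42.9 / 28.9 %, current split into
#: pack-year tertile-like groups 16.9 / 12.0 / 71.1 % of current smokers
_SMOKING_P = (0.282, 0.429, 0.289 * 0.169, 0.289 * 0.120, 0.289 * 0.711)
_EDU_P = (0.459, 0.196, 0.119, 0.093, 0.133)


@dataclass(frozen=True)
class GompertzHazard:
    """Cause-specific hazard h(age) = rate60 * exp(slope * (age - 60))."""

    rate60: float  # events per person-year at age 60
    slope: float = 0.0  # log-hazard increase per year of age

    def at(self, age: np.ndarray) -> np.ndarray:
        return self.rate60 * np.exp(self.slope * (np.asarray(age, dtype=float) - 60.0))


@dataclass(frozen=True)
class JointEffect:
    """Joint-group relative risks on one target cause.

    Groups: reference (normal BP, lower-half wGRS), 10 (high BP only),
    01 (high wGRS only), 11 (both).  True RERI = rr11 - rr10 - rr01 + 1.
    """

    rr10: float = 1.0
    rr01: float = 1.0
    rr11: float = 1.0
    cause: str = "uc_aggressive"
    bp_variable: str = "sbp"
    bp_cut: float = 140.0

    @property
    def true_reri(self) -> float:
        return self.rr11 - self.rr10 - self.rr01 + 1.0


@dataclass(frozen=True)
class SimConfig:
    """All knobs of one simulated cohort; the seed fully determines output."""

    n: int = 10576
    seed: int = 0
    baseline_age_range: tuple[float, float] = (45.0, 73.0)
    baseline_age_mean: float = 59.0
    baseline_age_sd: float = 7.0
    admin_censor_years: float = 27.0
    recruitment_span_years: float = 5.0  # staggered entry shortens max follow-up
    sbp_mean: float = 144.0
    sbp_sd: float = 19.0
    dbp_mean: float = 88.0
    dbp_sd: float = 10.0
    bp_correlation: float = 0.7
    smoking_p: tuple[float, ...] = _SMOKING_P
    education_p: tuple[float, ...] = _EDU_P
    hazards: Mapping[str, GompertzHazard] = field(
        default_factory=lambda: {
            "uc_nonaggressive": GompertzHazard(6.0e-4, 0.06),
            "uc_aggressive": GompertzHazard(2.9e-4, 0.06),
            "death": GompertzHazard(7.0e-3, 0.085),
        }
    )
    #: per-cause log-HR per covariate column, e.g. {"uc_aggressive": {"sbp_z": 0.25}}
    log_hr: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    joint_effect: JointEffect | None = None
    missing_genotype_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for p, name in ((self.smoking_p, "smoking_p"), (self.education_p, "education_p")):
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        for cause, hz in self.hazards.items():
            if hz.rate60 < 0:
                raise ValueError(f"{cause}: hazard rate must be >= 0")


def simulate_genotypes(
    n: int, weights: Sequence[SnpWeight], seed: int | np.random.Generator
) -> pd.DataFrame:
    """HWE genotype dosages: per SNP, dosage ~ Binomial(2, EAF), independent SNPs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = {w.rsid: rng.binomial(2, w.eaf, size=n).astype(float) for w in weights}
    ids = [f"S{i:06d}" for i in range(n)]
    return pd.DataFrame(data, index=pd.Index(ids, name="id"))


def _draw_covariates(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = cfg.baseline_age_range
    a, b = (lo - cfg.baseline_age_mean) / cfg.baseline_age_sd, (
        hi - cfg.baseline_age_mean
    ) / cfg.baseline_age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=cfg.baseline_age_mean, scale=cfg.baseline_age_sd,
        size=cfg.n, random_state=rng,
    )
    cov = np.array(
        [
            [cfg.sbp_sd**2, cfg.bp_correlation * cfg.sbp_sd * cfg.dbp_sd],
            [cfg.bp_correlation * cfg.sbp_sd * cfg.dbp_sd, cfg.dbp_sd**2],
        ]
    )
    bp = rng.multivariate_normal([cfg.sbp_mean, cfg.dbp_mean], cov, size=cfg.n)
    smoking = rng.choice(_SMOKING_LEVELS, size=cfg.n, p=cfg.smoking_p)
    return pd.DataFrame(
        {
            "entry_age": age,
            "sbp": bp[:, 0],
            "dbp": bp[:, 1],
            "smoking": smoking,
            "bmi_quartile": rng.integers(1, 5, size=cfg.n),
            "activity_tertile": rng.integers(1, 4, size=cfg.n),
            "education": rng.choice(np.arange(1, 6), size=cfg.n, p=cfg.education_p),
        },
        index=pd.Index([f"S{i:06d}" for i in range(cfg.n)], name="id"),
    )


def _cause_multipliers(
    cfg: SimConfig, cov: pd.DataFrame, score: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Per-person hazard multipliers for each cause."""
    frame = cov.copy()
    frame["sbp_z"] = (cov["sbp"] - cov["sbp"].mean()) / cov["sbp"].std(ddof=1)
    frame["dbp_z"] = (cov["dbp"] - cov["dbp"].mean()) / cov["dbp"].std(ddof=1)
    if score is not None:
        frame["wgrs_z"] = score["z_score"].reindex(frame.index)
    mult = {c: np.ones(len(frame)) for c in cfg.hazards}
    for cause, terms in cfg.log_hr.items():
        lp = np.zeros(len(frame))
        for col, beta in terms.items():
            lp += beta * frame[col].to_numpy(dtype=float)
        mult[cause] = mult[cause] * np.exp(lp)
    je = cfg.joint_effect
    if je is not None:
        high_bp = cov[je.bp_variable].to_numpy() >= je.bp_cut
        med = np.median(score["raw_score"].reindex(frame.index).to_numpy())
        high_g = score["raw_score"].reindex(frame.index).to_numpy() > med
        rr = np.ones(len(frame))
        rr[high_bp & ~high_g] = je.rr10
        rr[~high_bp & high_g] = je.rr01
        rr[high_bp & high_g] = je.rr11
        mult[je.cause] = mult[je.cause] * rr
    return mult


def simulate_cohort(
    config: SimConfig, weights: Sequence[SnpWeight] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; returns ``(cohort_table, dosage_matrix)``.

    Event ages come from competing piecewise-exponential cause-specific
    hazards evaluated on 1-year bands of attained age; the first of
    {UC event, death, administrative censoring} sets the exit age.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if weights is None:
        weights = load_weights()
    cov = _draw_covariates(cfg, rng)
    dosages = simulate_genotypes(cfg.n, weights, rng)
    score = standardize(compute_wgrs(dosages, weights))

    causes = list(cfg.hazards)
    mult = _cause_multipliers(cfg, cov, score)

    entry = cov["entry_age"].to_numpy()
    horizon = cfg.admin_censor_years - rng.uniform(0, cfg.recruitment_span_years, cfg.n)
    # 1-year bands of attained age covering every possible follow-up age
    lo = np.floor(entry.min())
    hi = np.ceil((entry + horizon).max())
    edges = np.arange(lo, hi + 1.0)
    mids = edges[:-1] + 0.5
    base = np.stack([cfg.hazards[c].at(mids) for c in causes])  # causes x bands
    per_cause = np.stack([np.outer(mult[c], base[k]) for k, c in enumerate(causes)])
    total = per_cause.sum(axis=0)  # n x bands

    # piecewise-linear cumulative hazard from entry; invert at an Exp(1) draw
    dur = np.clip(edges[1:] - np.maximum(entry[:, None], edges[:-1]), 0.0, 1.0)
    dur = np.minimum(dur, np.clip(entry[:, None] + horizon[:, None] - edges[:-1], 0.0, 1.0))
    dur = np.clip(dur, 0.0, None)
    cum = np.cumsum(total * dur, axis=1)
    e_draw = rng.exponential(size=cfg.n)
    crossed = cum >= e_draw[:, None]
    has_event = crossed.any(axis=1)
    band = np.where(has_event, crossed.argmax(axis=1), -1)

    exit_age = entry + horizon
    event = np.full(cfg.n, "censored", dtype=object)
    idx = np.flatnonzero(has_event)
    if idx.size:
        prev = np.where(band[idx] > 0, cum[idx, band[idx] - 1], 0.0)
        need = (e_draw[idx] - prev) / total[idx, band[idx]]
        band_start = np.maximum(entry[idx], edges[band[idx]])
        t_event = band_start + need
        exit_age[idx] = t_event
        probs = per_cause[:, idx, band[idx]] / total[idx, band[idx]]
        u = rng.random(idx.size)
        cdf = np.cumsum(probs, axis=0)
        which = (u[None, :] > cdf).sum(axis=0)
        event[idx] = np.array(causes, dtype=object)[which]

    frac_year1 = float((exit_age - entry < 1.0).mean())
    if frac_year1 > 0.99:
        warnings.warn("hazards so large that >99% of the cohort fails within 1 year")

    cohort = cov.copy()
    cohort["exit_age"] = exit_age
    cohort["event"] = event
    cohort["wgrs"] = score["raw_score"].reindex(cohort.index)
    cohort["wgrs_z"] = score["z_score"].reindex(cohort.index)

    if cfg.missing_genotype_rate > 0:
        drop = rng.random(cfg.n) < cfg.missing_genotype_rate
        dosages = dosages.copy()
        dosages.iloc[np.flatnonzero(drop), 0] = np.nan
        cohort.loc[drop, ["wgrs", "wgrs_z"]] = np.nan
    return cohort, dosages


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Case/non-case descriptive table: counts, category %, mean (SD) rows."""
    if cohort.empty:
        raise ValueError("empty cohort")
    is_case = cohort["event"].isin(("uc_nonaggressive", "uc_aggressive"))
    groups = {"cases": cohort[is_case], "non_cases": cohort[~is_case], "total": cohort}
    rows = []
    rows.append(("population_n", *[len(g) for g in groups.values()]))
    for var in ("entry_age", "sbp", "dbp"):
        rows.append(
            (f"{var}_mean", *[g[var].mean() if len(g) else np.nan for g in groups.values()])
        )
        rows.append(
            (f"{var}_sd", *[g[var].std(ddof=1) if len(g) > 1 else np.nan for g in groups.values()])
        )
    fu = cohort["exit_age"] - cohort["entry_age"]
    rows.append(("followup_mean", *[
        fu[is_case].mean() if is_case.any() else np.nan,
        fu[~is_case].mean() if (~is_case).any() else np.nan,
        fu.mean(),
    ]))
    for var in ("smoking", "bmi_quartile", "activity_tertile", "education", "event"):
        levels = sorted(cohort[var].unique(), key=str)
        for lev in levels:
            vals = []
            for g in groups.values():
                vals.append(100.0 * (g[var] == lev).mean() if len(g) else np.nan)
            rows.append((f"{var}={lev}_pct", *vals))
    return pd.DataFrame(rows, columns=["row", "cases", "non_cases", "total"]).set_index("row")


def category_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentages of a count breakdown (used for descriptive tables)."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return {k: 100.0 * v / total for k, v in counts.items()}
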