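"""Additive and multiplicative gene-environment interaction inference.

Additive interaction between a binary blood-pressure exposure and a binary
(median-split) genetic-risk-score exposure is quantified by the relative
excess risk due to interaction,

    RERI = RR11 - RR10 - RR01 + 1,

where the joint-group relative risks come from exponentiated cause-specific
Cox coefficients: the reference group has normal BP and lower-half wGRS,
group 10 high BP only, group 01 high wGRS only, group 11 both.  RERI > 0
means the joint effect exceeds the sum of the separate effects
(super-additivity).  Confidence intervals use the Hosmer-Lemeshow delta
method on the RR scale: Var(RERI) = g' Sigma g with gradient
g = (-RR10, -RR01, RR11) over the (b10, b01, b11) coefficient block.

Multiplicative interaction is a likelihood-ratio test of the product term:
the restricted model (main effects) is nested in the full model that adds
the product.

A continuous-scale variant expresses both exposures as z-scores, restricts
the sample to |z| <= 2 on both, fits main effects plus product, and
evaluates RERI at increments (delta1, delta2) above the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survival import DEFAULT_ADJUSTMENT, ConvergenceError, CoxFit, fit_cox, fit_cox_arrays

__all__ = [
    "ReriEstimate",
    "assign_joint_groups",
    "reri_binary",
    "reri_continuous",
    "lr_test_multiplicative",
    "reri_analysis",
    "continuous_reri_analysis",
    "sensitivity_cuts",
    "bootstrap_reri",
]

_Z95 = 1.959963984540054

JOINT_TERMS = ("joint_10", "joint_01", "joint_11")


@dataclass(frozen=True)
class ReriEstimate:
    """RERI point estimate with delta-method uncertainty and the three RRs."""

    rr10: float
    rr01: float
    rr11: float
    reri: float
    se: float
    ci95: tuple[float, float]
    p_additive: float
    p_multiplicative: float | None = None
    n_events: int | None = None

    def __post_init__(self) -> None:
        expected = self.rr11 - self.rr10 - self.rr01 + 1.0
        if abs(self.reri - expected) > 1e-9:
            raise ValueError("reri must equal rr11 - rr10 - rr01 + 1")


def assign_joint_groups(
    cohort: pd.DataFrame,
    bp_variable: str = "sbp",
    bp_cut: float = 140.0,
    grs_column: str = "wgrs",
) -> pd.DataFrame:
    """Add joint-exposure indicator columns to a cohort copy.

    High BP is ``bp >= cut``; high genetic risk is above the sample median of
    the score among individuals with a non-missing score.  The four groups
    partition the scored sample; rows without a score get NaN indicators.
    """
    bp = cohort[bp_variable].to_numpy(dtype=float)
    if not (np.nanmin(bp) <= bp_cut <= np.nanmax(bp)):
        raise ValueError(f"BP cut {bp_cut} lies outside the observed {bp_variable} range")
    g = cohort[grs_column].to_numpy(dtype=float)
    scored = np.isfinite(g) & np.isfinite(bp)
    med = np.median(g[scored])
    high_bp = bp >= bp_cut
    high_g = g > med
    out = cohort.copy()
    for name, mask in (
        ("joint_10", high_bp & ~high_g),
        ("joint_01", ~high_bp & high_g),
        ("joint_11", high_bp & high_g),
    ):
        col = np.where(scored, mask.astype(float), np.nan)
        out[name] = col
    counts = {
        "ref": int((scored & ~high_bp & ~high_g).sum()),
        "10": int((scored & high_bp & ~high_g).sum()),
        "01": int((scored & ~high_bp & high_g).sum()),
        "11": int((scored & high_bp & high_g).sum()),
    }
    empty = [k for k, v in counts.items() if v == 0]
    if empty:
        raise ValueError(f"empty joint exposure group(s) at cut {bp_cut}: {empty}")
    out.attrs["joint_group_counts"] = counts
    return out


def _joint_block(fit: CoxFit) -> tuple[np.ndarray, np.ndarray]:
    try:
        idx = [fit.terms.index(t) for t in JOINT_TERMS]
    except ValueError as err:
        raise ValueError(f"fit lacks joint-group terms {JOINT_TERMS}: {err}") from err
    b = fit.coef[idx]
    sub = fit.cov[np.ix_(idx, idx)]
    return b, sub


def reri_binary(fit: CoxFit, p_multiplicative: float | None = None) -> ReriEstimate:
    """RERI with Hosmer-Lemeshow delta-method CI from a joint-group fit.

    The fit must contain the three indicator terms ``joint_10``, ``joint_01``,
    ``joint_11`` (reference = unexposed to both).
    """
    (b10, b01, b11), sub = _joint_block(fit)
    rr10, rr01, rr11 = np.exp([b10, b01, b11])
    reri = rr11 - rr10 - rr01 + 1.0
    grad = np.array([-rr10, -rr01, rr11])
    var = float(grad @ sub @ grad)
    if var <= 0 or not np.isfinite(var):
        raise ValueError("singular or invalid joint-coefficient covariance")
    se = float(np.sqrt(var))
    z = reri / se
    return ReriEstimate(
        rr10=float(rr10),
        rr01=float(rr01),
        rr11=float(rr11),
        reri=float(reri),
        se=se,
        ci95=(float(reri - _Z95 * se), float(reri + _Z95 * se)),
        p_additive=float(2 * stats.norm.sf(abs(z))),
        p_multiplicative=p_multiplicative,
        n_events=fit.n_events,
    )


def reri_continuous(
    fit: CoxFit,
    terms: Sequence[str] = ("z1", "z2", "z1_z2"),
    delta1: float = 1.0,
    delta2: float = 1.0,
    p_multiplicative: float | None = None,
) -> ReriEstimate:
    """RERI for continuous exposures at increments (delta1, delta2) SD.

    With coefficients (b1, b2, b3) for z1, z2 and their product,

        RERI = exp(b1 d1 + b2 d2 + b3 d1 d2) - exp(b1 d1) - exp(b2 d2) + 1.
    """
    if delta1 <= 0 or delta2 <= 0:
        raise ValueError("increments must be > 0")
    idx = [fit.terms.index(t) for t in terms]
    b1, b2, b3 = fit.coef[idx]
    sub = fit.cov[np.ix_(idx, idx)]
    d1, d2 = delta1, delta2
    rr11 = float(np.exp(b1 * d1 + b2 * d2 + b3 * d1 * d2))
    rr10 = float(np.exp(b1 * d1))
    rr01 = float(np.exp(b2 * d2))
    reri = rr11 - rr10 - rr01 + 1.0
    grad = np.array([d1 * (rr11 - rr10), d2 * (rr11 - rr01), d1 * d2 * rr11])
    var = float(grad @ sub @ grad)
    if var <= 0 or not np.isfinite(var):
        raise ValueError("invalid coefficient covariance for delta method")
    se = float(np.sqrt(var))
    z = reri / se
    return ReriEstimate(
        rr10=rr10,
        rr01=rr01,
        rr11=rr11,
        reri=float(reri),
        se=se,
        ci95=(float(reri - _Z95 * se), float(reri + _Z95 * se)),
        p_additive=float(2 * stats.norm.sf(abs(z))),
        p_multiplicative=p_multiplicative,
        n_events=fit.n_events,
    )


def lr_test_multiplicative(restricted: CoxFit, full: CoxFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of the product term(s): returns (stat, df, p).

    The restricted model must be nested in the full model (same analysis
    sample, term set a strict subset).
    """
    if restricted.n != full.n or restricted.n_events != full.n_events:
        raise ValueError(
            f"models fit on different samples: n {restricted.n} vs {full.n}, "
            f"events {restricted.n_events} vs {full.n_events}"
        )
    extra = [t for t in full.terms if t not in restricted.terms]
    if not extra or any(t not in full.terms for t in restricted.terms):
        raise ValueError("restricted terms must be a strict subset of full terms")
    stat = 2.0 * (full.loglik - restricted.loglik)
    if stat < -1e-6:
        raise ValueError(f"full model has lower likelihood ({stat=}); models not nested")
    stat = max(stat, 0.0)
    df = len(extra)
    return float(stat), df, float(stats.chi2.sf(stat, df))


def _multiplicative_p(
    cohort_j: pd.DataFrame, outcome: str, adjustment: Sequence[str]
) -> float:
    """LR p for the product term using the equivalent main-effects coding."""
    work = cohort_j.copy()
    work["bp_high"] = cohort_j[["joint_10", "joint_11"]].sum(axis=1, min_count=1)
    work["grs_high"] = cohort_j[["joint_01", "joint_11"]].sum(axis=1, min_count=1)
    restricted = fit_cox(
        work, None, outcome, adjustment, extra_terms=("bp_high", "grs_high")
    )
    # the joint-indicator model is a reparametrization of main effects + product
    full = fit_cox(work, None, outcome, adjustment, extra_terms=list(JOINT_TERMS))
    stat = 2.0 * (full.loglik - restricted.loglik)
    return float(stats.chi2.sf(max(stat, 0.0), 1))


def reri_analysis(
    cohort: pd.DataFrame,
    outcome: str,
    bp_variable: str = "sbp",
    bp_cut: float = 140.0,
    grs_column: str = "wgrs",
    adjustment: Sequence[str] = DEFAULT_ADJUSTMENT,
) -> tuple[ReriEstimate, CoxFit]:
    """Full binary-exposure interaction analysis for one outcome.

    Builds the joint-group design (BP cut x median wGRS split), fits the
    adjusted cause-specific Cox model, and returns the RERI estimate
    (including the multiplicative LR p) plus the underlying fit.
    """
    cj = assign_joint_groups(cohort, bp_variable, bp_cut, grs_column)
    fit = fit_cox(cj, None, outcome, adjustment, extra_terms=list(JOINT_TERMS))
    p_mult = _multiplicative_p(cj, outcome, adjustment)
    return reri_binary(fit, p_multiplicative=p_mult), fit


def continuous_reri_analysis(
    cohort: pd.DataFrame,
    outcome: str,
    bp_variable: str = "sbp",
    grs_column: str = "wgrs",
    adjustment: Sequence[str] = DEFAULT_ADJUSTMENT,
    delta1: float = 1.0,
    delta2: float = 1.0,
    sd_limit: float = 2.0,
) -> tuple[ReriEstimate, CoxFit]:
    """Continuous-scale RERI: z-scored exposures, sample limited to |z| <= 2.

    Both exposures are z-scored on the analysis sample, the sample is
    restricted to observations within ``sd_limit`` SDs on both (jointly),
    and RERI is evaluated at (+delta1, +delta2) SD from the mean.
    """
    work = cohort.loc[cohort[[bp_variable, grs_column]].notna().all(axis=1)].copy()
    for src, dst in ((bp_variable, "z1"), (grs_column, "z2")):
        x = work[src].to_numpy(dtype=float)
        work[dst] = (x - x.mean()) / x.std(ddof=1)
    work = work.loc[(work["z1"].abs() <= sd_limit) & (work["z2"].abs() <= sd_limit)]
    work["z1_z2"] = work["z1"] * work["z2"]
    full = fit_cox(work, None, outcome, adjustment, extra_terms=("z1", "z2", "z1_z2"))
    restricted = fit_cox(work, None, outcome, adjustment, extra_terms=("z1", "z2"))
    _, _, p_mult = lr_test_multiplicative(restricted, full)
    est = reri_continuous(full, ("z1", "z2", "z1_z2"), delta1, delta2, p_mult)
    return est, full


def sensitivity_cuts(
    cohort: pd.DataFrame,
    outcome: str,
    cuts: Sequence[float],
    bp_variable: str = "sbp",
    grs_column: str = "wgrs",
    adjustment: Sequence[str] = DEFAULT_ADJUSTMENT,
) -> pd.DataFrame:
    """Repeat the binary RERI analysis at alternative BP thresholds.

    The median wGRS split is held fixed; one row per cut with the RERI
    estimate, CI and both interaction p-values.
    """
    rows = []
    for cut in cuts:
        est, _ = reri_analysis(cohort, outcome, bp_variable, cut, grs_column, adjustment)
        rows.append(
            {
                "cut": cut,
                "rr10": est.rr10,
                "rr01": est.rr01,
                "rr11": est.rr11,
                "reri": est.reri,
                "se": est.se,
                "ci_lo": est.ci95[0],
                "ci_hi": est.ci95[1],
                "p_additive": est.p_additive,
                "p_multiplicative": est.p_multiplicative,
            }
        )
    return pd.DataFrame(rows).set_index("cut")


def bootstrap_reri(
    cohort: pd.DataFrame,
    outcome: str,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
    bp_variable: str = "sbp",
    bp_cut: float = 140.0,
    grs_column: str = "wgrs",
    adjustment: Sequence[str] = (),
) -> np.ndarray:
    """Nonparametric bootstrap replicates of RERI (resampling individuals).

    A cross-check on the delta-method SE; replicates that fail to converge
    are skipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(cohort)
    out = []
    if not adjustment:
        # fast path on raw arrays; the median split is re-estimated per replicate
        from .survival import event_indicator

        bp = cohort[bp_variable].to_numpy(dtype=float)
        g = cohort[grs_column].to_numpy(dtype=float)
        entry = cohort["entry_age"].to_numpy(dtype=float)
        exit_ = cohort["exit_age"].to_numpy(dtype=float)
        ev = event_indicator(cohort, outcome)
        ok = np.isfinite(bp) & np.isfinite(g)
        bp, g, entry, exit_, ev = bp[ok], g[ok], entry[ok], exit_[ok], ev[ok]
        m = len(bp)
        warm = None
        for _ in range(n_boot):
            idx = rng.integers(0, m, size=m)
            b, gg = bp[idx], g[idx]
            hb = b >= bp_cut
            hg = gg > np.median(gg)
            X = np.column_stack([hb & ~hg, ~hb & hg, hb & hg]).astype(float)
            try:
                fit = fit_cox_arrays(
                    X, entry[idx], exit_[idx], ev[idx], terms=list(JOINT_TERMS),
                    init=warm,
                )
                warm = fit.coef
                out.append(reri_binary(fit).reri)
            except (ValueError, ConvergenceError):
                continue
        return np.asarray(out)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = cohort.iloc[idx].reset_index(drop=True)
        try:
            cj = assign_joint_groups(boot, bp_variable, bp_cut, grs_column)
            fit = fit_cox(cj, None, outcome, adjustment, extra_terms=list(JOINT_TERMS))
            out.append(reri_binary(fit).reri)
        except (ValueError, ConvergenceError):
            continue
    return np.asarray(out)
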