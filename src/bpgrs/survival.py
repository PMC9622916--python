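"""Cause-specific Cox proportional-hazards models on the age time scale.

Attained age is the time metric: a person enters the risk set at baseline
age (left truncation / delayed entry) and leaves at the age of their first
event or censoring.  Competing events are censored at their event age, so
each fit targets one cause-specific hazard.  The partial likelihood is
maximized by Newton-Raphson with Efron's correction for tied event ages.

The engine is vectorized over risk sets via the counting-process identity

    sum_{i in R(t)} f_i = sum_{exit_i >= t} f_i - sum_{entry_i >= t} f_i

(valid because entry < exit for everyone), so each Newton iteration costs
O(n p^2) after two sorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExposureSpec",
    "CoxFit",
    "ConvergenceError",
    "SBP_EDGES",
    "DBP_EDGES",
    "DEFAULT_ADJUSTMENT",
    "event_indicator",
    "cox_loglik",
    "fit_cox_arrays",
    "fit_cox",
    "trend_test",
    "ph_check",
    "results_table",
]

#: exposure category edges (lower bound of each non-reference category), mmHg
SBP_EDGES = (140.0, 150.0, 160.0)
DBP_EDGES = (90.0, 95.0, 100.0)

#: adjustment set of the main cohort models
DEFAULT_ADJUSTMENT = ("smoking", "bmi_quartile", "activity_tertile", "education")

_ADJ_LEVELS = {
    "smoking": ["never", "ex", "current_low", "current_mid", "current_high"],
    "bmi_quartile": [1, 2, 3, 4],
    "activity_tertile": [1, 2, 3],
    "education": [1, 2, 3, 4, 5],
}

OUTCOMES = ("uc_total", "uc_nonaggressive", "uc_aggressive", "death")


class ConvergenceError(RuntimeError):
    """Raised when Newton-Raphson fails to converge (or data are separated)."""


@dataclass(frozen=True)
class ExposureSpec:
    """How an exposure enters the model: per-SD continuous or categorical."""

    variable: Literal["sbp", "dbp", "wgrs"]
    form: Literal["per_sd", "categorical"] = "per_sd"
    edges: tuple[float, ...] | None = None

    def resolved_edges(self, values: np.ndarray) -> np.ndarray:
        if self.edges is not None:
            e = np.asarray(self.edges, dtype=float)
        elif self.variable == "sbp":
            e = np.asarray(SBP_EDGES)
        elif self.variable == "dbp":
            e = np.asarray(DBP_EDGES)
        else:  # wGRS: quartile cut points from the analysis sample
            e = np.percentile(values, [25, 50, 75])
        if np.any(np.diff(e) <= 0):
            raise ValueError("category edges must be strictly increasing")
        return e


@dataclass
class CoxFit:
    """Result of one cause-specific partial-likelihood fit."""

    terms: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    n_events: int
    outcome: str
    exposure_terms: list[str] = field(default_factory=list)
    _data: dict | None = field(default=None, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> pd.DataFrame:
        """HRs with 95% CIs and Wald p-values per term."""
        se = self.se
        z = self.coef / se
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": se,
                "hr": np.exp(self.coef),
                "ci_lo": np.exp(self.coef - 1.959963984540054 * se),
                "ci_hi": np.exp(self.coef + 1.959963984540054 * se),
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=pd.Index(self.terms, name="term"),
        )


def event_indicator(cohort: pd.DataFrame, outcome: str) -> np.ndarray:
    """0/1 indicator of the target cause; competing events count as censored."""
    ev = cohort["event"].to_numpy()
    if outcome == "uc_total":
        return np.isin(ev, ("uc_nonaggressive", "uc_aggressive")).astype(np.int8)
    if outcome in ("uc_nonaggressive", "uc_aggressive", "death"):
        return (ev == outcome).astype(np.int8)
    raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")


# ---------------------------------------------------------------------------
# partial-likelihood engine


def _suffix_sums(keys: np.ndarray, values: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """sum_{keys_i >= t} values_i for each threshold t; keys must be sorted."""
    c = np.zeros((len(keys) + 1,) + values.shape[1:])
    c[:-1] = np.cumsum(values[::-1], axis=0)[::-1]
    pos = np.searchsorted(keys, thresholds, side="left")
    return c[pos]


def cox_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    entry: np.ndarray,
    exit_: np.ndarray,
    event: np.ndarray,
    ties: Literal["efron", "breslow"] = "efron",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and Hessian at ``beta``.

    Returns ``(loglik, gradient, hessian)`` where the Hessian is negative
    semi-definite.  ``entry < exit`` is required for every row.
    """
    beta = np.asarray(beta, dtype=float)
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard exp overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    xw = X * w[:, None]
    xxw = X[:, :, None] * xw[:, None, :]

    ex_order = np.argsort(exit_, kind="stable")
    en_order = np.argsort(entry, kind="stable")
    ev = event.astype(bool)
    times, d = np.unique(exit_[ev], return_counts=True)

    S0 = _suffix_sums(exit_[ex_order], w[ex_order], times) - _suffix_sums(
        entry[en_order], w[en_order], times
    )
    S1 = _suffix_sums(exit_[ex_order], xw[ex_order], times) - _suffix_sums(
        entry[en_order], xw[en_order], times
    )
    S2 = _suffix_sums(exit_[ex_order], xxw[ex_order], times) - _suffix_sums(
        entry[en_order], xxw[en_order], times
    )

    # per-event-time sums over the tied death set
    ev_idx = np.flatnonzero(ev)
    ev_sort = ev_idx[np.argsort(exit_[ev_idx], kind="stable")]
    bounds = np.concatenate(([0], np.cumsum(d)[:-1]))
    sum_eta_D = np.add.reduceat(eta[ev_sort], bounds)
    sum_x_D = np.add.reduceat(X[ev_sort], bounds, axis=0)
    S0D = np.add.reduceat(w[ev_sort], bounds)
    S1D = np.add.reduceat(xw[ev_sort], bounds, axis=0)
    S2D = np.add.reduceat(xxw[ev_sort], bounds, axis=0)

    ll = float(sum_eta_D.sum())
    grad = sum_x_D.sum(axis=0)
    hess = np.zeros((p, p))

    singles = d == 1
    # untied (or Breslow) event times: fully vectorized
    if ties == "efron":
        mask = singles
        S0m, S1m, S2m, dm = S0[mask], S1[mask], S2[mask], d[mask]
    else:
        mask = np.ones_like(singles)
        S0m, S1m, S2m, dm = S0, S1, S2, d
    if S0m.size:
        m1 = S1m / S0m[:, None]
        ll -= float((dm * np.log(S0m)).sum())
        grad -= (dm[:, None] * m1).sum(axis=0)
        hess -= np.einsum(
            "j,jkl->kl", dm.astype(float), S2m / S0m[:, None, None] - m1[:, :, None] * m1[:, None, :]
        )

    if ties == "efron" and not singles.all():
        for j in np.flatnonzero(~singles):
            dj = d[j]
            f = np.arange(dj) / dj
            s0 = S0[j] - f * S0D[j]
            s1 = S1[j][None, :] - f[:, None] * S1D[j][None, :]
            s2 = S2[j][None, :, :] - f[:, None, None] * S2D[j][None, :, :]
            m1 = s1 / s0[:, None]
            ll -= float(np.log(s0).sum())
            grad -= m1.sum(axis=0)
            hess -= (s2 / s0[:, None, None] - m1[:, :, None] * m1[:, None, :]).sum(axis=0)

    return ll, grad, hess


def fit_cox_arrays(
    X: np.ndarray,
    entry: np.ndarray,
    exit_: np.ndarray,
    event: np.ndarray,
    terms: Sequence[str] | None = None,
    outcome: str = "",
    tol: float = 1e-9,
    max_iter: int = 100,
    ties: Literal["efron", "breslow"] = "efron",
    init: np.ndarray | None = None,
) -> CoxFit:
    """Newton-Raphson maximization of the Efron partial likelihood."""
    X = np.asarray(X, dtype=float)
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    event = np.asarray(event)
    n, p = X.shape
    if np.any(exit_ <= entry):
        raise ValueError("every exit age must exceed the entry age")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events of the target outcome; cannot fit")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        dead = [i for i, s in enumerate(sds) if s == 0]
        names = [terms[i] for i in dead] if terms else dead
        raise ValueError(f"constant (collinear) design columns: {names}")

    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    ll, grad, hess = cox_loglik(beta, X, entry, exit_, event, ties)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}") from err
        # step-halving keeps the likelihood monotone
        for _ in range(30):
            cand = beta + step
            ll_new, grad_new, hess_new = cox_loglik(cand, X, entry, exit_, event, ties)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2
        delta = np.max(np.abs(cand - beta))
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > 20:  # |log HR| > 20 is never a real effect
            raise ConvergenceError(
                "coefficients diverging (monotone likelihood / complete separation)"
            )
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations; |gradient| = {np.abs(grad).max():.3g}"
        )
    cov = np.linalg.inv(-hess)
    return CoxFit(
        terms=list(terms) if terms is not None else [f"x{i}" for i in range(p)],
        coef=beta,
        cov=cov,
        loglik=ll,
        n=n,
        n_events=n_events,
        outcome=outcome,
        _data={"X": X, "entry": entry, "exit": exit_, "event": event.astype(bool)},
    )


# ---------------------------------------------------------------------------
# design-matrix construction on a cohort table


def _adjustment_dummies(cohort: pd.DataFrame, adjustment: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for var in adjustment:
        if var not in _ADJ_LEVELS:
            raise ValueError(f"unknown adjustment covariate {var!r}")
        levels = _ADJ_LEVELS[var]
        vals = cohort[var]
        bad = ~vals.isin(levels) & vals.notna()
        if bad.any():
            raise ValueError(f"{var}: values outside level set: {sorted(vals[bad].unique())}")
        for lev in levels[1:]:  # lowest level is the reference
            cols[f"{var}_{lev}"] = (vals == lev).astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def _exposure_columns(
    cohort: pd.DataFrame, exposure: ExposureSpec
) -> tuple[pd.DataFrame, list[str]]:
    x = cohort[exposure.variable].to_numpy(dtype=float)
    if exposure.form == "per_sd":
        sd = np.nanstd(x, ddof=1)
        if sd == 0:
            raise ValueError(f"{exposure.variable}: zero variance")
        col = f"{exposure.variable}_per_sd"
        return pd.DataFrame({col: (x - np.nanmean(x)) / sd}, index=cohort.index), [col]
    edges = exposure.resolved_edges(x[np.isfinite(x)])
    cat = np.searchsorted(edges, x, side="left")  # value == edge goes to the lower category
    names = [f"{exposure.variable}_cat{k + 1}" for k in range(1, len(edges) + 1)]
    cols = {nm: (cat == k + 1).astype(float) for k, nm in enumerate(names)}
    df = pd.DataFrame(cols, index=cohort.index)
    df[f"_{exposure.variable}_ordinal"] = cat + 1.0  # 1..k, used by the trend test
    return df, names


def _assemble(
    cohort: pd.DataFrame,
    exposure: ExposureSpec | None,
    adjustment: Sequence[str],
    extra_terms: Sequence[str] = (),
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Complete-case design frame + (all term names, exposure term names)."""
    used = list(extra_terms)
    if exposure is not None:
        used.append(exposure.variable)
    used += list(adjustment)
    keep = cohort[used].notna().all(axis=1) if used else pd.Series(True, index=cohort.index)
    sub = cohort.loc[keep]
    parts = []
    exp_terms: list[str] = []
    if exposure is not None:
        edf, exp_terms = _exposure_columns(sub, exposure)
        parts.append(edf)
    if extra_terms:
        parts.append(sub[list(extra_terms)].astype(float))
        exp_terms = list(extra_terms) + exp_terms
    if adjustment:
        parts.append(_adjustment_dummies(sub, adjustment))
    design = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=sub.index)
    design["_entry"] = sub["entry_age"].to_numpy(dtype=float)
    design["_exit"] = sub["exit_age"].to_numpy(dtype=float)
    terms = [c for c in design.columns if not c.startswith("_")]
    design["_event_source"] = sub["event"].to_numpy()
    return design, terms, exp_terms


def fit_cox(
    cohort: pd.DataFrame,
    exposure: ExposureSpec | None,
    outcome: str,
    adjustment: Sequence[str] = DEFAULT_ADJUSTMENT,
    extra_terms: Sequence[str] = (),
    ties: Literal["efron", "breslow"] = "efron",
) -> CoxFit:
    """Fit one adjusted cause-specific model.

    ``exposure`` may be ``None`` when the model consists only of
    ``extra_terms`` (e.g. joint-exposure indicator columns) plus adjustment.
    Rows with a missing value in any used covariate are dropped
    (complete-case per model).
    """
    design, terms, exp_terms = _assemble(cohort, exposure, adjustment, extra_terms)
    ev = event_indicator(design.rename(columns={"_event_source": "event"}), outcome)
    fit = fit_cox_arrays(
        design[terms].to_numpy(dtype=float),
        design["_entry"].to_numpy(),
        design["_exit"].to_numpy(),
        ev,
        terms=terms,
        outcome=outcome,
        ties=ties,
    )
    fit.exposure_terms = exp_terms
    return fit


def trend_test(
    cohort: pd.DataFrame,
    exposure: ExposureSpec,
    outcome: str,
    adjustment: Sequence[str] = DEFAULT_ADJUSTMENT,
) -> tuple[float, float]:
    """Wald test for linear trend across ordered exposure categories.

    The category index (1..k) enters the model as a single continuous term;
    returns ``(z, p)`` for its coefficient.
    """
    if exposure.form != "categorical":
        raise ValueError("trend test requires a categorical exposure")
    design, terms, _ = _assemble(cohort, exposure, adjustment)
    ord_col = f"_{exposure.variable}_ordinal"
    ordvals = design[ord_col].to_numpy()
    if len(np.unique(ordvals)) < 3:
        raise ValueError("trend test needs at least 3 occupied ordered categories")
    keep_terms = [t for t in terms if not t.startswith(exposure.variable + "_cat")]
    design = design.rename(columns={ord_col: "trend"})
    ev = event_indicator(design.rename(columns={"_event_source": "event"}), outcome)
    fit = fit_cox_arrays(
        design[["trend"] + keep_terms].to_numpy(dtype=float),
        design["_entry"].to_numpy(),
        design["_exit"].to_numpy(),
        ev,
        terms=["trend"] + keep_terms,
        outcome=outcome,
    )
    z = fit.coef[0] / fit.se[0]
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics


def schoenfeld_residuals(fit: CoxFit) -> tuple[np.ndarray, np.ndarray]:
    """Per-event Schoenfeld residuals and their event ages.

    Residual for a death at age t is x_i - E[x | R(t)] with the expectation
    under the fitted model.  Residuals sum to ~0 over events (score equation).
    """
    if fit._data is None:
        raise ValueError("fit carries no data; refit with the package engine")
    X = fit._data["X"]
    entry, exit_, event = fit._data["entry"], fit._data["exit"], fit._data["event"]
    w = np.exp(X @ fit.coef - (X @ fit.coef).max())
    xw = X * w[:, None]
    ex_order = np.argsort(exit_, kind="stable")
    en_order = np.argsort(entry, kind="stable")
    ev_idx = np.flatnonzero(event)
    ev_idx = ev_idx[np.argsort(exit_[ev_idx], kind="stable")]
    t = exit_[ev_idx]
    S0 = _suffix_sums(exit_[ex_order], w[ex_order], t) - _suffix_sums(
        entry[en_order], w[en_order], t
    )
    S1 = _suffix_sums(exit_[ex_order], xw[ex_order], t) - _suffix_sums(
        entry[en_order], xw[en_order], t
    )
    resid = X[ev_idx] - S1 / S0[:, None]
    return resid, t


def ph_check(
    fit: CoxFit,
    transform: Literal["identity", "rank", "km"] = "rank",
) -> pd.DataFrame:
    """Grambsch-Therneau test of proportional hazards from Schoenfeld residuals.

    Correlates scaled residuals with a transform of event age; returns one
    chi-square and p-value per term plus a GLOBAL row.  Violations should be
    logged by callers, not raised: the test is a diagnostic.
    """
    resid, t = schoenfeld_residuals(fit)
    d = len(t)
    if d < 2:
        raise ValueError("proportional-hazards check needs at least 2 events")
    if transform == "identity":
        g = t.astype(float)
    elif transform == "rank":
        g = stats.rankdata(t)
    elif transform == "km":
        # left-continuous KM of the censoring-inclusive survival at event ages
        g = _km_transform(fit, t)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    g = g - g.mean()
    gg = float((g**2).sum())
    info_inv = fit.cov  # inverse information
    u = resid.T @ g
    su = info_inv @ u  # transform of the scaled residuals
    rows = []
    for j, term in enumerate(fit.terms):
        chi = d * su[j] ** 2 / (info_inv[j, j] * gg)
        rows.append((term, chi, 1, stats.chi2.sf(chi, 1)))
    chi_g = float(u @ info_inv @ u) * d / gg
    rows.append(("GLOBAL", chi_g, len(fit.terms), stats.chi2.sf(chi_g, len(fit.terms))))
    return pd.DataFrame(rows, columns=["term", "chi2", "df", "p"]).set_index("term")


def _km_transform(fit: CoxFit, event_times: np.ndarray) -> np.ndarray:
    entry = fit._data["entry"]
    exit_ = fit._data["exit"]
    event = fit._data["event"]
    times, d = np.unique(exit_[event], return_counts=True)
    at_risk = (entry[None, :] < times[:, None]) & (exit_[None, :] >= times[:, None])
    n_risk = at_risk.sum(axis=1)
    km = np.cumprod(1.0 - d / n_risk)
    km_left = np.concatenate(([1.0], km[:-1]))  # S(t-)
    return 1.0 - km_left[np.searchsorted(times, event_times)]


def results_table(
    cohort: pd.DataFrame,
    outcomes: Sequence[str],
    exposures: Sequence[ExposureSpec],
    adjustment: Sequence[str] = DEFAULT_ADJUSTMENT,
) -> pd.DataFrame:
    """Categorical + per-SD hazard ratios with trend p, per exposure and outcome.

    The tabular layout of a main-results table: one row per exposure category
    (reference row HR 1.00) and a per-SD row, columns per outcome.
    """
    frames = []
    for expo in exposures:
        for outc in outcomes:
            cat_spec = ExposureSpec(expo.variable, "categorical", expo.edges)
            fit_cat = fit_cox(cohort, cat_spec, outc, adjustment)
            _, p_trend = trend_test(cohort, cat_spec, outc, adjustment)
            fit_sd = fit_cox(cohort, ExposureSpec(expo.variable, "per_sd"), outc, adjustment)
            summ = fit_cat.summary().loc[fit_cat.exposure_terms]
            ref = pd.DataFrame(
                {"hr": [1.0], "ci_lo": [np.nan], "ci_hi": [np.nan]},
                index=[f"{expo.variable}_cat1"],
            )
            sd_row = fit_sd.summary().loc[fit_sd.exposure_terms]
            block = pd.concat([ref, summ[["hr", "ci_lo", "ci_hi"]], sd_row[["hr", "ci_lo", "ci_hi"]]])
            block["exposure"] = expo.variable
            block["outcome"] = outc
            block["p_trend"] = p_trend
            block["n_events"] = fit_cat.n_events
            frames.append(block.rename_axis("term").reset_index())
    return pd.concat(frames, ignore_index=True)
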