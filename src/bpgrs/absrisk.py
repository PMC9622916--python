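"""Absolute (crude) risk of urothelial carcinoma with death as a competing event.

Cause-specific hazards are estimated nonparametrically as occurrence /
exposure rates on 1-year bands of attained age, within an exposure group,
then combined by the piecewise-exponential competing-risk integral:

    risk(a0, h) = sum_j  h1_j * exp(-sum_{k<j} (h1_k + h2_k) w_k)
                        * (1 - exp(-(h1_j + h2_j) w_j)) / (h1_j + h2_j)

over the bands j covering [a0, a0 + h), where h1 is the outcome hazard,
h2 the competing-death hazard and w_j the band width.  Within each band the
hazards are constant, so the integral is exact (a band with h1 + h2 = 0
contributes nothing).  The two-cause decomposition
risk(outcome) + risk(death) + P(event-free) = 1 holds identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .survival import event_indicator

__all__ = ["AbsRiskEstimate", "estimate_hazards", "absolute_risk", "group_absolute_risks"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AbsRiskEstimate:
    """Probability of the outcome within a horizon from a start age."""

    start_age: float
    horizon: float
    group: str
    risk: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk <= 1.0:
            raise ValueError(f"risk must lie in [0, 1], got {self.risk}")


def estimate_hazards(
    cohort: pd.DataFrame,
    outcome: str,
    age_min: float = 45.0,
    age_max: float = 90.0,
    competing: Sequence[str] = ("death",),
) -> pd.DataFrame:
    """Occurrence/exposure rates per 1-year age band for outcome and competing death.

    Person-years in a band are the overlap of each person's (entry, exit]
    interval with the band; events are counted in the band containing the
    exit age.  Bands with zero person-years get rate 0 (logged).
    """
    if age_max <= age_min:
        raise ValueError("age_max must exceed age_min")
    entry = cohort["entry_age"].to_numpy(dtype=float)
    exit_ = cohort["exit_age"].to_numpy(dtype=float)
    if np.any(exit_ <= entry):
        raise ValueError("every exit age must exceed the entry age")
    edges = np.arange(np.floor(age_min), np.ceil(age_max) + 1.0)
    starts = edges[:-1]
    py = np.clip(
        np.minimum(exit_[:, None], edges[1:][None, :])
        - np.maximum(entry[:, None], starts[None, :]),
        0.0,
        None,
    ).sum(axis=0)

    ev_out = event_indicator(cohort, outcome).astype(bool)
    ev_comp = np.zeros(len(cohort), dtype=bool)
    for c in competing:
        ev_comp |= event_indicator(cohort, c).astype(bool)
    # an exit exactly on a band edge belongs to the band below (risk interval
    # is half-open on the left: the person was at risk through that band)
    band_of_exit = np.digitize(exit_, edges, right=True) - 1
    in_range = (band_of_exit >= 0) & (band_of_exit < len(starts))
    n_out = np.bincount(band_of_exit[ev_out & in_range], minlength=len(starts))
    n_comp = np.bincount(band_of_exit[ev_comp & in_range], minlength=len(starts))

    empty = (py == 0) & ((n_out > 0) | (n_comp > 0))
    if empty.any():  # events cannot occur in a zero-exposure band
        raise ValueError("events counted in a band with zero person-years")
    zero = py == 0
    if zero.any():
        logger.warning(
            "%d age band(s) with zero person-years in [%g, %g); rates set to 0",
            int(zero.sum()), age_min, age_max,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rate_out = np.where(py > 0, n_out / py, 0.0)
        rate_comp = np.where(py > 0, n_comp / py, 0.0)
    return pd.DataFrame(
        {
            "age_start": starts,
            "age_end": edges[1:],
            "person_years": py,
            "events_outcome": n_out,
            "events_competing": n_comp,
            "rate_outcome": rate_out,
            "rate_competing": rate_comp,
        }
    )


def absolute_risk(
    hazards: pd.DataFrame,
    start_age: float,
    horizon: float = 20.0,
    group: str = "",
    outcome_col: str = "rate_outcome",
    competing_col: str = "rate_competing",
) -> AbsRiskEstimate:
    """Integrate the cause-specific hazards into a crude risk over the horizon.

    Bands are clipped to [start_age, start_age + horizon); partial band
    overlap uses the band's constant rates over the overlapping width.
    """
    a0, a1 = float(start_age), float(start_age) + float(horizon)
    lo = hazards["age_start"].to_numpy(dtype=float)
    hi = hazards["age_end"].to_numpy(dtype=float)
    if a0 < lo.min() or a1 > hi.max():
        raise ValueError(
            f"hazard table bands [{lo.min()}, {hi.max()}) do not cover [{a0}, {a1})"
        )
    h1 = hazards[outcome_col].to_numpy(dtype=float)
    h2 = hazards[competing_col].to_numpy(dtype=float)
    if np.any(h1 < 0) or np.any(h2 < 0):
        raise ValueError("negative hazard rate")
    w = np.clip(np.minimum(hi, a1) - np.maximum(lo, a0), 0.0, None)
    keep = w > 0
    h1, h2, w = h1[keep], h2[keep], w[keep]
    tot = h1 + h2
    cum = np.concatenate(([0.0], np.cumsum(tot * w)[:-1]))
    surv = np.exp(-cum)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(tot > 0, h1 / np.where(tot > 0, tot, 1.0), 0.0)
        band_risk = frac * (1.0 - np.exp(-tot * w))
    risk = float((surv * band_risk).sum())
    return AbsRiskEstimate(start_age=a0, horizon=float(horizon), group=group, risk=risk)


def group_absolute_risks(
    cohort: pd.DataFrame,
    outcome: str,
    start_age: float = 60.0,
    horizon: float = 20.0,
    competing: Sequence[str] = ("death",),
    shared_competing: bool = False,
) -> pd.DataFrame:
    """Crude risk per joint exposure group (columns from ``assign_joint_groups``).

    By default each group's own death hazard is used (hypertension raises
    mortality, so sharing it would distort the comparison);
    ``shared_competing=True`` substitutes the whole-sample death hazard.
    """
    need = ["joint_10", "joint_01", "joint_11"]
    if any(c not in cohort.columns for c in need):
        raise ValueError("cohort lacks joint-group columns; run assign_joint_groups first")
    scored = cohort[need].notna().all(axis=1)
    sub = cohort.loc[scored]
    labels = np.select(
        [sub["joint_10"] == 1, sub["joint_01"] == 1, sub["joint_11"] == 1],
        ["10", "01", "11"],
        default="ref",
    )
    shared = estimate_hazards(sub, outcome, competing=competing) if shared_competing else None
    rows = []
    for grp in ("ref", "10", "01", "11"):
        part = sub.loc[labels == grp]
        window_py = np.clip(
            np.minimum(part["exit_age"], start_age + horizon)
            - np.maximum(part["entry_age"], start_age),
            0.0,
            None,
        ).sum()
        if window_py <= 0:
            raise ValueError(f"joint group {grp!r} has no person-years in the risk window")
        hz = estimate_hazards(part, outcome, competing=competing)
        if shared is not None:
            hz = hz.assign(rate_competing=shared["rate_competing"].to_numpy())
        est = absolute_risk(hz, start_age, horizon, group=grp)
        rows.append(
            {
                "group": grp,
                "n": len(part),
                "start_age": start_age,
                "horizon": horizon,
                "absolute_risk": est.risk,
                "absolute_risk_percent": 100.0 * est.risk,
            }
        )
    return pd.DataFrame(rows).set_index("group")
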