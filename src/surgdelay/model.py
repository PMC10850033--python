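"""Three-state cohort state-transition model of surgical delay.

A cohort of patients awaiting one surgery is tracked weekly through the
states *pre-operative*, *post-operative* and *deceased* (absorbing).
Everyone starts pre-operative; at the scheduled delay the survivors
undergo surgery and move to the post-operative state; permanent
cancellation leaves them pre-operative until death.  Annual survival
proportions are converted to weekly death probabilities under a constant
hazard, and two treatment-futility windows cut off the survival and the
HRQoL benefit of surgery once the delay exceeds them (step functions).

The outcome is the DALY accrued per month of surgical delay: healthy
life years (occupancy-weighted utility, disability weight = 1 − utility)
are computed for each delay on a grid from 2 to 52 weeks in 10-week
steps, losses are taken relative to the 2-week reference, and the
DALY/month figure is the least-squares slope of loss against delay in
months.  No discounting and no half-cycle correction are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

WEEKS_PER_YEAR = 52
MONTHS_PER_WEEK = 12.0 / 52.0
#: Delay scenarios: intervals of ten weeks, from two weeks up to one year.
DELAY_GRID_WEEKS = (2, 12, 22, 32, 42, 52)
LIFETIME_AGE = 100.0


@dataclass(frozen=True)
class SurgeryParameters:
    """The seven inputs the decision model needs for one surgery."""

    surgery: str
    label: str
    surv_pre: float          # annual survival while awaiting surgery, (0, 1]
    surv_post: float         # annual survival after surgery, (0, 1]
    hrqol_pre: float         # utility in the pre-operative state, [0, 1]
    hrqol_post: float        # utility in the post-operative state, [0, 1]
    mean_age: float          # years, < 100
    t_no_surv_benefit: float     # weeks until surgery stops helping survival
    t_no_hrqol_benefit: float    # weeks until surgery stops helping HRQoL

    def __post_init__(self) -> None:
        if not (0.0 < self.surv_pre <= 1.0 and 0.0 < self.surv_post <= 1.0):
            raise ConfigurationError(
                f"{self.surgery}: annual survival must lie in (0, 1]")
        if not (0.0 <= self.hrqol_pre <= self.hrqol_post <= 1.0):
            raise ConfigurationError(
                f"{self.surgery}: need 0 <= hrqol_pre <= hrqol_post <= 1")
        if not (0.0 < self.mean_age < LIFETIME_AGE):
            raise ConfigurationError(
                f"{self.surgery}: mean_age must lie in (0, {LIFETIME_AGE})")
        if self.t_no_surv_benefit < 0 or self.t_no_hrqol_benefit < 0:
            raise ConfigurationError(
                f"{self.surgery}: futility windows must be >= 0 weeks")

    @classmethod
    def from_row(cls, row) -> "SurgeryParameters":
        return cls(surgery=str(row["surgery"]), label=str(row["label"]),
                   surv_pre=float(row["surv_pre"]),
                   surv_post=float(row["surv_post"]),
                   hrqol_pre=float(row["hrqol_pre"]),
                   hrqol_post=float(row["hrqol_post"]),
                   mean_age=float(row["mean_age"]),
                   t_no_surv_benefit=float(row["t_no_surv_benefit"]),
                   t_no_hrqol_benefit=float(row["t_no_hrqol_benefit"]))


@dataclass(frozen=True)
class DelayScenario:
    """A scheduled delay in weeks, or permanent cancellation (``None``)."""

    weeks: int | None

    @property
    def cancelled(self) -> bool:
        return self.weeks is None

    @classmethod
    def cancellation(cls) -> "DelayScenario":
        return cls(weeks=None)

    def __post_init__(self) -> None:
        if self.weeks is not None and self.weeks < 0:
            raise ConfigurationError("delay must be >= 0 weeks")


@dataclass(frozen=True)
class CohortTrace:
    """Weekly occupancy of the three states.

    Row ``t`` holds the occupancy *during* cycle ``t`` — after any
    scheduled surgery that week, before that week's deaths — so that
    occupancy-weighted utility sums give healthy life years directly.
    """

    pre: np.ndarray
    post: np.ndarray
    deceased: np.ndarray
    cycle_weeks: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cycle": np.arange(len(self.pre)),
                             "pre": self.pre, "post": self.post,
                             "deceased": self.deceased})


@dataclass(frozen=True)
class DalyOutcome:
    """DALY per month of delay for one surgery under one HRQoL source."""

    surgery: str
    hrqol_source: str
    daly_per_month: float
    ci_low: float | None = None
    ci_high: float | None = None
    loss_by_delay: dict[int, float] | None = None   # DALYs vs 2-week reference
    cancellation_daly: float | None = None          # total DALYs if cancelled


def per_cycle_death_probability(annual_survival: float,
                                cycle_weeks: float = 1.0) -> float:
    """Constant-hazard conversion of an annual survival proportion.

    p = 1 − s^(cycle_weeks / 52).  An annual survival of zero implies an
    infinite hazard and is rejected.
    """
    if not 0.0 < annual_survival <= 1.0:
        raise ConfigurationError("annual survival must lie in (0, 1]")
    if cycle_weeks <= 0:
        raise ConfigurationError("cycle length must be positive")
    return 1.0 - annual_survival ** (cycle_weeks / WEEKS_PER_YEAR)


def horizon_cycles(mean_age: float, cycle_weeks: float = 1.0) -> int:
    """Number of weekly cycles until the cohort turns 100."""
    cycles = math.ceil((LIFETIME_AGE - mean_age) * WEEKS_PER_YEAR / cycle_weeks)
    if cycles <= 0:
        raise ConfigurationError("mean age at or beyond the lifetime horizon")
    return cycles


def effective_post_params(params: SurgeryParameters,
                          scenario: DelayScenario) -> tuple[float, float]:
    """Post-operative survival and utility after the futility rule.

    Delays at or beyond a futility window forfeit that benefit: the
    post-operative value reverts to its pre-operative counterpart.
    Cancellation trivially exceeds both windows.
    """
    if scenario.cancelled:
        return params.surv_pre, params.hrqol_pre
    surv = (params.surv_pre if scenario.weeks >= params.t_no_surv_benefit
            else params.surv_post)
    hrqol = (params.hrqol_pre if scenario.weeks >= params.t_no_hrqol_benefit
             else params.hrqol_post)
    return surv, hrqol


def run_cohort(params: SurgeryParameters,
               scenario: DelayScenario) -> CohortTrace:
    """Run the weekly cohort simulation until the cohort turns 100.

    The whole cohort starts pre-operative.  While waiting it faces the
    pre-operative weekly death probability; in the delay week the
    survivors transition to post-operative (surgery first, then that
    week's post-operative hazard) and face the effective post-operative
    death probability thereafter.  Under cancellation nobody ever
    transitions.
    """
    n = horizon_cycles(params.mean_age)
    q_pre = 1.0 - per_cycle_death_probability(params.surv_pre)
    surv_eff, _ = effective_post_params(params, scenario)
    q_post = 1.0 - per_cycle_death_probability(surv_eff)
    t = np.arange(n)
    if scenario.cancelled or scenario.weeks >= n:
        pre = q_pre ** t
        post = np.zeros(n)
    else:
        d = scenario.weeks
        pre = np.where(t < d, q_pre ** t, 0.0)
        post = np.where(t >= d, q_pre ** d * q_post ** np.maximum(t - d, 0), 0.0)
    deceased = 1.0 - pre - post
    return CohortTrace(pre=pre, post=post, deceased=deceased)


def _geometric_sum(q: float, k: int) -> float:
    """sum_{t=0}^{k-1} q^t, stable at q == 1."""
    if k <= 0:
        return 0.0
    if q == 1.0:
        return float(k)
    return (1.0 - q ** k) / (1.0 - q)


def healthy_life_years(trace: CohortTrace, params: SurgeryParameters,
                       scenario: DelayScenario,
                       hrqol_pre: float | None = None,
                       hrqol_post: float | None = None) -> float:
    """Occupancy-weighted utility summed over the trace, in years.

    The deceased state contributes nothing (disability weight 1); no
    discounting.  ``hrqol_pre``/``hrqol_post`` override the parameter
    table's utilities, e.g. to substitute a different panel's values;
    the futility rule still applies to the effective post value.
    """
    u_pre = params.hrqol_pre if hrqol_pre is None else hrqol_pre
    u_post = params.hrqol_post if hrqol_post is None else hrqol_post
    if scenario.cancelled or scenario.weeks >= params.t_no_hrqol_benefit:
        u_post_eff = u_pre
    else:
        u_post_eff = u_post
    weekly = trace.pre * u_pre + trace.post * u_post_eff
    return float(weekly.sum() * trace.cycle_weeks / WEEKS_PER_YEAR)


def _hly_closed(params: SurgeryParameters, scenario: DelayScenario,
                u_pre: float, u_post: float) -> float:
    """Healthy life years via geometric sums (no trace allocation)."""
    n = horizon_cycles(params.mean_age)
    q_pre = 1.0 - per_cycle_death_probability(params.surv_pre)
    surv_eff, _ = effective_post_params(params, scenario)
    q_post = 1.0 - per_cycle_death_probability(surv_eff)
    if scenario.cancelled or scenario.weeks >= params.t_no_hrqol_benefit:
        u_post_eff = u_pre
    else:
        u_post_eff = u_post
    if scenario.cancelled or scenario.weeks >= n:
        return u_pre * _geometric_sum(q_pre, n) / WEEKS_PER_YEAR
    d = scenario.weeks
    hly = (u_pre * _geometric_sum(q_pre, d)
           + u_post_eff * q_pre ** d * _geometric_sum(q_post, n - d))
    return hly / WEEKS_PER_YEAR


def daly_per_month(params: SurgeryParameters,
                   hrqol_source: str = "parameters",
                   utilities: tuple[float, float] | None = None,
                   delays: Sequence[int] = DELAY_GRID_WEEKS,
                   reference_weeks: int = DELAY_GRID_WEEKS[0],
                   include_cancellation: bool = True) -> DalyOutcome:
    """Point estimate of DALYs per month of surgical delay.

    For each delay ``d`` on the grid the health loss relative to the
    reference delay is ``loss(d) = HLY(reference) − HLY(d)``; the
    DALY/month figure is the ordinary least-squares slope of these losses
    against delay expressed in months.  Cancellation is reported
    separately as a total loss and never enters the slope.

    ``utilities = (u_pre, u_post)`` substitutes HRQoL values from a
    respondent panel for the parameter-table values.
    """
    if utilities is None:
        u_pre, u_post = params.hrqol_pre, params.hrqol_post
    else:
        u_pre, u_post = utilities
    if not 0.0 <= u_pre <= 1.0 or not 0.0 <= u_post <= 1.0:
        raise ConfigurationError(
            f"{params.surgery}: substituted utilities must lie in [0, 1]")
    delays = sorted(set(delays) | {reference_weeks})
    hly = {d: _hly_closed(params, DelayScenario(d), u_pre, u_post)
           for d in delays}
    losses = {d: hly[reference_weeks] - hly[d] for d in delays}
    months = np.array([d * MONTHS_PER_WEEK for d in delays])
    loss_vec = np.array([losses[d] for d in delays])
    if np.allclose(loss_vec, 0.0):
        slope = 0.0
    else:
        slope = float(np.polyfit(months, loss_vec, 1)[0])
    cancellation = None
    if include_cancellation:
        cancellation = (hly[reference_weeks]
                        - _hly_closed(params, DelayScenario.cancellation(),
                                      u_pre, u_post))
    return DalyOutcome(surgery=params.surgery, hrqol_source=hrqol_source,
                       daly_per_month=slope, loss_by_delay=losses,
                       cancellation_daly=cancellation)


def outcomes_table(outcomes: Sequence[DalyOutcome]) -> pd.DataFrame:
    """Flatten DalyOutcome records into the CSV-ready outcome table."""
    rows = []
    for o in outcomes:
        rows.append({"surgery": o.surgery, "hrqol_source": o.hrqol_source,
                     "daly_per_month": o.daly_per_month,
                     "ci_low": o.ci_low, "ci_high": o.ci_high,
                     "cancellation_daly": o.cancellation_daly})
    return pd.DataFrame(rows)


def model_outcomes(parameters: pd.DataFrame, utilities: pd.DataFrame | None,
                   source: str = "parameters",
                   delays: Sequence[int] = DELAY_GRID_WEEKS,
                   ) -> list[DalyOutcome]:
    """Deterministic DALY/month for every surgery in a parameter table.

    ``utilities`` is a utility-estimate table (one group) whose
    pre/post-operative means replace the parameter-table HRQoL columns;
    pass ``None`` to use the parameter table's own values.
    """
    from .synthetic import PHASE_POST, PHASE_PRE
    lookup = None
    if utilities is not None:
        lookup = utilities.set_index(["surgery", "phase"])["mean_utility"]
    outcomes = []
    for _, row in parameters.iterrows():
        params = SurgeryParameters.from_row(row)
        subst = None
        if lookup is not None:
            try:
                u_pre = float(lookup[(params.surgery, PHASE_PRE)])
                u_post = float(lookup[(params.surgery, PHASE_POST)])
            except KeyError as exc:
                raise ConfigurationError(
                    f"utility table lacks vignette {exc.args[0]}") from None
            subst = (u_pre, u_post)
        outcomes.append(daly_per_month(params, hrqol_source=source,
                                       utilities=subst, delays=delays))
    return outcomes
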