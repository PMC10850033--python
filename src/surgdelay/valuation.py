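"""Two-round Delphi valuation: feedback statistics, exclusion rules,
VAS-to-utility conversion and per-panel aggregation.

Respondents rate pre- and post-operative health-state vignettes on a
calibrated visual analogue scale from 0 ("worst imaginable health") to 100
("best imaginable health").  After the second round, doubtful respondents
are excluded by three rules — any negative rating, all ratings zero, or a
post-operative rating strictly below the pre-operative one for *every*
surgery — and the surviving ratings are divided by 100 and aggregated into
per-panel utility estimates that feed the decision model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError
from .synthetic import (CRITERION_ALL_ZERO, CRITERION_NEGATIVE,
                        CRITERION_POST_BELOW_PRE, PHASE_POST, PHASE_PRE,
                        PHASES)

UTILITY_COLUMNS = ["group", "surgery", "phase", "mean_utility", "sd_utility", "n"]


@dataclass(frozen=True)
class FeedbackSummary:
    """Round-1 group feedback shown to respondents in round 2."""

    surgery: str
    phase: str
    median_vas: float
    iqr_low: float
    iqr_high: float
    n: int


@dataclass(frozen=True)
class ExclusionReport:
    """One excluded respondent and the (single) criterion that fired."""

    respondent: str
    criterion: str
    panel: str


def round1_feedback(responses: pd.DataFrame,
                    panel: str) -> list[FeedbackSummary]:
    """Median and interquartile range per vignette for one panel.

    Quantiles use linear interpolation between order statistics (the
    common default convention).

    Raises
    ------
    DataValidationError
        If any vignette present in the table has no rows for the panel.
    """
    vignettes = sorted(
        responses[["surgery", "phase"]].drop_duplicates().itertuples(index=False))
    subset = responses[responses["panel"] == panel]
    grouped = subset.groupby(["surgery", "phase"])["vas"]
    summaries = []
    for surgery, phase in vignettes:
        try:
            values = grouped.get_group((surgery, phase)).to_numpy()
        except KeyError:
            raise DataValidationError(
                f"no responses from panel {panel} for vignette "
                f"{surgery}/{phase}") from None
        lo, med, hi = np.percentile(values, [25, 50, 75])
        summaries.append(FeedbackSummary(surgery, phase, float(med),
                                         float(lo), float(hi), len(values)))
    return summaries


def _respondent_matrix(responses: pd.DataFrame) -> pd.DataFrame:
    """Pivot to one row per respondent, one column per vignette.

    Raises if any respondent has a missing or duplicated vignette —
    incomplete respondents must be handled upstream, never silently
    excluded.
    """
    counts = responses.pivot_table(index="respondent",
                                   columns=["surgery", "phase"], values="vas",
                                   aggfunc="count")
    # the vignette universe is the full surgery x phase cross of the table
    cross = pd.MultiIndex.from_product(
        [sorted(responses["surgery"].unique()), list(PHASES)],
        names=["surgery", "phase"])
    counts = counts.reindex(columns=cross)
    incomplete = counts.index[counts.isna().any(axis=1)
                              | (counts > 1).any(axis=1)]
    if len(incomplete):
        raise DataValidationError(
            f"incomplete or duplicated vignette set for respondent(s) "
            f"{list(incomplete[:5])}; refusing to apply exclusion rules")
    return responses.pivot(index="respondent", columns=["surgery", "phase"],
                           values="vas")


def _classify(row: pd.Series) -> str | None:
    """Return the first exclusion criterion that fires, or None.

    Precedence is negative -> all-zero -> post-below-pre, so each excluded
    respondent carries exactly one label and per-criterion counts are
    disjoint.
    """
    values = row.to_numpy()
    if (values < 0).any():
        return CRITERION_NEGATIVE
    if (values == 0).all():
        return CRITERION_ALL_ZERO
    surgeries = row.index.get_level_values(0).unique()
    if all(row[(s, PHASE_POST)] < row[(s, PHASE_PRE)] for s in surgeries):
        return CRITERION_POST_BELOW_PRE
    return None


def apply_exclusions(responses: pd.DataFrame
                     ) -> tuple[pd.DataFrame, list[ExclusionReport]]:
    """Drop doubtful respondents from a final-round response table.

    A respondent is excluded iff (1) any rating is negative, (2) all
    ratings are zero, or (3) the post-operative rating is strictly below
    the pre-operative one for every surgery ("consistently lower" read as
    all surgeries — the most conservative interpretation).

    Returns
    -------
    (retained, reports)
        ``retained`` holds only non-excluded respondents' rows;
        ``reports`` lists one :class:`ExclusionReport` per excluded
        respondent, in respondent order.
    """
    if responses.empty:
        return responses.copy(), []
    matrix = _respondent_matrix(responses)
    panels = responses.drop_duplicates("respondent").set_index("respondent")["panel"]
    reports = []
    excluded = []
    for respondent, row in matrix.iterrows():
        criterion = _classify(row)
        if criterion is not None:
            excluded.append(respondent)
            reports.append(ExclusionReport(str(respondent), criterion,
                                           str(panels[respondent])))
    retained = responses[~responses["respondent"].isin(excluded)].copy()
    return retained, reports


def exclusion_summary(reports: Iterable[ExclusionReport]) -> pd.DataFrame:
    """Tabulate exclusion reports as panel x criterion counts."""
    frame = pd.DataFrame([(r.panel, r.criterion) for r in reports],
                         columns=["panel", "criterion"])
    if frame.empty:
        return pd.DataFrame(columns=["panel", "criterion", "n"])
    return (frame.value_counts().rename("n").reset_index()
            .sort_values(["panel", "criterion"]).reset_index(drop=True))


def vas_to_utility(vas):
    """Convert VAS scores on [0, 100] to utilities on [0, 1].

    Accepts scalars or arrays.  Out-of-range input raises — it signals
    that the exclusion stage was skipped.
    """
    arr = np.asarray(vas, dtype=float)
    if (arr < 0).any() or (arr > 100).any():
        raise DataValidationError(
            "VAS outside [0, 100]; apply exclusions before conversion")
    utility = arr / 100.0
    return float(utility) if np.isscalar(vas) else utility


def aggregate_panel(retained: pd.DataFrame, panels: Sequence[str],
                    group_label: str | None = None) -> pd.DataFrame:
    """Mean, SD and n of utilities per vignette for a (pooled) panel group.

    ``panels`` lists panel labels treated as one group, e.g. ``["CP1",
    "CP2"]`` pools both citizen panels.  SD uses the n-1 denominator; a
    single-respondent group has SD 0.

    Returns a DataFrame with columns ``group, surgery, phase,
    mean_utility, sd_utility, n``.
    """
    label = group_label if group_label is not None else "+".join(panels)
    subset = retained[retained["panel"].isin(panels)]
    if subset.empty:
        raise DataValidationError(f"no retained responses for group {label}")
    vignettes = sorted(
        retained[["surgery", "phase"]].drop_duplicates().itertuples(index=False))
    grouped = subset.groupby(["surgery", "phase"])["vas"]
    rows = []
    for surgery, phase in vignettes:
        try:
            utilities = vas_to_utility(grouped.get_group((surgery, phase)).to_numpy())
        except KeyError:
            raise DataValidationError(
                f"group {label} has no responses for vignette "
                f"{surgery}/{phase}") from None
        n = len(utilities)
        sd = float(np.std(utilities, ddof=1)) if n > 1 else 0.0
        rows.append((label, surgery, phase, float(np.mean(utilities)), sd, n))
    return pd.DataFrame(rows, columns=UTILITY_COLUMNS)
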