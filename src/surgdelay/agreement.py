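"""Agreement between respondent panels.

Three complementary views:

* **Bland–Altman** on per-vignette mean utilities — bias (mean
  difference), 95% limits of agreement (bias ± 1.96 SD of differences)
  and the per-vignette (average, difference) pairs for plotting.
* **Mixed-effects bias estimation** on respondent-level utilities —
  utility ~ intercept + panel + health-state, with crossed random
  intercepts for surgical procedure and participant, fitted by REML.
  No significant bias is declared when the Wald 95% CI of the panel
  coefficient includes zero.
* **Consensus comparison** of per-vignette SDs — a lower SD means more
  consensus; panels are compared by the paired standardized mean
  difference of their SDs.

Sign convention: every comparison reports *second group minus first
group* and carries that convention in its label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError
from .lmm import fit_crossed_intercepts
from .synthetic import PHASE_POST, PHASE_PRE
from .valuation import vas_to_utility

LOA_MULTIPLIER = 1.96  # conventional 95% limits of agreement
STRATA = ("all", PHASE_PRE, PHASE_POST)


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman agreement between two sets of vignette means."""

    comparison: str                # "<B>-minus-<A>"
    stratum: str
    bias: float
    ci_low: float
    ci_high: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n_vignettes: int
    points: pd.DataFrame = field(repr=False)  # average, difference per vignette


@dataclass(frozen=True)
class BiasModelResult:
    """Panel bias estimated by the crossed random-intercept mixed model."""

    comparison: str
    stratum: str
    bias: float
    ci_low: float
    ci_high: float
    se: float
    significant: bool              # CI excludes zero
    converged: bool
    used_fallback: bool
    variance_components: dict[str, float]
    n_obs: int


@dataclass(frozen=True)
class ConsensusResult:
    """Paired comparison of per-vignette SDs between two groups."""

    comparison: str
    smd_of_sds: float
    ci_low: float
    ci_high: float
    mean_diff: float               # raw mean of SD differences
    mean_diff_ci: tuple[float, float]
    degenerate: bool
    n_vignettes: int


def _stratum_mask(frame: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=frame.index)
    if stratum not in (PHASE_PRE, PHASE_POST):
        raise ValueError(f"unknown stratum {stratum!r}")
    return frame["phase"] == stratum


def bland_altman(estimates_a: pd.DataFrame, estimates_b: pd.DataFrame,
                 stratum: str = "all", label_a: str = "A",
                 label_b: str = "B") -> AgreementResult:
    """Bland–Altman agreement of two per-vignette utility tables.

    Inputs are utility-estimate tables (``surgery, phase, mean_utility``);
    each vignette contributes one (average, difference) point, with the
    difference taken as B minus A.  The bias CI is the t interval on the
    mean difference.

    Raises
    ------
    DataValidationError
        If the two tables do not cover the same vignettes.
    """
    a = estimates_a.set_index(["surgery", "phase"])["mean_utility"]
    b = estimates_b.set_index(["surgery", "phase"])["mean_utility"]
    missing = sorted(a.index.symmetric_difference(b.index).tolist())
    if missing:
        raise DataValidationError(
            f"vignette mismatch between panels: {missing}")
    merged = pd.DataFrame({"mean_a": a, "mean_b": b}).reset_index()
    merged = merged[_stratum_mask(merged, stratum)]
    diff = (merged["mean_b"] - merged["mean_a"]).to_numpy()
    avg = ((merged["mean_a"] + merged["mean_b"]) / 2.0).to_numpy()
    n = len(diff)
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1)) if n > 1 else 0.0
    if n > 1 and sd > 0:
        half = float(stats.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    else:
        half = 0.0
    points = pd.DataFrame({"surgery": merged["surgery"],
                           "phase": merged["phase"],
                           "average": avg, "difference": diff})
    return AgreementResult(
        comparison=f"{label_b}-minus-{label_a}", stratum=stratum,
        bias=bias, ci_low=bias - half, ci_high=bias + half,
        loa_low=bias - LOA_MULTIPLIER * sd, loa_high=bias + LOA_MULTIPLIER * sd,
        sd_diff=sd, n_vignettes=n, points=points.reset_index(drop=True))


def fit_bias_model(retained: pd.DataFrame, panels_a: Sequence[str],
                   panels_b: Sequence[str], stratum: str = "all",
                   label_a: str | None = None, label_b: str | None = None,
                   ) -> BiasModelResult:
    """Estimate the systematic panel difference with a mixed model.

    Utility (VAS/100) is regressed on an intercept, a group-B indicator
    and — in the pooled stratum — a health-state indicator, with crossed
    random intercepts for surgical procedure and participant (REML).
    The group-B coefficient is the bias of group B relative to group A;
    its Wald 95% CI decides significance.

    If the REML optimisation fails, the vignette-level paired
    (Bland–Altman) estimate is returned instead, flagged via
    ``used_fallback``.
    """
    label_a = label_a or "+".join(panels_a)
    label_b = label_b or "+".join(panels_b)
    subset = retained[retained["panel"].isin(list(panels_a) + list(panels_b))]
    subset = subset[_stratum_mask(subset, stratum)]
    if subset["respondent"].nunique() < 4 or subset["surgery"].nunique() < 2:
        raise DataValidationError(
            "bias model needs >= 2 respondents per group and >= 2 procedures")
    y = vas_to_utility(subset["vas"].to_numpy())
    is_b = subset["panel"].isin(panels_b).to_numpy().astype(float)
    columns = [np.ones(len(subset)), is_b]
    if stratum == "all":
        columns.append((subset["phase"] == PHASE_POST).to_numpy().astype(float))
    X = np.column_stack(columns)
    surg_codes = pd.Categorical(subset["surgery"]).codes
    resp_codes = pd.Categorical(subset["respondent"]).codes
    comparison = f"{label_b}-minus-{label_a}"

    fit = fit_crossed_intercepts(y, X, surg_codes, resp_codes)
    if fit.converged:
        bias = float(fit.beta[1])
        se = float(fit.se()[1])
        half = 1.96 * se
        ci_low, ci_high = bias - half, bias + half
        used_fallback = False
        vc = {"procedure": fit.sigma2_factor1,
              "participant": fit.sigma2_factor2,
              "residual": fit.sigma2_residual}
    else:
        # paired vignette-level estimate as a last resort
        from .valuation import aggregate_panel
        est_a = aggregate_panel(subset, list(panels_a), label_a)
        est_b = aggregate_panel(subset, list(panels_b), label_b)
        ba = bland_altman(est_a, est_b, "all", label_a, label_b)
        bias, se = ba.bias, ba.sd_diff / max(np.sqrt(ba.n_vignettes), 1.0)
        ci_low, ci_high = ba.ci_low, ba.ci_high
        used_fallback = True
        vc = {}
    return BiasModelResult(
        comparison=comparison, stratum=stratum, bias=bias,
        ci_low=ci_low, ci_high=ci_high, se=se,
        significant=not (ci_low <= 0.0 <= ci_high),
        converged=fit.converged, used_fallback=used_fallback,
        variance_components=vc, n_obs=fit.n_obs)


def consensus_sd_comparison(sds_a: Sequence[float], sds_b: Sequence[float],
                            label_a: str = "A", label_b: str = "B",
                            ) -> ConsensusResult:
    """Compare per-vignette SDs of two groups (consensus comparison).

    Differences are taken vignette-wise as B minus A.  The point estimate
    is the mean difference standardized by the SD of the differences; its
    95% CI is the paired t interval on the same scale (smd ± t / sqrt(n)).
    A positive value means group B shows more spread, i.e. less
    consensus.  Zero variance of the differences degenerates the CI to
    the point estimate and is flagged.
    """
    a = np.asarray(sds_a, dtype=float)
    b = np.asarray(sds_b, dtype=float)
    if a.shape != b.shape:
        raise DataValidationError("SD vectors must be paired per vignette")
    d = b - a
    n = len(d)
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1)) if n > 1 else 0.0
    comparison = f"{label_b}-minus-{label_a}"
    if sd_d == 0.0:
        smd = 0.0 if mean_d == 0.0 else float(np.sign(mean_d) * np.inf)
        return ConsensusResult(comparison, smd, smd, smd, mean_d,
                               (mean_d, mean_d), True, n)
    smd = mean_d / sd_d
    t_crit = float(stats.t.ppf(0.975, n - 1))
    half_raw = t_crit * sd_d / np.sqrt(n)
    return ConsensusResult(
        comparison=comparison, smd_of_sds=smd,
        ci_low=smd - t_crit / np.sqrt(n), ci_high=smd + t_crit / np.sqrt(n),
        mean_diff=mean_d, mean_diff_ci=(mean_d - half_raw, mean_d + half_raw),
        degenerate=False, n_vignettes=n)
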