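"""Probabilistic sensitivity analysis.

Every (0, 1)-bounded model input — the two HRQoL utilities and the two
annual survival proportions — is given a beta distribution parameterised
by the method of moments; mean age and the futility windows are held
fixed.  Utility uncertainty defaults to the standard error of the panel
mean (sd / sqrt(n)): the PSA is meant to reflect how precisely the panel
pinned the value down, not respondent heterogeneity.  Draws violating
``hrqol_pre <= hrqol_post`` are jointly resampled so neither marginal is
truncated asymmetrically.  The reported interval is the empirical
2.5th–97.5th percentile range of DALY/month over the draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model import DELAY_GRID_WEEKS, SurgeryParameters, daly_per_month
from .synthetic import PHASE_POST, PHASE_PRE

_MAX_RESAMPLE_ROUNDS = 1000


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling distribution of one scalar model input."""

    name: str
    family: str            # "beta" or "fixed"
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in ("beta", "fixed"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.sd < 0:
            raise ConfigurationError(f"{self.name}: sd must be >= 0")
        if self.family == "beta" and self.sd > 0:
            beta_from_moments(self.mean, self.sd)  # feasibility check

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "fixed" or self.sd == 0.0:
            return np.full(size, self.mean)
        alpha, beta = beta_from_moments(self.mean, self.sd)
        return rng.beta(alpha, beta, size=size)


@dataclass(frozen=True)
class PsaResult:
    """Draws and percentile interval of DALY/month for one surgery."""

    surgery: str
    hrqol_source: str
    draws: np.ndarray
    mean: float
    ci_low: float           # 2.5th percentile
    ci_high: float          # 97.5th percentile
    n_draws: int
    seed: int


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters of the beta distribution with given mean and SD.

    alpha = m (m(1-m)/sd^2 - 1), beta = (1-m) (same factor).  Requires
    0 < mean < 1 and sd^2 < mean (1 - mean); sd = 0 denotes a point mass
    and is rejected here (handled by the caller as "fixed").
    """
    if not 0.0 < mean < 1.0:
        raise ConfigurationError(f"beta mean {mean} outside (0, 1)")
    if sd <= 0.0:
        raise ConfigurationError("beta sd must be positive; use family='fixed'")
    variance = sd * sd
    limit = mean * (1.0 - mean)
    if variance >= limit:
        raise ConfigurationError(
            f"infeasible beta moments: sd^2 = {variance:.6g} >= "
            f"mean(1-mean) = {limit:.6g}")
    factor = limit / variance - 1.0
    return mean * factor, (1.0 - mean) * factor


def _utility_distribution(name: str, mean: float, sd: float, n: int,
                          use_standard_error: bool) -> ParameterDistribution:
    spread = sd / np.sqrt(n) if use_standard_error else sd
    if spread == 0.0 or not 0.0 < mean < 1.0:
        # degenerate or boundary panel mean: treat as fixed
        return ParameterDistribution(name, "fixed", mean, 0.0)
    return ParameterDistribution(name, "beta", mean, float(spread))


def _survival_distribution(name: str, mean: float,
                           sd: float) -> ParameterDistribution:
    if sd == 0.0 or not 0.0 < mean < 1.0:
        return ParameterDistribution(name, "fixed", mean, 0.0)
    return ParameterDistribution(name, "beta", mean, sd)


def _draw_ordered_pair(rng: np.random.Generator,
                       dist_pre: ParameterDistribution,
                       dist_post: ParameterDistribution,
                       n_draws: int, surgery: str) -> tuple[np.ndarray, np.ndarray]:
    """Joint draws of (pre, post) utilities with pre <= post enforced by
    resampling violating pairs.

    If the panel estimates themselves are inverted (mean pre above mean
    post) the constraint is infeasible; the draws are then propagated
    unconstrained, mirroring how the deterministic pipeline carries an
    inverted panel estimate through the model.
    """
    pre = dist_pre.sample(rng, n_draws)
    post = dist_post.sample(rng, n_draws)
    if dist_pre.mean > dist_post.mean:
        return pre, post
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = pre > post
        if not bad.any():
            return pre, post
        k = int(bad.sum())
        pre[bad] = dist_pre.sample(rng, k)
        post[bad] = dist_post.sample(rng, k)
    raise ConfigurationError(
        f"{surgery}: could not satisfy hrqol_pre <= hrqol_post after "
        f"{_MAX_RESAMPLE_ROUNDS} resampling rounds")


def run_psa(parameters: pd.DataFrame, utilities: pd.DataFrame,
            n_draws: int = 1000, seed: int = 0,
            source: str | None = None, surv_sd: float = 0.02,
            use_standard_error: bool = True,
            delays: Sequence[int] = DELAY_GRID_WEEKS) -> list[PsaResult]:
    """Propagate parameter uncertainty through the decision model.

    Parameters
    ----------
    parameters
        Surgery parameter table (seven inputs per surgery).
    utilities
        Utility-estimate table of one panel group supplying
        ``mean_utility, sd_utility, n`` per vignette.
    n_draws
        Monte-Carlo sample size per surgery.
    seed
        Seeds a fresh generator; identical seeds give bit-identical
        results.
    surv_sd
        Sampling SD applied to both annual survival proportions
        (0 keeps them fixed).
    use_standard_error
        Sample utilities with sd/sqrt(n) (default) instead of the raw
        respondent SD.
    """
    if n_draws < 1:
        raise ConfigurationError("n_draws must be >= 1")
    lookup = utilities.set_index(["surgery", "phase"])
    label = source if source is not None else str(utilities["group"].iloc[0])
    rng = np.random.default_rng(seed)
    results = []
    for _, row in parameters.iterrows():
        base = SurgeryParameters.from_row(row)
        try:
            row_pre = lookup.loc[(base.surgery, PHASE_PRE)]
            row_post = lookup.loc[(base.surgery, PHASE_POST)]
        except KeyError:
            raise ConfigurationError(
                f"utility table lacks a vignette for {base.surgery}") from None
        dist_u_pre = _utility_distribution(
            "hrqol_pre", float(row_pre["mean_utility"]),
            float(row_pre["sd_utility"]), int(row_pre["n"]), use_standard_error)
        dist_u_post = _utility_distribution(
            "hrqol_post", float(row_post["mean_utility"]),
            float(row_post["sd_utility"]), int(row_post["n"]), use_standard_error)
        dist_s_pre = _survival_distribution("surv_pre", base.surv_pre, surv_sd)
        dist_s_post = _survival_distribution("surv_post", base.surv_post,
                                             surv_sd)
        u_pre, u_post = _draw_ordered_pair(rng, dist_u_pre, dist_u_post,
                                           n_draws, base.surgery)
        s_pre = dist_s_pre.sample(rng, n_draws)
        s_post = dist_s_post.sample(rng, n_draws)
        draws = np.empty(n_draws)
        for i in range(n_draws):
            params_i = replace(base, surv_pre=float(s_pre[i]),
                               surv_post=float(s_post[i]),
                               hrqol_pre=0.0, hrqol_post=1.0)
            draws[i] = daly_per_month(
                params_i, hrqol_source=label,
                utilities=(float(u_pre[i]), float(u_post[i])),
                delays=delays, include_cancellation=False).daly_per_month
        lo, hi = np.percentile(draws, [2.5, 97.5])
        results.append(PsaResult(surgery=base.surgery, hrqol_source=label,
                                 draws=draws, mean=float(draws.mean()),
                                 ci_low=float(lo), ci_high=float(hi),
                                 n_draws=n_draws, seed=seed))
    return results


def psa_table(results: Sequence[PsaResult]) -> pd.DataFrame:
    """Summary table (one row per surgery) of a PSA run."""
    return pd.DataFrame([{
        "surgery": r.surgery, "hrqol_source": r.hrqol_source,
        "daly_per_month": r.mean, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "n_draws": r.n_draws, "seed": r.seed} for r in results])
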