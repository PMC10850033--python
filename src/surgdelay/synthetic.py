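"""Synthetic Delphi-panel data generator.

Real panel responses from health-state valuation studies are rarely
deposited, so this module generates long-format VAS response tables and
surgery parameter tables with the statistical structure the downstream
analysis assumes: a systematic panel offset (physicians rating health
states higher than citizens), respondent and vignette random intercepts,
panel-specific residual spread, and deterministically injected
rule-violating respondents for exercising the exclusion engine.

The generative model for one rating is

    VAS / 100 = clip(u_true + delta * 1[physician]
                     + b_respondent + b_vignette + eps, 0, 1)

with ``b_respondent ~ N(0, sd_respondent^2)``, ``b_vignette ~
N(0, sd_vignette^2)`` and ``eps ~ N(0, sd_residual[panel]^2)`` — a linear
random-intercept model chosen to match the mixed model the agreement
stage fits, so parameter-recovery tests are well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

PHASE_PRE = "pre-operative"
PHASE_POST = "post-operative"
PHASES = (PHASE_PRE, PHASE_POST)

#: Exclusion criterion codes, in the precedence order the valuation stage uses.
CRITERION_NEGATIVE = "negative"
CRITERION_ALL_ZERO = "all_zero"
CRITERION_POST_BELOW_PRE = "post_below_pre"
CRITERIA = (CRITERION_NEGATIVE, CRITERION_ALL_ZERO, CRITERION_POST_BELOW_PRE)

#: Reference health states from the Global Burden of Disease study shown to
#: respondents as VAS anchors.  Display metadata only — they never enter the
#: value model.
GBD_REFERENCE_STATES = ("dementia", "severe depression", "blindness",
                       "deafness", "infertility")

RESPONSE_COLUMNS = ["respondent", "panel", "round", "surgery", "phase", "vas"]
PARAMETER_COLUMNS = ["surgery", "label", "surv_pre", "surv_post", "hrqol_pre",
                     "hrqol_post", "mean_age", "t_no_surv_benefit",
                     "t_no_hrqol_benefit"]


def _default_panel_sizes() -> dict[str, int]:
    # First-round completers in the two citizen panels and the physician panel.
    return {"CP1": 47, "CP2": 41, "PP": 15}


def _default_residual_sds() -> dict[str, float]:
    # Citizens show larger spread (less consensus) than physicians.
    return {"CP1": 0.12, "CP2": 0.12, "PP": 0.08}


def _default_injection() -> dict[str, dict[str, int]]:
    # Offender counts matching the study's exclusion flow:
    # CP1 47 -> 39 retained, CP2 41 -> 32 retained, physicians all retained.
    return {
        "CP1": {CRITERION_NEGATIVE: 1, CRITERION_ALL_ZERO: 1,
                CRITERION_POST_BELOW_PRE: 6},
        "CP2": {CRITERION_NEGATIVE: 2, CRITERION_ALL_ZERO: 4,
                CRITERION_POST_BELOW_PRE: 3},
        "PP": {},
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic panel-response generator.

    Parameters
    ----------
    n_respondents_per_panel
        Respondents entering the final round per panel label.
    n_surgeries
        Number of surgeries; each contributes a pre- and a post-operative
        vignette.
    panel_offset
        Systematic physician-minus-citizen difference on the 0–1 utility
        scale.  Positive means physicians rate health states higher.
    sd_respondent, sd_vignette
        Random-intercept standard deviations (utility units) shared by all
        panels.
    sd_residual
        Residual standard deviation (utility units) per panel label.
    exclusion_injection
        Per panel, how many respondents to overwrite per exclusion
        criterion.  Offenders occupy the last slots of the panel so
        fixtures are reproducible.
    physician_panels
        Panel labels receiving the offset.
    seed
        Master seed; identical configs produce bit-identical tables.
    """

    n_respondents_per_panel: Mapping[str, int] = field(
        default_factory=_default_panel_sizes)
    n_surgeries: int = 10
    panel_offset: float = 0.07
    sd_respondent: float = 0.05
    sd_vignette: float = 0.03
    sd_residual: Mapping[str, float] = field(
        default_factory=_default_residual_sds)
    exclusion_injection: Mapping[str, Mapping[str, int]] = field(
        default_factory=_default_injection)
    physician_panels: tuple[str, ...] = ("PP",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surgeries < 1:
            raise ConfigurationError("n_surgeries must be >= 1")
        for panel, n in self.n_respondents_per_panel.items():
            if n < 0:
                raise ConfigurationError(f"negative respondent count for {panel}")
        for name, sd in (("sd_respondent", self.sd_respondent),
                         ("sd_vignette", self.sd_vignette)):
            if sd < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for panel, sd in self.sd_residual.items():
            if sd < 0:
                raise ConfigurationError(f"sd_residual[{panel}] must be >= 0")
        for panel, counts in self.exclusion_injection.items():
            for criterion, k in counts.items():
                if criterion not in CRITERIA:
                    raise ConfigurationError(
                        f"unknown exclusion criterion {criterion!r}")
                if k < 0:
                    raise ConfigurationError(
                        f"negative injection count for {panel}/{criterion}")
            total = sum(counts.values())
            if total > self.n_respondents_per_panel.get(panel, 0):
                raise ConfigurationError(
                    f"panel {panel}: {total} injected offenders exceed "
                    f"{self.n_respondents_per_panel.get(panel, 0)} respondents")
        if not (-1.0 <= self.panel_offset <= 1.0):
            raise ConfigurationError("panel_offset must lie in [-1, 1]")


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator operation."""
    return np.random.default_rng([int(config.seed), stream])


def generate_true_values(config: GeneratorConfig) -> pd.DataFrame:
    """Draw latent ground-truth utilities for every vignette.

    Pre-operative utilities are drawn uniformly on [0.1, 0.6] and
    post-operative on [0.5, 0.95], resampling the post value when it would
    fall below its pre counterpart — surgery is assumed to improve health.

    Returns
    -------
    DataFrame with columns ``surgery``, ``phase``, ``true_utility``,
    two rows (pre, post) per surgery.
    """
    rng = _rng(config, 1)
    rows = []
    for s in range(config.n_surgeries):
        surgery = f"S{s + 1:02d}"
        pre = rng.uniform(0.10, 0.60)
        post = rng.uniform(0.50, 0.95)
        while post < pre:  # only possible for pre in (0.5, 0.6)
            post = rng.uniform(0.50, 0.95)
        rows.append((surgery, PHASE_PRE, pre))
        rows.append((surgery, PHASE_POST, post))
    return pd.DataFrame(rows, columns=["surgery", "phase", "true_utility"])


def _check_truth(config: GeneratorConfig, truth: pd.DataFrame) -> pd.Series:
    """Validate vignette coverage; return utilities indexed by (surgery, phase)."""
    indexed = truth.set_index(["surgery", "phase"])["true_utility"]
    surgeries = sorted(truth["surgery"].unique())
    if len(surgeries) != config.n_surgeries:
        raise ConfigurationError(
            f"truth table covers {len(surgeries)} surgeries, "
            f"config expects {config.n_surgeries}")
    for surgery in surgeries:
        for phase in PHASES:
            if (surgery, phase) not in indexed.index:
                raise ConfigurationError(
                    f"truth table missing vignette {surgery}/{phase}")
    return indexed


def generate_panel_responses(config: GeneratorConfig,
                             truth: pd.DataFrame) -> pd.DataFrame:
    """Generate the final-round (round 2) VAS response table.

    Honest respondents follow the clipped linear random-intercept model in
    the module docstring.  Injected offenders overwrite the last respondents
    of each panel, in criterion order (all-negative, all-zero, post-below-pre
    on every surgery), so the exclusion engine has known targets.

    Returns
    -------
    Long DataFrame with one row per respondent x surgery x phase and
    columns ``respondent, panel, round, surgery, phase, vas``.
    """
    utilities = _check_truth(config, truth)
    surgeries = sorted(truth["surgery"].unique())
    vignettes = [(s, p) for s in surgeries for p in PHASES]
    rng = _rng(config, 2)

    # Vignette intercepts are a property of the vignette text, shared by all
    # panels and respondents.
    vignette_effect = {v: rng.normal(0.0, config.sd_vignette)
                       for v in vignettes}
    true_vec = np.array([utilities[v] for v in vignettes])
    vig_vec = np.array([vignette_effect[v] for v in vignettes])

    frames = []
    for panel, n_resp in config.n_respondents_per_panel.items():
        offset = config.panel_offset if panel in config.physician_panels else 0.0
        sd_res = config.sd_residual.get(panel, 0.0)
        resp_effect = rng.normal(0.0, config.sd_respondent, size=n_resp)
        residual = rng.normal(0.0, sd_res, size=(n_resp, len(vignettes)))
        value = (true_vec[None, :] + offset + resp_effect[:, None]
                 + vig_vec[None, :] + residual)
        vas = np.clip(value, 0.0, 1.0) * 100.0

        # Overwrite offenders: last k respondents, criterion order fixed.
        counts = config.exclusion_injection.get(panel, {})
        k_total = sum(counts.values())
        cursor = n_resp - k_total
        for criterion in CRITERIA:
            for _ in range(counts.get(criterion, 0)):
                if criterion == CRITERION_NEGATIVE:
                    vas[cursor, :] = -10.0
                elif criterion == CRITERION_ALL_ZERO:
                    vas[cursor, :] = 0.0
                else:  # post strictly below pre for every surgery
                    for j in range(0, len(vignettes), 2):
                        pre = max(vas[cursor, j], 20.0)
                        vas[cursor, j] = pre
                        vas[cursor, j + 1] = pre / 2.0
                cursor += 1

        frame = pd.DataFrame({
            "respondent": np.repeat(
                [f"{panel}-{i + 1:03d}" for i in range(n_resp)],
                len(vignettes)),
            "panel": panel,
            "round": 2,
            "surgery": np.tile([v[0] for v in vignettes], n_resp),
            "phase": np.tile([v[1] for v in vignettes], n_resp),
            "vas": vas.ravel(),
        })
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=RESPONSE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[RESPONSE_COLUMNS]


def generate_surgery_parameters(config: GeneratorConfig,
                                truth: pd.DataFrame) -> pd.DataFrame:
    """Draw the seven decision-model inputs for each surgery.

    Annual survival pre-surgery is uniform on (0.80, 0.98); post-surgery
    survival adds a uniform (0.005, 0.15) benefit capped at 0.995.  HRQoL pre
    and post come from the latent truth.  Mean age is uniform on (30, 85)
    years and the two treatment-futility windows uniform on (26, 208) weeks,
    so some surgeries lose part of their benefit inside the one-year delay
    grid — spreading the DALY-per-month ranking.
    """
    utilities = _check_truth(config, truth)
    surgeries = sorted(truth["surgery"].unique())
    rng = _rng(config, 3)
    rows = []
    for surgery in surgeries:
        surv_pre = rng.uniform(0.80, 0.98)
        surv_post = min(surv_pre + rng.uniform(0.005, 0.15), 0.995)
        rows.append({
            "surgery": surgery,
            "label": surgery,
            "surv_pre": surv_pre,
            "surv_post": surv_post,
            "hrqol_pre": utilities[(surgery, PHASE_PRE)],
            "hrqol_post": utilities[(surgery, PHASE_POST)],
            "mean_age": rng.uniform(30.0, 85.0),
            "t_no_surv_benefit": rng.uniform(26.0, 208.0),
            "t_no_hrqol_benefit": rng.uniform(26.0, 208.0),
        })
    return pd.DataFrame(rows, columns=PARAMETER_COLUMNS)
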