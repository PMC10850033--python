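"""End-to-end orchestration: generate → valuate → agree → model → psa → rank.

All stage outputs are headered UTF-8 CSV files plus a JSON manifest
recording the configuration hash, seeds, library versions, row counts and
stage timings.  All randomness flows from one master seed: the generator
re-uses it directly and the PSA receives a derived child seed, so a run
is reproducible from a single integer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import (STRATA, bland_altman, consensus_sd_comparison,
                        fit_bias_model)
from .errors import ConfigurationError
from .model import DELAY_GRID_WEEKS, model_outcomes, outcomes_table
from .psa import psa_table, run_psa
from .ranking import rank_shifts, rank_surgeries, shifts_table, spearman_rho
from .synthetic import (GeneratorConfig, generate_panel_responses,
                        generate_surgery_parameters, generate_true_values)
from .valuation import aggregate_panel, apply_exclusions, exclusion_summary

logger = logging.getLogger("surgdelay")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "surgdelay-run"
    responses_path: str | None = None      # unused when generating
    parameters_path: str | None = None
    generator: GeneratorConfig | None = field(default_factory=GeneratorConfig)
    citizen_panels: tuple[str, ...] = ("CP1", "CP2")
    physician_panels: tuple[str, ...] = ("PP",)
    scenario_grid: tuple[int, ...] = DELAY_GRID_WEEKS
    psa_draws: int = 1000
    seed: int = 0
    rank_from_psa_mean: bool = True
    surv_sd: float = 0.02

    def __post_init__(self) -> None:
        # one-number reproducibility: the master seed governs the generator
        if self.generator is not None and self.generator.seed != self.seed:
            object.__setattr__(self, "generator",
                               dataclasses.replace(self.generator,
                                                   seed=self.seed))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", "default")
        if gen is None:
            generator = None
        elif gen == "default":
            generator = GeneratorConfig(seed=int(raw.get("seed", 0)))
        else:
            generator = GeneratorConfig(**gen)
        for key in ("citizen_panels", "physician_panels", "scenario_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(generator=generator, **raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = dataclasses.asdict(self.generator)
        return d

    def with_seed(self, seed: int) -> "RunConfig":
        generator = self.generator
        if generator is not None:
            generator = dataclasses.replace(generator, seed=seed)
        return dataclasses.replace(self, seed=seed, generator=generator)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derive_seed(master: int, stage: int) -> int:
    """Deterministic per-stage child seed below 2^31."""
    return int(np.random.SeedSequence([int(master), stage]).generate_state(1)[0]
               % (2 ** 31))


def _write(frame: pd.DataFrame, path: Path, manifest: dict,
           stage: str) -> None:
    frame.to_csv(path, index=False, encoding="utf-8")
    manifest["outputs"].setdefault(stage, {})[path.name] = int(len(frame))


def _load_inputs(config: RunConfig, out: Path, manifest: dict
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate synthetic inputs or read them from configured paths."""
    if config.generator is not None:
        truth = generate_true_values(config.generator)
        responses = generate_panel_responses(config.generator, truth)
        parameters = generate_surgery_parameters(config.generator, truth)
        _write(truth, out / "true_values.csv", manifest, "generate")
        _write(responses, out / "responses.csv", manifest, "generate")
        _write(parameters, out / "parameters.csv", manifest, "generate")
        return responses, parameters
    for name, path in (("responses", config.responses_path),
                       ("parameters", config.parameters_path)):
        if path is None or not Path(path).exists():
            raise ConfigurationError(
                f"stage generate: {name} file not found: {path}")
    return (pd.read_csv(config.responses_path),
            pd.read_csv(config.parameters_path))


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "library_versions": {"numpy": np.__version__,
                             "pandas": pd.__version__},
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "psa_seed": derive_seed(config.seed, 5),
        "stages": [],
        "outputs": {},
        "timings_s": {},
        "results": {},
    }
    t_start = time.perf_counter()

    def stage_done(name: str) -> None:
        manifest["stages"].append(name)
        manifest["timings_s"][name] = round(time.perf_counter() - t_stage, 4)
        logger.info("stage %s done in %.2fs", name, manifest["timings_s"][name])

    # generate -----------------------------------------------------------
    t_stage = time.perf_counter()
    responses, parameters = _load_inputs(config, out, manifest)
    stage_done("generate")

    # valuate ------------------------------------------------------------
    t_stage = time.perf_counter()
    retained, reports = apply_exclusions(responses)
    excl = exclusion_summary(reports)
    _write(excl, out / "exclusions.csv", manifest, "valuate")
    groups = {
        "CP": list(config.citizen_panels),
        "PP": list(config.physician_panels),
    }
    for panel in config.citizen_panels:
        groups[panel] = [panel]
    estimates = {label: aggregate_panel(retained, panels, label)
                 for label, panels in groups.items()}
    utilities = pd.concat(estimates.values(), ignore_index=True)
    _write(utilities, out / "utilities.csv", manifest, "valuate")
    manifest["results"]["respondents_total"] = int(responses["respondent"].nunique())
    manifest["results"]["respondents_retained"] = int(retained["respondent"].nunique())
    manifest["results"]["respondents_excluded"] = len(reports)
    stage_done("valuate")

    # agree --------------------------------------------------------------
    t_stage = time.perf_counter()
    comparisons = []
    if len(config.citizen_panels) >= 2:
        p1, p2 = config.citizen_panels[0], config.citizen_panels[1]
        comparisons.append((p1, p2, [p1], [p2]))
    comparisons.append(("PP", "CP", list(config.physician_panels),
                        list(config.citizen_panels)))
    agree_rows, point_frames = [], []
    for label_a, label_b, panels_a, panels_b in comparisons:
        for stratum in STRATA:
            ba = bland_altman(estimates[label_a], estimates[label_b],
                              stratum, label_a, label_b)
            agree_rows.append({
                "method": "bland_altman", "comparison": ba.comparison,
                "stratum": stratum, "estimate": ba.bias,
                "ci_low": ba.ci_low, "ci_high": ba.ci_high,
                "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                "n": ba.n_vignettes, "flag": ""})
            pts = ba.points.assign(comparison=ba.comparison, stratum=stratum)
            point_frames.append(pts)
            mm = fit_bias_model(retained, panels_a, panels_b, stratum,
                                label_a, label_b)
            agree_rows.append({
                "method": "mixed_model", "comparison": mm.comparison,
                "stratum": stratum, "estimate": mm.bias,
                "ci_low": mm.ci_low, "ci_high": mm.ci_high,
                "loa_low": np.nan, "loa_high": np.nan, "n": mm.n_obs,
                "flag": "fallback" if mm.used_fallback else ""})
            if stratum == "all":
                manifest["results"][f"bias_{mm.comparison}"] = mm.bias
                manifest["results"][f"bias_{mm.comparison}_ci"] = [mm.ci_low,
                                                                   mm.ci_high]
        merged = estimates[label_a].merge(
            estimates[label_b], on=["surgery", "phase"], suffixes=("_a", "_b"))
        cons = consensus_sd_comparison(merged["sd_utility_a"],
                                       merged["sd_utility_b"],
                                       label_a, label_b)
        agree_rows.append({
            "method": "consensus_smd", "comparison": cons.comparison,
            "stratum": "all", "estimate": cons.smd_of_sds,
            "ci_low": cons.ci_low, "ci_high": cons.ci_high,
            "loa_low": np.nan, "loa_high": np.nan, "n": cons.n_vignettes,
            "flag": "degenerate" if cons.degenerate else ""})
    _write(pd.DataFrame(agree_rows), out / "agreement.csv", manifest, "agree")
    _write(pd.concat(point_frames, ignore_index=True),
           out / "bland_altman_points.csv", manifest, "agree")
    stage_done("agree")

    # model --------------------------------------------------------------
    t_stage = time.perf_counter()
    det_outcomes = {}
    for label in ("PP", "CP"):
        det_outcomes[label] = model_outcomes(parameters, estimates[label],
                                             source=label,
                                             delays=config.scenario_grid)
    daly = pd.concat([outcomes_table(o) for o in det_outcomes.values()],
                     ignore_index=True)
    _write(daly, out / "daly.csv", manifest, "model")
    stage_done("model")

    # psa ----------------------------------------------------------------
    t_stage = time.perf_counter()
    psa_results = {}
    for label in ("PP", "CP"):
        psa_results[label] = run_psa(
            parameters, estimates[label], n_draws=config.psa_draws,
            seed=manifest["psa_seed"], source=label, surv_sd=config.surv_sd,
            delays=config.scenario_grid)
    psa_frame = pd.concat([psa_table(r) for r in psa_results.values()],
                          ignore_index=True)
    _write(psa_frame, out / "psa.csv", manifest, "psa")
    stage_done("psa")

    # rank ---------------------------------------------------------------
    t_stage = time.perf_counter()
    labels_frame = parameters[["surgery", "label"]]
    rankings = {}
    for label in ("PP", "CP"):
        if config.rank_from_psa_mean:
            base = psa_table(psa_results[label])
        else:
            base = outcomes_table(det_outcomes[label])
        base = base.merge(labels_frame, on="surgery")
        rankings[label] = rank_surgeries(base, hrqol_source=label)
    rho = spearman_rho(rankings["PP"], rankings["CP"])
    shifts, adjacent_only = rank_shifts(rankings["PP"], rankings["CP"])
    comparison = pd.merge(
        rankings["PP"].frame.rename(columns={
            "rank": "rank_pp", "daly_per_month": "daly_per_month_pp"}),
        rankings["CP"].frame.rename(columns={
            "rank": "rank_cp", "daly_per_month": "daly_per_month_cp"}),
        on=["surgery", "label"]).sort_values("rank_pp")
    _write(comparison, out / "ranking.csv", manifest, "rank")
    _write(shifts_table(shifts), out / "rank_shifts.csv", manifest, "rank")
    manifest["results"]["spearman_rho"] = rho.rho
    manifest["results"]["spearman_p"] = rho.p_value
    manifest["results"]["adjacent_swaps_only"] = bool(adjacent_only)
    stage_done("rank")

    manifest["timings_s"]["total"] = round(time.perf_counter() - t_start, 4)
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
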