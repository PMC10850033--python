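"""Agreement stage: Bland–Altman, mixed-model bias, consensus SDs."""

import warnings

import numpy as np
import pandas as pd
import pytest

from surgdelay import (DataValidationError, GeneratorConfig, aggregate_panel,
                       apply_exclusions, bland_altman, consensus_sd_comparison,
                       fit_bias_model, generate_panel_responses,
                       generate_true_values)
from surgdelay.lmm import fit_crossed_intercepts
from surgdelay.synthetic import PHASE_POST, PHASE_PRE


def _estimates(mean_by_vignette, group="G"):
    rows = [(group, s, p, m, 0.1, 5) for (s, p), m in mean_by_vignette.items()]
    return pd.DataFrame(rows, columns=["group", "surgery", "phase",
                                       "mean_utility", "sd_utility", "n"])


VIGNETTES = [("S01", PHASE_PRE), ("S01", PHASE_POST),
             ("S02", PHASE_PRE), ("S02", PHASE_POST)]


class TestBlandAltman:
    def test_self_agreement(self):
        est = _estimates({v: 0.5 + 0.1 * i for i, v in enumerate(VIGNETTES)})
        res = bland_altman(est, est)
        assert res.bias == 0.0
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)

    def test_hand_computed_loa(self):
        a = _estimates({v: 0.5 for v in VIGNETTES[:2]})
        b = _estimates({VIGNETTES[0]: 0.6, VIGNETTES[1]: 0.4})
        res = bland_altman(a, b)
        # differences {+0.1, -0.1}: bias 0, sd = sqrt(0.02)
        assert res.bias == pytest.approx(0.0, abs=1e-15)
        assert res.loa_high == pytest.approx(1.96 * np.sqrt(0.02), abs=1e-12)
        assert res.loa_low == pytest.approx(-1.96 * np.sqrt(0.02), abs=1e-12)

    def test_bias_is_mean_of_pairwise_differences(self):
        rng = np.random.default_rng(5)
        means_a = {v: rng.uniform(0.2, 0.8) for v in VIGNETTES}
        means_b = {v: rng.uniform(0.2, 0.8) for v in VIGNETTES}
        res = bland_altman(_estimates(means_a), _estimates(means_b))
        brute = np.mean([means_b[v] - means_a[v] for v in VIGNETTES])
        assert res.bias == pytest.approx(brute, abs=1e-15)
        assert res.loa_low <= res.bias <= res.loa_high
        assert res.ci_low <= res.bias <= res.ci_high

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(6)
        a = _estimates({v: rng.uniform(0.2, 0.8) for v in VIGNETTES})
        b = _estimates({v: rng.uniform(0.2, 0.8) for v in VIGNETTES})
        fwd = bland_altman(a, b)
        rev = bland_altman(b, a)
        assert fwd.bias == pytest.approx(-rev.bias)
        assert fwd.loa_low == pytest.approx(-rev.loa_high)
        assert fwd.loa_high == pytest.approx(-rev.loa_low)

    def test_stratum_filters_phase(self):
        a = _estimates({v: 0.5 for v in VIGNETTES})
        b = _estimates({v: (0.6 if v[1] == PHASE_PRE else 0.4)
                        for v in VIGNETTES})
        pre = bland_altman(a, b, stratum=PHASE_PRE)
        post = bland_altman(a, b, stratum=PHASE_POST)
        assert pre.bias == pytest.approx(0.1)
        assert post.bias == pytest.approx(-0.1)
        assert pre.n_vignettes == post.n_vignettes == 2

    def test_vignette_mismatch_errors(self):
        a = _estimates({v: 0.5 for v in VIGNETTES})
        b = _estimates({v: 0.5 for v in VIGNETTES[:-1]})
        with pytest.raises(DataValidationError, match="S02"):
            bland_altman(a, b)

    def test_simulated_offset_recovered(self):
        """Mean BA bias over seeds approaches the configured panel offset."""
        biases = []
        for seed in range(60):
            cfg = GeneratorConfig(seed=seed, exclusion_injection={})
            truth = generate_true_values(cfg)
            resp = generate_panel_responses(cfg, truth)
            cp = aggregate_panel(resp, ["CP1", "CP2"], "CP")
            pp = aggregate_panel(resp, ["PP"], "PP")
            biases.append(bland_altman(cp, pp, "all", "CP", "PP").bias)
        assert np.mean(biases) == pytest.approx(0.07, abs=0.015)


class TestBiasModel:
    def test_noise_free_identifiability(self):
        """A pure constant offset is recovered exactly."""
        cfg = GeneratorConfig(
            panel_offset=0.05, sd_respondent=0.0, sd_vignette=0.0,
            sd_residual={"CP1": 0.0, "CP2": 0.0, "PP": 0.0},
            exclusion_injection={}, seed=3)
        truth = generate_true_values(cfg)
        resp = generate_panel_responses(cfg, truth)
        res = fit_bias_model(resp, ["CP1", "CP2"], ["PP"])
        assert res.bias == pytest.approx(0.05, abs=1e-6)

    def test_iid_limit_equals_bland_altman_bias(self):
        """Without random effects the model collapses to the paired estimate."""
        cfg = GeneratorConfig(
            panel_offset=0.04, sd_respondent=0.0, sd_vignette=0.0,
            exclusion_injection={}, seed=9)
        truth = generate_true_values(cfg)
        resp = generate_panel_responses(cfg, truth)
        mm = fit_bias_model(resp, ["CP1", "CP2"], ["PP"])
        cp = aggregate_panel(resp, ["CP1", "CP2"], "CP")
        pp = aggregate_panel(resp, ["PP"], "PP")
        ba = bland_altman(cp, pp, "all", "CP", "PP")
        assert mm.bias == pytest.approx(ba.bias, abs=1e-6)

    def test_stratified_variants_bracket_pooled(self, responses):
        retained, _ = apply_exclusions(responses)
        pooled = fit_bias_model(retained, ["CP1", "CP2"], ["PP"])
        pre = fit_bias_model(retained, ["CP1", "CP2"], ["PP"], PHASE_PRE)
        post = fit_bias_model(retained, ["CP1", "CP2"], ["PP"], PHASE_POST)
        lo, hi = sorted([pre.bias, post.bias])
        assert lo - 0.01 <= pooled.bias <= hi + 0.01

    def test_significance_follows_ci(self, responses):
        retained, _ = apply_exclusions(responses)
        res = fit_bias_model(retained, ["CP1", "CP2"], ["PP"])
        assert res.significant == (not res.ci_low <= 0.0 <= res.ci_high)
        assert res.ci_low <= res.bias <= res.ci_high

    def test_agrees_with_statsmodels_mixedlm(self):
        """Independent oracle: MixedLM with variance components on a
        small panel where its optimiser converges."""
        smf = pytest.importorskip("statsmodels.formula.api")
        cfg = GeneratorConfig(
            n_respondents_per_panel={"CP1": 12, "PP": 8},
            n_surgeries=5, seed=4, exclusion_injection={},
            sd_residual={"CP1": 0.10, "PP": 0.08})
        truth = generate_true_values(cfg)
        resp = generate_panel_responses(cfg, truth)
        ours = fit_bias_model(resp, ["CP1"], ["PP"])
        frame = resp.assign(u=resp.vas / 100,
                            is_pp=(resp.panel == "PP").astype(float),
                            is_post=(resp.phase == PHASE_POST).astype(float),
                            grp=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(
                "u ~ is_pp + is_post", frame, groups="grp",
                vc_formula={"surgery": "0 + C(surgery)",
                            "resp": "0 + C(respondent)"}).fit(reml=True)
        assert ours.bias == pytest.approx(fit.params["is_pp"], abs=2e-4)
        assert ours.se == pytest.approx(fit.bse["is_pp"], rel=0.05)

    def test_reml_fitter_recovers_variance_components(self):
        """Large balanced design: REML variance estimates land near truth."""
        rng = np.random.default_rng(12)
        q1, q2, reps = 8, 60, 4
        codes1 = np.tile(np.repeat(np.arange(q1), reps), q2)
        codes2 = np.repeat(np.arange(q2), q1 * reps)
        u1 = rng.normal(0, 0.3, q1)
        u2 = rng.normal(0, 0.2, q2)
        y = 1.0 + u1[codes1] + u2[codes2] + rng.normal(0, 0.1, len(codes1))
        X = np.ones((len(y), 1))
        fit = fit_crossed_intercepts(y, X, codes1, codes2)
        assert fit.converged
        assert np.sqrt(fit.sigma2_factor1) == pytest.approx(0.3, abs=0.15)
        assert np.sqrt(fit.sigma2_factor2) == pytest.approx(0.2, abs=0.07)
        assert np.sqrt(fit.sigma2_residual) == pytest.approx(0.1, abs=0.02)


class TestConsensus:
    def test_identical_sds_degenerate_zero(self):
        res = consensus_sd_comparison([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.smd_of_sds == 0.0
        assert res.degenerate
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)

    def test_constant_difference_flagged(self):
        res = consensus_sd_comparison([0.1, 0.1], [0.2, 0.2])
        assert res.degenerate
        assert res.mean_diff == pytest.approx(0.1)

    def test_point_estimate_inside_ci(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0.05, 0.2, 20)
        b = a + rng.normal(0.02, 0.01, 20)
        res = consensus_sd_comparison(a, b)
        assert res.ci_low <= res.smd_of_sds <= res.ci_high
        assert res.mean_diff == pytest.approx(np.mean(b - a))

    def test_citizen_spread_exceeds_physician_spread(self, responses):
        """Direction check: citizens (larger residual SD) show less
        consensus than physicians in the generated data."""
        retained, _ = apply_exclusions(responses)
        cp = aggregate_panel(retained, ["CP1", "CP2"], "CP")
        pp = aggregate_panel(retained, ["PP"], "PP")
        merged = pp.merge(cp, on=["surgery", "phase"], suffixes=("_pp", "_cp"))
        res = consensus_sd_comparison(merged["sd_utility_pp"],
                                      merged["sd_utility_cp"], "PP", "CP")
        assert res.smd_of_sds > 0
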