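import numpy as np
import pandas as pd
import pytest

from surgdelay import (GeneratorConfig, SurgeryParameters,
                       generate_panel_responses, generate_surgery_parameters,
                       generate_true_values)


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    """Study-sized generator configuration (the default conditions)."""
    return GeneratorConfig(seed=20260920)


@pytest.fixture(scope="session")
def truth(default_config) -> pd.DataFrame:
    return generate_true_values(default_config)


@pytest.fixture(scope="session")
def responses(default_config, truth) -> pd.DataFrame:
    return generate_panel_responses(default_config, truth)


@pytest.fixture(scope="session")
def parameters(default_config, truth) -> pd.DataFrame:
    return generate_surgery_parameters(default_config, truth)


@pytest.fixture
def noise_free_config() -> GeneratorConfig:
    """No noise, no offset, no injected offenders: identity conditions."""
    return GeneratorConfig(
        panel_offset=0.0, sd_respondent=0.0, sd_vignette=0.0,
        sd_residual={"CP1": 0.0, "CP2": 0.0, "PP": 0.0},
        exclusion_injection={}, seed=7)


def make_params(**overrides) -> SurgeryParameters:
    """A valid surgery parameter set with selective overrides."""
    base = dict(surgery="S01", label="S01", surv_pre=0.9, surv_post=0.97,
                hrqol_pre=0.5, hrqol_post=0.9, mean_age=60.0,
                t_no_surv_benefit=104.0, t_no_hrqol_benefit=104.0)
    base.update(overrides)
    return SurgeryParameters(**base)


@pytest.fixture
def simple_params() -> SurgeryParameters:
    return make_params()


def random_vas_table(rng: np.random.Generator, n_respondents: int = 8,
                     n_surgeries: int = 4) -> pd.DataFrame:
    """A random (possibly rule-violating) final-round response table."""
    rows = []
    for r in range(n_respondents):
        kind = rng.integers(0, 5)
        for s in range(n_surgeries):
            surgery = f"S{s + 1:02d}"
            pre = float(rng.integers(-5, 101))
            post = float(rng.integers(-5, 101))
            if kind == 1:
                pre, post = abs(pre), abs(post)
            if kind == 2:
                pre, post = 0.0, 0.0
            if kind == 3:
                pre, post = max(abs(pre), 10.0), max(abs(pre), 10.0) / 2
            rows.append((f"R{r:02d}", "CP1", 2, surgery, "pre-operative", pre))
            rows.append((f"R{r:02d}", "CP1", 2, surgery, "post-operative", post))
    return pd.DataFrame(rows, columns=["respondent", "panel", "round",
                                       "surgery", "phase", "vas"])
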