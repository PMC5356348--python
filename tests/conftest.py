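import numpy as np
import pandas as pd
import pytest

from reachdecomp.fitting import FitConfig, fit_nlme
from reachdecomp.synthetic import (control_config, generate_cohort,
                                   stroke_config)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Three identical subjects at the stroke medians, no noise at all."""
    cfg = stroke_config(3, seed=11, a_log_sd=0, tau_log_sd=0, c_sd=0,
                        d_sd=0, sigma_eps=0, retention_noise_sd=0)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def stroke_cohort():
    """Full 16-subject stroke cohort at the published operating point."""
    return generate_cohort(stroke_config(16, seed=3))


@pytest.fixture(scope="session")
def control_cohort():
    return generate_cohort(control_config(10, seed=103))


@pytest.fixture(scope="session")
def stroke_fit(stroke_cohort):
    """One seeded SAEM fit of the stroke cohort, shared across tests."""
    return fit_nlme(stroke_cohort.trials, FitConfig(seed=3))


@pytest.fixture(scope="session")
def joint_trials(stroke_cohort, control_cohort):
    return pd.concat([stroke_cohort.trials, control_cohort.trials],
                     ignore_index=True)
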