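import numpy as np
import pandas as pd
import pytest

from telotrack import SimConfig, simulate_cohort, simulate_qpcr


@pytest.fixture(scope="session")
def small_config():
    """A small but complete study: 3 cohorts x 120 children, balanced runs."""
    return SimConfig(seed=7, n_per_cohort=120, samples_per_run=60, followup_rate=1.0)


@pytest.fixture(scope="session")
def small_study(small_config):
    truth, cohort_table, sb = simulate_cohort(small_config)
    plates = simulate_qpcr(truth, small_config)
    return {"config": small_config, "truth": truth, "cohort": cohort_table,
            "sb": sb, "plates": plates}


@pytest.fixture(scope="session")
def noise_free_config():
    """Single-run, noise-free measurement: CNRQ must equal true T/S exactly
    (up to one global scale factor)."""
    return SimConfig(seed=11, n_per_cohort=40, samples_per_run=40,
                     cq_noise_sd=0.0, run_shift_sd=0.0, followup_rate=1.0)


@pytest.fixture(scope="session")
def noise_free_study(noise_free_config):
    truth, cohort_table, sb = simulate_cohort(noise_free_config)
    plates = simulate_qpcr(truth, noise_free_config)
    return {"config": noise_free_config, "truth": truth, "cohort": cohort_table,
            "sb": sb, "plates": plates}
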