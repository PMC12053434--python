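import numpy as np
import pandas as pd
import pytest

from episcore.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_reference_panel,
)


@pytest.fixture(scope="session")
def small_config():
    # unpaired cohort at a scale where every stage runs in well under a second
    return SimulationConfig(seed=7, n_subjects=40, paired=False, n_sites=2000,
                            noise_sd=0.05)


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, true_dmrs = simulate_reference_panel(small_config)
    return panel, true_dmrs


@pytest.fixture(scope="session")
def small_cohort(small_config, small_panel):
    panel, _ = small_panel
    return simulate_cohort(small_config, panel)


@pytest.fixture()
def toy_matrix():
    return pd.DataFrame(
        [[0.2, 0.8], [0.5, 0.5]],
        index=pd.Index(["chr1:100", "chr2:5"], name="site"),
        columns=["A", "B"],
    )


@pytest.fixture()
def toy_metadata():
    rows = []
    for i, (cmv, atg, risk) in enumerate(
        [("positive", "yes", "yes"), ("positive", "no", "no"),
         ("negative", "yes", "no"), ("positive", "no", "yes")]
    ):
        rows.append({
            "subject_id": f"S{i}", "sample_id": f"S{i}_x", "age": 40 + i,
            "sex": "M" if i % 2 else "F", "cmv": cmv, "transplant": "post",
            "atg": atg, "infection_risk": risk,
            "days_to_infection": [30, 365, 365, 100][i],
            "event_observed": ["yes", "no", "no", "yes"][i],
            "ancestry_pc1": 0.1 * i,
        })
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
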