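import numpy as np
import pytest

from audloc import (ApparatusConfig, DesignConfig, ObserverPopulation,
                    exclude_trials, mean_summaries, simulate_study,
                    summarize_conditions)

STUDY_SEED = 7


@pytest.fixture(scope="session")
def apparatus():
    return ApparatusConfig()


@pytest.fixture(scope="session")
def default_study(apparatus):
    """Full study at the design's scale, run once through estimation."""
    trials = simulate_study(DesignConfig(), apparatus, ObserverPopulation(),
                            STUDY_SEED)
    kept, exclusions = exclude_trials(trials)
    summaries = summarize_conditions(kept)
    means = mean_summaries(summaries)
    return {"trials": trials, "kept": kept, "exclusions": exclusions,
            "summaries": summaries, "means": means}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
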