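import numpy as np
import pandas as pd
import pytest

from gestwear.config import AlignmentScheme, SimulationConfig
from gestwear.cohort import align_cohort, build_cohort
from gestwear.profiles import baseline_stats
from gestwear.simulate import PregnancySpec, simulate_cohort


@pytest.fixture(scope="session")
def fixture_bundle():
    """Fixture-mode cohort with its eligibility result and aligned frames."""
    cohort = simulate_cohort(SimulationConfig(), seed=1, fixture=True)
    result = build_cohort(cohort.survey, cohort.daily, AlignmentScheme())
    included = set(result.included["pregnancy_id"])
    daily = cohort.daily[cohort.daily["pregnancy_id"].isin(included)]
    aligned = align_cohort(daily, cohort.survey, anchor="dkp")
    bstats = baseline_stats(aligned)
    return {
        "cohort": cohort,
        "result": result,
        "aligned": aligned,
        "baseline": bstats,
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A modest mixed cohort for analysis-level tests."""
    cfg = SimulationConfig(n_full_term=12, n_efl=4)
    cohort = simulate_cohort(cfg, seed=7)
    aligned = align_cohort(cohort.daily, cohort.survey, anchor="dkp")
    return {"cfg": cfg, "cohort": cohort, "aligned": aligned}


@pytest.fixture
def ft_spec():
    return PregnancySpec(
        participant_id="P1",
        pregnancy_id="G1",
        age_bin="30-34",
        dkp="2020-06-01",
        dps="2021-02-15",
        outcome="full_term",
    )


@pytest.fixture
def noise_free_cfg():
    base = SimulationConfig()
    return SimulationConfig(
        noise_sd={k: 0.0 for k in base.noise_sd},
        between_subject_sd={k: 0.0 for k in base.between_subject_sd},
        missing_day_rate=0.0,
        nonwear_rate=0.0,
    )
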