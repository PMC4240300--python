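import numpy as np
import pandas as pd
import pytest

import flankcrowd as fc


@pytest.fixture(scope="session")
def glyphset():
    return fc.default_glyphset()


@pytest.fixture(scope="session")
def cohort_default():
    """Default three-group cohort at seed 1 (shared: simulation is the slow part)."""
    return fc.simulate_cohort(fc.CohortConfig(seed=1))


def make_trial(
    target="N",
    flankers=("Z", "H"),
    response="N",
    participant="P01",
    group="PCA",
    task=2,
    spacing="condensed",
    polarity="none",
    prompted=False,
    distracted=False,
    latency=800.0,
):
    return {
        "participant_id": participant,
        "group": group,
        "task": task,
        "spacing_condition": spacing,
        "polarity_condition": polarity,
        "target": target,
        "flanker_left": flankers[0] if flankers else "",
        "flanker_right": flankers[1] if flankers else "",
        "response": response,
        "prompted": prompted,
        "distracted": distracted,
        "latency_ms": latency,
    }


def trials_frame(rows):
    return pd.DataFrame(rows, columns=fc.taxonomy.TRIAL_COLUMNS)


@pytest.fixture
def latency_fixture():
    """One participant: ten 500 ms correct trials plus one 5000 ms correct trial."""
    rows = [make_trial(response="N", latency=500.0) for _ in range(10)]
    rows.append(make_trial(response="N", latency=5000.0))
    return trials_frame(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
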