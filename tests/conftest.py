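import numpy as np
import pandas as pd
import pytest

from cptspect.simulate import TaskSpec, generate_trial_sequence


@pytest.fixture(scope="session")
def default_spec():
    return TaskSpec()


@pytest.fixture(scope="session")
def default_sequence(default_spec):
    return generate_trial_sequence(default_spec, seed=1)


def make_trials(
    n_trials,
    target_idx,
    responses,
    soa_ms=985.0,
    participant_id="p0",
    group="HC",
    age=40.0,
    sex="F",
):
    """Hand-built trial table: ``responses`` maps trial_index -> latency ms."""
    idx = np.arange(n_trials)
    rt = np.full(n_trials, np.nan)
    for k, v in responses.items():
        rt[k] = v
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "group": group,
            "age": age,
            "sex": sex,
            "trial_index": idx,
            "onset_time_s": idx * soa_ms / 1000.0,
            "stimulus": "X",
            "is_target": np.isin(idx, list(target_idx)),
            "rt_ms": rt,
        }
    )
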