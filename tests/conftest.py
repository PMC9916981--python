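import numpy as np
import pandas as pd
import pytest

from hypkernel import models as hk_models
from hypkernel import simulate
from hypkernel.kernel import AU_COLUMNS


@pytest.fixture(scope="session")
def registry():
    return hk_models.load_registry("basic6")


@pytest.fixture(scope="session")
def registry_by_name(registry):
    return {m.name: m for m in registry}


@pytest.fixture(scope="session")
def basic6_categories():
    return hk_models.task_categories("basic6")


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-culture synthetic experiment, 'other' rows included."""
    return simulate.simulate_dataset(
        n_participants=8, n_trials=200, n_shared=40, seed=11
    )


@pytest.fixture(scope="session")
def small_trials(small_dataset):
    """The same experiment after the 'other' exclusion filter."""
    return small_dataset.loc[small_dataset["response"] != "other"].reset_index(
        drop=True
    )


def make_trials(S, responses, participant="p0", culture="sim"):
    """Wrap a stimulus matrix and response labels as a minimal trial table."""
    df = pd.DataFrame(np.asarray(S, dtype=float), columns=list(AU_COLUMNS))
    df.insert(0, "face_id", "f0")
    df.insert(0, "culture", culture)
    df.insert(0, "participant_id", participant)
    df["response"] = list(responses)
    return df
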