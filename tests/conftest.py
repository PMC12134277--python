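import numpy as np
import pytest

from eisrisk.synth import (
    default_human_config,
    default_pig_config,
    generate_cohort,
    human_class_specs,
    pig_class_specs,
)


@pytest.fixture(scope="session")
def human_ds():
    """Default human cohort (clinical-table structure), fixed seed."""
    return generate_cohort(default_human_config(seed=42), human_class_specs())


@pytest.fixture(scope="session")
def pig_ds():
    """Default porcine cohort (220 normal / 80 treated readings), fixed seed."""
    return generate_cohort(default_pig_config(seed=42), pig_class_specs())


@pytest.fixture
def rng():
    return np.random.default_rng(20250924)
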