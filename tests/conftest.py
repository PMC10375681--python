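import numpy as np
import pytest

from mitorea.reference import load_reference
from mitorea.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def genome():
    return load_reference()


@pytest.fixture(scope="session")
def small_cohort():
    """Two groups of four subjects at the default study conditions."""
    config = SimConfig(
        groups={"CTRL": 4, "maternal": 4},
        structure_seed=11,
        noise_seed=12,
    )
    return simulate_cohort(config)


def make_records(sense_vals, anti_vals, position=100):
    """Build a (sense, antisense) record pair from two 4-vectors (A,C,G,T)."""
    from mitorea.arraydata import ANTISENSE, SENSE, BASES, IntensityRecord

    return (
        IntensityRecord(position, SENSE, dict(zip(BASES, map(float, sense_vals)))),
        IntensityRecord(position, ANTISENSE, dict(zip(BASES, map(float, anti_vals)))),
    )
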