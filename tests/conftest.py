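import numpy as np
import pytest

from moodinstability.cohort import SyntheticCohortConfig, generate_cohort
from moodinstability.instability import InstabilitySeries, InstabilityWindow


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully-featured cohort shared by read-only tests."""
    cfg = SyntheticCohortConfig(n_bd=20, n_pc=8, n_hc=10, n_timepoints=31, seed=42)
    ds, truth = generate_cohort(cfg)
    return ds, truth, cfg


def make_series(raw_values, participant_id="p1", scale="PHQ9", k=6, start=0):
    """Build an InstabilitySeries directly from raw variance values."""
    return InstabilitySeries(
        participant_id,
        scale,
        k,
        [InstabilityWindow(start + i, float(v)) for i, v in enumerate(raw_values)],
    )
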