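"""Shared fixtures: simulated trials and cohort feature matrices.

The expensive artifacts (a 24-participant cohort and its two feature
matrices) are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from wheelmotion.io import WheelchairGeometry, synchronize
from wheelmotion.pipeline import cohort_feature_matrix
from wheelmotion.simulate import (
    NoiseModel,
    build_participant_script,
    generate_cohort,
    simulate_trial,
    _participant_styles,
)

COHORT_SEED = 11


@pytest.fixture(scope="session")
def geometry():
    return WheelchairGeometry()


@pytest.fixture(scope="session")
def cohort(geometry):
    """Default 24-participant cohort with sensor noise."""
    return generate_cohort(n_participants=24, seed=COHORT_SEED, geometry=geometry)


@pytest.fixture(scope="session")
def cohort_features(cohort, geometry):
    """(fm_s1, fm_s2, segments_s1, segments_s2) for the default cohort."""
    fm1, segs1 = cohort_feature_matrix(cohort, "S1", geometry)
    fm2, segs2 = cohort_feature_matrix(cohort, "S2", geometry)
    return fm1, fm2, segs1, segs2


@pytest.fixture(scope="session")
def noiseless_trial(geometry):
    """One full simulated measurement rendered without sensor noise."""
    rng = np.random.default_rng(4)
    active, passive, _ = _participant_styles("amputation", rng, True)
    script = build_participant_script(active, passive, rng)
    return simulate_trial(
        script, geometry, NoiseModel.noiseless(), seed=13, participant_id="P00",
        diagnosis="amputation",
    )


@pytest.fixture(scope="session")
def noiseless_synced(noiseless_trial):
    wheel, frame = synchronize(noiseless_trial.wheel, noiseless_trial.frame)
    return wheel, frame
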