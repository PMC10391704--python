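import numpy as np
import pandas as pd
import pytest

import ampcyt as ac
from ampcyt.events import compute_features


@pytest.fixture(scope="session")
def acq() -> ac.AcquisitionConfig:
    return ac.AcquisitionConfig()


@pytest.fixture(scope="session")
def mixed_stream(acq) -> ac.StreamBundle:
    """Untreated beads + bacteria + RBC sample, 4 s, fixed seed."""
    return ac.generate_stream(
        ac.default_populations(), 0.0, ac.DoseModel(), acq, duration=4.0, seed=2024
    )


@pytest.fixture(scope="session")
def mixed_features(mixed_stream) -> pd.DataFrame:
    """Fully processed (detected, fitted, filtered) features of mixed_stream."""
    feats = ac.process_stream(mixed_stream)
    return ac.quality_filter(feats)


def features_from_truth(stream: ac.StreamBundle) -> pd.DataFrame:
    """Feature table computed directly from ground-truth amplitudes.

    Bypasses detection/fitting so calibration and gating can be exercised
    quickly and without estimation noise; keeps the true labels in a
    ``true_label`` column.
    """
    gt = stream.ground_truth
    events = gt.copy().reset_index(drop=True)
    events["event_id"] = np.arange(len(events))
    events["residual"] = 0.0
    events["quality_flag"] = True
    feats = compute_features(events, tuple(stream.frequencies))
    feats = feats.rename(columns={"label": "true_label"})
    return feats
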