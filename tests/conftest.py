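"""Shared fixtures: one small synthetic dataset reused across modules."""

import numpy as np
import pytest

from pentail.synthetic import SynthConfig, generate

#: Small but fully structured dataset: 6 pens x 2 min at 10 fps, with the
#: default planted-signature strength.  Feature width is reduced so unit
#: tests stay fast; the acceptance suite runs the full-width conditions.
SMALL_CONFIG = SynthConfig(
    n_pens=6,
    frames_per_pen=1200,
    n_features=96,
    signature_dim=16,
    event_rate=4.0,
    distractor_rates={"negative_social": 3.0, "nursing": 2.0},
    seed=123,
)


@pytest.fixture(scope="session")
def small_data():
    """(config, FrameTable, per-pen raw features, event log)."""
    table, features, event_log = generate(SMALL_CONFIG)
    return SMALL_CONFIG, table, features, event_log


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
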