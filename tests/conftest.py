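"""Shared fixtures: small synthetic duets and once-per-session trained nets.

The trained models here use reduced windows and durations so the unit suite
stays fast; the full published configuration is exercised by the acceptance
benchmark test.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from duetseg import (
    DuetConfig,
    SegNetConfig,
    build_network,
    extract_training_windows,
    synth_duet,
    train_network,
)
from duetseg.synth import strip_unilateral_portions


@pytest.fixture(scope="session")
def duet_60s():
    """One 60 s default-condition duet recording with ground truth."""
    return synth_duet(DuetConfig(total_duration_s=60.0, seed=11))


@pytest.fixture(scope="session")
def heldout_duet_60s():
    """A second 60 s duet (different seed) for held-out checks."""
    return synth_duet(DuetConfig(total_duration_s=60.0, seed=99))


@pytest.fixture(scope="session")
def small_models(duet_60s):
    """A reduced four-class + two-class model pair trained on 60 s of audio.

    Window sizes 801/401 keep training to seconds while preserving the
    architecture; fusion and pipeline tests share these.
    """
    rec, truth = duet_60s
    c4 = SegNetConfig(window_samples=801, epochs=3, seed=0)
    m4 = build_network(c4)
    train_network(m4, extract_training_windows(rec, truth.labels, c4), c4)

    rec2, labels2 = strip_unilateral_portions(rec, truth.labels)
    c2 = SegNetConfig.two_class(window_samples=401, epochs=2, seed=0)
    m2 = build_network(c2)
    train_network(m2, extract_training_windows(rec2, labels2, c2), c2)
    return m4, m2


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
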