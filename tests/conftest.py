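"""Shared fixtures: small synthetic sessions generated at test time."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from forcemi.containers import TrialSet
from forcemi.synthetic import (ERDSpec, SessionConfig, TrialTimeline,
                               generate_session, generate_trial)


@pytest.fixture(scope="session")
def timeline() -> TrialTimeline:
    return TrialTimeline()


@pytest.fixture(scope="session")
def tiny_session():
    """12-trial session at 250 Hz: enough to exercise the full chain."""
    cfg = SessionConfig(fs=250.0, n_rounds=3, trials_per_round=4,
                        round_class_order=(0, 1, 2), seed=7)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def erd_trialset_factory(timeline):
    """Factory for epoched single-channel-group trial sets with known ERD.

    Generates trials directly at 128 Hz (the post-downsampling rate) so
    spectral tests are fast; the epoch window is (-1.5, 6.5) s so the
    full baseline second has clean STFT columns.
    """
    def make(depth_db: float, n_trials: int = 100, seed: int = 1,
             channels=("C3",), window=(-1.5, 6.5), fs=128.0) -> TrialSet:
        erd = ERDSpec(depth_db_by_class=(depth_db,) * 3)
        rng = np.random.default_rng(seed)
        a = int(round((timeline.mi_onset_s + window[0]) * fs))
        b = int(round((timeline.mi_onset_s + window[1]) * fs))
        data = np.stack([
            generate_trial(timeline, erd, 0, channels, None, rng, fs)[:, a:b]
            for _ in range(n_trials)])
        return TrialSet(data, np.zeros(n_trials, dtype=int), fs,
                        window, list(channels))
    return make


@pytest.fixture()
def suppress_mastoid_warning():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*mastoid.*")
        yield
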