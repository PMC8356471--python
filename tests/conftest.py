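"""Shared fixtures: small synthetic sessions preprocessed once per run.

Problem sizes are scaled to a single desk CPU: a 6-sensor occipital
patch, 600 Hz acquisition downsampled to the 150 Hz decoding rate for
SSVEP, and 250 Hz acquisition downsampled to 50 Hz for the ERP decoder.
"""

from __future__ import annotations

import numpy as np
import pytest

from opmbci.containers import SensorLayout, TargetLayout
from opmbci.preprocessing import (
    bandpass_filter,
    baseline_correct,
    downsample,
    extract_epochs,
)
from opmbci.synthetic import (
    ErpSessionConfig,
    NoiseSpec,
    SsvepSessionConfig,
    generate_erp_session,
    generate_ssvep_session,
)

#: default generator noise level (white + 1/f quadrature sum)
NOISE_SIGMA = float(np.hypot(200.0, 200.0))


@pytest.fixture(scope="session")
def sensor_grid() -> SensorLayout:
    return SensorLayout.grid(2, 3)


@pytest.fixture(scope="session")
def target_layout() -> TargetLayout:
    return TargetLayout.default()


def prep_ssvep(rec, trial_ms=4000.0, fs_dec=150.0):
    rec = bandpass_filter(rec, 4.0, 40.0)
    ep = extract_epochs(rec, 0.0, trial_ms)
    return downsample(ep, fs_dec)


@pytest.fixture(scope="session")
def ssvep_train_epochs(sensor_grid, target_layout):
    """72-trial training session at response amplitude 5x the noise sigma."""
    cfg = SsvepSessionConfig(
        layout=target_layout, reps=8, fs_hz=600.0, seed=3,
        amplitude=5.0 * NOISE_SIGMA,
    )
    return prep_ssvep(generate_ssvep_session(cfg, sensor_grid))


@pytest.fixture(scope="session")
def ssvep_model(ssvep_train_epochs, target_layout):
    from opmbci.beamformer import train_ssvep_model

    return train_ssvep_model(
        ssvep_train_epochs, target_layout, discard_before_ms=150.0
    )


def prep_erp(rec, fs_dec=50.0):
    rec = bandpass_filter(rec, 0.5, 15.0)
    ep = baseline_correct(extract_epochs(rec, -200.0, 600.0), -200.0, 0.0)
    return downsample(ep, fs_dec)


@pytest.fixture(scope="session")
def erp_epochs(sensor_grid):
    """Default 45-trial motion-onset session, fully preprocessed."""
    cfg = ErpSessionConfig(fs_hz=250.0, seed=2)
    return prep_erp(generate_erp_session(cfg, sensor_grid))


@pytest.fixture(scope="session")
def noisy_erp_epochs(sensor_grid):
    """Same session at 10x noise, where repetition averaging matters."""
    cfg = ErpSessionConfig(
        fs_hz=250.0, seed=2, noise=NoiseSpec(2000.0, 1.0, 2000.0)
    )
    return prep_erp(generate_erp_session(cfg, sensor_grid))
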