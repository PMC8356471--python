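"""Seeded generators for synthetic OPM-MEG / EEG BCI sessions.

Two visual paradigms are emulated so the full decoding pipeline can be
exercised end-to-end without access to real recordings:

* **Motion-onset ERP/ERF sessions** — 45 trials in which each of nine
  on-screen crosses expands 5 times in pseudorandom block order with a
  jittered inter-stimulus interval of 150 +/- 75 ms.  Gazing the expanding
  cross evokes an N/M200 component (~190 ms) followed by a P/M300
  (~350 ms); non-gazed expansions evoke nothing.
* **SSVEP sessions** — either a single square flickering at integer
  frequencies 8-12 and 25-29 Hz (10 repetitions each, 4-s trials), or a
  nine-target grid where each target carries a unique frequency-phase
  combination (training: each target cued 8 times in block order).

Signals are built from three ingredients: a deterministic evoked /
oscillatory component with a spatially smooth gain over the sensor array
(dipolar for magnetometers — neighbouring sensors show a polarity
reversal — single-signed for EEG), white Gaussian sensor noise, and
1/f^beta background noise emulating the higher low-frequency noise floor
of OPMs.  Every generator is driven by a single ``numpy`` Generator
seeded from the config, so identical configs produce bit-identical
recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ContinuousRecording, SensorLayout, TargetLayout

__all__ = [
    "NoiseSpec",
    "ComponentSpec",
    "ErpSessionConfig",
    "SsvepSessionConfig",
    "generate_erp_session",
    "generate_ssvep_session",
    "generate_training_schedule",
    "flicker_epoch",
    "response_gains",
    "make_noise",
    "default_erp_components",
]


# ---------------------------------------------------------------------------
# noise and spatial gain models


@dataclass(frozen=True)
class NoiseSpec:
    """Additive sensor noise: white Gaussian plus 1/f^beta background.

    ``white_sigma`` and ``pink_scale`` are standard deviations in sensor
    units (fT or uV); ``pink_exponent`` is the power-spectral slope beta
    (power ~ 1/f^beta, default 1).
    """

    white_sigma: float = 200.0
    pink_exponent: float = 1.0
    pink_scale: float = 200.0

    def __post_init__(self) -> None:
        if self.white_sigma < 0 or self.pink_scale < 0:
            raise ValueError("noise scales must be non-negative")

    @property
    def total_sigma(self) -> float:
        return math.hypot(self.white_sigma, self.pink_scale)


def make_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs_hz: float,
    noise: NoiseSpec,
) -> np.ndarray:
    """Channels x samples noise realisation for the given spec.

    The 1/f^beta component is synthesised by shaping a white complex
    spectrum with f^(-beta/2) and inverse-transforming; each channel is
    rescaled to an empirical standard deviation of ``pink_scale``.
    """
    out = np.zeros((n_channels, n_samples))
    if noise.white_sigma > 0:
        out += rng.standard_normal((n_channels, n_samples)) * noise.white_sigma
    if noise.pink_scale > 0 and n_samples > 2:
        freqs = np.fft.rfftfreq(n_samples, 1.0 / fs_hz)
        shape = np.zeros_like(freqs)
        shape[1:] = freqs[1:] ** (-noise.pink_exponent / 2.0)
        z = rng.standard_normal((n_channels, freqs.size)) + 1j * rng.standard_normal(
            (n_channels, freqs.size)
        )
        pink = np.fft.irfft(z * shape, n=n_samples, axis=-1)
        sd = pink.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        out += pink / sd * noise.pink_scale
    return out


def _kind_gain(kind: str, dx: float, dy: float, sigma: float) -> float:
    r2 = dx * dx + dy * dy
    if kind == "mag":
        # dipolar field pattern: polarity reversal across the source axis
        return (dx / sigma) * math.exp(-r2 / (2 * sigma * sigma))
    # EEG (and derived channels): spatially blurred single-signed bump
    return math.exp(-r2 / (2 * sigma * sigma))


def response_gains(
    layout: SensorLayout,
    center: tuple[float, float] = (0.0, 0.0),
    sigma: float = 1.5,
) -> np.ndarray:
    """Per-channel spatial gain of a focal cortical source.

    Magnetometers see a signed dipolar pattern g(x) = x * exp(-r^2/2s^2)
    along the x scalp axis; EEG sees a single-signed Gaussian.  The gain
    vector is normalised so its largest magnitude is exactly 1.
    """
    g = np.array(
        [
            _kind_gain(k, p[0] - center[0], p[1] - center[1], sigma)
            for k, p in zip(layout.kinds, layout.positions)
        ]
    )
    peak = np.abs(g).max()
    return g / peak if peak > 0 else g


# ---------------------------------------------------------------------------
# evoked components


@dataclass(frozen=True)
class ComponentSpec:
    """One evoked component: a Gaussian-windowed half-sine deflection.

    The waveform spans ``width_ms`` centred on ``latency_ms`` and reaches
    exactly ``amplitude`` at the latency sample.  ``center``/``sigma``
    parameterise the spatial gain over the sensor array.
    """

    latency_ms: float
    width_ms: float
    amplitude: float
    center: tuple[float, float] = (0.0, 0.0)
    sigma: float = 1.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude):
            raise ValueError("component amplitude must be finite")
        if self.width_ms <= 0:
            raise ValueError("component width must be positive")


def default_erp_components() -> tuple[ComponentSpec, ...]:
    """N/M200 and P/M300 components with the canonical motion-onset
    latencies and magnetometer amplitudes (fT)."""
    return (
        ComponentSpec(latency_ms=191.0, width_ms=100.0, amplitude=-567.34,
                      center=(0.0, -0.5), sigma=1.5),
        ComponentSpec(latency_ms=347.0, width_ms=160.0, amplitude=1103.38,
                      center=(0.0, 0.5), sigma=2.0),
    )


def component_waveform(
    spec: ComponentSpec, fs_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Onset-relative sample indices and waveform values of a component."""
    half = spec.width_ms / 2.0
    first = math.ceil((spec.latency_ms - half) * fs_hz / 1000.0)
    last = math.floor((spec.latency_ms + half) * fs_hz / 1000.0)
    idx = np.arange(first, last + 1)
    t_ms = idx * 1000.0 / fs_hz
    u = t_ms - spec.latency_ms
    half_sine = np.sin(np.pi * (u + half) / spec.width_ms)
    window = np.exp(-(u ** 2) / (2 * (spec.width_ms / 4.0) ** 2))
    return idx, spec.amplitude * half_sine * window


# ---------------------------------------------------------------------------
# session configs


@dataclass(frozen=True)
class ErpSessionConfig:
    """Motion-onset ERP session layout and signal model parameters."""

    n_trials: int = 45
    n_targets: int = 9
    reps_per_target: int = 5
    isi_mean_ms: float = 150.0
    isi_jitter_ms: float = 75.0
    stim_duration_ms: float = 150.0
    pre_stim_s: float = 2.0
    post_trial_s: float = 1.0
    components: tuple[ComponentSpec, ...] = field(default_factory=default_erp_components)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    fs_hz: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.isi_jitter_ms < 0:
            raise ValueError("jitter must be non-negative")
        if self.isi_mean_ms - self.isi_jitter_ms <= 0:
            raise ValueError("jitter allows a non-positive inter-stimulus interval")
        if self.reps_per_target < 1:
            raise ValueError("reps_per_target must be >= 1")
        if self.n_trials % self.n_targets:
            raise ValueError("n_trials must be a multiple of n_targets (block cues)")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")


@dataclass(frozen=True)
class SsvepSessionConfig:
    """SSVEP session: single-square frequency sweep or 9-target grid.

    Exactly one of ``frequencies`` (single-square mode) or ``layout``
    (frequency-phase grid mode) must be given.  ``latency_s`` models the
    visual-system latency, shifting the response phase by -2*pi*f*latency
    so the phase-versus-frequency relation has the expected negative
    slope.
    """

    frequencies: tuple[float, ...] | None = None
    layout: TargetLayout | None = None
    trial_s: float = 4.0
    reps: int = 10
    amplitude: float = 300.0
    response_center: tuple[float, float] = (0.0, 0.0)
    response_sigma: float = 1.5
    latency_s: float = 0.1
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    inter_trial_mean_s: float = 1.75
    inter_trial_jitter_s: float = 0.25
    fs_hz: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.frequencies is None) == (self.layout is None):
            raise ValueError("give exactly one of frequencies or layout")
        if self.frequencies is not None:
            object.__setattr__(self, "frequencies", tuple(float(f) for f in self.frequencies))
            if any(f <= 0 for f in self.frequencies):
                raise ValueError("frequencies must be positive")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.trial_s <= 0 or self.fs_hz <= 0:
            raise ValueError("durations and sampling rate must be positive")
        for f in self.all_frequencies():
            if f >= self.fs_hz / 2:
                raise ValueError(f"frequency {f} Hz is at or above Nyquist")

    def all_frequencies(self) -> tuple[float, ...]:
        if self.frequencies is not None:
            return self.frequencies
        return tuple(self.layout.frequency_hz)

    @classmethod
    def single_square(cls, **kw) -> "SsvepSessionConfig":
        """The integer-frequency sweep: 8-12 and 25-29 Hz, 10 reps each."""
        kw.setdefault("frequencies", tuple(range(8, 13)) + tuple(range(25, 30)))
        return cls(**kw)


# ---------------------------------------------------------------------------
# schedules


def _block_design(rng: np.random.Generator, n_items: int, reps: int) -> np.ndarray:
    """Pseudorandom block order: each block of ``n_items`` is a permutation."""
    return np.concatenate([rng.permutation(n_items) for _ in range(reps)])


def generate_training_schedule(
    layout: TargetLayout, reps: int, seed: int
) -> np.ndarray:
    """Cued-target order for a frequency-phase training session.

    Block design: every contiguous block of 9 cues is a permutation of
    the 9 targets, so ``reps`` repetitions give ``9 * reps`` cues.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    return _block_design(np.random.default_rng(seed), layout.n_targets, reps)


# ---------------------------------------------------------------------------
# ERP session


def generate_erp_session(
    config: ErpSessionConfig, layout: SensorLayout
) -> ContinuousRecording:
    """Simulate a full motion-onset session as a continuous recording.

    One event row is emitted per stimulation, labelled with the trial,
    the stimulated target, and the trial's cued target.  Evoked
    components are injected only at stimulations of the cued target.
    """
    if layout.n_channels < 1:
        raise ValueError("layout must contain at least one channel")
    rng = np.random.default_rng(config.seed)
    fs = config.fs_hz

    cue_reps = config.n_trials // config.n_targets
    cued = _block_design(rng, config.n_targets, cue_reps)

    rows = []
    t = 0.0  # running time in seconds
    for trial, cue in enumerate(cued):
        t += config.pre_stim_s
        order = _block_design(rng, config.n_targets, config.reps_per_target)
        for stim in order:
            rows.append((int(round(t * fs)), trial, int(stim), int(cue)))
            isi = config.isi_mean_ms + rng.uniform(-1, 1) * config.isi_jitter_ms
            t += (config.stim_duration_ms + isi) / 1000.0
        t += config.post_trial_s
    events = pd.DataFrame(rows, columns=["sample", "trial", "stimulated", "cued"])

    # leave room for the slowest component's tail after the last event
    tail_ms = max((c.latency_ms + c.width_ms for c in config.components), default=0.0)
    n_samples = int(round(t * fs)) + int(math.ceil(tail_ms * fs / 1000.0)) + 1

    data = make_noise(rng, layout.n_channels, n_samples, fs, config.noise)
    for spec in config.components:
        idx, wave = component_waveform(spec, fs)
        gains = response_gains(layout, spec.center, spec.sigma)
        hit = events.loc[events.stimulated == events.cued, "sample"].to_numpy()
        for onset in hit:
            sl = onset + idx
            ok = (sl >= 0) & (sl < n_samples)
            data[:, sl[ok]] += np.outer(gains, wave[ok])

    return ContinuousRecording(data=data, fs_hz=fs, layout=layout, events=events)


# ---------------------------------------------------------------------------
# SSVEP sessions


def flicker_epoch(
    frequency_hz: float,
    phase_rad: float,
    duration_s: float,
    fs_hz: float,
    gains: np.ndarray,
    amplitude: float,
    latency_s: float,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One channels x samples steady-state response epoch.

    The oscillation is ``amplitude * cos(2*pi*f*t + phase - 2*pi*f*latency)``
    scaled by the per-channel spatial gain, plus sensor noise — i.e. the
    epoch phase in the cosine-at-onset convention is
    ``phase - 2*pi*f*latency``.
    """
    if frequency_hz >= fs_hz / 2:
        raise ValueError("flicker frequency at or above Nyquist")
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    osc = np.cos(2 * np.pi * frequency_hz * (t - latency_s) + phase_rad)
    x = np.outer(gains, amplitude * osc)
    return x + make_noise(rng, len(gains), n, fs_hz, noise)


def generate_ssvep_session(
    config: SsvepSessionConfig, layout: SensorLayout
) -> ContinuousRecording:
    """Simulate a flicker session (single square or 9-target grid).

    Trial count is ``len(frequencies) * reps`` (single-square) or
    ``9 * reps`` (grid); each event row records the trial, the gazed
    target index, and its frequency and phase.
    """
    if layout.n_channels < 1:
        raise ValueError("layout must contain at least one channel")
    rng = np.random.default_rng(config.seed)
    fs = config.fs_hz
    gains = response_gains(layout, config.response_center, config.response_sigma)

    if config.frequencies is not None:
        order = _block_design(rng, len(config.frequencies), config.reps)
        freqs = np.asarray(config.frequencies)[order]
        phases = np.zeros_like(freqs)
        targets = order
    else:
        targets = _block_design(rng, config.layout.n_targets, config.reps)
        freqs = config.layout.frequency_hz[targets]
        phases = config.layout.phase_rad[targets]

    n_trial = int(round(config.trial_s * fs))
    rows, chunks = [], []
    t = config.inter_trial_mean_s
    for trial, (tg, f, ph) in enumerate(zip(targets, freqs, phases)):
        onset = int(round(t * fs))
        rows.append((onset, trial, int(tg), float(f), float(ph)))
        gap = config.inter_trial_mean_s + rng.uniform(-1, 1) * config.inter_trial_jitter_s
        t += config.trial_s + max(gap, 0.0)
    events = pd.DataFrame(
        rows, columns=["sample", "trial", "target", "frequency_hz", "phase_rad"]
    )

    n_samples = int(round(t * fs)) + 1
    data = make_noise(rng, layout.n_channels, n_samples, fs, config.noise)
    tt = np.arange(n_trial) / fs
    for onset, _, _, f, ph in rows:
        osc = np.cos(2 * np.pi * f * (tt - config.latency_s) + ph)
        data[:, onset : onset + n_trial] += np.outer(gains, config.amplitude * osc)

    return ContinuousRecording(data=data, fs_hz=fs, layout=layout, events=events)
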