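"""Frequency-domain SSVEP characterisation.

For each flicker trial the response is summarised by three features:

* the **spectral SNR** — the amplitude of the DFT bin at the gazed
  frequency divided by the mean amplitude of the six neighbouring bins
  on each side (12 bins total, never including DC or Nyquist),
* the **phase** of that DFT coefficient in the cosine-at-onset
  convention, mapped to (-pi, pi],
* the **circular standard deviation** sqrt(-2 ln R) of the phases across
  repeated trials of the same frequency, R being the mean resultant
  length.

The time-domain counterpart is the *stereotypical response*: the average
of all two-period 50%-overlap segments across all epochs of a given
frequency, with a BCa bootstrap confidence band.

Both SNR and circular std are scale-free; amplitudes are exported with
the |DFT|/N normalisation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EpochSet, EvokedResponse
from .evoked import bca_bootstrap_ci
from .preprocessing import segment_two_periods

__all__ = [
    "amplitude_spectrum",
    "spectral_snr",
    "phase_at",
    "circular_std",
    "stereotypical_response",
    "snr_phase_table",
]

#: spectral-SNR ratios above this are reported as the cap (noise-free bins)
SNR_CAP = 1e6


def _bin_index(n_samples: int, fs_hz: float, f_hz: float) -> int:
    k = f_hz * n_samples / fs_hz
    k_round = int(round(k))
    if abs(k - k_round) > 1e-6:
        raise ValueError(
            f"{f_hz} Hz is not on a DFT bin for {n_samples} samples at {fs_hz} Hz"
        )
    if not 0 < k_round < n_samples / 2:
        raise ValueError("frequency must lie strictly between DC and Nyquist")
    return k_round


def amplitude_spectrum(x: np.ndarray, fs_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum |X_k|/N and its frequency axis."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    return np.fft.rfftfreq(n, 1.0 / fs_hz), np.abs(np.fft.rfft(x, axis=-1)) / n


def spectral_snr(
    x: np.ndarray, fs_hz: float, f_hz: float, n_neighbours: int = 6
) -> tuple[float, float]:
    """Amplitude and neighbour-normalised SNR at an on-bin frequency.

    Returns ``(amplitude, snr_ratio)`` where the ratio is the bin
    amplitude over the mean of ``n_neighbours`` bins on each side of it,
    the target bin itself excluded.  A vanishing neighbour mean (pure
    sinusoid, no noise) yields the capped ratio ``SNR_CAP``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("spectral_snr operates on a single channel trace")
    n = x.size
    k = _bin_index(n, fs_hz, f_hz)
    amp = np.abs(np.fft.rfft(x)) / n
    nyq = n // 2 if n % 2 == 0 else None
    neigh = [
        j
        for off in range(1, n_neighbours + 1)
        for j in (k - off, k + off)
        if 0 < j < amp.size and j != nyq
    ]
    denom = amp[neigh].mean()
    if denom <= amp[k] / SNR_CAP:
        warnings.warn("neighbour amplitude ~0; SNR capped")
        return float(amp[k]), SNR_CAP
    return float(amp[k]), float(amp[k] / denom)


def phase_at(x: np.ndarray, fs_hz: float, f_hz: float) -> float:
    """Phase of the DFT coefficient at ``f_hz`` (cosine reference).

    ``cos(2*pi*f*t)`` maps to 0, ``sin(2*pi*f*t)`` to -pi/2; the result
    lies in (-pi, pi].
    """
    x = np.asarray(x, dtype=float)
    k = _bin_index(x.size, fs_hz, f_hz)
    ph = float(np.angle(np.fft.rfft(x)[k]))
    return np.pi if ph == -np.pi else ph


def circular_std(phases) -> float:
    """Circular standard deviation sqrt(-2 ln R) in radians.

    R is the mean resultant length; antipodal phase pairs give R = 0 and
    an infinite dispersion (returned as ``inf``).
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size < 2:
        raise ValueError("need at least two phases")
    r = np.abs(np.exp(1j * phases).mean())
    if r <= 1e-15:
        warnings.warn("zero resultant length; circular std is infinite")
        return np.inf
    with np.errstate(divide="ignore"):
        return float(stats.circstd(phases))


def stereotypical_response(
    ep: EpochSet,
    f_hz: float,
    ci: bool = True,
    n_boot: int = 1000,
    seed: int | None = None,
) -> EvokedResponse:
    """Average two-period segment across all epochs gazing frequency ``f``.

    Epochs are selected by their ``frequency_hz`` label, cut into
    two-period 50%-overlap segments, and all segments are averaged; the
    confidence band is a per-sample BCa bootstrap over segments.
    """
    mask = np.isclose(ep.labels["frequency_hz"].to_numpy(dtype=float), f_hz)
    if not mask.any():
        raise ValueError(f"no epochs labelled with frequency {f_hz} Hz")
    segs = segment_two_periods(ep.select_epochs(mask), f_hz, overlap=0.5)
    mean = segs.data.mean(axis=0)
    lo = hi = None
    if ci and segs.n_segments >= 2:
        lo, hi = bca_bootstrap_ci(
            segs.data, np.mean, n_boot=n_boot, seed=seed, axis=0, vectorized=True
        )
    return EvokedResponse(
        mean=mean, n_epochs=segs.n_segments, t0_ms=0.0, fs_hz=ep.fs_hz,
        condition=f"ssvep-{f_hz}Hz", ci_low=lo, ci_high=hi,
    )


def snr_phase_table(ep: EpochSet, channels=None, n_neighbours: int = 6) -> pd.DataFrame:
    """Tidy per-epoch, per-channel feature table.

    Each row holds epoch id, channel, gazed frequency, bin amplitude,
    neighbour-normalised SNR and phase — the tabular export format.
    """
    if channels is None:
        channels = ep.layout.channel_names
    rows = []
    freqs = ep.labels["frequency_hz"].to_numpy(dtype=float)
    for e in range(ep.n_epochs):
        f = freqs[e]
        for name in channels:
            c = ep.layout.index(name)
            x = ep.data[e, c]
            amp, snr = spectral_snr(x, ep.fs_hz, f, n_neighbours)
            rows.append(
                (e, name, f, amp, snr, phase_at(x, ep.fs_hz, f))
            )
    return pd.DataFrame(
        rows,
        columns=["epoch", "channel", "frequency_hz", "amplitude", "snr", "phase_rad"],
    )
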