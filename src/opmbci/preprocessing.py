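"""Deterministic preprocessing of continuous recordings and epochs.

All steps mirror a conventional evoked/SSVEP pipeline: mastoid
re-referencing (EEG only), zero-phase Butterworth band-pass filtering,
stimulus-locked epoching with half-open sample windows, pre-onset
baseline correction, anti-aliased polyphase downsampling, synthetic
planar-gradiometer construction from magnetometer pairs, and the
two-period 50%-overlap segmentation used by the frequency-phase decoder.

Conventions: 0-based sample indices and half-open windows
``[start, end)`` throughout, so an fs = 1000 Hz epoch from -200 ms to
600 ms holds exactly 800 samples.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .containers import ContinuousRecording, EpochSet, SegmentSet, SensorLayout

__all__ = [
    "bandpass_filter",
    "rereference_mastoids",
    "extract_epochs",
    "baseline_correct",
    "downsample",
    "make_gradiometers",
    "segment_two_periods",
    "segment_starts",
    "two_period_samples",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# filtering


def _butter_sos(low_hz: float, high_hz: float, fs_hz: float, order: int):
    if not 0 < low_hz < high_hz:
        raise ValueError("require 0 < low < high")
    if high_hz >= fs_hz / 2:
        raise ValueError("upper band edge must be below Nyquist")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass",
                         fs=fs_hz, output="sos")


def _filtfilt(data: np.ndarray, sos: np.ndarray, order: int) -> np.ndarray:
    # reflective padding of at least 3x the filter order (per pass the SOS
    # cascade has 2*order poles); sosfiltfilt's default padlen already
    # satisfies this but we make the floor explicit
    padlen = max(3 * (2 * order + 1), 3 * order)
    if data.shape[-1] <= padlen:
        raise ValueError(
            f"signal too short for zero-phase filtering (needs > {padlen} samples)"
        )
    return signal.sosfiltfilt(sos, data, axis=-1, padtype="odd", padlen=padlen)


def bandpass_filter(x, low_hz: float, high_hz: float, order: int = 4):
    """Zero-phase Butterworth band-pass, applied forward and backward.

    Accepts a :class:`ContinuousRecording` or an :class:`EpochSet` and
    returns the same type.  The two-pass application cancels the phase
    response entirely (a symmetric input stays symmetric) and squares the
    magnitude response of the order-``order`` prototype.
    """
    sos = _butter_sos(low_hz, high_hz, x.fs_hz, order)
    if isinstance(x, ContinuousRecording):
        return x.copy_with(data=_filtfilt(x.data, sos, order))
    if isinstance(x, EpochSet):
        return x.copy_with(data=_filtfilt(x.data, sos, order))
    raise TypeError("expected ContinuousRecording or EpochSet")


# ---------------------------------------------------------------------------
# re-referencing


def rereference_mastoids(
    rec: ContinuousRecording, left_name: str, right_name: str
) -> ContinuousRecording:
    """Subtract the mastoid average from every EEG channel.

    MEG channels are reference-free and pass through unchanged.
    """
    li, ri = rec.layout.index(left_name), rec.layout.index(right_name)
    for i, nm in ((li, left_name), (ri, right_name)):
        if rec.layout.kinds[i] != "eeg":
            raise ValueError(f"mastoid channel {nm!r} is not an EEG channel")
    ref = 0.5 * (rec.data[li] + rec.data[ri])
    data = rec.data.copy()
    eeg = [i for i, k in enumerate(rec.layout.kinds) if k == "eeg"]
    data[eeg] -= ref
    return rec.copy_with(data=data)


# ---------------------------------------------------------------------------
# epoching and baselining


def extract_epochs(
    rec: ContinuousRecording,
    tmin_ms: float,
    tmax_ms: float,
    event_filter: Callable[[pd.DataFrame], np.ndarray] | None = None,
) -> EpochSet:
    """Cut one epoch per selected event spanning ``[onset+tmin, onset+tmax)``.

    ``event_filter`` receives the event table and returns a boolean mask.
    Events whose window would exceed the recording are skipped (logged).
    """
    if not tmin_ms < tmax_ms:
        raise ValueError("require tmin < tmax")
    fs = rec.fs_hz
    start_off = int(round(tmin_ms * fs / 1000.0))
    stop_off = int(round(tmax_ms * fs / 1000.0))
    events = rec.events
    if event_filter is not None:
        events = events[np.asarray(event_filter(events), dtype=bool)]

    keep, chunks = [], []
    n_skipped = 0
    for i, onset in zip(events.index, events["sample"].to_numpy()):
        a, b = onset + start_off, onset + stop_off
        if a < 0 or b > rec.n_samples:
            n_skipped += 1
            continue
        keep.append(i)
        chunks.append(rec.data[:, a:b])
    if n_skipped:
        logger.info("extract_epochs: skipped %d out-of-bounds event(s)", n_skipped)
    if not chunks:
        raise ValueError("no usable events for the requested window")
    return EpochSet(
        data=np.stack(chunks),
        fs_hz=fs,
        t0_ms=start_off * 1000.0 / fs,
        labels=events.loc[keep],
        layout=rec.layout,
    )


def _window_slice(ep: EpochSet, start_ms: float, end_ms: float) -> slice:
    fs = ep.fs_hz
    a = int(round((start_ms - ep.t0_ms) * fs / 1000.0))
    b = int(round((end_ms - ep.t0_ms) * fs / 1000.0))
    if a < 0 or b > ep.n_samples or a >= b:
        raise ValueError("window lies outside the epoch")
    return slice(a, b)


def baseline_correct(ep: EpochSet, base_start_ms: float, base_end_ms: float) -> EpochSet:
    """Subtract each epoch's per-channel mean over the baseline window."""
    sl = _window_slice(ep, base_start_ms, base_end_ms)
    base = ep.data[:, :, sl].mean(axis=-1, keepdims=True)
    return ep.copy_with(data=ep.data - base)


# ---------------------------------------------------------------------------
# downsampling


def downsample(ep: EpochSet, fs_new: float = 150.0) -> EpochSet:
    """Anti-aliased polyphase downsampling of an epoch set."""
    if fs_new >= ep.fs_hz:
        raise ValueError("fs_new must be below the current sampling rate")
    ratio = Fraction(fs_new / ep.fs_hz).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    out = signal.resample_poly(ep.data, up, down, axis=-1, padtype="line")
    n_target = int(np.floor(ep.n_samples * fs_new / ep.fs_hz))
    out = out[..., :n_target]
    return ep.copy_with(data=out, fs_hz=fs_new)


# ---------------------------------------------------------------------------
# synthetic planar gradiometers


def make_gradiometers(x, pairs: Sequence[tuple[str, str]] | str = "all-pairs",
                      max_distance: float | None = None):
    """Build synthetic planar gradiometers as magnetometer differences.

    Each output channel is ``first - second`` of a magnetometer pair;
    over opposite poles of a dipolar field the signals add while
    independent sensor noise only grows by sqrt(2), boosting SNR.

    ``pairs`` may be an explicit list of name pairs, ``"all-pairs"`` (all
    C(k, 2) combinations of the k magnetometers), or ``"neighbours"``
    (all pairs within ``max_distance`` scalp units).  Returns the same
    container type holding only the new gradiometer channels.
    """
    layout = x.layout
    mags = [n for n, k in zip(layout.channel_names, layout.kinds) if k == "mag"]
    if isinstance(pairs, str):
        if pairs == "all-pairs":
            pair_list = list(combinations(mags, 2))
        elif pairs == "neighbours":
            if max_distance is None:
                raise ValueError("neighbours mode requires max_distance")
            pair_list = [
                (a, b)
                for a, b in combinations(mags, 2)
                if np.linalg.norm(
                    layout.positions[layout.index(a)] - layout.positions[layout.index(b)]
                )
                <= max_distance
            ]
        else:
            raise ValueError(f"unknown pairing mode {pairs!r}")
    else:
        pair_list = [tuple(p) for p in pairs]
    if not pair_list:
        raise ValueError("no gradiometer pairs to build")

    names, kinds, pos, parents = [], [], [], {}
    rows = []
    for a, b in pair_list:
        ia, ib = layout.index(a), layout.index(b)
        for i, nm in ((ia, a), (ib, b)):
            if layout.kinds[i] != "mag":
                raise ValueError(f"{nm!r} is not a magnetometer")
        name = f"{a}-{b}"
        names.append(name)
        kinds.append("grad")
        pos.append(0.5 * (layout.positions[ia] + layout.positions[ib]))
        parents[name] = (a, b)
        rows.append((ia, ib))

    new_layout = SensorLayout(tuple(names), tuple(kinds), np.array(pos), parents)
    ia = np.array([r[0] for r in rows])
    ib = np.array([r[1] for r in rows])
    if isinstance(x, ContinuousRecording):
        return x.copy_with(data=x.data[ia] - x.data[ib], layout=new_layout)
    if isinstance(x, EpochSet):
        return x.copy_with(data=x.data[:, ia] - x.data[:, ib], layout=new_layout)
    raise TypeError("expected ContinuousRecording or EpochSet")


# ---------------------------------------------------------------------------
# two-period segmentation


def two_period_samples(fs_hz: float, f_hz: float) -> int:
    """Length in samples of two flicker periods, rounded to the nearest
    integer (ties to even)."""
    return int(round(2.0 * fs_hz / f_hz))


def segment_starts(
    n_samples: int,
    fs_hz: float,
    f_hz: float,
    overlap: float = 0.5,
    discard_before_ms: float = 0.0,
) -> tuple[int, np.ndarray]:
    """Two-period segment length and start offsets for an epoch.

    Starts are multiples of ``round(n * (1 - overlap))``; a trailing
    partial segment is dropped and starts before ``discard_before_ms``
    are removed.  Returns ``(n, starts)``.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    n = two_period_samples(fs_hz, f_hz)
    if n_samples < n:
        raise ValueError(f"epoch of {n_samples} samples shorter than two periods ({n})")
    step = max(int(round(n * (1.0 - overlap))), 1)
    first_sample = discard_before_ms * fs_hz / 1000.0
    starts = np.array(
        [s for s in range(0, n_samples - n + 1, step) if s >= first_sample],
        dtype=int,
    )
    return n, starts


def segment_two_periods(
    ep: EpochSet,
    f_hz: float,
    overlap: float = 0.5,
    discard_before_ms: float = 0.0,
) -> SegmentSet:
    """Cut every epoch into overlapping segments of two flicker periods.

    Segments start at multiples of ``round(n * (1 - overlap))`` from
    epoch onset; a trailing partial segment is dropped.  Segments
    starting before ``discard_before_ms`` (used to skip the transient at
    stimulation onset during spelling) are removed.
    """
    n, starts = segment_starts(ep.n_samples, ep.fs_hz, f_hz, overlap, discard_before_ms)
    if starts.size == 0:
        raise ValueError("no segments remain after the discard rule")
    segs = np.stack([ep.data[:, :, s : s + n] for s in starts], axis=1)
    # segs: epochs x starts x channels x n -> flatten epoch-major
    parent = np.repeat(np.arange(ep.n_epochs), starts.size)
    return SegmentSet(
        data=segs.reshape(-1, ep.n_channels, n),
        fs_hz=ep.fs_hz,
        source_frequency_hz=f_hz,
        parent_epochs=parent,
        starts=np.tile(starts, ep.n_epochs),
    )
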