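"""Core in-memory containers for multichannel neuromagnetic recordings.

The pipeline passes data through four stages of container:

``ContinuousRecording``
    raw channels x samples matrix with a sensor layout and an event table,
``EpochSet``
    stimulus-locked epochs x channels x samples with per-epoch labels,
``SegmentSet``
    two-period flicker segments cut from epochs with 50% overlap,
``EvokedResponse``
    an across-epoch (or across-segment) average with optional confidence
    bands.

All containers are plain dataclasses over numpy arrays and pandas tables;
they validate their invariants on construction and are cheap to copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensorLayout",
    "TargetLayout",
    "ContinuousRecording",
    "EpochSet",
    "SegmentSet",
    "EvokedResponse",
]

#: recognised channel kinds: OPM magnetometer, synthetic planar gradiometer,
#: scalp-EEG electrode
CHANNEL_KINDS = ("mag", "grad", "eeg")


@dataclass(frozen=True)
class SensorLayout:
    """Names, kinds and flattened 2-D scalp positions of a sensor array.

    Positions are in arbitrary head-surface units (the generator and the
    spatial gain models only use relative distances).  Gradiometer channels
    record the two parent magnetometer names they were derived from.
    """

    channel_names: tuple[str, ...]
    kinds: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)
    grad_parents: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        kinds = tuple(self.kinds)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "channel_names", names)
        object.__setattr__(self, "kinds", kinds)
        object.__setattr__(self, "positions", pos)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if len(kinds) != len(names) or pos.shape != (len(names), 2):
            raise ValueError("layout fields disagree in length")
        for k in kinds:
            if k not in CHANNEL_KINDS:
                raise ValueError(f"unknown channel kind {k!r}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        for g, parents in self.grad_parents.items():
            # parent magnetometers may live in the source layout rather than
            # this (gradiometer-only) one; only the arity is structural
            if len(parents) != 2:
                raise ValueError(
                    f"gradiometer {g!r} must reference exactly two magnetometers"
                )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def indices(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def select(self, names: Sequence[str]) -> "SensorLayout":
        idx = self.indices(names)
        keep = set(names)
        return SensorLayout(
            channel_names=tuple(names),
            kinds=tuple(self.kinds[i] for i in idx),
            positions=self.positions[idx],
            grad_parents={g: p for g, p in self.grad_parents.items() if g in keep},
        )

    @classmethod
    def grid(
        cls,
        n_rows: int,
        n_cols: int,
        kind: str = "mag",
        prefix: str | None = None,
        spacing: float = 1.0,
    ) -> "SensorLayout":
        """Regular ``n_rows x n_cols`` scalp grid centred on the origin.

        Emulates an evenly distributed helmet patch (e.g. parieto-occipital
        OPMs in a rigid 3-D printed helmet).
        """
        prefix = prefix or kind.upper()
        names, kinds, pos = [], [], []
        for r in range(n_rows):
            for c in range(n_cols):
                names.append(f"{prefix}{r * n_cols + c:02d}")
                kinds.append(kind)
                pos.append(
                    (
                        (c - (n_cols - 1) / 2.0) * spacing,
                        (r - (n_rows - 1) / 2.0) * spacing,
                    )
                )
        return cls(tuple(names), tuple(kinds), np.array(pos))


@dataclass(frozen=True)
class TargetLayout:
    """Nine on-screen flicker targets with joint frequency-phase coding.

    Each target on the 3 x 3 grid is assigned a unique combination of
    flicker frequency (Hz) and phase offset (rad), so nine selectable
    targets can be coded with only three distinct frequencies.
    """

    frequency_hz: np.ndarray  # (9,)
    phase_rad: np.ndarray  # (9,)
    grid_pos: np.ndarray  # (9, 2) row, col
    characters: tuple[str, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency_hz, dtype=float)
        p = np.asarray(self.phase_rad, dtype=float)
        g = np.asarray(self.grid_pos, dtype=int)
        object.__setattr__(self, "frequency_hz", f)
        object.__setattr__(self, "phase_rad", p)
        object.__setattr__(self, "grid_pos", g)
        object.__setattr__(self, "characters", tuple(self.characters))
        if not (f.shape == p.shape == (9,) and g.shape == (9, 2)):
            raise ValueError("a target layout has exactly 9 entries")
        if len(self.characters) != 9:
            raise ValueError("a target layout has exactly 9 characters")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        if np.any((p < 0) | (p >= 2 * np.pi)):
            raise ValueError("phases must lie in [0, 2*pi)")
        pairs = set(zip(np.round(f, 9), np.round(p, 9)))
        if len(pairs) != 9:
            raise ValueError("(frequency, phase) pairs must be unique")

    @property
    def n_targets(self) -> int:
        return 9

    def with_characters(self, characters: Sequence[str]) -> "TargetLayout":
        return replace(self, characters=tuple(characters))

    @classmethod
    def default(cls) -> "TargetLayout":
        """{7.5, 10, 12.5} Hz crossed with phases {0, 2pi/3, 4pi/3}.

        Frequency varies across columns and phase across rows; the exact
        on-screen assignment is configurable.  The default frequencies
        are commensurate with the 150 Hz decoding rate: two flicker
        periods span exactly 40, 30 and 24 samples, so 50%-overlap
        segment starts stay phase-aligned with the flicker and segment
        averaging does not smear the phase code.  They also sit on the
        0.25 Hz DFT grid of a 4-s epoch.
        """
        freqs, phases, grid = [], [], []
        for r in range(3):
            for c in range(3):
                freqs.append((7.5, 10.0, 12.5)[c])
                phases.append(r * 2 * np.pi / 3)
                grid.append((r, c))
        return cls(
            frequency_hz=np.array(freqs),
            phase_rad=np.array(phases),
            grid_pos=np.array(grid),
            characters=tuple("ABCDEFGHI"),
        )


def _check_events(events: pd.DataFrame, n_samples: int) -> pd.DataFrame:
    if "sample" not in events.columns:
        raise ValueError("event table requires a 'sample' column")
    s = events["sample"].to_numpy()
    if len(s) and (s.min() < 0 or s.max() >= n_samples):
        raise ValueError("event sample indices must lie within the recording")
    return events.reset_index(drop=True)


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording with an event table.

    ``data`` is channels x samples in sensor units (fT for magnetometers,
    fT per unit baseline for synthetic gradiometers, uV for EEG).  The
    event table has one row per marker with at least a ``sample`` column;
    generators add paradigm-specific label columns (``trial``,
    ``stimulated``, ``cued``, ``target``, ``frequency_hz``, ``phase_rad``).
    """

    data: np.ndarray
    fs_hz: float
    layout: SensorLayout
    events: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError("data row count must match layout")
        if not self.fs_hz > 0:
            raise ValueError("sampling rate must be positive")
        self.events = _check_events(self.events, self.data.shape[1])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "ContinuousRecording":
        out = {"data": self.data, "fs_hz": self.fs_hz, "layout": self.layout,
               "events": self.events}
        out.update(kw)
        return ContinuousRecording(**out)

    def select_channels(self, names: Sequence[str]) -> "ContinuousRecording":
        idx = self.layout.indices(names)
        return self.copy_with(data=self.data[idx], layout=self.layout.select(names))


@dataclass
class EpochSet:
    """Stimulus-locked epochs: epochs x channels x samples.

    ``t0_ms`` is the time of the first sample relative to event onset
    (negative for a pre-onset baseline).  ``labels`` carries one row per
    epoch, copied from the source event table.
    """

    data: np.ndarray
    fs_hz: float
    t0_ms: float
    labels: pd.DataFrame
    layout: SensorLayout

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.data.shape[1] != self.layout.n_channels:
            raise ValueError("channel count must match layout")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal epoch count")
        if not self.fs_hz > 0:
            raise ValueError("sampling rate must be positive")
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs_hz

    def copy_with(self, **kw) -> "EpochSet":
        out = {"data": self.data, "fs_hz": self.fs_hz, "t0_ms": self.t0_ms,
               "labels": self.labels, "layout": self.layout}
        out.update(kw)
        return EpochSet(**out)

    def select_channels(self, names: Sequence[str]) -> "EpochSet":
        idx = self.layout.indices(names)
        return self.copy_with(data=self.data[:, idx], layout=self.layout.select(names))

    def select_epochs(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return self.copy_with(data=self.data[mask], labels=self.labels.iloc[mask])


@dataclass
class SegmentSet:
    """Two-period flicker segments cut from epochs with fixed overlap."""

    data: np.ndarray  # segments x channels x n
    fs_hz: float
    source_frequency_hz: float
    parent_epochs: np.ndarray  # (segments,) epoch index each segment came from
    starts: np.ndarray  # (segments,) start sample within the parent epoch

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.parent_epochs = np.asarray(self.parent_epochs, dtype=int)
        self.starts = np.asarray(self.starts, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be segments x channels x n")
        if len(self.parent_epochs) != self.data.shape[0]:
            raise ValueError("parent ids must match segment count")

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def segment_length(self) -> int:
        return self.data.shape[2]


@dataclass
class EvokedResponse:
    """Across-epoch average with optional 95% confidence bands."""

    mean: np.ndarray  # channels x samples
    n_epochs: int
    t0_ms: float
    fs_hz: float
    condition: str = ""
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        if self.n_epochs < 1:
            raise ValueError("an evoked response averages at least one epoch")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("both or neither confidence bound must be given")
        if self.ci_low is not None:
            self.ci_low = np.asarray(self.ci_low, dtype=float)
            self.ci_high = np.asarray(self.ci_high, dtype=float)
            if self.ci_low.shape != self.mean.shape or self.ci_high.shape != self.mean.shape:
                raise ValueError("confidence bands must match the mean's shape")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.mean.shape[-1]) * 1000.0 / self.fs_hz
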