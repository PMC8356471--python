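"""Spatiotemporal LCMV beamformer decoding for ERP and SSVEP paradigms.

The classifier estimates the contribution of an a-priori activation
pattern ``a`` (a vectorised channels x samples template, channel-major)
to a data segment.  With the segment covariance ``Sigma`` regularised as

    Sigma_hat = alpha * Sigma + (1 - alpha) * I,      alpha = 0.95,

the linearly-constrained minimum-variance (LCMV) weights under the
unit-gain constraint ``a . w = 1`` are

    w = a Sigma_hat^-1 / (a Sigma_hat^-1 a^T),

using the pseudo-inverse of ``Sigma_hat``.  These weights minimise the
output variance ``w Sigma_hat w^T`` among all unit-gain filters, so the
filter passes the template while suppressing everything else.

Two paradigm variants share this core:

* **ERP** — a single beamformer whose pattern is the vectorised average
  target ERP/F; a gazed cross is predicted by averaging the epochs of
  each candidate cross, applying the filter, and taking the argmax.
* **SSVEP** — nine beamformers, one per frequency-phase target, whose
  patterns are average two-period segments; an epoch is scored per
  target by segmenting at that target's frequency (50% overlap,
  optionally discarding segments that start inside the initial onset
  transient), averaging, and applying the filter.

Evaluation uses stratified k-fold cross-validation accumulated into a
confusion matrix, and dimensionality is reduced with greedy forward
channel selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .containers import EpochSet, SegmentSet, TargetLayout
from .preprocessing import segment_starts

__all__ = [
    "BeamformerModel",
    "TargetBeamformer",
    "ConfusionMatrix",
    "ChannelSelectionResult",
    "build_pattern_and_covariance",
    "train_beamformer",
    "train_ssvep_model",
    "train_erp_model",
    "score",
    "classify_ssvep",
    "classify_erp",
    "crossval_ssvep",
    "crossval_erp",
    "greedy_forward_selection",
    "ssvep_subset_scorer",
    "erp_subset_scorer",
]


# ---------------------------------------------------------------------------
# core LCMV algebra


def build_pattern_and_covariance(
    pattern_segments: SegmentSet | np.ndarray,
    cov_segments: SegmentSet | np.ndarray,
    alpha: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised activation pattern and regularised covariance.

    ``a`` is the channel-major vectorisation of the mean pattern
    segment; ``Sigma`` is the empirical (mean-centred, 1/(N-1))
    covariance of the vectorised covariance segments; the return is
    ``(a, alpha * Sigma + (1 - alpha) * I)``.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    P = pattern_segments.data if isinstance(pattern_segments, SegmentSet) else np.asarray(pattern_segments)
    C = cov_segments.data if isinstance(cov_segments, SegmentSet) else np.asarray(cov_segments)
    if P.shape[1:] != C.shape[1:]:
        raise ValueError("pattern and covariance segments disagree in shape")
    if C.shape[0] < 2:
        raise ValueError("need at least two covariance segments")
    mn = P.shape[1] * P.shape[2]
    a = P.reshape(P.shape[0], mn).mean(axis=0)
    X = C.reshape(C.shape[0], mn)
    sigma = np.cov(X, rowvar=False, ddof=1)
    return a, alpha * sigma + (1.0 - alpha) * np.eye(mn)


def train_beamformer(
    a: np.ndarray, sigma_hat: np.ndarray, rcond: float = 1e-10
) -> np.ndarray:
    """Unit-gain minimum-variance weights ``w = a S^-1 / (a S^-1 a^T)``.

    The inverse is the pseudo-inverse with singular values below
    ``rcond`` times the largest discarded.
    """
    a = np.asarray(a, dtype=float).ravel()
    if not np.any(a):
        raise ValueError("activation pattern must be nonzero")
    s_inv = np.linalg.pinv(sigma_hat, rcond=rcond, hermitian=True)
    num = a @ s_inv
    denom = float(num @ a)
    if abs(denom) < 1e-300:
        raise np.linalg.LinAlgError("pattern lies in the null space of the covariance")
    return num / denom


# ---------------------------------------------------------------------------
# models


@dataclass
class TargetBeamformer:
    """Weights and pattern of one target's spatiotemporal filter."""

    target: int
    n_samples: int
    weights: np.ndarray
    pattern: np.ndarray
    frequency_hz: float | None = None
    phase_rad: float | None = None


@dataclass
class BeamformerModel:
    """A trained decoder: one filter per target plus shared settings.

    ``discard_before_ms`` applies at scoring time only (the real-time
    spelling mode removes segments that start within the initial 150 ms
    of the stimulation); training always uses the full epochs.
    """

    paradigm: str  # "erp" | "ssvep"
    targets: list[TargetBeamformer]
    channel_names: tuple[str, ...]
    fs_hz: float
    alpha: float
    overlap: float = 0.5
    discard_before_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.paradigm not in ("erp", "ssvep"):
            raise ValueError("paradigm must be 'erp' or 'ssvep'")
        m = len(self.channel_names)
        for tb in self.targets:
            if tb.weights.size != m * tb.n_samples:
                raise ValueError("weight length must equal channels * samples")
            gain = float(tb.pattern @ tb.weights)
            if abs(gain - 1.0) > 1e-6:
                raise ValueError(f"unit-gain violated for target {tb.target}: {gain}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "paradigm": self.paradigm,
                "channel_names": list(self.channel_names),
                "fs_hz": self.fs_hz,
                "alpha": self.alpha,
                "overlap": self.overlap,
                "discard_before_ms": self.discard_before_ms,
                "targets": [
                    {
                        "target": tb.target,
                        "n_samples": tb.n_samples,
                        "frequency_hz": tb.frequency_hz,
                        "phase_rad": tb.phase_rad,
                        "weights": tb.weights.tolist(),
                        "pattern": tb.pattern.tolist(),
                    }
                    for tb in self.targets
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BeamformerModel":
        d = json.loads(text)
        return cls(
            paradigm=d["paradigm"],
            channel_names=tuple(d["channel_names"]),
            fs_hz=d["fs_hz"],
            alpha=d["alpha"],
            overlap=d["overlap"],
            discard_before_ms=d["discard_before_ms"],
            targets=[
                TargetBeamformer(
                    target=t["target"],
                    n_samples=t["n_samples"],
                    frequency_hz=t["frequency_hz"],
                    phase_rad=t["phase_rad"],
                    weights=np.array(t["weights"]),
                    pattern=np.array(t["pattern"]),
                )
                for t in d["targets"]
            ],
        )


def _segments_of(
    data: np.ndarray, fs: float, f: float, overlap: float, discard_ms: float
) -> np.ndarray:
    """Two-period segments of one channels x samples epoch.

    Falls back to the undiscarded segmentation when the onset-discard
    rule would leave nothing (short post hoc truncations).
    """
    n, starts = segment_starts(data.shape[-1], fs, f, overlap, discard_ms)
    if starts.size == 0:
        _, starts = segment_starts(data.shape[-1], fs, f, overlap, 0.0)
    return np.stack([data[:, s : s + n] for s in starts])


def train_ssvep_model(
    ep: EpochSet,
    layout: TargetLayout,
    alpha: float = 0.95,
    overlap: float = 0.5,
    discard_before_ms: float = 0.0,
) -> BeamformerModel:
    """Train the nine per-target frequency-phase beamformers.

    For target ``i``, the pattern is the average two-period segment of
    the epochs cued to ``i`` at its frequency ``f_i``; the covariance is
    estimated from segments of *all* epochs (also those of other
    frequencies) cut at that same length.
    """
    labels = ep.labels["target"].to_numpy(dtype=int)
    targets = []
    for i in range(layout.n_targets):
        f = float(layout.frequency_hz[i])
        own = ep.data[labels == i]
        if own.shape[0] == 0:
            raise ValueError(f"no training epochs for target {i}")
        pat = np.concatenate([_segments_of(x, ep.fs_hz, f, overlap, 0.0) for x in own])
        cov = np.concatenate(
            [_segments_of(x, ep.fs_hz, f, overlap, 0.0) for x in ep.data]
        )
        a, s_hat = build_pattern_and_covariance(pat, cov, alpha)
        w = train_beamformer(a, s_hat)
        targets.append(
            TargetBeamformer(
                target=i, n_samples=pat.shape[-1], weights=w, pattern=a,
                frequency_hz=f, phase_rad=float(layout.phase_rad[i]),
            )
        )
    return BeamformerModel(
        paradigm="ssvep", targets=targets, channel_names=ep.layout.channel_names,
        fs_hz=ep.fs_hz, alpha=alpha, overlap=overlap,
        discard_before_ms=discard_before_ms,
    )


def train_erp_model(ep: EpochSet, alpha: float = 0.95) -> BeamformerModel:
    """Train the single ERP beamformer.

    The pattern is the vectorised average *target* epoch (stimulated
    cross == cued cross); the covariance uses all vectorised epochs.
    """
    mask = (ep.labels["stimulated"] == ep.labels["cued"]).to_numpy()
    if not mask.any():
        raise ValueError("no target epochs to build the activation pattern")
    a, s_hat = build_pattern_and_covariance(ep.data[mask], ep.data, alpha)
    w = train_beamformer(a, s_hat)
    tb = TargetBeamformer(target=0, n_samples=ep.n_samples, weights=w, pattern=a)
    return BeamformerModel(
        paradigm="erp", targets=[tb], channel_names=ep.layout.channel_names,
        fs_hz=ep.fs_hz, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# scoring and classification


def score(epoch: np.ndarray, model: BeamformerModel, target: int) -> float:
    """Beamformer output of one channels x samples epoch for one target.

    SSVEP: segment at the target's frequency, average, vectorise, apply
    the weights.  ERP: vectorise the epoch directly.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.shape[0] != model.n_channels:
        raise ValueError("epoch channel count does not match the model")
    tb = model.targets[target]
    if model.paradigm == "ssvep":
        segs = _segments_of(
            epoch, model.fs_hz, tb.frequency_hz, model.overlap,
            model.discard_before_ms,
        )
        x = segs.mean(axis=0).ravel()
    else:
        if epoch.shape[-1] != tb.n_samples:
            raise ValueError("epoch length does not match the ERP pattern")
        x = epoch.ravel()
    return float(tb.weights @ x)


def classify_ssvep(epoch: np.ndarray, model: BeamformerModel) -> tuple[int, np.ndarray]:
    """Winning target of a flicker epoch: argmax of the per-target scores.

    Targets whose two-period length exceeds the epoch are given a score
    of ``-inf``; ties break toward the lowest target index.
    """
    if model.paradigm != "ssvep":
        raise ValueError("model is not an SSVEP decoder")
    scores = np.full(len(model.targets), -np.inf)
    for i, tb in enumerate(model.targets):
        if tb.n_samples <= np.asarray(epoch).shape[-1]:
            scores[i] = score(epoch, model, i)
    if not np.isfinite(scores).any():
        raise ValueError("epoch too short for every target's two-period window")
    return int(np.argmax(scores)), scores


def classify_erp(
    ep: EpochSet, model: BeamformerModel, k_reps: int, candidates: Sequence[int] | None = None
) -> tuple[int, np.ndarray]:
    """Predict the gazed cross from one trial's epochs.

    For each candidate cross, the first ``k_reps`` epochs stimulating it
    are averaged, vectorised and passed through the ERP beamformer; the
    candidate with maximal output wins (ties to the lowest index).
    """
    if model.paradigm != "erp":
        raise ValueError("model is not an ERP decoder")
    stim = ep.labels["stimulated"].to_numpy(dtype=int)
    if candidates is None:
        candidates = np.unique(stim)
    w = model.targets[0].weights
    scores = np.full(len(candidates), -np.inf)
    for j, cand in enumerate(candidates):
        idx = np.flatnonzero(stim == cand)
        if idx.size < k_reps:
            raise ValueError(f"candidate {cand} has fewer than {k_reps} epochs")
        avg = ep.data[idx[:k_reps]].mean(axis=0)
        scores[j] = float(w @ avg.ravel())
    return int(candidates[int(np.argmax(scores))]), scores


# ---------------------------------------------------------------------------
# cross-validated evaluation


@dataclass
class ConfusionMatrix:
    """Accumulated true x predicted counts."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_predictions(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts)


def crossval_ssvep(
    ep: EpochSet,
    layout: TargetLayout,
    k_folds: int = 4,
    alpha: float = 0.95,
    overlap: float = 0.5,
    discard_before_ms: float = 0.0,
    seed: int = 0,
) -> tuple[ConfusionMatrix, float]:
    """Stratified k-fold accuracy of the frequency-phase decoder."""
    y = ep.labels["target"].to_numpy(dtype=int)
    _check_fold_counts(y, k_folds)
    counts = np.zeros((layout.n_targets, layout.n_targets), dtype=int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        model = train_ssvep_model(
            ep.select_epochs(train_idx), layout, alpha, overlap, discard_before_ms
        )
        for t in test_idx:
            pred, _ = classify_ssvep(ep.data[t], model)
            counts[y[t], pred] += 1
    cm = ConfusionMatrix(counts)
    return cm, cm.accuracy


def crossval_erp(
    ep: EpochSet,
    k_folds: int = 5,
    k_reps: int = 5,
    alpha: float = 0.95,
    seed: int = 0,
) -> tuple[ConfusionMatrix, float]:
    """Trial-level stratified k-fold accuracy of the ERP decoder.

    Folds are assigned to whole trials (stratified by the cued cross) so
    no epoch of a test trial leaks into training.
    """
    trials = ep.labels["trial"].to_numpy(dtype=int)
    cued = ep.labels["cued"].to_numpy(dtype=int)
    uniq, first = np.unique(trials, return_index=True)
    trial_cue = cued[first]
    _check_fold_counts(trial_cue, k_folds)
    n_classes = int(max(cued.max(), ep.labels["stimulated"].max())) + 1
    counts = np.zeros((n_classes, n_classes), dtype=int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train_t, test_t in skf.split(np.zeros(len(uniq)), trial_cue):
        train_mask = np.isin(trials, uniq[train_t])
        model = train_erp_model(ep.select_epochs(train_mask), alpha)
        for t in uniq[test_t]:
            trial_ep = ep.select_epochs(trials == t)
            pred, _ = classify_erp(trial_ep, model, k_reps)
            counts[trial_cue[uniq == t][0], pred] += 1
    cm = ConfusionMatrix(counts)
    return cm, cm.accuracy


def _check_fold_counts(y: np.ndarray, k_folds: int) -> None:
    vals, cnt = np.unique(y, return_counts=True)
    if cnt.min() < k_folds:
        raise ValueError(
            f"every class needs at least {k_folds} instances for {k_folds}-fold CV"
        )


# ---------------------------------------------------------------------------
# greedy forward channel selection


@dataclass
class ChannelSelectionResult:
    """Outcome of greedy forward selection."""

    selected: list[str]
    accuracy_trace: list[float]
    termination_reason: str

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected channels must be unique")


def greedy_forward_selection(
    candidates: Sequence[str],
    scorer: Callable[[Sequence[str]], float],
    max_channels: int | None = None,
) -> ChannelSelectionResult:
    """Iteratively add the channel that improves the CV score the most.

    Stops when no candidate strictly improves the score, when the score
    reaches 100%, or when ``max_channels`` are selected.  The retained
    trace is strictly increasing by construction.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    selected: list[str] = []
    trace: list[float] = []
    best = -np.inf
    remaining = list(candidates)
    limit = max_channels or len(remaining)
    reason = "exhausted"
    while remaining and len(selected) < limit:
        step_scores = [scorer(selected + [c]) for c in remaining]
        j = int(np.argmax(step_scores))
        if selected and step_scores[j] <= best:
            reason = "no_improvement"
            break
        best = step_scores[j]
        selected.append(remaining.pop(j))
        trace.append(best)
        if best >= 1.0:
            reason = "perfect"
            break
    return ChannelSelectionResult(selected, trace, reason)


def ssvep_subset_scorer(
    ep: EpochSet,
    layout: TargetLayout,
    k_folds: int = 4,
    alpha: float = 0.95,
    seed: int = 0,
) -> Callable[[Sequence[str]], float]:
    """Fourfold-CV accuracy of a channel subset (speller selection score)."""

    def scorer(names: Sequence[str]) -> float:
        _, acc = crossval_ssvep(
            ep.select_channels(names), layout, k_folds=k_folds, alpha=alpha, seed=seed
        )
        return acc

    return scorer


def erp_subset_scorer(
    ep: EpochSet,
    k_folds: int = 5,
    reps: Sequence[int] = (1, 2, 3, 4, 5),
    alpha: float = 0.95,
    seed: int = 0,
) -> Callable[[Sequence[str]], float]:
    """Mean CV accuracy over 1..5 stimulus repetitions (ERP selection score)."""

    def scorer(names: Sequence[str]) -> float:
        sub = ep.select_channels(names)
        return float(
            np.mean([crossval_erp(sub, k_folds, k, alpha, seed)[1] for k in reps])
        )

    return scorer
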