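"""Simulated real-time mind-spelling with backspace correction.

A spelling session presents words one at a time.  Eight of the nine
flicker targets carry the characters needed for the current word (plus
random fillers), the ninth a backspace.  For each selection the
simulated user gazes the next needed character — or the backspace after
a decoding error — a 2-s stimulation epoch is synthesised, band-pass
filtered 4-40 Hz, matched to the decoder's sampling rate, and classified
with the frequency-phase beamformer bank (segments starting within the
initial 150 ms of the stimulation are discarded).  The session for a
word ends once the spelled text equals the target word.

The post hoc stimulation-length sweep re-classifies the session's 2-s
epochs truncated to their initial 0.25 ... 2.0 s to estimate how short
the stimulation could have been.

``run_full_experiment`` chains the whole pipeline: training-session
generation, preprocessing, optional greedy channel selection, decoder
training, the spelling session and the length sweep, writing a JSON +
CSV report.
"""

from __future__ import annotations

import json
import string
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .beamformer import (
    BeamformerModel,
    ConfusionMatrix,
    classify_ssvep,
    greedy_forward_selection,
    ssvep_subset_scorer,
    train_ssvep_model,
)
from .containers import EpochSet, SensorLayout, TargetLayout
from .preprocessing import bandpass_filter, downsample, extract_epochs
from .synthetic import (
    NoiseSpec,
    SsvepSessionConfig,
    flicker_epoch,
    generate_ssvep_session,
    response_gains,
)

__all__ = [
    "BACKSPACE",
    "SpellingLog",
    "LengthSweepResult",
    "assign_characters",
    "apply_selections",
    "session_accuracy_percent",
    "run_spelling_session",
    "posthoc_length_sweep",
    "run_full_experiment",
]

#: character displayed on the backspace target
BACKSPACE = "<"

DEFAULT_WORDS = ("WAVE", "MIND", "SPELL", "BRAIN", "FIELD")


def session_accuracy_percent(n_correct: int, n_total: int) -> float:
    """Session accuracy as the percentage of correct selections."""
    if n_total < 1 or n_correct < 0 or n_correct > n_total:
        raise ValueError("need 0 <= n_correct <= n_total with n_total >= 1")
    return 100.0 * n_correct / n_total


def apply_selections(selections) -> str:
    """Fold a sequence of ``(char, is_backspace)`` into the working text.

    A backspace removes exactly one prior character (no-op on empty
    text); any other character is appended.
    """
    text = ""
    for char, is_backspace in selections:
        text = text[:-1] if is_backspace else text + char
    return text


def assign_characters(
    word: str, layout: TargetLayout, rng: np.random.Generator
) -> TargetLayout:
    """Distribute the word's characters over the flicker targets.

    The word's unique characters (at most 8) and the backspace are
    placed on random targets; remaining targets get random filler
    letters not used by the word.
    """
    uniq = list(dict.fromkeys(word))
    if len(uniq) > 8:
        raise ValueError("a word may use at most 8 unique characters")
    pool = [c for c in string.ascii_uppercase if c not in uniq]
    fillers = list(rng.choice(pool, size=8 - len(uniq), replace=False))
    chars = uniq + fillers + [BACKSPACE]
    order = rng.permutation(9)
    assigned = [""] * 9
    for c, pos in zip(chars, order):
        assigned[pos] = c
    return layout.with_characters(assigned)


@dataclass
class SpellingLog:
    """Ordered record of a spelling session."""

    words: tuple[str, ...]
    selections: pd.DataFrame  # word, intended, decoded, correct, backspace
    final_texts: tuple[str, ...]
    epochs: EpochSet | None = None  # decoder-rate epochs, for the sweep
    aborted: bool = False

    @property
    def n_selections(self) -> int:
        return len(self.selections)

    @property
    def n_correct(self) -> int:
        return int(self.selections["correct"].sum())

    @property
    def session_accuracy(self) -> float:
        return self.n_correct / self.n_selections

    @property
    def accuracy_percent(self) -> float:
        return session_accuracy_percent(self.n_correct, self.n_selections)

    def confusion(self, n_targets: int = 9) -> ConfusionMatrix:
        counts = np.zeros((n_targets, n_targets), dtype=int)
        for _, row in self.selections.iterrows():
            counts[int(row["gazed_target"]), int(row["decoded_target"])] += 1
        return ConfusionMatrix(counts)


def _prepare_epoch(
    raw: np.ndarray, fs_raw: float, model: BeamformerModel, band=(4.0, 40.0)
) -> np.ndarray:
    """Filter a raw stimulation epoch and match the decoder rate."""
    layout = SensorLayout(
        tuple(model.channel_names),
        tuple("mag" for _ in model.channel_names),
        np.zeros((len(model.channel_names), 2)),
    )
    ep = EpochSet(
        data=raw[None], fs_hz=fs_raw, t0_ms=0.0,
        labels=pd.DataFrame({"sample": [0]}), layout=layout,
    )
    ep = bandpass_filter(ep, band[0], band[1])
    if fs_raw > model.fs_hz:
        ep = downsample(ep, model.fs_hz)
    elif fs_raw != model.fs_hz:
        raise ValueError("generator rate below the decoder rate")
    return ep.data[0]


def run_spelling_session(
    model: BeamformerModel,
    target_layout: TargetLayout,
    sensor_layout: SensorLayout,
    generator: SsvepSessionConfig,
    words=DEFAULT_WORDS,
    stim_s: float = 2.0,
    seed: int = 0,
    band: tuple[float, float] = (4.0, 40.0),
    max_selections_per_word: int | None = None,
) -> SpellingLog:
    """Spell each word with simulated gaze, decoding and correction.

    After a wrong selection the simulated user gazes the backspace and
    then retries the intended character; a word is finished when the
    working text equals it.  Sessions that would loop (a persistently
    wrong decoder) abort after ``max_selections_per_word`` selections.
    """
    rng = np.random.default_rng(seed)
    gains = response_gains(
        sensor_layout, generator.response_center, generator.response_sigma
    )
    rows, kept_epochs, kept_labels = [], [], []
    finals = []
    aborted = False
    for word in words:
        layout_w = assign_characters(word, target_layout, rng)
        char_to_target = {c: i for i, c in enumerate(layout_w.characters)}
        text = ""
        cap = max_selections_per_word or max(20, 6 * len(word))
        n_sel = 0
        while text != word:
            if n_sel >= cap:
                aborted = True
                break
            intended = (
                word[len(text)]
                if text == word[: len(text)] and len(text) < len(word)
                else BACKSPACE
            )
            gazed = char_to_target[intended]
            raw = flicker_epoch(
                float(layout_w.frequency_hz[gazed]),
                float(layout_w.phase_rad[gazed]),
                stim_s,
                generator.fs_hz,
                gains,
                generator.amplitude,
                generator.latency_s,
                generator.noise,
                rng,
            )
            epoch = _prepare_epoch(raw, generator.fs_hz, model, band)
            decoded, _scores = classify_ssvep(epoch, model)
            decoded_char = layout_w.characters[decoded]
            rows.append(
                (
                    word, intended, decoded_char, decoded_char == intended,
                    decoded_char == BACKSPACE, gazed, decoded,
                )
            )
            kept_epochs.append(epoch)
            kept_labels.append((gazed, float(layout_w.frequency_hz[gazed]),
                                float(layout_w.phase_rad[gazed])))
            text = text[:-1] if decoded_char == BACKSPACE else text + decoded_char
            n_sel += 1
        finals.append(text)

    selections = pd.DataFrame(
        rows,
        columns=[
            "word", "intended", "decoded", "correct", "backspace",
            "gazed_target", "decoded_target",
        ],
    )
    epochs = None
    if kept_epochs:
        lab = pd.DataFrame(
            kept_labels, columns=["target", "frequency_hz", "phase_rad"]
        )
        lab["sample"] = 0
        layout = SensorLayout(
            tuple(model.channel_names),
            tuple("mag" for _ in model.channel_names),
            np.zeros((len(model.channel_names), 2)),
        )
        epochs = EpochSet(
            data=np.stack(kept_epochs), fs_hz=model.fs_hz, t0_ms=0.0,
            labels=lab, layout=layout,
        )
    return SpellingLog(
        words=tuple(words), selections=selections, final_texts=tuple(finals),
        epochs=epochs, aborted=aborted,
    )


@dataclass
class LengthSweepResult:
    """Decoding accuracy as a function of retained stimulation length."""

    lengths_s: np.ndarray
    accuracy: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        self.lengths_s = np.asarray(self.lengths_s, dtype=float)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if self.lengths_s.shape != self.accuracy.shape:
            raise ValueError("lengths and accuracies must align")
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"length_s": self.lengths_s, "accuracy": self.accuracy}
        )


def posthoc_length_sweep(
    spelling_epochs: EpochSet,
    model: BeamformerModel,
    lengths_s=None,
) -> LengthSweepResult:
    """Re-classify spelling epochs truncated to their initial n seconds.

    The default grid runs from 250 ms to 2 s in steps of 250 ms.  Epochs
    must be at least 2 s long.
    """
    if lengths_s is None:
        lengths_s = np.arange(1, 9) * 0.25
    lengths_s = np.asarray(lengths_s, dtype=float)
    fs = spelling_epochs.fs_hz
    if spelling_epochs.n_samples < int(round(2.0 * fs)):
        raise ValueError("spelling epochs must be at least 2 s long")
    truth = spelling_epochs.labels["target"].to_numpy(dtype=int)
    acc = np.empty(lengths_s.size)
    for i, L in enumerate(lengths_s):
        n_keep = int(round(L * fs))
        hits = 0
        for e in range(spelling_epochs.n_epochs):
            pred, _ = classify_ssvep(spelling_epochs.data[e, :, :n_keep], model)
            hits += int(pred == truth[e])
        acc[i] = hits / spelling_epochs.n_epochs
    return LengthSweepResult(lengths_s, acc, spelling_epochs.n_epochs)


# ---------------------------------------------------------------------------
# end-to-end experiment


def run_full_experiment(
    config: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Training session -> preprocessing -> channel selection -> decoder
    -> spelling session -> length sweep, fully seeded.

    Returns the report dict; with ``out_dir`` also writes ``report.json``,
    ``selections.csv``, ``sweep.csv`` and ``confusion.csv``.
    """
    cfg = {
        "grid_rows": 2,
        "grid_cols": 3,
        "fs_hz": 600.0,
        "decoder_fs_hz": 150.0,
        "training_reps": 8,
        "amplitude": 300.0,
        "white_sigma": 200.0,
        "pink_scale": 200.0,
        "alpha": 0.95,
        "discard_before_ms": 150.0,
        "words": list(DEFAULT_WORDS),
        "channel_selection": True,
        "max_channels": 4,
        "stim_s": 2.0,
    }
    cfg.update(config or {})

    stage_seeds = [int(s) % 2**31 for s in
                   np.random.SeedSequence(seed).generate_state(4)]
    t_start = time.perf_counter()

    target_layout = TargetLayout.default()
    sensor_layout = SensorLayout.grid(cfg["grid_rows"], cfg["grid_cols"])
    noise = NoiseSpec(white_sigma=cfg["white_sigma"], pink_scale=cfg["pink_scale"])
    train_cfg = SsvepSessionConfig(
        layout=target_layout, trial_s=4.0, reps=cfg["training_reps"],
        amplitude=cfg["amplitude"], noise=noise, fs_hz=cfg["fs_hz"],
        seed=stage_seeds[0],
    )

    rec = generate_ssvep_session(train_cfg, sensor_layout)
    rec = bandpass_filter(rec, 4.0, 40.0)
    ep = extract_epochs(rec, 0.0, train_cfg.trial_s * 1000.0)
    ep = downsample(ep, cfg["decoder_fs_hz"])

    if cfg["channel_selection"]:
        scorer = ssvep_subset_scorer(ep, target_layout, seed=stage_seeds[1])
        sel = greedy_forward_selection(
            list(sensor_layout.channel_names), scorer,
            max_channels=cfg["max_channels"],
        )
        ep_sel = ep.select_channels(sel.selected)
        selection_report = {
            "selected": sel.selected,
            "trace": sel.accuracy_trace,
            "termination": sel.termination_reason,
        }
        sensor_sel = sensor_layout.select(sel.selected)
    else:
        ep_sel, sensor_sel = ep, sensor_layout
        selection_report = {"selected": list(sensor_layout.channel_names),
                            "trace": [], "termination": "disabled"}

    model = train_ssvep_model(
        ep_sel, target_layout, alpha=cfg["alpha"],
        discard_before_ms=cfg["discard_before_ms"],
    )

    spell_cfg = replace(train_cfg, seed=stage_seeds[2])
    log = run_spelling_session(
        model, target_layout, sensor_sel, spell_cfg,
        words=tuple(cfg["words"]), stim_s=cfg["stim_s"], seed=stage_seeds[3],
    )
    sweep = posthoc_length_sweep(log.epochs, model)

    report = {
        "seed": seed,
        "config": {k: v for k, v in cfg.items()},
        "training_trials": int(len(ep.labels)),
        "channel_selection": selection_report,
        "spelling": {
            "words": list(log.words),
            "final_texts": list(log.final_texts),
            "n_selections": log.n_selections,
            "n_correct": log.n_correct,
            "accuracy_percent": log.accuracy_percent,
            "aborted": log.aborted,
        },
        "length_sweep": {
            "lengths_s": sweep.lengths_s.tolist(),
            "accuracy": sweep.accuracy.tolist(),
        },
        "runtime_s": round(time.perf_counter() - t_start, 3),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {k: v for k, v in report.items() if k != "runtime_s"}
        (out / "report.json").write_text(json.dumps(payload, indent=2))
        log.selections.to_csv(out / "selections.csv", index=False)
        sweep.to_frame().to_csv(out / "sweep.csv", index=False)
        log.confusion().to_frame().to_csv(out / "confusion.csv")
    return report
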