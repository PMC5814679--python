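"""Decoding of timbre deviants from 200-ms response epochs.

A timbre deviant is a brief morph of a vowel's first two formants that is
amplitude-neutral, so neither the sound envelope nor the luminance envelope
carries information about it.  Whether the deviant can nevertheless be read
out of the spiking response -- and whether that readout improves when the
deviant's auditory stream is temporally coherent with the visual stream --
is the binding test: an orthogonal ("non-binding") feature should be
enhanced only if the streams are bound.

Deviant and no-deviant trials of an otherwise identical stimulus are
compared over the 200-ms deviant window, binned at 10 ms (20 bins), with
the same leave-one-out Euclidean template classifier and permutation test
used for stream decoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spike_decoding import (
    PSTHMatrix,
    bin_spikes,
    permutation_null,
)

__all__ = [
    "EpochMatrix",
    "DeviantScore",
    "DeviantSummary",
    "extract_epochs",
    "deviant_discrimination",
    "summarize_unit",
    "coherency_grouping",
]

EPOCH_DURATION = 0.200  # s
EPOCH_BIN_WIDTH = 0.010  # s -> 20 bins


@dataclass
class EpochMatrix:
    """Binned 200-ms response epochs around one deviant (or its control)."""

    counts: np.ndarray  # (trials, 20)
    onset: float
    stream: str
    visual_condition: str | None = None
    bin_width: float = EPOCH_BIN_WIDTH


@dataclass
class DeviantScore:
    stream: str
    onset: float
    visual_condition: str | None
    score: float  # percent correct
    p: float
    detected: bool


@dataclass
class DeviantSummary:
    """Per-unit deviant detection counts and scores for one grouping."""

    scores: list  # DeviantScore
    n_detected: int
    mean_score: float | None  # over all deviants, only if n_detected >= 1


def extract_epochs(
    deviant_trials,
    control_trials,
    onset: float,
    trial_duration: float = 3.0,
    stream: str = "A1",
    visual_condition: str | None = None,
    seed: int = 0,
) -> tuple[EpochMatrix, EpochMatrix]:
    """Extract matched 200-ms epochs from deviant and no-deviant trials.

    Both sets are binned over ``[onset, onset + 0.2)`` at 10 ms.  The control
    epochs come from the no-deviant rendering of the same stimulus at the
    identical time.  If the trial counts differ, the larger set is
    subsampled at random (seeded) to the smaller count.
    """
    if onset < 0 or onset > trial_duration - EPOCH_DURATION + 1e-9:
        raise ValueError("deviant epoch extends outside the trial window")
    window = (onset, onset + EPOCH_DURATION)
    dev = bin_spikes(deviant_trials, window, EPOCH_BIN_WIDTH)
    ctl = bin_spikes(control_trials, window, EPOCH_BIN_WIDTH)
    n = min(dev.n_trials, ctl.n_trials)
    rng = np.random.default_rng(seed)
    if dev.n_trials > n:
        dev = PSTHMatrix(dev.counts[rng.choice(dev.n_trials, n, replace=False)],
                         EPOCH_BIN_WIDTH, window)
    if ctl.n_trials > n:
        ctl = PSTHMatrix(ctl.counts[rng.choice(ctl.n_trials, n, replace=False)],
                         EPOCH_BIN_WIDTH, window)
    mk = lambda m: EpochMatrix(m.counts, onset, stream, visual_condition)
    return mk(dev), mk(ctl)


def deviant_discrimination(
    epoch_pair: tuple[EpochMatrix, EpochMatrix],
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    scheme: str = "permute",
) -> DeviantScore:
    """LOOCV discrimination of deviant vs no-deviant epochs + permutation test.

    The discrimination score is the percentage of trials correctly
    classified; "detected" means the observed score exceeds the 95th
    percentile of the permutation null.
    """
    dev, ctl = epoch_pair
    groups = {"deviant": dev.counts, "control": ctl.counts}
    res = permutation_null(groups, n_iter=n_iter, alpha=alpha, seed=seed,
                           scheme=scheme)
    return DeviantScore(
        stream=dev.stream,
        onset=dev.onset,
        visual_condition=dev.visual_condition,
        score=res.observed,
        p=res.p,
        detected=res.significant,
    )


def coherency_grouping(deviant_stream: str, visual_condition: str) -> str:
    """Map (deviant stream, visual stream) to 'coherent' or 'independent'.

    The grouping is symmetric: a deviant in stream A1 accompanied by V1 is
    coherent, as is A2 with V2; the crossed pairs are independent.
    """
    pairs = {("A1", "V1"), ("A2", "V2")}
    if deviant_stream not in ("A1", "A2") or visual_condition not in ("V1", "V2"):
        raise ValueError("stream must be A1/A2 and visual condition V1/V2")
    return "coherent" if (deviant_stream, visual_condition) in pairs else "independent"


def summarize_unit(scores: list) -> dict:
    """Group a unit's deviant scores by audio-visual coherency.

    ``scores`` holds one :class:`DeviantScore` per decoded deviant.  Scores
    with a V1/V2 visual condition are grouped into coherent vs independent
    (by :func:`coherency_grouping`); scores from no-visual conditions are
    grouped under 'auditory-only'.  Each group reports the number detected
    and the mean score across *all* its deviants provided at least one was
    detected (units detecting none are excluded from score averages).
    """
    grouped: dict[str, list] = {}
    for s in scores:
        if s.visual_condition in ("V1", "V2"):
            key = coherency_grouping(s.stream, s.visual_condition)
        else:
            key = "auditory-only"
        grouped.setdefault(key, []).append(s)
    out = {}
    for key, ss in grouped.items():
        n_det = sum(s.detected for s in ss)
        mean = float(np.mean([s.score for s in ss])) if n_det >= 1 else None
        out[key] = DeviantSummary(scores=ss, n_detected=n_det, mean_score=mean)
    return out
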