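"""Synthesis of amplitude-modulated artificial vowels and matched luminance envelopes.

The stimulus design pairs two competing auditory streams -- artificial vowels
with distinct pitch (F0) and timbre (formant pattern) -- with a full-field
visual stimulus whose luminance follows the amplitude envelope of one of the
streams.  Streams are amplitude modulated by independent noisy low-pass
(7 Hz cut-off) envelopes; the luminance envelope is sample-identical to the
envelope of the stream named in the condition.  Brief (200 ms) timbre
deviants morph the first two formants to another vowel and back without
changing the amplitude envelope, so the deviant is orthogonal to the feature
(envelope coherence) that links the auditory and visual streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

__all__ = [
    "VowelSpec",
    "Envelope",
    "DeviantMarker",
    "StimulusSet",
    "VOWEL_U",
    "VOWEL_A",
    "VOWEL_EPS",
    "VOWEL_I",
    "CONDITIONS",
    "DEVIANT_DURATION",
    "make_am_envelope",
    "synthesize_vowel",
    "deviant_formant_track",
    "insert_timbre_deviants",
    "build_stimulus_set",
    "write_stimulus_set",
]

#: Conditions: single auditory stream with/without visual, and dual-stream
#: mixtures accompanied by one of the two visual envelopes (or none).
CONDITIONS = (
    "A1",
    "A2",
    "A1V1",
    "A1V2",
    "A2V1",
    "A2V2",
    "A12V1",
    "A12V2",
    "A12",
)

DEVIANT_DURATION = 0.200  # s; fixed epoch length of a timbre deviant

DEFAULT_AUDIO_RATE = 24414.0  # Hz
DEFAULT_BANDWIDTHS = (80.0, 120.0, 160.0, 200.0)  # Hz, F1-F4 resonance widths

# Aspiration-noise floor relative to the harmonic part (amplitude ratio).
# The noise shares the formant envelope, so the continuous spectrum peaks at
# the formant frequencies between the harmonics of F0.
_NOISE_LEVEL = 10 ** (-30.0 / 20.0)


@dataclass(frozen=True)
class VowelSpec:
    """An artificial vowel: fundamental plus four formant resonances."""

    label: str
    f0: float
    formants: tuple[float, float, float, float]
    formant_bandwidths: tuple[float, float, float, float] = DEFAULT_BANDWIDTHS

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if list(self.formants) != sorted(self.formants) or len(set(self.formants)) != 4:
            raise ValueError("formants must be strictly increasing")
        if any(b <= 0 for b in self.formant_bandwidths):
            raise ValueError("formant bandwidths must be positive")


# The two stream vowels and the morph targets of their timbre deviants.
VOWEL_U = VowelSpec("[u]", 195.0, (460.0, 1105.0, 2857.0, 4205.0))
VOWEL_A = VowelSpec("[a]", 175.0, (936.0, 1551.0, 2975.0, 4263.0))
VOWEL_EPS = VowelSpec("[eps]", 195.0, (730.0, 2058.0, 2857.0, 4205.0))
VOWEL_I = VowelSpec("[i]", 175.0, (437.0, 2761.0, 2975.0, 4263.0))


@dataclass(frozen=True)
class Envelope:
    """A noisy low-pass amplitude envelope in [0, 1]."""

    samples: np.ndarray
    sample_rate: float
    cutoff: float
    seed: int

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def resample(self, rate: float, n_samples: int) -> np.ndarray:
        """Linear interpolation onto ``n_samples`` points at ``rate`` Hz."""
        t_out = np.arange(n_samples) / rate
        t_in = np.arange(len(self.samples)) / self.sample_rate
        return np.interp(t_out, t_in, self.samples)


@dataclass(frozen=True)
class DeviantMarker:
    """A 200-ms epoch in which F1/F2 morph to another vowel and back."""

    onset: float
    stream: str  # "A1" or "A2"
    morph_target: VowelSpec
    duration: float = DEVIANT_DURATION

    def __post_init__(self) -> None:
        if abs(self.duration - DEVIANT_DURATION) > 1e-12:
            raise ValueError("deviant epochs are fixed at 200 ms")
        if self.stream not in ("A1", "A2"):
            raise ValueError("stream must be 'A1' or 'A2'")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")


@dataclass
class StimulusSet:
    """One condition's audio, per-stream envelopes and optional luminance."""

    condition: str
    audio: np.ndarray
    audio_rate: float
    envelopes: dict  # stream name -> Envelope
    luminance: Envelope | None
    deviants: list = field(default_factory=list)
    duration: float = 3.0
    level_spl: float = 65.0  # dB SPL, metadata only


def make_am_envelope(
    duration: float, sample_rate: float, cutoff: float = 7.0, seed: int = 0
) -> Envelope:
    """Generate a noisy low-pass amplitude envelope.

    Gaussian white noise is zero-phase low-pass filtered at ``cutoff`` Hz
    (FFT-domain real transfer function: flat to 0.9x cutoff, raised-cosine
    roll-off reaching zero at the cutoff) and min-max normalized to [0, 1],
    so the cutoff is a true band edge.  Deterministic in ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= sample_rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    edge0 = 0.9 * cutoff
    h = np.where(
        freqs <= edge0,
        1.0,
        np.where(
            freqs < cutoff,
            0.5 * (1 + np.cos(np.pi * (freqs - edge0) / (cutoff - edge0))),
            0.0,
        ),
    )
    env = np.fft.irfft(np.fft.rfft(noise) * h, n=n)
    lo, hi = env.min(), env.max()
    env = (env - lo) / (hi - lo)
    return Envelope(samples=env, sample_rate=sample_rate, cutoff=cutoff, seed=seed)


def _formant_gain(freqs: np.ndarray, formants, bandwidths) -> np.ndarray:
    """Amplitude gain of the cascade of four two-pole resonators.

    Each resonator has the analog magnitude response
    ``F^2 / sqrt((f^2 - F^2)^2 + (B f)^2)``, peaking (for B << F) at the
    formant frequency F with -3 dB width ~B.  ``freqs`` may have any shape.
    """
    g = np.ones_like(freqs, dtype=float)
    for F, B in zip(formants, bandwidths):
        g = g * F**2 / np.sqrt((freqs**2 - F**2) ** 2 + (B * freqs) ** 2)
    return g


def _harmonic_part(
    f0: float, n_samples: int, audio_rate: float, gains: np.ndarray
) -> np.ndarray:
    """Sum of cosine harmonics of ``f0`` weighted by ``gains``.

    ``gains`` is (n_harmonics,) for a static vowel or (n_samples,
    n_harmonics) for a time-varying (deviant) vowel.
    """
    k = np.arange(1, gains.shape[-1] + 1)
    out = np.empty(n_samples)
    for start in range(0, n_samples, 131072):  # chunked: bounds the (n, K) buffer
        stop = min(start + 131072, n_samples)
        t = np.arange(start, stop) / audio_rate
        phases = 2 * np.pi * f0 * np.outer(t, k)
        if gains.ndim == 1:
            out[start:stop] = np.cos(phases) @ gains
        else:
            out[start:stop] = np.einsum("nk,nk->n", np.cos(phases), gains[start:stop])
    return out


def _noise_part(
    spec: VowelSpec, n_samples: int, audio_rate: float, seed: int
) -> np.ndarray:
    """Formant-shaped Gaussian noise floor (frequency-domain shaping)."""
    rng = np.random.default_rng([seed, 0xA51E])  # distinct stream from the envelope
    white = rng.standard_normal(n_samples)
    spec_f = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / audio_rate)
    gain = _formant_gain(freqs, spec.formants, spec.formant_bandwidths)
    gain[0] = 0.0
    shaped = np.fft.irfft(spec_f * gain, n=n_samples)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def _harmonic_gains(spec: VowelSpec, audio_rate: float) -> np.ndarray:
    """Formant-filter amplitude of each harmonic k*f0 below Nyquist."""
    n_harm = int(np.floor((audio_rate / 2 - 1e-9) / spec.f0))
    if n_harm < 1:
        raise ValueError("audio_rate too low for any harmonic of f0")
    k = np.arange(1, n_harm + 1)
    return _formant_gain(k * spec.f0, spec.formants, spec.formant_bandwidths)


def _assemble(
    spec: VowelSpec,
    envelope: Envelope,
    audio_rate: float,
    gains: np.ndarray,
    norm: float | None = None,
) -> tuple[np.ndarray, float]:
    """Harmonics + noise, peak-normalized, then multiplied by the envelope.

    Returns the waveform and the normalization constant used, so a deviant
    rendering can reuse the constant of its no-deviant counterpart and stay
    sample-identical outside the morph epochs.
    """
    n = int(round(envelope.duration * audio_rate))
    carrier = _harmonic_part(spec.f0, n, audio_rate, gains)
    # analytic RMS of the harmonic part (cross terms vanish on average)
    noise_rms_target = _NOISE_LEVEL * np.sqrt(np.sum(gains**2) / 2)
    carrier = carrier + noise_rms_target * _noise_part(spec, n, audio_rate, envelope.seed)
    if norm is None:
        norm = np.max(np.abs(carrier))
        if norm == 0:
            norm = 1.0
    env = envelope.resample(audio_rate, n)
    return (carrier / norm) * env, norm


def synthesize_vowel(
    spec: VowelSpec, envelope: Envelope, audio_rate: float = DEFAULT_AUDIO_RATE
) -> np.ndarray:
    """Render an amplitude-modulated artificial vowel.

    The source is a harmonic comb at ``spec.f0`` shaped by the four formant
    resonances, plus a -30 dB formant-shaped noise floor; the sum is
    peak-normalized and multiplied by the (resampled) amplitude envelope.
    """
    if audio_rate < 4 * spec.formants[-1]:
        raise ValueError("audio_rate must be at least 4x the highest formant")
    wave, _ = _assemble(spec, envelope, audio_rate, _harmonic_gains(spec, audio_rate))
    return wave


def deviant_formant_track(
    spec: VowelSpec, marker: DeviantMarker, t: np.ndarray | float
) -> np.ndarray:
    """Instantaneous (F1, F2) during a morph, raised-cosine out and back.

    F1/F2 leave the base vowel at the marker onset, reach the morph target
    exactly at the epoch midpoint (onset + 100 ms) and return by the epoch
    end; F3/F4 never move.  Outside the epoch the base formants are returned.
    Result shape: t-shape + (2,).
    """
    t = np.asarray(t, dtype=float)
    # 0 -> 1 -> 0 raised-cosine weight over the epoch
    x = (t - marker.onset) / marker.duration
    w = np.where((x >= 0) & (x <= 1), 0.5 * (1 - np.cos(2 * np.pi * np.clip(x, 0, 1))), 0.0)
    base = np.array(spec.formants[:2])
    target = np.array(marker.morph_target.formants[:2])
    return base + w[..., None] * (target - base)


def insert_timbre_deviants(
    spec: VowelSpec,
    markers: list[DeviantMarker],
    envelope: Envelope,
    audio_rate: float = DEFAULT_AUDIO_RATE,
) -> np.ndarray:
    """Render a vowel stream whose F1/F2 morph during each 200-ms marker.

    Outside the marker epochs the output is sample-identical to
    :func:`synthesize_vowel` with the same envelope/seed.  Within an epoch
    the per-harmonic gains follow the morphing formant pattern but are
    rescaled to preserve the instantaneous power of the harmonic part, so
    the amplitude envelope carries no information about the deviant.
    """
    if audio_rate < 4 * spec.formants[-1]:
        raise ValueError("audio_rate must be at least 4x the highest formant")
    duration = envelope.duration
    for m in markers:
        if m.onset < 0 or m.onset > duration - m.duration + 1e-9:
            raise ValueError("marker epoch extends outside the stimulus")
    for a, b in zip(sorted(markers, key=lambda m: m.onset)[:-1],
                    sorted(markers, key=lambda m: m.onset)[1:]):
        if b.onset < a.onset + a.duration:
            raise ValueError("deviant epochs overlap")

    static_gains = _harmonic_gains(spec, audio_rate)
    base_wave, norm = _assemble(spec, envelope, audio_rate, static_gains)
    if not markers:
        return base_wave

    n = int(round(duration * audio_rate))
    t = np.arange(n) / audio_rate
    k = np.arange(1, len(static_gains) + 1)
    static_power = np.sum(static_gains**2)
    out = base_wave.copy()
    env = envelope.resample(audio_rate, n)
    for m in markers:
        sel = (t >= m.onset) & (t < m.onset + m.duration)
        f12 = deviant_formant_track(spec, m, t[sel])  # (m, 2)
        formants = np.concatenate(
            [f12, np.broadcast_to(spec.formants[2:], (len(f12), 2))], axis=1
        )
        gains = np.ones((sel.sum(), len(k)))
        for i in range(4):
            F = formants[:, i : i + 1]
            B = spec.formant_bandwidths[i]
            fk = (k * spec.f0)[None, :]
            gains *= F**2 / np.sqrt((fk**2 - F**2) ** 2 + (B * fk) ** 2)
        # equal instantaneous power of the harmonic part -> amplitude-neutral
        gains *= np.sqrt(static_power / np.sum(gains**2, axis=1, keepdims=True))
        phases = 2 * np.pi * spec.f0 * np.outer(t[sel], k)
        carrier = np.einsum("nk,nk->n", np.cos(phases), gains)
        noise = _noise_part(spec, n, audio_rate, envelope.seed)[sel]
        noise_scale = _NOISE_LEVEL * np.sqrt(static_power / 2)
        out[sel] = (carrier + noise_scale * noise) / norm * env[sel]
    return out


def build_stimulus_set(
    condition: str,
    envelope_A1: Envelope,
    envelope_A2: Envelope,
    deviants: list[DeviantMarker] | None = None,
    audio_rate: float = DEFAULT_AUDIO_RATE,
    vowel_A1: VowelSpec = VOWEL_U,
    vowel_A2: VowelSpec = VOWEL_A,
) -> StimulusSet:
    """Assemble a single- or dual-stream audio-visual condition.

    Dual-stream audio is the sample-wise sum of the two stream waveforms;
    the luminance envelope is the AM envelope of the stream named by the
    visual part of the condition token (absent for no-visual conditions).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if len(envelope_A1.samples) != len(envelope_A2.samples) or (
        envelope_A1.sample_rate != envelope_A2.sample_rate
    ):
        raise ValueError("stream envelopes must share duration and sample rate")
    deviants = list(deviants or [])
    aud_part = condition.split("V")[0]
    streams = ("A1", "A2") if aud_part == "A12" else (aud_part,)

    waves = {}
    specs = {"A1": vowel_A1, "A2": vowel_A2}
    envs = {"A1": envelope_A1, "A2": envelope_A2}
    for s in streams:
        marks = [m for m in deviants if m.stream == s]
        waves[s] = insert_timbre_deviants(specs[s], marks, envs[s], audio_rate)
    audio = sum(waves.values())

    luminance = None
    if "V" in condition:
        luminance = envs["A1" if condition.endswith("V1") else "A2"]
    return StimulusSet(
        condition=condition,
        audio=audio,
        audio_rate=audio_rate,
        envelopes={s: envs[s] for s in streams},
        luminance=luminance,
        deviants=deviants,
        duration=envelope_A1.duration,
    )


def write_stimulus_set(stim: StimulusSet, directory) -> None:
    """Write audio as float WAV, envelopes/luminance as CSV, manifest as JSON."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    wavfile.write(
        directory / f"{stim.condition}.wav",
        int(round(stim.audio_rate)),
        stim.audio.astype(np.float32),
    )
    for name, env in stim.envelopes.items():
        _write_env_csv(directory / f"{stim.condition}_{name}_envelope.csv", env)
    if stim.luminance is not None:
        _write_env_csv(directory / f"{stim.condition}_luminance.csv", stim.luminance)
    manifest = {
        "condition": stim.condition,
        "duration": stim.duration,
        "audio_rate": stim.audio_rate,
        "level_spl": stim.level_spl,
        "envelope_seeds": {k: v.seed for k, v in stim.envelopes.items()},
        "deviants": [
            {"onset": m.onset, "stream": m.stream, "target": m.morph_target.label}
            for m in stim.deviants
        ],
    }
    (directory / f"{stim.condition}_manifest.json").write_text(
        json.dumps(manifest, indent=2)
    )


def _write_env_csv(path, env: Envelope) -> None:
    t = np.arange(len(env.samples)) / env.sample_rate
    with open(path, "w") as fh:
        fh.write("time,value\n")
        for ti, vi in zip(t, env.samples):
            fh.write(f"{ti:.6f},{vi:.8f}\n")
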