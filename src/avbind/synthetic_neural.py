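"""Synthetic spiking and LFP data with the statistical structure the
analyses are designed to detect.

The generator is deliberately phenomenological, not biophysical: it encodes
exactly the response properties the downstream analyses test, so that every
stage of the pipeline has a ground-truth acceptance surface.

Spiking units follow the stimulus amplitude envelope(s) as an inhomogeneous
Poisson process.  Audio-visual temporal coherence enters as *reliability*,
not rate: the per-trial multiplicative gain noise applied to a stream's
envelope drive has standard deviation ``trial_noise_sd / (1 + kappa)`` when
that stream's envelope matches the luminance envelope (kappa is
``coherence_reliability``), and ``trial_noise_sd`` otherwise.  Mean evoked
rates are therefore identical across coherence conditions by construction.
Timbre-deviant epochs scale the deviant stream's envelope drive by
``1 + deviant_gain * (1 + kappa * coherent)``: the deviant-evoked rate
perturbation is larger when the deviant's stream is coherent with the
visual stimulus, which is the binding signature the deviant analysis is
built to detect.  Deviants occupy a small fraction of the trial, so mean
evoked rates remain matched across conditions.

LFP sites superimpose 1/f background noise, an envelope-following auditory
evoked component, and a band-limited oscillation whose phase is reset toward
a fixed target at luminance rising edges (envelope crossing 0.5 upward) with
von Mises concentration set by ``reset_strength``.  The reset changes phase
only -- oscillation amplitude is untouched -- so LFP power is matched across
visual conditions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from .stimuli import StimulusSet

__all__ = [
    "UnitParams",
    "LFPParams",
    "UnitRecording",
    "LFPSet",
    "simulate_spiking_unit",
    "simulate_lfp_site",
    "generate_population",
    "PopulationDataset",
    "save_dataset",
    "load_dataset",
]

SPIKE_DT = 0.001  # s, Poisson discretization step
DEFAULT_LFP_RATE = 600.0  # Hz


@dataclass(frozen=True)
class UnitParams:
    """Generative parameters of one synthetic spiking unit."""

    baseline_rate: float = 5.0  # spikes/s
    gain_auditory: float = 0.0  # spikes/s per unit envelope
    gain_visual: float = 0.0  # spikes/s per unit envelope
    latency: float = 0.02  # s
    coherence_reliability: float = 0.0  # kappa >= 0, gain-noise reduction
    deviant_gain: float = 0.0  # fractional rate change in deviant epochs
    trial_noise_sd: float = 0.4  # sd of multiplicative per-trial gain noise

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.gain_auditory < 0 or self.gain_visual < 0:
            raise ValueError("rates and gains must be non-negative")
        if self.coherence_reliability < 0:
            raise ValueError("coherence_reliability must be >= 0")


@dataclass(frozen=True)
class LFPParams:
    """Generative parameters of one synthetic LFP site."""

    noise_exponent: float = 1.0  # 1/f^exponent background slope
    reset_band: tuple[float, float] = (8.0, 15.0)  # Hz
    reset_strength: float = 0.0  # in [0, 1]: resultant length of reset phases
    reset_trigger_threshold: float = 0.5  # luminance rising-edge criterion
    auditory_evoked_gain: float = 20.0  # uV per unit envelope
    oscillation_amplitude: float = 15.0  # uV
    noise_amplitude: float = 10.0  # uV, rms of the 1/f background
    amplitude_noise: float = 0.6  # per-trial slow multiplicative AM of the oscillation
    min_reset_interval: float = 0.35  # s; edges closer than this to the previous
    # anchor are skipped, bounding the FM excursion of the phase track
    power_modulation_gain: float = 0.0  # luminance-driven amplitude modulation

    def __post_init__(self) -> None:
        if not 0 <= self.reset_strength <= 1:
            raise ValueError("reset_strength must lie in [0, 1]")
        lo, hi = self.reset_band
        if not (1.0 <= lo < hi <= 150.0):
            raise ValueError("reset band must lie inside [1, 150] Hz")


@dataclass
class UnitRecording:
    """Per-condition spike-time trials of one unit."""

    unit_id: str
    trials: dict  # condition -> list of np.ndarray spike times (s)
    state: str = "awake"
    area: str = "AC"
    params: UnitParams | None = None

    def n_trials(self, condition: str) -> int:
        return len(self.trials[condition])


@dataclass
class LFPSet:
    """Per-condition trials x time voltage traces of one site."""

    site_id: str
    traces: dict  # condition -> (trials, time) array
    sample_rate: float = DEFAULT_LFP_RATE
    band: tuple[float, float] = (1.0, 150.0)
    params: LFPParams | None = None


# ---------------------------------------------------------------------------
# helpers


_DRIVE_RMS = 0.55  # common RMS of normalized envelope drives


def _condition_drive(stim: StimulusSet, n_samples: int, rate: float):
    """Per-stream envelope drives, luminance envelope and coherence flags.

    Stream envelopes are rescaled to a common RMS so both streams drive a
    unit equally strongly on average; otherwise random energy differences
    between the two 3-s envelopes would bias dual-stream decoding toward
    one template irrespective of the visual stream.
    """
    envs = {
        s: e.resample(rate, n_samples)
        * (_DRIVE_RMS / max(np.sqrt(np.mean(e.samples**2)), 1e-12))
        for s, e in stim.envelopes.items()
    }
    lum = None
    coh = {s: 0.0 for s in envs}
    if stim.luminance is not None:
        lum = stim.luminance.resample(rate, n_samples) * (
            _DRIVE_RMS / max(np.sqrt(np.mean(stim.luminance.samples**2)), 1e-12)
        )
        for s, e in stim.envelopes.items():
            if np.array_equal(stim.luminance.samples, e.samples):
                coh[s] = 1.0
    return envs, lum, coh


def _deviant_mask(stim: StimulusSet, stream: str, n_samples: int, rate: float):
    mask = np.zeros(n_samples)
    t = np.arange(n_samples) / rate
    for m in stim.deviants:
        if m.stream == stream:
            mask[(t >= m.onset) & (t < m.onset + m.duration)] = 1.0
    return mask


def simulate_spiking_unit(
    p: UnitParams,
    stimuli: dict,
    n_trials: int = 20,
    seed: int = 0,
    duration: float | None = None,
    unit_id: str = "unit",
    state: str = "awake",
) -> UnitRecording:
    """Simulate inhomogeneous-Poisson spike trains for each condition.

    ``stimuli`` maps condition name -> :class:`~avbind.stimuli.StimulusSet`.
    The firing intensity on each trial is::

        lambda(t) = baseline
                  + sum_s g_s * gain_auditory * env_s(t - latency) * deviant_s(t)
                  + g_v * gain_visual * env_V(t - latency)

    with per-trial Gaussian gains ``g_s ~ N(1, sd_s)`` where
    ``sd_s = trial_noise_sd / (1 + kappa * coherent(s))``, and similarly for
    the visual drive.  Negative intensities are clipped at zero.  Spike
    counts are drawn per 1-ms step and jittered uniformly within the step.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    rng = np.random.default_rng(seed)
    trials: dict[str, list] = {}
    for cond, stim in stimuli.items():
        dur = duration if duration is not None else stim.duration
        n = int(round(dur / SPIKE_DT))
        envs, lum, coh = _condition_drive(stim, n, 1.0 / SPIKE_DT)
        lag = int(round(p.latency / SPIKE_DT))

        def _delay(x: np.ndarray) -> np.ndarray:
            if lag == 0:
                return x
            return np.concatenate([np.zeros(lag), x[:-lag]])

        # deviant perturbation is boosted by kappa when its stream is
        # temporally coherent with the luminance envelope (binding effect)
        dev = {
            s: 1.0
            + p.deviant_gain
            * (1.0 + p.coherence_reliability * coh[s])
            * _deviant_mask(stim, s, n, 1.0 / SPIKE_DT)
            for s in envs
        }
        # in a mixture with a visual stream, the coherent stream's drive is
        # weighted up and the other stream's down by the same rate-neutral
        # amount: binding enhances the bound stream's representation without
        # changing the total evoked rate
        weights = {s: 1.0 for s in envs}
        if len(envs) > 1 and lum is not None and any(coh.values()):
            delta = p.coherence_reliability / (1.0 + p.coherence_reliability)
            weights = {s: 1.0 + delta if coh[s] else 1.0 - delta for s in envs}

        cond_trials = []
        for _ in range(n_trials):
            lam = np.full(n, p.baseline_rate, dtype=float)
            for s, env in envs.items():
                sd = p.trial_noise_sd / (1.0 + p.coherence_reliability * coh[s])
                g = 1.0 + sd * rng.standard_normal()
                lam += g * weights[s] * p.gain_auditory * _delay(env * dev[s])
            if lum is not None and p.gain_visual > 0:
                gv = 1.0 + p.trial_noise_sd * rng.standard_normal()
                lam += gv * p.gain_visual * _delay(lum)
            np.maximum(lam, 0.0, out=lam)
            counts = rng.poisson(lam * SPIKE_DT)
            idx = np.repeat(np.arange(n), counts)
            times = (idx + rng.random(len(idx))) * SPIKE_DT
            cond_trials.append(np.sort(times))
        trials[cond] = cond_trials
    return UnitRecording(unit_id=unit_id, trials=trials, state=state, params=p)


# ---------------------------------------------------------------------------
# LFP simulation


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-rms Gaussian noise with 1/f^exponent amplitude spectrum."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _vonmises_kappa(r: float) -> float:
    """Concentration giving mean resultant length ~r (Fisher approximation)."""
    if r <= 0:
        return 0.0
    if r >= 1:
        return np.inf
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def _rising_edges(env: np.ndarray, threshold: float) -> np.ndarray:
    above = env >= threshold
    return np.flatnonzero(above[1:] & ~above[:-1]) + 1


def _slow_noise(n: int, sample_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-sd Gaussian noise low-passed below 2 Hz (trial-private AM)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[freqs > 2.0] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _phase_offset_track(
    n: int,
    t: np.ndarray,
    f_c: float,
    edges: np.ndarray,
    target_phase: float,
    kappa: float,
    reset_strength: float,
    rng: np.random.Generator,
    min_interval: float = 0.35,
) -> np.ndarray:
    """Smooth phase-offset trajectory anchored at luminance rising edges.

    At each edge the total oscillation phase is required to equal the reset
    target plus von Mises jitter; between anchors the offset follows a
    raised-cosine interpolation (zero slope at the anchors), so the signal
    is a constant-amplitude frequency-modulated sinusoid with no transients.
    With ``reset_strength == 0`` (or no edges) the offset is a constant
    uniform draw.
    """
    o0 = rng.uniform(0, 2 * np.pi)
    if reset_strength <= 0 or len(edges) == 0:
        return np.full(n, o0)
    anchor_t = [0.0]
    anchor_o = [o0]
    for e in edges:
        if t[e] - anchor_t[-1] < min_interval:
            continue
        eps = rng.vonmises(0.0, kappa) if np.isfinite(kappa) else 0.0
        want = target_phase + eps - 2 * np.pi * f_c * t[e]
        prev = anchor_o[-1]
        # nearest 2*pi representative: bounds the inter-anchor FM excursion
        want = prev + np.angle(np.exp(1j * (want - prev)))
        anchor_t.append(t[e])
        anchor_o.append(want)
    offset = np.empty(n)
    idx = np.searchsorted(t, anchor_t)
    for i in range(len(anchor_t) - 1):
        a, b = idx[i], idx[i + 1]
        if b <= a:
            continue
        x = (t[a:b] - anchor_t[i]) / (anchor_t[i + 1] - anchor_t[i])
        w = 0.5 * (1 - np.cos(np.pi * x))  # smoothstep, zero slope at ends
        offset[a:b] = anchor_o[i] + w * (anchor_o[i + 1] - anchor_o[i])
    offset[idx[-1] :] = anchor_o[-1]
    return offset


def simulate_lfp_site(
    p: LFPParams,
    stimuli: dict,
    n_trials: int = 20,
    seed: int = 0,
    sample_rate: float = DEFAULT_LFP_RATE,
    site_id: str = "site",
) -> LFPSet:
    """Simulate trials x time LFP traces for each condition.

    Each trace is 1/f background + envelope-following auditory component +
    a narrowband oscillation at the centre of ``reset_band``.  At every
    luminance rising edge the oscillation phase is redrawn from a von Mises
    distribution centred on a fixed target phase with resultant length
    ``reset_strength`` (blended over one cycle to avoid amplitude
    transients); between edges the phase advances freely.  With
    ``power_modulation_gain > 0`` the oscillation amplitude additionally
    follows the luminance envelope -- a deliberately non-power-neutral
    control mode.
    """
    if sample_rate < 300:
        raise ValueError("sample_rate must be at least 300 Hz")
    rng = np.random.default_rng(seed)
    kappa = _vonmises_kappa(p.reset_strength)
    target_phase = 0.0
    traces: dict[str, np.ndarray] = {}
    for cond, stim in stimuli.items():
        n = int(round(stim.duration * sample_rate))
        t = np.arange(n) / sample_rate
        envA = sum(e.resample(sample_rate, n) for e in stim.envelopes.values())
        lum = (
            stim.luminance.resample(sample_rate, n)
            if stim.luminance is not None
            else None
        )
        edges = (
            _rising_edges(lum, p.reset_trigger_threshold)
            if lum is not None
            else np.array([], dtype=int)
        )
        cond_traces = np.empty((n_trials, n))
        for k in range(n_trials):
            # trial-private carrier within the reset band (clipped normal
            # around the band centre): the phase is anchored to the target
            # at every edge (a decaying locked transient across trials),
            # while the fine FM/AM structure stays trial-specific, keeping
            # the power analysis null
            lo, hi = p.reset_band
            f_c = float(
                np.clip(rng.normal(0.5 * (lo + hi), (hi - lo) / 6.0), lo, hi)
            )
            offset = _phase_offset_track(
                n, t, f_c, edges, target_phase, kappa, p.reset_strength, rng,
                min_interval=p.min_reset_interval,
            )
            osc = np.cos(2 * np.pi * f_c * t + offset)
            if p.amplitude_noise > 0:
                osc = osc * np.maximum(
                    1.0 + p.amplitude_noise * _slow_noise(n, sample_rate, rng), 0.05
                )
            if p.power_modulation_gain > 0 and lum is not None:
                osc = osc * (1.0 + p.power_modulation_gain * lum)
            trace = (
                p.oscillation_amplitude * osc
                + p.auditory_evoked_gain * envA
                + p.noise_amplitude * _pink_noise(n, p.noise_exponent, rng)
            )
            cond_traces[k] = trace
        traces[cond] = cond_traces
    return LFPSet(site_id=site_id, traces=traces, sample_rate=sample_rate, params=p)


# ---------------------------------------------------------------------------
# population generation and HDF5 round-trip


@dataclass
class PopulationDataset:
    units: list  # UnitRecording
    sites: list  # LFPSet
    stimuli: dict  # condition -> StimulusSet
    ground_truth: dict  # unit_id -> class label & params
    seed: int = 0

    def digest(self) -> str:
        h = hashlib.sha256()
        for u in self.units:
            for cond in sorted(u.trials):
                for tr in u.trials[cond]:
                    h.update(np.asarray(tr).tobytes())
        for s in self.sites:
            for cond in sorted(s.traces):
                h.update(np.ascontiguousarray(s.traces[cond]).tobytes())
        return h.hexdigest()


DEFAULT_CLASS_PROPORTIONS = {"auditory": 0.4, "visual": 0.1, "none": 0.5}


def _unit_params_for_class(cls: str, rng: np.random.Generator, kappa: float,
                           deviant_gain: float) -> UnitParams:
    base = float(rng.uniform(2.0, 8.0))
    if cls == "auditory":
        return UnitParams(
            baseline_rate=base,
            gain_auditory=float(rng.uniform(20.0, 40.0)),
            coherence_reliability=kappa,
            deviant_gain=deviant_gain,
        )
    if cls == "visual":
        return UnitParams(
            baseline_rate=base,
            gain_visual=float(rng.uniform(20.0, 40.0)),
            coherence_reliability=kappa,
        )
    if cls == "audiovisual":
        return UnitParams(
            baseline_rate=base,
            gain_auditory=float(rng.uniform(15.0, 30.0)),
            gain_visual=float(rng.uniform(15.0, 30.0)),
            coherence_reliability=kappa,
            deviant_gain=deviant_gain,
        )
    if cls == "none":
        return UnitParams(baseline_rate=base)
    raise ValueError(f"unknown unit class {cls!r}")


def generate_population(
    proportions: dict | None = None,
    n_units: int = 100,
    n_sites: int = 0,
    stimuli: dict | None = None,
    n_trials: int = 20,
    seed: int = 0,
    coherence_reliability: float = 1.0,
    deviant_gain: float = 0.0,
    lfp_params: LFPParams | None = None,
) -> PopulationDataset:
    """Generate a reproducible population of units (and optional LFP sites).

    ``proportions`` maps unit class ('auditory', 'visual', 'audiovisual',
    'none') to its population fraction (must sum to 1); unit counts per
    class are multinomial draws.  All unit/site seeds derive from ``seed``,
    and the ground-truth labels and parameters are recorded.
    """
    proportions = dict(proportions or DEFAULT_CLASS_PROPORTIONS)
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    if stimuli is None:
        raise ValueError("a condition -> StimulusSet mapping is required")
    rng = np.random.default_rng(seed)
    classes = list(proportions)
    counts = rng.multinomial(n_units, [proportions[c] for c in classes])
    units, truth = [], {}
    i = 0
    for cls, cnt in zip(classes, counts):
        for _ in range(cnt):
            uid = f"u{i:04d}"
            params = _unit_params_for_class(cls, rng, coherence_reliability, deviant_gain)
            units.append(
                simulate_spiking_unit(
                    params, stimuli, n_trials=n_trials,
                    seed=int(rng.integers(2**31)), unit_id=uid,
                )
            )
            truth[uid] = {"class": cls, "params": asdict(params)}
            i += 1
    sites = []
    for j in range(n_sites):
        sid = f"s{j:04d}"
        sp = lfp_params or LFPParams(reset_strength=0.8)
        sites.append(
            simulate_lfp_site(
                sp, stimuli, n_trials=n_trials, seed=int(rng.integers(2**31)),
                site_id=sid,
            )
        )
        # JSON-normalized so the manifest round-trips exactly
        truth[sid] = {"class": "lfp", "params": json.loads(json.dumps(asdict(sp)))}
    return PopulationDataset(units, sites, stimuli or {}, truth, seed)


def save_dataset(ds: PopulationDataset, path) -> None:
    """Write the dataset to HDF5 (spike times, LFP traces, ground truth)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["seed"] = ds.seed
        f.attrs["ground_truth"] = json.dumps(ds.ground_truth)
        for u in ds.units:
            g = f.create_group(f"units/{u.unit_id}")
            g.attrs["state"] = u.state
            g.attrs["area"] = u.area
            for cond, trs in u.trials.items():
                cg = g.create_group(cond)
                for k, tr in enumerate(trs):
                    cg.create_dataset(f"trial_{k:03d}", data=np.asarray(tr))
        for s in ds.sites:
            g = f.create_group(f"lfp/{s.site_id}")
            g.attrs["sample_rate"] = s.sample_rate
            g.attrs["band"] = s.band
            for cond, tr in s.traces.items():
                g.create_dataset(cond, data=tr)


def load_dataset(path) -> PopulationDataset:
    import h5py

    units, sites = [], []
    with h5py.File(path, "r") as f:
        truth = json.loads(f.attrs["ground_truth"])
        seed = int(f.attrs["seed"])
        for uid in sorted(f.get("units", {})):
            g = f[f"units/{uid}"]
            trials = {
                cond: [g[cond][k][()] for k in sorted(g[cond])] for cond in g
            }
            units.append(
                UnitRecording(uid, trials, state=g.attrs["state"], area=g.attrs["area"])
            )
        for sid in sorted(f.get("lfp", {})):
            g = f[f"lfp/{sid}"]
            traces = {cond: g[cond][()] for cond in g}
            sites.append(
                LFPSet(sid, traces, sample_rate=float(g.attrs["sample_rate"]),
                       band=tuple(g.attrs["band"]))
            )
    return PopulationDataset(units, sites, {}, truth, seed)
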