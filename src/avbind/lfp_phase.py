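"""Morlet time-frequency analysis, inter-trial phase coherence (ITPC) and
phase/power dissimilarity indices (PDI) for local field potentials.

ITPC at a time-frequency point is the resultant length of the per-trial
phase distribution::

    ITPC(t, f) = | (1/N) * sum_k exp(i * theta_k(t, f)) |

which is 1 when every trial has the same phase and tends to 0 for random
phases (expectation ~ sqrt(pi)/(2 sqrt(N)) for uniform phase).

The phase dissimilarity index contrasts the ITPC computed *within*
repetitions of one stimulus against the ITPC computed *across* trials in
which the auditory stimulus was identical but the visual stimulus was drawn
at random.  Because both terms contain identical sounds, a positive PDI
isolates phase structure contributed by the visual stream.  The same
construction applied to the two sound mixtures (A12V1 vs A12V2) is the
dual-stream PDI.  A parallel "power dissimilarity" analysis substitutes
normalized single-trial power time courses for unit phasors, providing the
control that visual stimuli reset LFP phase without changing LFP power.

Population significance per frequency uses a paired one-sided t test
(within > across) across recording sites with Bonferroni correction over
frequencies, and a run-length rule: only frequencies inside runs of at
least ``min_adjacent`` consecutive significant bins count, whose PDI values
sum to the PDI magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft, stats

__all__ = [
    "FrequencyGrid",
    "TFR",
    "ITPCMap",
    "PDIResult",
    "morlet_tfr",
    "itpc",
    "across_stimulus_itpc",
    "single_stream_pdi",
    "dual_stream_pdi",
    "pdi_significance",
    "power_dissimilarity",
    "bonferroni_alpha",
]


def _default_freqs() -> np.ndarray:
    # 2.5 to 45 Hz inclusive in 0.5-Hz steps: 86 points
    return np.arange(2.5, 45.0 + 0.25, 0.5)


@dataclass(frozen=True)
class FrequencyGrid:
    frequencies: np.ndarray = field(default_factory=_default_freqs)
    cycles: float = 7.0

    @property
    def n_points(self) -> int:
        return len(self.frequencies)


@dataclass
class TFR:
    """Complex Morlet coefficients, (trials, frequencies, time)."""

    coef: np.ndarray
    grid: FrequencyGrid
    sample_rate: float
    edge: np.ndarray  # per-frequency number of contaminated samples each side

    @property
    def n_trials(self) -> int:
        return self.coef.shape[0]

    def valid_mask(self) -> np.ndarray:
        """(frequencies, time) mask of samples clear of edge contamination."""
        n = self.coef.shape[2]
        t = np.arange(n)
        return (t[None, :] >= self.edge[:, None]) & (t[None, :] < n - self.edge[:, None])


@dataclass
class ITPCMap:
    values: np.ndarray  # (frequencies, time) in [0, 1]
    n_trials: int
    profile: np.ndarray  # (frequencies,) time-averaged over valid samples
    grid: FrequencyGrid


@dataclass
class PDIResult:
    frequencies: np.ndarray
    pdi: np.ndarray  # per-frequency values (site-mean when population-level)
    kind: str  # single-stream / dual-stream / power
    significant_mask: np.ndarray | None = None
    magnitude: float = 0.0
    alpha_corrected: float | None = None


# ---------------------------------------------------------------------------
# wavelet decomposition


def morlet_tfr(
    traces: np.ndarray,
    sample_rate: float,
    grid: FrequencyGrid | None = None,
) -> TFR:
    """Complex Morlet wavelet transform of trials x time voltage traces.

    Wavelets are Gaussian-windowed complex exponentials with
    ``sigma_t = cycles / (2 pi f)`` and unit energy; convolution is
    zero-padded FFT convolution.  Samples within ``2 sigma_t`` of either
    trace end are flagged as edge-contaminated per frequency and excluded
    from time-averaged profiles.
    """
    grid = grid or FrequencyGrid()
    x = np.atleast_2d(np.asarray(traces, dtype=float))
    n_trials, n = x.shape
    freqs = grid.frequencies
    sigma_t = grid.cycles / (2 * np.pi * freqs)
    if n / sample_rate < grid.cycles / freqs.min():
        raise ValueError("trace shorter than the wavelet at the lowest frequency")
    half = np.ceil(3 * sigma_t * sample_rate).astype(int)
    nfft = fft.next_fast_len(n + 2 * half.max())
    Xf = np.fft.fft(x, n=nfft, axis=1)
    coef = np.empty((n_trials, len(freqs), n), dtype=np.complex128)
    for i, (f, s, h) in enumerate(zip(freqs, sigma_t, half)):
        t = np.arange(-h, h + 1) / sample_rate
        w = np.exp(-(t**2) / (2 * s**2)) * np.exp(2j * np.pi * f * t)
        w /= np.sqrt(np.sum(np.abs(w) ** 2))
        Wf = np.fft.fft(w, n=nfft)
        conv = np.fft.ifft(Xf * Wf[None, :], axis=1)
        coef[:, i, :] = conv[:, h : h + n]  # centre of the full convolution
    edge = np.ceil(2 * sigma_t * sample_rate).astype(int)
    return TFR(coef=coef, grid=grid, sample_rate=sample_rate, edge=edge)


# ---------------------------------------------------------------------------
# inter-trial phase coherence


def _itpc_from_phasors(ph: np.ndarray) -> np.ndarray:
    return np.abs(ph.mean(axis=0))


def _profile(values: np.ndarray, tfr: TFR) -> np.ndarray:
    mask = tfr.valid_mask()
    s = np.where(mask, values, 0.0).sum(axis=1)
    cnt = mask.sum(axis=1)
    return s / np.maximum(cnt, 1)


def itpc(tfr: TFR) -> ITPCMap:
    """Within-stimulus ITPC over all trials of a TFR."""
    if tfr.n_trials < 2:
        raise ValueError("ITPC requires at least 2 trials")
    ph = tfr.coef / np.maximum(np.abs(tfr.coef), 1e-300)
    values = _itpc_from_phasors(ph)
    return ITPCMap(values, tfr.n_trials, _profile(values, tfr), tfr.grid)


def across_stimulus_itpc(
    tfr_a: TFR, tfr_b: TFR, n_shuffles: int = 100, seed: int = 0
) -> ITPCMap:
    """ITPC across trials pooled from two conditions with shared audio.

    For each shuffle, N trials (N matching the within-condition count) are
    drawn without replacement from the pooled trials of both conditions and
    their ITPC computed; maps are averaged over shuffles.
    """
    na, nb = tfr_a.n_trials, tfr_b.n_trials
    if max(na, nb) > 2 * min(na, nb):
        raise ValueError("trial counts differ by more than a factor of 2")
    coef = np.concatenate([tfr_a.coef, tfr_b.coef], axis=0)
    ph = coef / np.maximum(np.abs(coef), 1e-300)
    rng = np.random.default_rng(seed)
    n_draw = min(na, nb)
    ntot = ph.shape[0]
    F, T = ph.shape[1], ph.shape[2]
    flat = ph.reshape(ntot, F * T)
    acc = np.zeros(F * T)
    done = 0
    while done < n_shuffles:  # batched: shuffle sums as one matmul
        r = min(25, n_shuffles - done)
        sel = np.zeros((r, ntot))
        for row in range(r):
            sel[row, rng.choice(ntot, size=n_draw, replace=False)] = 1.0 / n_draw
        acc += np.abs(sel @ flat).sum(axis=0)
        done += r
    values = (acc / n_shuffles).reshape(F, T)
    return ITPCMap(values, n_draw, _profile(values, tfr_a), tfr_a.grid)


# ---------------------------------------------------------------------------
# phase dissimilarity indices


_COHERENCY_GROUPS = {
    "coherent": ("A1V1", "A2V2"),
    "independent": ("A1V2", "A2V1"),
}
_ACROSS_PAIRS = {"A1V1": "A1V2", "A1V2": "A1V1", "A2V1": "A2V2", "A2V2": "A2V1"}


def single_stream_pdi(
    tfrs: dict, n_shuffles: int = 100, seed: int = 0
) -> dict:
    """Per-site single-stream PDI profiles grouped by audio-visual coherency.

    ``tfrs`` maps the four single-stream conditions to their TFRs.  For each
    stimulus, PDI(f) = within-ITPC profile - across-ITPC profile, where the
    across term pools that stimulus with its same-audio partner (e.g. A1V1
    with A1V2).  Profiles are then averaged over the two stimuli of each
    grouping (coherent: A1V1/A2V2; independent: A1V2/A2V1).
    """
    per_stim = {}
    for i, (cond, partner) in enumerate(_ACROSS_PAIRS.items()):
        if cond not in tfrs or partner not in tfrs:
            raise ValueError(f"missing condition {cond!r} or {partner!r}")
        _check_grids(tfrs[cond], tfrs[partner])
        within = itpc(tfrs[cond]).profile
        across = across_stimulus_itpc(
            tfrs[cond], tfrs[partner], n_shuffles, seed + i
        ).profile
        per_stim[cond] = within - across
    out = {}
    freqs = next(iter(tfrs.values())).grid.frequencies
    for group, (c1, c2) in _COHERENCY_GROUPS.items():
        pdi = 0.5 * (per_stim[c1] + per_stim[c2])
        out[group] = PDIResult(freqs, pdi, kind="single-stream")
    return out


def dual_stream_pdi(
    tfr_v1: TFR, tfr_v2: TFR, n_shuffles: int = 100, seed: int = 0
) -> PDIResult:
    """Dual-stream PDI: within-mixture ITPC minus across-visual ITPC.

    The within term averages the ITPC profiles of A12V1 and A12V2; the
    across term draws trials at random across the two visual conditions.
    Positive values mean the visual stream shaped the response timing to an
    identical sound mixture.
    """
    _check_grids(tfr_v1, tfr_v2)
    within = 0.5 * (itpc(tfr_v1).profile + itpc(tfr_v2).profile)
    across = across_stimulus_itpc(tfr_v1, tfr_v2, n_shuffles, seed).profile
    return PDIResult(
        tfr_v1.grid.frequencies, within - across, kind="dual-stream"
    )


def _check_grids(a: TFR, b: TFR) -> None:
    if not np.array_equal(a.grid.frequencies, b.grid.frequencies):
        raise ValueError("frequency grids do not match")


def bonferroni_alpha(base_alpha: float, n_freq: int) -> float:
    """Bonferroni-corrected per-frequency alpha (0.05/43 -> 0.0012)."""
    return base_alpha / n_freq


def pdi_significance(
    within: np.ndarray,
    across: np.ndarray,
    base_alpha: float = 0.05,
    n_freq: int | None = None,
    min_adjacent: int = 2,
) -> PDIResult:
    """Population-level PDI significance across sites.

    ``within`` and ``across`` are (sites, frequencies) paired samples (e.g.
    time-averaged ITPC profiles per site).  Each frequency is tested with a
    paired one-sided t test (within > across) at the Bonferroni-corrected
    level ``base_alpha / n_freq``; only frequencies inside runs of at least
    ``min_adjacent`` consecutive significant bins are retained, and the PDI
    magnitude is the sum of the site-mean PDI over retained frequencies.
    """
    within = np.asarray(within, dtype=float)
    across = np.asarray(across, dtype=float)
    if within.shape != across.shape or within.ndim != 2:
        raise ValueError("within/across must be matching (sites, freqs) arrays")
    if within.shape[0] < 3:
        raise ValueError("at least 3 paired sites are required")
    nf = within.shape[1]
    alpha_c = bonferroni_alpha(base_alpha, n_freq if n_freq is not None else nf)
    t, p = stats.ttest_rel(within, across, axis=0, alternative="greater")
    raw = p < alpha_c
    mask = _adjacency_filter(raw, min_adjacent)
    pdi = (within - across).mean(axis=0)
    magnitude = float(pdi[mask].sum()) if mask.any() else 0.0
    return PDIResult(
        frequencies=np.arange(nf, dtype=float),
        pdi=pdi,
        kind="significance",
        significant_mask=mask,
        magnitude=magnitude,
        alpha_corrected=alpha_c,
    )


def _adjacency_filter(raw: np.ndarray, min_adjacent: int) -> np.ndarray:
    """Keep only runs of >= min_adjacent consecutive True bins."""
    mask = np.zeros_like(raw)
    i = 0
    n = len(raw)
    while i < n:
        if raw[i]:
            j = i
            while j < n and raw[j]:
                j += 1
            if j - i >= min_adjacent:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


# ---------------------------------------------------------------------------
# power dissimilarity (control analysis)


def _power_z(coef: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-trial z-scored power time courses, zeroed outside the valid mask.

    Z-scoring each trial over its valid samples makes pairwise correlations
    depend on the pair alone, so trial-subset consistencies reduce to sums.
    """
    p = np.abs(coef) ** 2  # (n, F, T)
    m = mask[None, :, :]
    cnt = mask.sum(axis=1)  # (F,)
    mu = (p * m).sum(axis=2) / cnt[None, :]
    p = p - mu[:, :, None]
    var = ((p**2) * m).sum(axis=2) / cnt[None, :]
    return np.where(m, p / np.sqrt(np.maximum(var, 1e-300))[:, :, None], 0.0)


def _consistency_from_sums(s: np.ndarray, n: int, mask: np.ndarray) -> np.ndarray:
    """Mean pairwise correlation per frequency from summed z-courses.

    ``s`` is the sum of n z-scored courses, (..., F, T); correlations use
    sum-of-pairs = (||s||^2 - n * T_valid) since each course has unit
    variance over its T_valid valid samples.
    """
    cnt = mask.sum(axis=1)
    tot = ((s**2) * mask).sum(axis=-1) / cnt  # (..., F)
    return (tot - n) / (n * (n - 1))


def power_dissimilarity(
    tfr_a: TFR, tfr_b: TFR, n_shuffles: int = 100, seed: int = 0,
    kind: str = "power",
) -> PDIResult:
    """Within-minus-across consistency of single-trial power time courses.

    The analogue of the phase dissimilarity pipeline with normalized power
    substituted for unit phasors: within-condition consistency is the mean
    pairwise correlation of per-trial power envelopes; the across term
    recomputes it on trial subsets drawn across the two conditions.
    Positive values indicate condition-specific power dynamics; a
    phase-only reset leaves it at zero.
    """
    _check_grids(tfr_a, tfr_b)
    mask = tfr_a.valid_mask()
    rng = np.random.default_rng(seed)
    na, nb = tfr_a.n_trials, tfr_b.n_trials
    coef = np.concatenate([tfr_a.coef, tfr_b.coef], axis=0)
    z = _power_z(coef, mask)  # (ntot, F, T)
    within = 0.5 * (
        _consistency_from_sums(z[:na].sum(axis=0), na, mask)
        + _consistency_from_sums(z[na:].sum(axis=0), nb, mask)
    )
    ntot, F, T = z.shape
    flat = z.reshape(ntot, F * T)
    n_draw = min(na, nb)
    acc = np.zeros(F)
    done = 0
    while done < n_shuffles:
        r = min(25, n_shuffles - done)
        sel = np.zeros((r, ntot))
        for row in range(r):
            sel[row, rng.choice(ntot, size=n_draw, replace=False)] = 1.0
        s = (sel @ flat).reshape(r, F, T)
        acc += _consistency_from_sums(s, n_draw, mask).sum(axis=0)
        done += r
    across = acc / n_shuffles
    return PDIResult(tfr_a.grid.frequencies, within - across, kind=kind)
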