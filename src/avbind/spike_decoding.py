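"""Template-matching spike-pattern decoding, unit classification and the
visual preference index (VPI).

The decoder bins each trial's spike train into a peri-stimulus count vector,
builds per-class mean templates and assigns each trial to the class whose
template is nearest in Euclidean distance.  Within-condition discrimination
uses leave-one-out cross-validation (the held-out trial is removed from its
own class template); dual-stream decoding classifies sound-mixture trials
against templates built from disjoint single-stream conditions, so no
cross-validation is required there.

Significance everywhere is non-parametric: trials are resampled and randomly
reassigned to classes, the statistic is recomputed for ``n_iter`` iterations,
and the observed value is compared with the null distribution (flagged when
it exceeds the 95th percentile).

The VPI summarizes how strongly the identity of the visual stream biases the
decoding of a dual-stream (two competing sounds) response: the percentage of
A12V1 trials decoded as stream A1 minus the percentage of A12V2 trials
decoded as A1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PSTHMatrix",
    "ClassifierResult",
    "PermutationResult",
    "DualStreamResult",
    "VPIResult",
    "UnitClass",
    "bin_spikes",
    "euclidean_loocv",
    "permutation_null",
    "classify_unit_discrimination",
    "decode_dual_stream",
    "compute_vpi",
    "vpi_permutation",
    "coherence_decoding_contrast",
    "classify_simple_unit",
    "truncate_percent",
]

DEFAULT_WINDOW = (0.0, 3.0)  # s, analysis window from stimulus onset
DEFAULT_BIN_WIDTH = 0.020  # s


# ---------------------------------------------------------------------------
# containers


@dataclass
class PSTHMatrix:
    """Binned spike counts, trials x bins, over a half-open analysis window."""

    counts: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH
    window: tuple[float, float] = DEFAULT_WINDOW

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class ClassifierResult:
    labels: list  # assigned class label per trial (input order)
    true_labels: list
    proportions: dict  # assigned label -> fraction of trials
    percent_correct: float
    permutation_p: float | None = None
    significant: bool | None = None
    n_iterations: int | None = None


@dataclass
class PermutationResult:
    observed: float
    p: float
    significant: bool
    null_scores: np.ndarray
    n_iterations: int


@dataclass
class DualStreamResult:
    """Counts of dual-stream trials labeled A1, per visual condition."""

    counts_a1: dict  # visual condition ("V1"/"V2"/"none") -> trials labeled A1
    totals: dict  # visual condition -> total trials
    template_source: str = "av"

    def proportion(self, visual: str) -> float:
        return self.counts_a1[visual] / self.totals[visual]


@dataclass
class VPIResult:
    pct_a1_given_v1: float
    pct_a1_given_v2: float
    vpi: float
    convention: str = "whole-truncate"
    permutation_p: float | None = None
    significant: bool | None = None


@dataclass
class UnitClass:
    label: str  # auditory-discriminating / visual-discriminating / both / none
    auditory_score: float
    visual_score: float
    auditory_p: float
    visual_p: float


# ---------------------------------------------------------------------------
# binning


def bin_spikes(
    trials,
    window: tuple[float, float] = DEFAULT_WINDOW,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> PSTHMatrix:
    """Bin per-trial spike times into counts over a half-open window.

    Bins are half-open ``[edge, edge + bin_width)``: a spike exactly at an
    edge belongs to the later bin, and spikes at or after the window end are
    excluded.  ``bin_width`` must divide the window length exactly.
    """
    start, end = window
    if start >= end:
        raise ValueError("window start must precede end")
    n_bins_f = (end - start) / bin_width
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError("bin_width must divide the window length")
    counts = np.zeros((len(trials), n_bins), dtype=np.int64)
    for i, t in enumerate(trials):
        t = np.asarray(t, dtype=float)
        t = t[(t >= start) & (t < end)]
        idx = np.floor((t - start) / bin_width).astype(np.int64)
        np.clip(idx, 0, n_bins - 1, out=idx)  # guards float round-off at edges
        np.add.at(counts[i], idx, 1)
    return PSTHMatrix(counts=counts, bin_width=bin_width, window=window)


# ---------------------------------------------------------------------------
# LOOCV Euclidean classifier


def _argmin_random_ties(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Argmin along the last axis with uniform random tie-breaking."""
    m = d.min(axis=-1, keepdims=True)
    ties = d <= m + 1e-9 * (1.0 + np.abs(m))
    u = rng.random(d.shape) * ties
    return u.argmax(axis=-1)


def _loocv_assign_batch(
    x: np.ndarray, class_sizes, rng: np.random.Generator
) -> np.ndarray:
    """Leave-one-out nearest-template assignment for a batch of problems.

    ``x`` has shape (R, n, B): R independent problems over the same trial
    layout, in which the first ``class_sizes[0]`` columns belong to class 0,
    the next to class 1, etc.  Returns assigned class indices (R, n).
    """
    R, n, B = x.shape
    k = len(class_sizes)
    bounds = np.concatenate([[0], np.cumsum(class_sizes)])
    sums = np.stack(
        [x[:, bounds[c] : bounds[c + 1]].sum(axis=1) for c in range(k)], axis=1
    )  # (R, k, B)
    counts = np.asarray(class_sizes, dtype=float)

    # distances to full-class means, then correct the trial's own class to
    # the leave-one-out template
    means = sums / counts[None, :, None]
    x2 = np.einsum("rnb,rnb->rn", x, x)
    m2 = np.einsum("rkb,rkb->rk", means, means)
    cross = np.einsum("rnb,rkb->rnk", x, means)
    d2 = x2[:, :, None] - 2 * cross + m2[:, None, :]  # (R, n, k)

    for c in range(k):
        nc = counts[c]
        if nc < 2:
            raise ValueError("each class needs at least 2 trials for LOOCV")
        sl = slice(bounds[c], bounds[c + 1])
        xo = x[:, sl]  # (R, nc, B)
        loo = (sums[:, c][:, None, :] - xo) / (nc - 1)
        diff = xo - loo
        d2[:, sl, c] = np.einsum("rnb,rnb->rn", diff, diff)

    np.maximum(d2, 0, out=d2)
    return _argmin_random_ties(d2, rng)


def _stack_groups(groups: dict) -> tuple[np.ndarray, list, list]:
    labels = list(groups.keys())
    mats = []
    for lab in labels:
        g = groups[lab]
        m = g.counts if isinstance(g, PSTHMatrix) else np.asarray(g)
        mats.append(np.asarray(m, dtype=float))
    n_bins = {m.shape[1] for m in mats}
    if len(n_bins) != 1:
        raise ValueError("all classes must share the same bin structure")
    if any(m.shape[0] < 2 for m in mats):
        raise ValueError("each class needs at least 2 trials")
    return np.concatenate(mats, axis=0), labels, [m.shape[0] for m in mats]


def euclidean_loocv(groups: dict, seed: int = 0, rng=None) -> ClassifierResult:
    """Leave-one-out nearest-mean-template classification.

    ``groups`` maps class label -> :class:`PSTHMatrix` (or count matrix).
    Each trial is assigned to the class with the nearest mean template,
    excluding the trial itself from its own class template; distance ties
    are broken uniformly at random under ``seed``.
    """
    x, labels, sizes = _stack_groups(groups)
    rng = np.random.default_rng(seed) if rng is None else rng
    assigned = _loocv_assign_batch(x[None], sizes, rng)[0]
    true = np.repeat(np.arange(len(labels)), sizes)
    pct = 100.0 * float(np.mean(assigned == true))
    props = {lab: float(np.mean(assigned == c)) for c, lab in enumerate(labels)}
    return ClassifierResult(
        labels=[labels[a] for a in assigned],
        true_labels=[labels[t] for t in true],
        proportions=props,
        percent_correct=pct,
    )


def permutation_null(
    groups: dict,
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    scheme: str = "permute",
) -> PermutationResult:
    """Permutation/bootstrap null for the LOOCV decoding score.

    ``scheme='permute'`` (default) shuffles the observed trials across
    classes without replacement, preserving class sizes, which yields
    calibrated p-values under exchangeability.  ``scheme='bootstrap'``
    redraws trials with replacement before random class assignment; because
    a duplicated trial can appear in its own leave-one-out template this
    null is biased toward higher scores and is conservative.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    x, _, sizes = _stack_groups(groups)
    rng = np.random.default_rng(seed)
    observed = euclidean_loocv(groups, rng=rng).percent_correct
    null = _null_scores(x, sizes, n_iter, rng, scheme)
    p = float(np.mean(null >= observed))
    flag = observed > np.percentile(null, 100 * (1 - alpha))
    return PermutationResult(observed, p, bool(flag), null, n_iter)


def _null_scores(x, sizes, n_iter, rng, scheme, batch: int = 250) -> np.ndarray:
    n = x.shape[0]
    true = np.repeat(np.arange(len(sizes)), sizes)
    out = np.empty(n_iter)
    done = 0
    while done < n_iter:
        r = min(batch, n_iter - done)
        if scheme == "bootstrap":
            idx = rng.integers(0, n, size=(r, n))
        elif scheme == "permute":
            idx = np.argsort(rng.random((r, n)), axis=1)
        else:
            raise ValueError("scheme must be 'permute' or 'bootstrap'")
        xb = x[idx]  # (r, n, B)
        assigned = _loocv_assign_batch(xb, sizes, rng)
        out[done : done + r] = 100.0 * np.mean(assigned == true[None, :], axis=1)
        done += r
    return out


# ---------------------------------------------------------------------------
# unit classification from single-stream conditions

SINGLE_STREAM = ("A1V1", "A1V2", "A2V1", "A2V2")


def _unit_psth(unit, condition, window, bin_width) -> np.ndarray:
    if condition not in unit.trials:
        raise ValueError(f"unit lacks condition {condition!r}")
    return bin_spikes(unit.trials[condition], window, bin_width).counts.astype(float)


def classify_unit_discrimination(
    unit,
    window: tuple[float, float] = DEFAULT_WINDOW,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    scheme: str = "permute",
) -> UnitClass:
    """Label a unit by which single-stream axes its responses discriminate.

    Auditory axis: decode A1 vs A2 sound identity from {A1V1 u A1V2} vs
    {A2V1 u A2V2}; visual axis: decode V1 vs V2 from {A1V1 u A2V1} vs
    {A1V2 u A2V2}.  A unit is auditory-discriminating, visual-discriminating,
    both, or none according to which axes beat their permutation null.
    """
    psth = {c: _unit_psth(unit, c, window, bin_width) for c in SINGLE_STREAM}
    aud = {
        "A1": np.concatenate([psth["A1V1"], psth["A1V2"]]),
        "A2": np.concatenate([psth["A2V1"], psth["A2V2"]]),
    }
    vis = {
        "V1": np.concatenate([psth["A1V1"], psth["A2V1"]]),
        "V2": np.concatenate([psth["A1V2"], psth["A2V2"]]),
    }
    ra = permutation_null(aud, n_iter, alpha, seed, scheme)
    rv = permutation_null(vis, n_iter, alpha, seed + 1, scheme)
    if ra.significant and rv.significant:
        label = "both"
    elif ra.significant:
        label = "auditory-discriminating"
    elif rv.significant:
        label = "visual-discriminating"
    else:
        label = "none"
    return UnitClass(label, ra.observed, rv.observed, ra.p, rv.p)


# ---------------------------------------------------------------------------
# dual-stream decoding and the visual preference index

_TEMPLATE_CONDITIONS = {"av": ("A1V1", "A2V2"), "audio": ("A1", "A2")}
_DUAL_VISUAL = {"A12V1": "V1", "A12V2": "V2", "A12": "none"}


def decode_dual_stream(
    unit,
    template_source: str = "av",
    window: tuple[float, float] = DEFAULT_WINDOW,
    bin_width: float = DEFAULT_BIN_WIDTH,
    seed: int = 0,
) -> DualStreamResult:
    """Label each dual-stream (sound mixture) trial as stream A1 or A2.

    Templates are the mean responses to the temporally coherent single-stream
    stimuli (``template_source='av'``: A1V1 and A2V2) or the auditory-only
    controls (``'audio'``: A1 and A2).  Template and test conditions are
    disjoint, so the full template conditions are used without
    cross-validation.  Also decodes the no-visual mixture (A12) if present.
    """
    try:
        cond_a1, cond_a2 = _TEMPLATE_CONDITIONS[template_source]
    except KeyError:
        raise ValueError("template_source must be 'av' or 'audio'") from None
    t1 = _unit_psth(unit, cond_a1, window, bin_width).mean(axis=0)
    t2 = _unit_psth(unit, cond_a2, window, bin_width).mean(axis=0)
    rng = np.random.default_rng(seed)
    counts_a1, totals = {}, {}
    for cond, visual in _DUAL_VISUAL.items():
        if cond not in unit.trials:
            continue
        x = _unit_psth(unit, cond, window, bin_width)
        d = np.stack(
            [((x - t1) ** 2).sum(axis=1), ((x - t2) ** 2).sum(axis=1)], axis=-1
        )
        lab = _argmin_random_ties(d, rng)
        counts_a1[visual] = int(np.sum(lab == 0))
        totals[visual] = x.shape[0]
    if "V1" not in counts_a1 or "V2" not in counts_a1:
        raise ValueError("unit lacks a dual-stream condition (A12V1/A12V2)")
    return DualStreamResult(counts_a1, totals, template_source)


def truncate_percent(numerator: int, denominator: int) -> int:
    """Whole-percent value truncated toward zero (19/23 -> 82)."""
    return math.trunc(100.0 * numerator / denominator)


def compute_vpi(
    dual: DualStreamResult, convention: str = "whole-truncate"
) -> VPIResult:
    """Visual preference index: %A1-under-V1 minus %A1-under-V2.

    Under the default reporting convention each percentage is truncated to a
    whole percent before subtraction; ``convention='raw'`` subtracts the
    un-rounded percentages.
    """
    n1, d1 = dual.counts_a1["V1"], dual.totals["V1"]
    n2, d2 = dual.counts_a1["V2"], dual.totals["V2"]
    if convention == "whole-truncate":
        p1, p2 = truncate_percent(n1, d1), truncate_percent(n2, d2)
    elif convention == "raw":
        p1, p2 = 100.0 * n1 / d1, 100.0 * n2 / d2
    else:
        raise ValueError("convention must be 'whole-truncate' or 'raw'")
    return VPIResult(p1, p2, p1 - p2, convention)


def vpi_permutation(
    unit,
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    template_source: str = "av",
    window: tuple[float, float] = DEFAULT_WINDOW,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> VPIResult:
    """Permutation test of the VPI by shuffling template-trial identity.

    The single-stream trials that generate the two classifier templates are
    pooled and randomly re-split (class sizes preserved) ``n_iter`` times;
    the VPI is recomputed from raw percentages each time and the observed
    |VPI| is compared two-sidedly with the null |VPI| distribution.
    """
    cond_a1, cond_a2 = _TEMPLATE_CONDITIONS[template_source]
    g1 = _unit_psth(unit, cond_a1, window, bin_width)
    g2 = _unit_psth(unit, cond_a2, window, bin_width)
    rng = np.random.default_rng(seed)

    observed_dual = decode_dual_stream(unit, template_source, window, bin_width, seed)
    observed = compute_vpi(observed_dual, "raw").vpi

    pool = np.concatenate([g1, g2])
    n1 = g1.shape[0]
    xv1 = _unit_psth(unit, "A12V1", window, bin_width)
    xv2 = _unit_psth(unit, "A12V2", window, bin_width)

    null = np.empty(n_iter)
    batch = 250
    done = 0
    npool = pool.shape[0]
    while done < n_iter:
        r = min(batch, n_iter - done)
        perm = np.argsort(rng.random((r, npool)), axis=1)
        xb = pool[perm]  # (r, npool, B)
        t1 = xb[:, :n1].mean(axis=1)  # (r, B)
        t2 = xb[:, n1:].mean(axis=1)
        props = []
        for x in (xv1, xv2):
            d1 = ((x[None] - t1[:, None]) ** 2).sum(axis=-1)  # (r, m)
            d2 = ((x[None] - t2[:, None]) ** 2).sum(axis=-1)
            d = np.stack([d1, d2], axis=-1)
            lab = _argmin_random_ties(d, rng)
            props.append(100.0 * np.mean(lab == 0, axis=1))
        null[done : done + r] = props[0] - props[1]
        done += r
    p = float(np.mean(np.abs(null) >= abs(observed)))
    reported = compute_vpi(observed_dual)
    reported.permutation_p = p
    reported.significant = p < alpha
    return reported


# ---------------------------------------------------------------------------
# coherent vs independent single-stream decoding (rate-controlled)


def coherence_decoding_contrast(
    unit,
    window: tuple[float, float] = DEFAULT_WINDOW,
    bin_width: float = DEFAULT_BIN_WIDTH,
    seed: int = 0,
) -> dict:
    """LOOCV decoding of coherent (A1V1 vs A2V2) and independent (A1V2 vs
    A2V1) single-stream pairs, with per-condition mean/max evoked rates
    exposed for the rate-control comparison."""
    psth = {c: _unit_psth(unit, c, window, bin_width) for c in SINGLE_STREAM}
    coh = euclidean_loocv(
        {"A1V1": psth["A1V1"], "A2V2": psth["A2V2"]}, seed=seed
    ).percent_correct
    ind = euclidean_loocv(
        {"A1V2": psth["A1V2"], "A2V1": psth["A2V1"]}, seed=seed + 1
    ).percent_correct
    dur = window[1] - window[0]
    rates = {
        c: {
            "mean_rate": float(psth[c].sum(axis=1).mean() / dur),
            "max_rate": float(psth[c].max(axis=1).mean() / bin_width),
        }
        for c in SINGLE_STREAM
    }
    return {"coherent_score": coh, "independent_score": ind, "rates": rates}


# ---------------------------------------------------------------------------
# auditory/visual classification with simple stimuli (two-way ANOVA)


def classify_simple_unit(counts: dict, alpha: float = 0.05) -> dict:
    """Two-factor ANOVA classification from noise-burst/light-flash counts.

    ``counts`` maps (auditory_on, visual_on) boolean pairs to arrays of
    spike counts (a balanced 2x2 design with equal replicates per cell).
    Sums of squares follow the standard closed-form decomposition; a unit is
    "auditory" (sound main effect only), "visual" (light main effect only),
    "auditory-visual" (both main effects or a significant interaction), or
    "none".
    """
    cells = {}
    for a in (False, True):
        for v in (False, True):
            if (a, v) not in counts:
                raise ValueError("all four (auditory, visual) cells are required")
            arr = np.asarray(counts[(a, v)], dtype=float)
            if arr.size < 2:
                raise ValueError("each cell needs at least 2 replicates")
            cells[(a, v)] = arr
    ns = {len(c) for c in cells.values()}
    if len(ns) != 1:
        raise ValueError("design must be balanced (equal replicates per cell)")
    n = ns.pop()
    grand = np.mean([c.mean() for c in cells.values()])
    mean_a = {a: np.mean([cells[(a, v)].mean() for v in (False, True)]) for a in (False, True)}
    mean_v = {v: np.mean([cells[(a, v)].mean() for a in (False, True)]) for v in (False, True)}

    ss_a = 2 * n * sum((mean_a[a] - grand) ** 2 for a in (False, True))
    ss_v = 2 * n * sum((mean_v[v] - grand) ** 2 for v in (False, True))
    ss_int = n * sum(
        (cells[(a, v)].mean() - mean_a[a] - mean_v[v] + grand) ** 2
        for a in (False, True)
        for v in (False, True)
    )
    ss_err = sum(((c - c.mean()) ** 2).sum() for c in cells.values())
    df_err = 4 * (n - 1)
    ms_err = ss_err / df_err
    out = {}
    for name, ss in (("auditory", ss_a), ("visual", ss_v), ("interaction", ss_int)):
        f = np.inf if ms_err == 0 and ss > 0 else (ss / 1) / ms_err
        p = float(stats.f.sf(f, 1, df_err))
        out[name] = {"ss": float(ss), "F": float(f), "p": p}
    out["error"] = {"ss": float(ss_err), "df": df_err}

    sig_a = out["auditory"]["p"] < alpha
    sig_v = out["visual"]["p"] < alpha
    sig_i = out["interaction"]["p"] < alpha
    if (sig_a and sig_v) or sig_i:
        label = "auditory-visual"
    elif sig_a:
        label = "auditory"
    elif sig_v:
        label = "visual"
    else:
        label = "none"
    out["label"] = label
    return out
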