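"""Morlet decomposition, ITPC and phase/power dissimilarity machinery."""

import numpy as np
import pytest
from scipy.signal import hilbert

from avbind import lfp_phase as lp


def _tfr_from_phasors(ph, freqs=None):
    """Wrap raw complex phasors (trials, freqs, time) as a TFR."""
    freqs = freqs if freqs is not None else np.arange(3.0, 3.0 + 0.5 * ph.shape[1], 0.5)
    grid = lp.FrequencyGrid(frequencies=freqs)
    return lp.TFR(ph.astype(complex), grid, 600.0, np.zeros(ph.shape[1], dtype=int))


class TestFrequencyGrid:
    def test_default_grid_has_86_points(self):
        assert lp.FrequencyGrid().n_points == 86
        f = lp.FrequencyGrid().frequencies
        assert f[0] == 2.5 and f[-1] == 45.0
        np.testing.assert_allclose(np.diff(f), 0.5)

    def test_bonferroni_alpha_formats(self):
        assert f"{lp.bonferroni_alpha(0.05, 43):.4f}" == "0.0012"


class TestMorlet:
    def test_amplitude_peak_at_stimulus_frequency(self):
        fs = 600.0
        t = np.arange(int(3 * fs)) / fs
        tfr = lp.morlet_tfr(np.cos(2 * np.pi * 10 * t)[None, :], fs)
        mask = tfr.valid_mask()
        prof = (np.abs(tfr.coef[0]) * mask).sum(1) / mask.sum(1)
        assert tfr.grid.frequencies[np.argmax(prof)] == 10.0

    def test_phase_matches_analytic_signal(self):
        """Mid-trace wavelet phase equals the Hilbert analytic phase."""
        fs = 600.0
        t = np.arange(int(3 * fs)) / fs
        x = np.cos(2 * np.pi * 10 * t + 0.7)
        tfr = lp.morlet_tfr(x[None, :], fs)
        i10 = int(np.argmin(np.abs(tfr.grid.frequencies - 10.0)))
        mid = len(t) // 2
        got = np.angle(tfr.coef[0, i10, mid])
        want = np.angle(hilbert(x))[mid]
        assert abs(np.angle(np.exp(1j * (got - want)))) < 0.1

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            lp.morlet_tfr(np.zeros((1, 300)), 600.0)  # 0.5 s < 7 cycles at 2.5 Hz


class TestITPC:
    def test_identical_phases_give_one(self):
        ph = np.exp(1j * 1.3) * np.ones((7, 4, 50))
        res = lp.itpc(_tfr_from_phasors(ph))
        np.testing.assert_allclose(res.values, 1.0)

    def test_balanced_antiphase_gives_zero(self):
        ph = np.concatenate(
            [np.exp(1j * 0.0) * np.ones((4, 2, 30)), np.exp(1j * np.pi) * np.ones((4, 2, 30))]
        )
        res = lp.itpc(_tfr_from_phasors(ph))
        np.testing.assert_allclose(res.values, 0.0, atol=1e-12)

    def test_uniform_phase_expectation(self, rng):
        """E[ITPC] for uniform phases is ~ sqrt(pi)/(2 sqrt(N))."""
        vals = [
            np.abs(np.exp(1j * rng.uniform(0, 2 * np.pi, 20)).mean())
            for _ in range(1000)
        ]
        assert abs(np.mean(vals) - np.sqrt(np.pi) / (2 * np.sqrt(20))) < 0.02

    def test_invariance_to_trial_order_and_global_rotation(self, rng):
        ph = np.exp(1j * rng.uniform(0, 2 * np.pi, (10, 3, 20)))
        base = lp.itpc(_tfr_from_phasors(ph)).values
        perm = lp.itpc(_tfr_from_phasors(ph[rng.permutation(10)])).values
        rot = lp.itpc(_tfr_from_phasors(ph * np.exp(1j * 1.1))).values
        np.testing.assert_allclose(perm, base, atol=1e-12)
        np.testing.assert_allclose(rot, base, atol=1e-12)

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            lp.itpc(_tfr_from_phasors(np.ones((1, 2, 5), dtype=complex)))


class TestAcrossITPC:
    def test_identical_conditions_match_within(self, rng):
        """When both conditions are statistically identical, the across-ITPC
        profile matches the within profile."""
        common = np.exp(1j * rng.uniform(0, 2 * np.pi, (1, 3, 200)))
        a = _tfr_from_phasors(np.repeat(common, 10, axis=0))
        b = _tfr_from_phasors(np.repeat(common, 10, axis=0))
        within = lp.itpc(a).profile
        across = lp.across_stimulus_itpc(a, b, n_shuffles=30, seed=0).profile
        np.testing.assert_allclose(across, within, atol=1e-9)

    def test_seeded_reproducibility(self, rng):
        a = _tfr_from_phasors(np.exp(1j * rng.uniform(0, 2 * np.pi, (8, 2, 40))))
        b = _tfr_from_phasors(np.exp(1j * rng.uniform(0, 2 * np.pi, (8, 2, 40))))
        r1 = lp.across_stimulus_itpc(a, b, n_shuffles=20, seed=5).profile
        r2 = lp.across_stimulus_itpc(a, b, n_shuffles=20, seed=5).profile
        np.testing.assert_array_equal(r1, r2)

    def test_mismatched_trial_counts_rejected(self, rng):
        a = _tfr_from_phasors(np.exp(1j * rng.uniform(0, 2 * np.pi, (20, 2, 10))))
        b = _tfr_from_phasors(np.exp(1j * rng.uniform(0, 2 * np.pi, (4, 2, 10))))
        with pytest.raises(ValueError):
            lp.across_stimulus_itpc(a, b)


class TestPDI:
    def test_grid_mismatch_rejected(self, rng):
        a = _tfr_from_phasors(np.ones((4, 2, 10), dtype=complex))
        b = _tfr_from_phasors(np.ones((4, 3, 10), dtype=complex),
                              freqs=np.arange(3.0, 4.5, 0.5))
        with pytest.raises(ValueError):
            lp.dual_stream_pdi(a, b)

    def test_identical_trials_give_zero_dual_pdi(self):
        """Degenerate input: every trial identical in both conditions."""
        ph = np.exp(1j * 0.4) * np.ones((6, 3, 40))
        a, b = _tfr_from_phasors(ph), _tfr_from_phasors(ph.copy())
        res = lp.dual_stream_pdi(a, b, n_shuffles=10, seed=0)
        np.testing.assert_allclose(res.pdi, 0.0, atol=1e-12)

    def test_pdi_bounded(self, rng):
        a = _tfr_from_phasors(np.exp(1j * rng.uniform(0, 2 * np.pi, (10, 4, 60))))
        b = _tfr_from_phasors(np.exp(1j * rng.uniform(0, 2 * np.pi, (10, 4, 60))))
        res = lp.dual_stream_pdi(a, b, n_shuffles=20, seed=1)
        assert np.all(res.pdi >= -1.0) and np.all(res.pdi <= 1.0)

    def test_single_stream_requires_all_conditions(self, rng):
        a = _tfr_from_phasors(np.ones((4, 2, 10), dtype=complex))
        with pytest.raises(ValueError):
            lp.single_stream_pdi({"A1V1": a})

    def test_single_stream_groupings_near_zero_under_null(self, rng):
        """With all four conditions statistically identical, both coherency
        groupings have PDI profiles near zero."""
        def tfr():
            return _tfr_from_phasors(
                np.exp(1j * rng.uniform(0, 2 * np.pi, (12, 3, 150)))
            )

        out = lp.single_stream_pdi(
            {c: tfr() for c in ("A1V1", "A1V2", "A2V1", "A2V2")},
            n_shuffles=40,
            seed=0,
        )
        assert set(out) == {"coherent", "independent"}
        for res in out.values():
            assert res.kind == "single-stream"
            assert np.all(np.abs(res.pdi) < 0.1)

    def test_antisymmetric_under_swapping_within_across(self, rng):
        """Swapping the roles of within and across flips the PDI sign."""
        w = rng.random((6, 10))
        a = rng.random((6, 10))
        r1 = lp.pdi_significance(w, a)
        r2 = lp.pdi_significance(a, w)
        np.testing.assert_allclose(r1.pdi, -r2.pdi)


class TestPDISignificance:
    def test_corrected_alpha_for_43_frequencies(self, rng):
        w = rng.random((5, 43)) + 1.0
        res = lp.pdi_significance(w, rng.random((5, 43)), n_freq=43)
        assert f"{res.alpha_corrected:.4f}" == "0.0012"

    def test_isolated_significant_bin_masked_out(self):
        raw = np.array([False, True, False, True, True, False])
        out = lp._adjacency_filter(raw, 2)
        np.testing.assert_array_equal(
            out, [False, False, False, True, True, False]
        )

    def test_strong_run_detected_and_magnitude_summed(self, rng):
        nf = 20
        w = rng.normal(0.3, 0.01, (8, nf))
        a = w + rng.normal(0, 1e-6, w.shape)
        w[:, 5:9] += 0.2  # a 4-bin run of genuinely higher within-ITPC
        res = lp.pdi_significance(w, a)
        assert res.significant_mask[5:9].all()
        assert not res.significant_mask[:5].any()
        assert res.magnitude == pytest.approx(res.pdi[5:9].sum())

    def test_null_rarely_flags(self, rng):
        """Bonferroni + adjacency: pure-null inputs almost never flag."""
        hits = 0
        for _ in range(200):
            w = rng.normal(0, 1, (6, 30))
            a = rng.normal(0, 1, (6, 30))
            hits += lp.pdi_significance(w, a).significant_mask.any()
        assert hits / 200 <= 0.05

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            lp.pdi_significance(rng.random((2, 5)), rng.random((2, 5)))
        with pytest.raises(ValueError):
            lp.pdi_significance(rng.random((5, 4)), rng.random((5, 5)))


class TestPowerDissimilarity:
    def test_identical_trials_give_zero(self):
        fs = 600.0
        t = np.arange(int(3 * fs)) / fs
        x = np.cos(2 * np.pi * 11 * t) * (1 + 0.5 * np.sin(2 * np.pi * 0.7 * t))
        tr = np.tile(x, (6, 1))
        a = lp.morlet_tfr(tr, fs)
        b = lp.morlet_tfr(tr.copy(), fs)
        res = lp.power_dissimilarity(a, b, n_shuffles=10, seed=0)
        np.testing.assert_allclose(res.pdi, 0.0, atol=1e-9)

    def test_condition_specific_power_modulation_detected(self, rng):
        """A band-limited amplitude modulation that differs between the
        conditions yields positive power dissimilarity in that band."""
        fs = 600.0
        t = np.arange(int(3 * fs)) / fs
        def make(mod_phase, n=12):
            out = []
            for _ in range(n):
                am = 1 + 0.8 * np.sin(2 * np.pi * 1.0 * t + mod_phase)
                x = am * np.cos(2 * np.pi * 11 * t + rng.uniform(0, 2 * np.pi))
                out.append(x + 0.3 * rng.standard_normal(len(t)))
            return lp.morlet_tfr(np.array(out), fs)
        a = make(0.0)
        b = make(np.pi)
        res = lp.power_dissimilarity(a, b, n_shuffles=30, seed=0)
        i11 = np.argmin(np.abs(res.frequencies - 11.0))
        i40 = np.argmin(np.abs(res.frequencies - 40.0))
        assert res.pdi[i11] > 0.2
        assert abs(res.pdi[i40]) < 0.1
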