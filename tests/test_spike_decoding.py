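"""Spike binning, the LOOCV Euclidean classifier, permutation nulls, VPI
and the two-way ANOVA unit classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hyp_st

from avbind import spike_decoding as sd


# ---------------------------------------------------------------------------
# binning


class TestBinSpikes:
    def test_default_window_gives_150_bins(self):
        m = sd.bin_spikes([[0.5, 1.0]])
        assert m.n_bins == 150

    def test_empty_trial_all_zero(self):
        m = sd.bin_spikes([[]])
        assert m.counts.sum() == 0

    def test_edge_spikes_go_to_later_bin_and_window_end_excluded(self):
        m = sd.bin_spikes([[0.02, 3.0 - 1e-12, 3.0]], bin_width=0.02)
        assert m.counts[0, 1] == 1  # exactly at a bin edge -> later bin
        assert m.counts[0, 0] == 0
        assert m.counts[0, -1] == 1  # just inside the window
        assert m.counts.sum() == 2  # the spike at 3.0 s is excluded

    def test_bin_width_must_divide_window(self):
        with pytest.raises(ValueError):
            sd.bin_spikes([[0.1]], window=(0.0, 1.0), bin_width=0.3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        hyp_st.lists(
            hyp_st.floats(min_value=-0.5, max_value=3.5, allow_nan=False),
            max_size=60,
        )
    )
    def test_count_conservation(self, times):
        """Column sums equal the number of spikes inside the window."""
        m = sd.bin_spikes([times], window=(0.0, 3.0), bin_width=0.02)
        expected = sum(1 for t in times if 0.0 <= t < 3.0)
        assert m.counts.sum() == expected


# ---------------------------------------------------------------------------
# LOOCV classifier


def _brute_force_loocv(groups, rng):
    """Independent re-implementation: explicit per-trial template exclusion."""
    labels = list(groups)
    assigned = []
    for c, lab in enumerate(labels):
        x = np.asarray(groups[lab], dtype=float)
        for i in range(x.shape[0]):
            dists = []
            for c2, lab2 in enumerate(labels):
                y = np.asarray(groups[lab2], dtype=float)
                if c2 == c:
                    tpl = np.delete(y, i, axis=0).mean(axis=0)
                else:
                    tpl = y.mean(axis=0)
                dists.append(np.sum((x[i] - tpl) ** 2))
            dists = np.array(dists)
            best = np.flatnonzero(dists <= dists.min() + 1e-9)
            assigned.append(labels[rng.choice(best)])
    return assigned


class TestEuclideanLOOCV:
    def test_disjoint_patterns_fully_correct(self):
        a = np.tile([5, 0, 5, 0], (5, 1))
        b = np.tile([0, 5, 0, 5], (5, 1))
        res = sd.euclidean_loocv({"a": a, "b": b})
        assert res.percent_correct == 100.0

    def test_identical_trials_chance_under_tie_break(self):
        x = np.ones((6, 8))
        scores = [
            sd.euclidean_loocv({"a": x, "b": x.copy()}, seed=s).percent_correct
            for s in range(200)
        ]
        assert abs(np.mean(scores) - 50.0) < 5.0

    def test_matches_brute_force_oracle(self, rng):
        """Vectorized assignments equal explicit enumeration on small cases."""
        for trial in range(100):
            sizes = rng.integers(2, 7, size=rng.integers(2, 4))
            n_bins = int(rng.integers(1, 11))
            groups = {
                f"c{i}": rng.integers(0, 4, size=(s, n_bins))
                for i, s in enumerate(sizes)
            }
            res = sd.euclidean_loocv(groups, rng=np.random.default_rng(trial))
            oracle = _brute_force_loocv(groups, np.random.default_rng(trial))
            # tie-broken assignments can differ; scores of tie-free problems
            # must match exactly, so compare distances via repeated seeds
            ours = res.labels
            # verify each assignment is among the oracle's minimal-distance set
            labels = list(groups)
            idx = 0
            for c, lab in enumerate(labels):
                x = np.asarray(groups[lab], dtype=float)
                for i in range(x.shape[0]):
                    dists = []
                    for c2, lab2 in enumerate(labels):
                        y = np.asarray(groups[lab2], dtype=float)
                        tpl = (
                            np.delete(y, i, axis=0).mean(axis=0)
                            if c2 == c
                            else y.mean(axis=0)
                        )
                        dists.append(np.sum((x[i] - tpl) ** 2))
                    dists = np.array(dists)
                    best = {
                        labels[j]
                        for j in np.flatnonzero(dists <= dists.min() + 1e-9)
                    }
                    assert ours[idx] in best
                    idx += 1

    def test_requires_two_trials_per_class(self):
        with pytest.raises(ValueError):
            sd.euclidean_loocv({"a": np.ones((1, 4)), "b": np.ones((3, 4))})

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError):
            sd.euclidean_loocv({"a": np.ones((3, 4)), "b": np.ones((3, 5))})


class TestPermutationNull:
    def test_separable_unit_is_significant(self, rng):
        a = rng.poisson(0.1, size=(10, 50)) + np.tile([3, 0] * 25, (10, 1))
        b = rng.poisson(0.1, size=(10, 50)) + np.tile([0, 3] * 25, (10, 1))
        res = sd.permutation_null({"a": a, "b": b}, seed=0)
        assert res.significant and res.p < 0.05

    def test_seed_reproducibility(self, rng):
        g = {"a": rng.poisson(1, (8, 20)), "b": rng.poisson(1, (8, 20))}
        r1 = sd.permutation_null(g, seed=42)
        r2 = sd.permutation_null(g, seed=42)
        assert r1.p == r2.p
        np.testing.assert_array_equal(r1.null_scores, r2.null_scores)

    def test_bootstrap_scheme_runs(self, rng):
        g = {"a": rng.poisson(1, (8, 20)), "b": rng.poisson(1, (8, 20))}
        res = sd.permutation_null(g, n_iter=200, seed=0, scheme="bootstrap")
        assert 0.0 <= res.p <= 1.0

    def test_invalid_scheme_and_n_iter(self, rng):
        g = {"a": rng.poisson(1, (4, 5)), "b": rng.poisson(1, (4, 5))}
        with pytest.raises(ValueError):
            sd.permutation_null(g, scheme="nope")
        with pytest.raises(ValueError):
            sd.permutation_null(g, n_iter=10)


# ---------------------------------------------------------------------------
# VPI


class TestVPI:
    def test_worked_example(self):
        """19/23 and 6/23 trials labeled A1 give 82% - 26% = VPI 56."""
        dual = sd.DualStreamResult({"V1": 19, "V2": 6}, {"V1": 23, "V2": 23})
        res = sd.compute_vpi(dual)
        assert (res.pct_a1_given_v1, res.pct_a1_given_v2) == (82, 26)
        assert res.vpi == 56

    def test_equal_proportions_zero(self):
        dual = sd.DualStreamResult({"V1": 10, "V2": 10}, {"V1": 20, "V2": 20})
        assert sd.compute_vpi(dual).vpi == 0

    def test_full_bias_reaches_bound(self):
        dual = sd.DualStreamResult({"V1": 23, "V2": 0}, {"V1": 23, "V2": 23})
        assert sd.compute_vpi(dual).vpi == 100

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        n1=hyp_st.integers(0, 23),
        n2=hyp_st.integers(0, 23),
    )
    def test_bounds_and_sign_flip(self, n1, n2):
        dual = sd.DualStreamResult({"V1": n1, "V2": n2}, {"V1": 23, "V2": 23})
        flipped = sd.DualStreamResult({"V1": n2, "V2": n1}, {"V1": 23, "V2": 23})
        v = sd.compute_vpi(dual).vpi
        assert -100 <= v <= 100
        assert sd.compute_vpi(flipped).vpi == -v

    def test_raw_convention(self):
        dual = sd.DualStreamResult({"V1": 19, "V2": 6}, {"V1": 23, "V2": 23})
        res = sd.compute_vpi(dual, convention="raw")
        assert res.vpi == pytest.approx(100 * (19 - 6) / 23)


# ---------------------------------------------------------------------------
# unit-level operations on simulated recordings


class _FakeUnit:
    def __init__(self, trials):
        self.trials = trials


def _poisson_unit(rng, conds, rate=5.0, n_trials=10):
    return _FakeUnit(
        {
            c: [np.sort(rng.uniform(0, 3, rng.poisson(rate * 3))) for _ in range(n_trials)]
            for c in conds
        }
    )


class TestUnitOperations:
    def test_classify_requires_all_conditions(self, rng):
        unit = _poisson_unit(rng, ["A1V1", "A1V2", "A2V1"])
        with pytest.raises(ValueError):
            sd.classify_unit_discrimination(unit)

    def test_decode_dual_stream_missing_template_condition(self, rng):
        unit = _poisson_unit(rng, ["A1V1", "A12V1", "A12V2"])
        with pytest.raises(ValueError):
            sd.decode_dual_stream(unit)
        with pytest.raises(ValueError):
            sd.decode_dual_stream(unit, template_source="nope")

    def test_decode_dual_stream_counts(self):
        """Trials near a template are labeled with that template's stream."""
        t = np.linspace(0, 3, 40, endpoint=False)
        a1_times = [list(t[:20])] * 4  # early spikes
        a2_times = [list(t[20:])] * 4  # late spikes
        unit = _FakeUnit(
            {
                "A1V1": a1_times,
                "A2V2": a2_times,
                "A12V1": a1_times + a2_times[:1],
                "A12V2": a2_times,
                "A12": a1_times[:2] + a2_times[:2],
            }
        )
        res = sd.decode_dual_stream(unit)
        assert res.counts_a1["V1"] == 4 and res.totals["V1"] == 5
        assert res.counts_a1["V2"] == 0 and res.totals["V2"] == 4
        assert res.totals["none"] == 4 and res.counts_a1["none"] == 2

    def test_vpi_permutation_reproducible(self, rng):
        unit = _poisson_unit(rng, ["A1V1", "A2V2", "A12V1", "A12V2"])
        r1 = sd.vpi_permutation(unit, n_iter=200, seed=7)
        r2 = sd.vpi_permutation(unit, n_iter=200, seed=7)
        assert r1.permutation_p == r2.permutation_p

    def test_coherence_contrast_outputs(self, rng):
        unit = _poisson_unit(rng, sd.SINGLE_STREAM)
        out = sd.coherence_decoding_contrast(unit)
        assert set(out) == {"coherent_score", "independent_score", "rates"}
        assert set(out["rates"]) == set(sd.SINGLE_STREAM)
        assert out["rates"]["A1V1"]["mean_rate"] == pytest.approx(5.0, rel=0.5)


# ---------------------------------------------------------------------------
# two-way ANOVA classification


def _anova_oracle(cells):
    """Hand-computed balanced two-way ANOVA sums of squares."""
    import itertools

    n = len(next(iter(cells.values())))
    y = np.array([cells[k] for k in itertools.product([False, True], repeat=2)])
    grand = y.mean()
    a_means = y.reshape(2, 2, n).mean(axis=(1, 2))
    v_means = y.reshape(2, 2, n).mean(axis=(0, 2))
    cell_means = y.reshape(2, 2, n).mean(axis=2)
    ss_a = 2 * n * ((a_means - grand) ** 2).sum()
    ss_v = 2 * n * ((v_means - grand) ** 2).sum()
    ss_int = n * (
        (cell_means - a_means[:, None] - v_means[None, :] + grand) ** 2
    ).sum()
    ss_err = ((y.reshape(2, 2, n) - cell_means[:, :, None]) ** 2).sum()
    return ss_a, ss_v, ss_int, ss_err


class TestClassifySimpleUnit:
    def test_matches_hand_oracle_and_statsmodels(self, rng):
        """F statistics agree with explicit sums of squares (1e-10) and with
        an OLS two-way ANOVA fit."""
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        cells = {
            (a, v): rng.poisson(5 + 3 * a + 2 * v + 4 * (a and v), size=8).astype(
                float
            )
            for a in (False, True)
            for v in (False, True)
        }
        res = sd.classify_simple_unit(cells)
        ss_a, ss_v, ss_int, ss_err = _anova_oracle(cells)
        assert res["auditory"]["ss"] == pytest.approx(ss_a, abs=1e-10)
        assert res["visual"]["ss"] == pytest.approx(ss_v, abs=1e-10)
        assert res["interaction"]["ss"] == pytest.approx(ss_int, abs=1e-10)
        assert res["error"]["ss"] == pytest.approx(ss_err, abs=1e-10)

        rows = [
            {"y": y, "a": a, "v": v}
            for (a, v), ys in cells.items()
            for y in ys
        ]
        fit = ols("y ~ C(a) * C(v)", data=pd.DataFrame(rows)).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert res["auditory"]["F"] == pytest.approx(table.loc["C(a)", "F"])
        assert res["visual"]["F"] == pytest.approx(table.loc["C(v)", "F"])
        assert res["interaction"]["F"] == pytest.approx(
            table.loc["C(a):C(v)", "F"]
        )

    def test_auditory_main_effect_only(self, rng):
        cells = {
            (a, v): 20.0 * a + rng.normal(0, 0.5, 10)
            for a in (False, True)
            for v in (False, True)
        }
        assert sd.classify_simple_unit(cells)["label"] == "auditory"

    def test_interaction_only_is_audiovisual(self, rng):
        cells = {
            (a, v): 10.0 * (a == v) + rng.normal(0, 0.5, 10)
            for a in (False, True)
            for v in (False, True)
        }
        assert sd.classify_simple_unit(cells)["label"] == "auditory-visual"

    def test_no_effect_is_none(self, rng):
        cells = {
            (a, v): rng.normal(5, 1, 10) for a in (False, True) for v in (False, True)
        }
        assert sd.classify_simple_unit(cells)["label"] == "none"

    def test_unbalanced_or_missing_cells_rejected(self, rng):
        cells = {
            (a, v): rng.normal(5, 1, 10) for a in (False, True) for v in (False, True)
        }
        cells[(True, True)] = cells[(True, True)][:5]
        with pytest.raises(ValueError):
            sd.classify_simple_unit(cells)
        del cells[(True, True)]
        with pytest.raises(ValueError):
            sd.classify_simple_unit(cells)
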