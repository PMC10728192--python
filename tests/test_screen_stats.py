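import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormforge.screen_stats import (
    ScreenRecord,
    Trace,
    bleach_correct,
    call_hits,
    chemotaxis_index_distal,
    chemotaxis_index_quadrant,
    delta_f_over_f0,
    interval_mean_response,
    lawn_indices,
    relative_change,
    response_correlation,
    single_worm_score,
)


class TestIndices:
    @pytest.mark.parametrize(
        "odor,control,ci",
        [(80, 20, 0.6), (50, 50, 0.0), (0, 100, -1.0), (100, 0, 1.0)],
    )
    def test_quadrant_ci(self, odor, control, ci):
        assert chemotaxis_index_quadrant(odor, control) == pytest.approx(ci)

    def test_quadrant_ci_empty_is_nan(self):
        with pytest.warns(UserWarning):
            assert math.isnan(chemotaxis_index_quadrant(0, 0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 300), st.integers(0, 300))
    def test_quadrant_ci_range_and_antisymmetry(self, a, b):
        if a + b == 0:
            return
        ci = chemotaxis_index_quadrant(a, b)
        assert -1.0 <= ci <= 1.0
        assert chemotaxis_index_quadrant(b, a) == pytest.approx(-ci)

    @pytest.mark.parametrize(
        "odor,control,total,ci",
        [(30, 10, 100, 0.2), (0, 0, 100, 0.0), (60, 0, 60, 1.0)],
    )
    def test_distal_ci_uses_plate_total(self, odor, control, total, ci):
        assert chemotaxis_index_distal(odor, control, total) == pytest.approx(ci)

    @pytest.mark.parametrize(
        "sectors,score", [("ABC", 6), ("F", -3), ("ABCDEF", 0), ("", 0)]
    )
    def test_single_worm_score(self, sectors, score):
        assert single_worm_score(set(sectors)) == score

    def test_single_worm_unknown_sector(self):
        with pytest.raises(ValueError):
            single_worm_score({"G"})

    @pytest.mark.parametrize(
        "off,total,av,occ",
        [(12, 30, 0.4, 0.6), (30, 30, 1.0, 0.0), (0, 30, 0.0, 1.0)],
    )
    def test_lawn_indices_complementary(self, off, total, av, occ):
        a, o = lawn_indices(off, total)
        assert (a, o) == (pytest.approx(av), pytest.approx(occ))
        assert a + o == pytest.approx(1.0)

    def test_lawn_overflow_rejected(self):
        with pytest.raises(ValueError):
            lawn_indices(31, 30)

    @pytest.mark.parametrize(
        "m,w,expected", [(0.2, 0.5, -0.6), (0.5, 0.5, 0.0), (4, 6, -1 / 3)]
    )
    def test_relative_change(self, m, w, expected):
        assert relative_change(m, w) == pytest.approx(expected)

    def test_relative_change_zero_wt(self):
        with pytest.warns(UserWarning):
            assert math.isnan(relative_change(0.2, 0.0))


class TestHitCalling:
    def test_repellent_threshold_is_strict(self):
        cis = [-0.9, -0.51, -0.5, -0.49, -0.3, 0.2]
        records = [ScreenRecord(f"s{i}", "NON", ci=c) for i, c in enumerate(cis)]
        hits = call_hits(records, "repellent_threshold", threshold=-0.5)
        assert [h.ci for h in hits] == [-0.49, -0.3, 0.2]  # -0.5 itself excluded

    def test_tail_rules(self):
        records = [
            ScreenRecord(f"s{i}", "Vc", relative_change=v)
            for i, v in enumerate(np.linspace(-1, 1, 21))
        ]
        low = call_hits(records, "low_tail", quantile=0.05)
        high = call_hits(records, "high_tail", quantile=0.05)
        assert all(h.relative_change < -0.8 for h in low)
        assert all(h.relative_change > 0.8 for h in high)

    def test_empty_input(self):
        assert call_hits([], "repellent_threshold") == []


class TestTraces:
    def test_interval_mean_step_response(self):
        t = np.arange(0, 100, 0.5)
        y = np.where(t < 50, 0.1, 0.3)
        trace = Trace("speed", t, y)
        base, stim, delta = interval_mean_response(trace, (10, 40), (55, 90))
        assert (base, stim, delta) == (
            pytest.approx(0.1),
            pytest.approx(0.3),
            pytest.approx(0.2),
        )

    def test_interval_mean_outside_trace_is_nan(self):
        trace = Trace("speed", np.arange(10.0), np.ones(10))
        _, stim, _ = interval_mean_response(trace, (0, 5), (100, 110))
        assert math.isnan(stim)

    def test_bleach_correct_pure_exponential(self):
        t = np.arange(0, 120, 0.25)
        y = 80.0 * np.exp(-0.03 * t)
        corrected = bleach_correct(Trace("fluorescence", t, y))
        assert corrected.corrected
        np.testing.assert_allclose(corrected.y, 1.0, rtol=1e-6)

    def test_bleach_correct_constant_input(self):
        t = np.arange(0, 120, 0.25)
        corrected = bleach_correct(Trace("fluorescence", t, np.full(t.size, 7.0)))
        np.testing.assert_allclose(corrected.y, 1.0, rtol=1e-9)

    def test_bleach_correct_excludes_response_window(self):
        # exponential + boxcar response between the fit windows: the fit
        # must come out flat (within 1%) outside the response
        t = np.arange(0, 120, 0.25)
        box = ((t >= 60) & (t < 80)).astype(float)
        y = 100 * np.exp(-0.02 * t) * (1 + 0.8 * box)
        corrected = bleach_correct(Trace("fluorescence", t, y))
        outside = corrected.y[(t < 60) | (t >= 80)]
        np.testing.assert_allclose(outside, 1.0, rtol=0.01)

    def test_bleach_correct_nonpositive_flagged(self):
        t = np.arange(0, 120, 0.25)
        y = np.zeros(t.size)
        out = bleach_correct(Trace("fluorescence", t, y))
        assert not out.corrected
        assert "bleach_fit_failed" in out.warning

    @pytest.mark.parametrize("factor,expected", [(2.0, 1.0), (0.5, -0.5)])
    def test_delta_f_over_f0(self, factor, expected):
        t = np.arange(0, 60, 0.25)
        y = np.where(t < 30, 1.0, factor)
        out = delta_f_over_f0(Trace("fluorescence", t, y), odor_onset_t=30)
        assert out.f0 == pytest.approx(1.0)
        np.testing.assert_allclose(out.y[t < 30], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.y[t >= 30], expected, atol=1e-12)

    def test_trace_contract(self):
        with pytest.raises(ValueError):
            Trace("speed", np.array([0.0, 0.0, 1.0]), np.zeros(3))
        with pytest.raises(ValueError):
            Trace("speed", np.arange(3.0), np.array([0.0, np.inf, 1.0]))


class TestResponseCorrelation:
    def test_identical_and_negated_profiles(self):
        base = np.array([0.1, -0.4, 0.9, 0.3, -0.2])
        profiles = pd.DataFrame(
            {"c%d" % i: [base[i], base[i], -base[i]] for i in range(5)},
            index=["a", "b", "c"],
        )
        corr = response_correlation(profiles)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert (np.diag(corr.values) == 1.0).all()

    def test_pairwise_complete_with_missing(self):
        profiles = pd.DataFrame(
            {
                "c1": [1.0, 1.0, np.nan],
                "c2": [2.0, 2.0, np.nan],
                "c3": [3.0, 3.0, 1.0],
            },
            index=["a", "b", "c"],
        )
        corr = response_correlation(profiles)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert math.isnan(corr.loc["a", "c"])  # <2 shared complete conditions

    def test_planted_pair_is_top_correlation(self, rng):
        """A ligand/receptor pair sharing an effect vector plus independent
        noise dominates the off-diagonal in nearly all simulations."""
        wins = 0
        n_sim = 50
        for _ in range(n_sim):
            effect = rng.normal(0, 1, 8)
            rows = {f"strain{i}": rng.normal(0, 1, 8) for i in range(8)}
            rows["lig"] = effect + rng.normal(0, 0.1, 8)
            rows["rec"] = effect + rng.normal(0, 0.1, 8)
            corr = response_correlation(pd.DataFrame(rows).T)
            vals = corr.values.copy()
            np.fill_diagonal(vals, -np.inf)
            i, j = np.unravel_index(np.argmax(vals), vals.shape)
            pair = {corr.index[i], corr.index[j]}
            wins += pair == {"lig", "rec"}
        assert wins / n_sim >= 0.9

    def test_spearman_available(self):
        profiles = pd.DataFrame(
            {"c1": [1.0, 10.0], "c2": [2.0, 100.0], "c3": [3.0, 1000.0]},
            index=["a", "b"],
        )
        corr = response_correlation(profiles, method="spearman")
        assert corr.loc["a", "b"] == pytest.approx(1.0)
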