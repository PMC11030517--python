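"""Windowed deviation score, cross-correlation, sync fraction, phase
offsets, and scaling fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frustranet.metrics import (
    PairList,
    TraceSet,
    WindowConfig,
    _window_layout,
    cross_correlation,
    deviation_score,
    fit_scaling_exponent,
    normalize_window,
    spike_phase_offset,
    sync_fraction,
)
from frustranet.qif import SpikeTrain


class TestNormalizeWindow:
    def test_affine_map_to_unit_interval(self):
        out, degenerate = normalize_window([2.0, 4.0, 6.0])
        assert np.allclose(out, [0.0, 0.5, 1.0])
        assert not degenerate

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=50,
        ).filter(lambda xs: max(xs) > min(xs))
    )
    def test_output_spans_zero_to_one(self, xs):
        out, degenerate = normalize_window(np.array(xs))
        assert not degenerate
        assert out.min() == 0.0
        assert out.max() == pytest.approx(1.0)

    def test_constant_segment_flagged_degenerate(self):
        out, degenerate = normalize_window([5.0, 5.0, 5.0])
        assert degenerate
        assert np.all(out == 0.0)


class TestDeviationScore:
    def test_identical_traces_score_zero(self, identical_traces):
        scores = deviation_score(identical_traces, WindowConfig(width=20.0))
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_antiphase_square_waves_score_half(self, antiphase_square_waves):
        scores = deviation_score(antiphase_square_waves, WindowConfig(width=20.0))
        assert np.allclose(scores.to_numpy(), 0.5, atol=1e-12)

    def test_invariant_under_per_node_affine_rescaling(self, antiphase_square_waves):
        ts = antiphase_square_waves
        rescaled = TraceSet(
            times=ts.times,
            values=pd.DataFrame(
                {"a": 7.0 * ts.values["a"] + 3.0, "b": 0.2 * ts.values["b"] - 5.0}
            ),
            period=ts.period,
        )
        w = WindowConfig(width=20.0)
        assert np.allclose(
            deviation_score(ts, w).to_numpy(), deviation_score(rescaled, w).to_numpy()
        )

    def test_scores_bounded_and_permutation_equivariant(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 120.0, 0.5)
        vals = pd.DataFrame(
            {f"n{i}": rng.random(t.size) for i in range(5)}
        )
        ts = TraceSet(times=t, values=vals)
        w = WindowConfig(width=30.0)
        scores = deviation_score(ts, w)
        assert ((scores >= 0) & (scores <= 1)).all()
        perm = ["n3", "n0", "n4", "n1", "n2"]
        scores_perm = deviation_score(
            TraceSet(times=t, values=vals[perm]), w
        )
        assert np.allclose(scores[perm].to_numpy(), scores_perm.to_numpy())

    def test_window_count_identity(self):
        # number of windows = floor((L - n_w)/hop) + 1
        n_w, hop, starts = _window_layout(1000, width=100.0, stride=25.0, dt=1.0)
        assert n_w == 101
        assert len(list(starts)) == (1000 - n_w) // hop + 1

    def test_requires_two_nodes(self):
        t = np.arange(0, 100.0, 1.0)
        ts = TraceSet(times=t, values=pd.DataFrame({"a": np.sin(t)}))
        with pytest.raises(ValueError, match="2 nodes"):
            deviation_score(ts, WindowConfig(width=20.0))

    def test_degenerate_windows_excluded_from_node_average(self):
        # node b is constant in the first window only
        t = np.arange(0, 40.0, 1.0)
        b = np.where(t < 20, 1.0, np.sin(t))
        ts = TraceSet(
            times=t, values=pd.DataFrame({"a": np.cos(t), "b": b})
        )
        scores, windows = deviation_score(
            ts, WindowConfig(width=19.0, stride=19.0), return_windows=True
        )
        assert np.isnan(windows.iloc[0]["b"])
        assert np.isfinite(scores["b"])


class TestCrossCorrelation:
    def test_perfect_and_inverted(self):
        x = np.sin(np.linspace(0, 10, 200))
        assert cross_correlation(x, x) == pytest.approx(1.0)
        assert cross_correlation(x, -x) == pytest.approx(-1.0)

    def test_quarter_period_shift_uncorrelated(self):
        t = np.linspace(0, 4 * 2 * np.pi, 4000, endpoint=False)
        assert cross_correlation(np.sin(t), np.sin(t + np.pi / 2)) == pytest.approx(
            0.0, abs=1e-3
        )

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cross_correlation(np.ones(10), np.arange(10.0))


class TestSyncFraction:
    def test_counts_strictly_above_threshold(self):
        assert sync_fraction([1.0, 1.0]) == 1.0
        assert sync_fraction([0.9, 0.7]) == 0.5
        assert sync_fraction([0.8]) == 0.0  # exactly at threshold: not counted

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sync_fraction([])


class TestSpikePhaseOffset:
    def _train(self, start, period, n):
        return SpikeTrain(start + period * np.arange(n))

    def test_identical_trains_offset_zero(self):
        a = self._train(0.0, 10.0, 30)
        assert spike_phase_offset(a, a, 10.0) == 0.0

    def test_half_period_offset(self):
        a = self._train(0.0, 10.0, 30)
        b = self._train(5.0, 10.0, 30)
        assert spike_phase_offset(a, b, 10.0) == pytest.approx(5.0)

    def test_folding_beyond_half_period(self):
        a = self._train(0.0, 10.0, 30)
        b = self._train(9.0, 10.0, 30)
        assert spike_phase_offset(a, b, 10.0) == pytest.approx(1.0)

    def test_too_few_spikes_rejected(self):
        a = self._train(0.0, 10.0, 4)
        with pytest.raises(ValueError, match="spikes"):
            spike_phase_offset(a, a, 10.0)


class TestScalingFit:
    def test_exact_power_law_recovered(self):
        Ts = np.array([40.0, 80.0, 120.0, 160.0, 200.0])
        fit = fit_scaling_exponent(Ts, 3.0 * Ts**-0.5)
        assert fit.exponent == pytest.approx(-0.5, abs=1e-12)
        assert fit.stderr == pytest.approx(0.0, abs=1e-12)

    def test_flat_scores_give_zero_exponent(self):
        fit = fit_scaling_exponent([10, 20, 40, 80], [0.3, 0.3, 0.3, 0.3])
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_non_positive_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_scaling_exponent([10, 20, 40, 80], [0.3, 0.0, 0.1, 0.2])

    def test_short_grids_rejected(self):
        with pytest.raises(ValueError):
            fit_scaling_exponent([10, 20, 40], [1, 2, 3])


class TestPairList:
    def test_rejects_self_and_duplicate_pairs(self):
        with pytest.raises(ValueError, match="self"):
            PairList(
                pd.DataFrame(
                    [("a", "a", "bridged")],
                    columns=["node_i", "node_j", "provenance"],
                )
            )
        with pytest.raises(ValueError, match="duplicate"):
            PairList(
                pd.DataFrame(
                    [("a", "b", "bridged"), ("b", "a", "bridged")],
                    columns=["node_i", "node_j", "provenance"],
                )
            )
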