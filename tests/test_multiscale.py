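"""Window scans, cohort scale curves, comparison curves, topographies."""

import numpy as np
import pytest

from conftest import make_recording
from ordirr.irrtest import test_series as run_series_test
from ordirr.multiscale import (
    ScaleCurve,
    channel_topography,
    comparison_curve,
    dataset_scale_curve,
    default_n_grid,
    is_irreversible_at_scale,
    make_selector,
    topography_difference,
    window_fraction,
)


class TestWindowFraction:
    def test_ramp_long_windows_all_reject(self):
        # every length-50 sub-window is all-(0,1,2): p = 2*(1/2)^48 << 0.01
        assert window_fraction(np.arange(200.0), 50) == 1.0

    def test_ramp_short_windows_never_reject(self):
        # 7 patterns per sub-window: p = 0.015625 > 0.01
        assert window_fraction(np.arange(200.0), 9) == 0.0

    def test_iid_noise_fraction_small(self, rng):
        fracs = [window_fraction(rng.standard_normal(2000), 100) for _ in range(20)]
        assert all(f < 0.9 for f in fracs)

    def test_matches_per_subwindow_oracle(self, rng):
        """The prefix-sum scan reproduces test_series on every sub-window."""
        for _ in range(25):
            x = rng.standard_normal(90)
            n = int(rng.integers(5, 80))
            stride = int(rng.integers(1, 4))
            fast = window_fraction(x, n, alpha=0.05, sub_stride=stride)
            slow = np.mean(
                [
                    run_series_test(x[a : a + n], alpha=0.05).irreversible
                    for a in range(0, len(x) - n + 1, stride)
                ]
            )
            assert fast == pytest.approx(slow)

    def test_bad_window_lengths(self):
        with pytest.raises(ValueError):
            window_fraction(np.arange(50.0), 2)
        with pytest.raises(ValueError):
            window_fraction(np.arange(50.0), 51)


class TestIsIrreversibleAtScale:
    def test_ramp_decision_by_scale(self):
        ramp = np.arange(200.0)
        assert is_irreversible_at_scale(ramp, 50)
        assert not is_irreversible_at_scale(ramp, 9)

    def test_zero_threshold_always_true(self, rng):
        assert is_irreversible_at_scale(rng.standard_normal(100), 50, threshold=0.0)

    def test_monotone_in_scale_for_ramp(self):
        ramp = np.arange(300.0)
        decisions = [is_irreversible_at_scale(ramp, n) for n in (9, 11, 15, 25, 50, 100, 300)]
        assert decisions == sorted(decisions)  # once true, stays true


class TestDatasetScaleCurve:
    def test_half_irreversible_cohort(self, mixed_cohort):
        curve = dataset_scale_curve(mixed_cohort, [50])
        assert curve.fractions == [0.5]
        assert curve.n_units == 8

    def test_channel_order_invariance(self, rng):
        data = np.vstack([np.arange(150.0), rng.standard_normal(150)])
        a = dataset_scale_curve([make_recording(data)], [40, 60])
        b = dataset_scale_curve([make_recording(data[::-1])], [40, 60])
        assert a.fractions == b.fractions

    def test_all_degenerate_cohort_errors(self):
        rec = make_recording(np.zeros((3, 100)))
        with pytest.raises(ValueError, match="degenerate"):
            dataset_scale_curve([rec], [50])

    def test_short_units_excluded_from_denominator(self, rng):
        long_rec = make_recording(np.arange(400.0))
        short_rec = make_recording(np.arange(100.0))
        curve = dataset_scale_curve([long_rec, short_rec], [50, 200])
        assert curve.denominators == [2, 1]
        assert curve.fractions == [1.0, 1.0]

    def test_selector_filters_groups(self, rng):
        recs = [
            make_recording(np.arange(200.0), group="control"),
            make_recording(rng.standard_normal(200), group="patient"),
        ]
        c = dataset_scale_curve(recs, [50], selector=make_selector(group="control"))
        assert c.fractions == [1.0] and c.n_units == 1
        with pytest.raises(ValueError):
            dataset_scale_curve(recs, [50], selector=make_selector(group="unknown"))


class TestComparisonCurve:
    def _curve(self, fractions, n_units=100, label=""):
        return ScaleCurve(
            window_lengths=list(range(50, 50 + 10 * len(fractions), 10)),
            fractions=list(fractions),
            n_units=n_units,
            label=label,
        )

    def test_self_comparison_is_diagonal_with_p_one(self):
        curve = self._curve([0.0, 0.25, 0.5, 0.75, 1.0])
        comp = comparison_curve(curve, curve, x_step=0.25)
        assert comp.x_grid == [0.0, 0.25, 0.5, 0.75, 1.0]
        assert comp.y_values == comp.x_grid
        assert all(lp == 0.0 for lp in comp.log10_pvalues)

    def test_uniformly_stronger_cohort_above_diagonal(self):
        ref = self._curve([0.1, 0.3, 0.5, 0.7])
        cmp_ = self._curve([0.4, 0.6, 0.8, 0.9])
        comp = comparison_curve(ref, cmp_, x_step=0.1)
        assert all(y > x for x, y in zip(comp.x_grid, comp.y_values))
        assert all(lp <= 0 for lp in comp.log10_pvalues)

    def test_unattained_x_omitted(self):
        ref = self._curve([0.1, 0.2, 0.4])
        comp = comparison_curve(ref, self._curve([0.1, 0.2, 0.3]), x_step=0.25)
        assert max(comp.x_grid) <= 0.4

    def test_minimum_window_length_selection(self):
        ref = self._curve([0.0, 0.6, 0.9])
        cmp_ = self._curve([0.2, 0.3, 0.4])
        comp = comparison_curve(ref, cmp_, x_step=0.5)
        # x=0.5 first attained at the second scale (fraction 0.6)
        assert comp.window_lengths_used[comp.x_grid.index(0.5)] == ref.window_lengths[1]
        assert comp.y_values[comp.x_grid.index(0.5)] == 0.3

    def test_mismatched_grids_rejected(self):
        a = self._curve([0.1, 0.2])
        b = ScaleCurve([10, 20], [0.1, 0.2], 10)
        with pytest.raises(ValueError):
            comparison_curve(a, b)


class TestChannelTopography:
    def test_row_per_channel_and_hot_channel(self, rng):
        data = np.vstack([rng.standard_normal((3, 300)), np.arange(300.0)])
        rec = make_recording(data, labels=["Fp1", "Fp2", "Cz", "O1"])
        table = channel_topography([rec], [30, 60, 120])
        assert table.channel_labels == ["Fp1", "Fp2", "Cz", "O1"]
        assert len(table.mean_fraction) == 4
        assert np.argmax(table.mean_fraction) == 3  # the ramp channel

    def test_identical_noise_gives_flat_difference(self, rng):
        labels = ["Fp1", "Fp2", "Cz"]
        recs = []
        for group in ("control", "patient"):
            for s in range(3):
                recs.append(
                    make_recording(
                        rng.standard_normal((3, 300)), labels=labels, group=group
                    )
                )
        grid = [50, 100]
        pat = channel_topography(recs, grid, selector=make_selector("patient"), group="patient")
        ctl = channel_topography(recs, grid, selector=make_selector("control"), group="control")
        diff = topography_difference(pat, ctl)
        assert np.all(np.abs(diff["difference"]) <= 0.5)
        assert list(diff["channel"]) == labels

    def test_montage_mismatch_lists_channels(self, rng):
        a = make_recording(rng.standard_normal((2, 100)), labels=["Fp1", "Fp2"])
        b = make_recording(rng.standard_normal((2, 100)), labels=["Fp1", "Oz"])
        with pytest.raises(ValueError, match="Oz"):
            channel_topography([a, b], [50])


class TestDefaultGrid:
    def test_grid_bounds_and_monotonicity(self):
        grid = default_n_grid(30000, sampling_rate=250.0)
        assert grid[0] == 50
        assert grid[-1] == 25000  # capped at 100 s of signal
        assert grid == sorted(set(grid))

    def test_short_series_error(self):
        with pytest.raises(ValueError):
            default_n_grid(20, sampling_rate=250.0)
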