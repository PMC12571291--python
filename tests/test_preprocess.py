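"""Missing-run filter, gap filling, anomaly differencing, zone profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import evacflow as ef
from evacflow.preprocess import longest_missing_run
from tests.conftest import make_panel

NAN = np.nan


def series_with_run(run: int, start: int = 3) -> np.ndarray:
    s = np.full(24, 10.0)
    if run:
        s[start : start + run] = NAN
    return s


class TestFilter:
    def test_complete_grid_retained(self):
        panel = make_panel([np.full(24, 5.0)], [np.full(24, 6.0)])
        kept, report = ef.filter_valid_grids(panel)
        assert kept.n_grids == 1 and report.n_valid == 1

    def test_run_of_exactly_three_removed(self):
        """Three consecutive missing hours on the baseline day reject the cell."""
        panel = make_panel([series_with_run(3)], [np.full(24, 6.0)])
        with pytest.warns(UserWarning, match="all grids rejected"):
            kept, report = ef.filter_valid_grids(panel)
        assert kept.n_grids == 0
        assert "pre day" in report.rejection_reasons["g000"]

    def test_ten_grid_fixture_retains_six(self):
        """Run lengths {0,1,2,2,3,3,4,5,2,1}: exactly the runs < 3 survive."""
        runs = [0, 1, 2, 2, 3, 3, 4, 5, 2, 1]
        pre = np.array([series_with_run(r) for r in runs])
        post = np.full((10, 24), 6.0)
        kept, report = ef.filter_valid_grids(make_panel(pre, post))
        assert report.n_valid == 6
        expected = {f"g{i:03d}" for i, r in enumerate(runs) if r < 3}
        assert set(kept.grid_ids) == expected

    def test_both_days_must_pass(self):
        panel = make_panel([np.full(24, 5.0)], [series_with_run(4)])
        with pytest.warns(UserWarning, match="all grids rejected"):
            _, report = ef.filter_valid_grids(panel)
        assert report.n_valid == 0
        assert "post day" in report.rejection_reasons["g000"]

    def test_population_share_uses_baseline_day(self):
        pre = np.array([np.full(24, 30.0), series_with_run(3)])
        pre[1, ~np.isnan(pre[1])] = 10.0
        post = np.full((2, 24), 6.0)
        _, report = ef.filter_valid_grids(make_panel(pre, post))
        # Excluded grid holds 21 observed hours of 10 vs 24 hours of 30.
        expected = 210.0 / (210.0 + 720.0)
        assert report.invalid_population_share == pytest.approx(expected)

    def test_monotone_in_max_run(self):
        rng = np.random.default_rng(3)
        pre = np.full((40, 24), 5.0)
        for i in range(40):
            k = rng.integers(0, 8)
            if k:
                start = rng.integers(0, 24 - k)
                pre[i, start : start + k] = NAN
        panel = make_panel(pre, np.full((40, 24), 5.0))
        kept_sets = []
        for max_run in (1, 2, 3, 4, 5):
            kept, _ = ef.filter_valid_grids(panel, max_run=max_run)
            kept_sets.append(set(kept.grid_ids))
        for smaller, larger in zip(kept_sets, kept_sets[1:]):
            assert smaller <= larger

    def test_empty_panel_errors(self):
        panel = make_panel(np.empty((1, 24)), np.empty((1, 24))).subset(
            np.zeros(1, dtype=bool)
        )
        with pytest.raises(ValueError, match="empty"):
            ef.filter_valid_grids(panel)

    def test_all_invalid_warns(self):
        panel = make_panel([series_with_run(5)], [np.full(24, 6.0)])
        with pytest.warns(UserWarning, match="all grids rejected"):
            kept, _ = ef.filter_valid_grids(panel)
        assert kept.n_grids == 0

    def test_longest_run_oracle(self):
        """Run-length encoding agrees with a brute-force scan."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            mask = rng.random(24) < 0.3
            s = np.where(mask, np.nan, 1.0)
            best = cur = 0
            for m in mask:
                cur = cur + 1 if m else 0
                best = max(best, cur)
            assert longest_missing_run(s) == best


class TestFillGaps:
    def test_linear_midpoint(self):
        s = np.full(24, NAN)
        s[:] = 8.0
        s[4], s[5], s[6] = 10.0, NAN, 20.0
        panel = make_panel([s], [np.full(24, 1.0)])
        filled = ef.fill_gaps(panel)
        assert filled.pre[0, 5] == pytest.approx(15.0)

    def test_two_hour_gap(self):
        s = np.full(24, 8.0)
        s[4], s[5], s[6], s[7] = 10.0, NAN, NAN, 40.0
        filled = ef.fill_gaps(make_panel([s], [np.full(24, 1.0)]))
        assert filled.pre[0, 5] == pytest.approx(20.0)
        assert filled.pre[0, 6] == pytest.approx(30.0)

    def test_boundary_nearest_value(self):
        s = np.full(24, 3.0)
        s[0], s[1] = NAN, 7.0
        s[23] = NAN
        filled = ef.fill_gaps(make_panel([s], [np.full(24, 1.0)]))
        assert filled.pre[0, 0] == pytest.approx(7.0)
        assert filled.pre[0, 23] == pytest.approx(3.0)

    def test_all_missing_day_errors(self):
        panel = make_panel([np.full(24, NAN)], [np.full(24, 1.0)])
        with pytest.raises(ValueError, match="zero observed"):
            ef.fill_gaps(panel)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        mask=st.lists(st.booleans(), min_size=24, max_size=24).filter(
            lambda m: not all(m)
        ),
        values=st.lists(
            st.floats(0.0, 1e6, allow_nan=False), min_size=24, max_size=24
        ),
    )
    def test_idempotent_and_preserves_observations(self, mask, values):
        s = np.array(values)
        s[np.array(mask)] = NAN
        panel = make_panel([s], [np.full(24, 1.0)])
        once = ef.fill_gaps(panel)
        twice = ef.fill_gaps(once)
        assert not np.isnan(once.pre).any()
        np.testing.assert_array_equal(once.pre, twice.pre)
        obs = ~np.array(mask)
        np.testing.assert_array_equal(once.pre[0, obs], s[obs])


class TestAnomaly:
    def test_direct_subtraction(self):
        panel = make_panel([np.full(24, 100.0)], [np.full(24, 120.0)])
        anom = ef.compute_anomaly(panel)
        np.testing.assert_allclose(anom.values, 20.0)

    def test_identical_days_zero(self):
        panel = make_panel([np.full(24, 9.0)], [np.full(24, 9.0)])
        assert not ef.compute_anomaly(panel).values.any()

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        pre = rng.uniform(0, 50, (3, 24))
        post = rng.uniform(0, 50, (3, 24))
        anom = ef.compute_anomaly(make_panel(pre, post))
        expected = np.array(
            [[post[i, t] - pre[i, t] for t in range(24)] for i in range(3)]
        )
        np.testing.assert_array_equal(anom.values, expected)

    def test_rows_sorted_by_grid_id(self):
        panel = make_panel(np.zeros((3, 24)), np.ones((3, 24)))
        panel.grid_ids = np.array(["c", "a", "b"], dtype=object)
        anom = ef.compute_anomaly(panel)
        assert list(anom.grid_index) == ["a", "b", "c"]

    def test_requires_gap_filled(self):
        pre = np.full((1, 24), 5.0)
        pre[0, 3] = NAN
        with pytest.raises(ValueError, match="gap-filled"):
            ef.compute_anomaly(make_panel(pre, np.ones((1, 24))))


class TestZoneProfiles:
    def test_two_point_mean(self):
        anom = ef.AnomalyMatrix(
            values=np.vstack([np.full(24, 2.0), np.full(24, 4.0)]),
            grid_index=np.array(["a", "b"], dtype=object),
        )
        with pytest.warns(UserWarning, match="no grids"):
            profile = ef.zone_profiles(anom, {"a": "VII", "b": "VII"})
        np.testing.assert_allclose(profile.mean_anomaly[0], 3.0)
        assert profile.grid_counts[0] == 2

    def test_singleton_zone_identity(self):
        values = np.arange(48, dtype=float).reshape(2, 24)
        anom = ef.AnomalyMatrix(
            values=values, grid_index=np.array(["a", "b"], dtype=object)
        )
        with pytest.warns(UserWarning):
            profile = ef.zone_profiles(anom, {"a": "VI", "b": "IX"})
        np.testing.assert_array_equal(profile.mean_anomaly[0], values[0])
        np.testing.assert_array_equal(profile.mean_anomaly[1], values[1])

    def test_aggregation_conservation(self, default_run):
        """Zone means times counts re-sum to the total anomaly per hour."""
        anom, panel = default_run["anomaly"], default_run["panel"]
        zones = dict(zip(panel.sorted_by_id().grid_ids.astype(str),
                         panel.sorted_by_id().zone))
        profile = ef.zone_profiles(anom, zones)
        total = (profile.mean_anomaly * profile.grid_counts[:, None]).sum(axis=0)
        np.testing.assert_allclose(total, anom.values.sum(axis=0), rtol=1e-10)

    def test_high_zone_profile_decreasing_over_window(self, noiseless_run):
        """Zone IX (pure source cells) drains monotonically during evacuation."""
        sc, panel, _ = noiseless_run
        anom = ef.compute_anomaly(panel)
        zones = dict(zip(panel.sorted_by_id().grid_ids.astype(str),
                         panel.sorted_by_id().zone))
        profile = ef.zone_profiles(anom, zones)
        ix = profile.mean_anomaly[profile.zones.index("IX")]
        window = ix[sc.evac_start_hour : sc.evac_end_hour + 1]
        assert np.all(np.diff(window) < 0)
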