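"""TLFB ingest/aggregation and the spline + discontinuity design."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gambrct import tlfb


def daily_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "rater", "study_day", "net_loss"])


class TestIngest:
    def test_clamps_negative_losses_and_counts(self):
        df, report = tlfb.ingest_daily(
            daily_frame([("a", "gambler", 0, -250.0), ("a", "gambler", 1, 0.0)])
        )
        assert df["net_loss"].tolist() == [0.0, 0.0]
        assert report.n_clamped == 1
        assert report.clamped_keys == [("a", "gambler", 0)]

    def test_duplicate_day_rejected_with_key(self):
        with pytest.raises(tlfb.TlfbError, match="'a', 'gambler', 3"):
            tlfb.ingest_daily(
                daily_frame([("a", "gambler", 3, 10.0), ("a", "gambler", 3, 20.0)])
            )

    def test_non_numeric_loss_names_row(self):
        with pytest.raises(tlfb.TlfbError, match="non-numeric"):
            tlfb.ingest_daily(daily_frame([("a", "gambler", 0, "oops")]))


class TestAggregateWeekly:
    def test_weekly_mean_over_observed_days(self):
        rows = [("a", "gambler", d, v) for d, v in enumerate([0, 0, 0, 100, 0, 0, 600])]
        daily, _ = tlfb.ingest_daily(daily_frame(rows))
        weekly = tlfb.aggregate_weekly(daily)
        assert weekly.loc[0, "avg_daily_loss"] == pytest.approx(100.0)
        assert weekly.loc[0, "n_days_observed"] == 7

    def test_partial_week_uses_observed_days_only(self):
        rows = [("a", "gambler", d, v) for d, v in [(0, 50.0), (2, 0.0), (5, 100.0)]]
        daily, _ = tlfb.ingest_daily(daily_frame(rows))
        weekly = tlfb.aggregate_weekly(daily)
        assert weekly.loc[0, "avg_daily_loss"] == pytest.approx(50.0)
        assert weekly.loc[0, "n_days_observed"] == 3

    def test_baseline_month_maps_to_week_zero(self):
        rows = [("a", "gambler", d, 10.0) for d in range(-30, 0)]
        daily, _ = tlfb.ingest_daily(daily_frame(rows))
        weekly = tlfb.aggregate_weekly(daily)
        assert weekly["week"].tolist() == [0]
        assert weekly.loc[0, "n_days_observed"] == 30

    @given(st.lists(st.floats(0, 5000), min_size=1, max_size=60), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_mass_conservation(self, losses, seed):
        """Sum over weeks of avg * n_days equals the sum of daily losses."""
        rng = np.random.default_rng(seed)
        days = rng.choice(np.arange(-30, 60), size=len(losses), replace=False)
        daily, _ = tlfb.ingest_daily(
            daily_frame([("a", "gambler", int(d), v) for d, v in zip(days, losses)])
        )
        weekly = tlfb.aggregate_weekly(daily)
        mass = (weekly["avg_daily_loss"] * weekly["n_days_observed"]).sum()
        assert mass == pytest.approx(daily["net_loss"].sum(), rel=1e-12, abs=1e-9)


def percentile_oracle(values, q):
    """Independent linear-interpolation percentile: h = (n-1)q between order
    statistics."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestPlaceKnots:
    def test_weeks_one_to_ten(self):
        knots = tlfb.place_knots(list(range(1, 11)))
        assert knots == pytest.approx([1.9, 5.5, 9.1])

    @pytest.mark.parametrize("weeks", [list(range(14)), [0, 0, 1, 1, 2, 5, 12, 25, 38]])
    def test_matches_percentile_oracle(self, weeks):
        knots = tlfb.place_knots(weeks)
        expected = [percentile_oracle(weeks, q) for q in (0.1, 0.5, 0.9)]
        assert knots == pytest.approx(expected, rel=1e-12)

    def test_degenerate_weeks_error(self):
        with pytest.raises(tlfb.TlfbError):
            tlfb.place_knots([3, 3, 3, 3])


def rcs_oracle(x, k1, k2, k3):
    """Independent transcription of the restricted-cubic-spline nonlinear term."""
    def plus3(u):
        return max(u, 0.0) ** 3

    return (
        plus3(x - k1)
        - plus3(x - k2) * (k3 - k1) / (k3 - k2)
        + plus3(x - k3) * (k2 - k1) / (k3 - k2)
    ) / (k3 - k1) ** 2


class TestRcsBasis:
    KNOTS = (1.9, 5.5, 9.1)

    def test_zero_below_first_knot(self):
        x = np.linspace(-5, self.KNOTS[0], 20)
        basis = tlfb.rcs_basis(x, self.KNOTS)
        assert np.all(basis[:, 1] == 0.0)

    def test_matches_truncated_power_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-2, 15, size=1000)
        basis = tlfb.rcs_basis(x, self.KNOTS)
        expected = [rcs_oracle(v, *self.KNOTS) for v in x]
        np.testing.assert_allclose(basis[:, 1], expected, atol=1e-10)
        np.testing.assert_allclose(basis[:, 0], x)

    def test_linear_beyond_boundary_knots(self):
        for lo, hi in [(self.KNOTS[2] + 0.5, self.KNOTS[2] + 30), (-30, self.KNOTS[0])]:
            x = np.linspace(lo, hi, 200)
            h = x[1] - x[0]
            nl = tlfb.rcs_basis(x, self.KNOTS)[:, 1]
            second = np.diff(nl, 2) / h**2
            assert np.max(np.abs(second)) <= 1e-8

    def test_c2_continuity_at_knots(self):
        h = 1e-4
        for k in self.KNOTS:
            x = np.array([k - 2 * h, k - h, k, k + h, k + 2 * h])
            nl = tlfb.rcs_basis(x, self.KNOTS)[:, 1]
            d1 = np.diff(nl) / h
            d2 = np.diff(nl, 2) / h**2
            assert np.max(np.abs(np.diff(d1))) < 1e-3  # first derivative continuous
            assert np.max(np.abs(np.diff(d2))) < 1e-2  # second derivative continuous

    def test_unsorted_knots_error(self):
        with pytest.raises(tlfb.TlfbError):
            tlfb.rcs_basis([1.0], (5.5, 1.9, 9.1))


class TestBuildDesign:
    def weekly(self):
        rows = []
        for pid, arm_weeks in [("a", [0, 1, 4, 8]), ("b", [0, 1, 4, 8])]:
            for w in arm_weeks:
                rows.append({"participant_id": pid, "rater": "gambler", "week": w,
                             "avg_daily_loss": 10.0, "n_days_observed": 7})
        return pd.DataFrame(rows)

    ARMS = {"a": "bct", "b": "cbt"}

    def test_week_zero_rows_have_intercept_only(self):
        d = tlfb.build_design(self.weekly(), self.ARMS, knots=(1, 4, 7))
        base_rows = d.matrix[np.asarray(d.weeks) == 0]
        assert np.all(base_rows["intercept"] == 1.0)
        for col in d.columns[1:]:
            assert np.all(base_rows[col] == 0.0), col

    def test_reference_coding(self):
        d = tlfb.build_design(self.weekly(), self.ARMS, knots=(1, 4, 7))
        m = d.matrix
        bct = m[(d.arm == 0) & (d.weeks > 0)]
        cbt = m[(d.arm == 1) & (d.weeks > 0)]
        for col in ("post:arm", "week_lin:arm", "week_nl:arm"):
            assert np.all(bct[col] == 0.0)
        np.testing.assert_allclose(cbt["post:arm"], cbt["post"])
        np.testing.assert_allclose(cbt["week_lin:arm"], cbt["week_lin"])
        np.testing.assert_allclose(cbt["week_nl:arm"], cbt["week_nl"])

    def test_matches_hand_built_matrix(self):
        """2 subjects x weeks {0,1,4,8}, knots (1,4,7), built by hand."""
        k1, k2, k3 = 1.0, 4.0, 7.0
        d = tlfb.build_design(self.weekly(), self.ARMS, knots=(k1, k2, k3))

        def nl(x):
            def p3(u):
                return max(u, 0.0) ** 3
            raw = (p3(x - k1) - p3(x - k2) * (k3 - k1) / (k3 - k2)
                   + p3(x - k3) * (k2 - k1) / (k3 - k2)) / (k3 - k1) ** 2
            return raw  # nl(0) = 0 for positive knots

        expect = []
        for arm01 in (0, 1):
            for w in (0, 1, 4, 8):
                post = 1.0 if w > 0 else 0.0
                row = [1.0, post, w, nl(w), post * arm01, w * arm01, nl(w) * arm01]
                expect.append(row)
        np.testing.assert_allclose(d.X, np.array(expect), atol=1e-12)

    def test_unknown_arm_label_error(self):
        with pytest.raises(tlfb.TlfbError, match="arm"):
            tlfb.build_design(self.weekly(), {"a": "bct", "b": "placebo"})

    def test_baseline_predictor_identical_across_arms(self):
        d = tlfb.build_design(self.weekly(), self.ARMS, knots=(1, 4, 7))
        rng = np.random.default_rng(0)
        beta = rng.normal(size=len(d.columns))
        r_bct = d.row(0.0, "bct") @ beta
        r_cbt = d.row(0.0, "cbt") @ beta
        assert r_bct == pytest.approx(r_cbt, abs=0)
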