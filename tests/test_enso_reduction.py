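"""Reduction-ratio estimation, empirical CDFs, level classification, Eq-3 application."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ensorice.calendars import EnsoCalendar
from ensorice.enso_reduction import (
    UnknownLevelError,
    apply_reduction,
    classify_levels,
    estimate_reductions,
    reduction_cdf,
    yield_reduction,
)
from ensorice.synthetic_data import generate_yield_panel


class TestYieldReduction:
    def test_arithmetic(self):
        assert yield_reduction(6.0, 6.0) == 0.0
        assert yield_reduction(3.0, 6.0) == pytest.approx(50.0)
        assert yield_reduction(0.06, 6.0) == pytest.approx(99.0)

    def test_good_years_clamp_to_zero(self):
        # observed above simulated is no loss, not a negative loss
        assert yield_reduction(7.0, 6.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            yield_reduction(5.0, 0.0)
        with pytest.raises(ValueError):
            yield_reduction(-1.0, 5.0)

    @given(yo=st.floats(0, 12), ys=st.floats(0.01, 12))
    def test_always_in_unit_interval(self, yo, ys):
        assert 0.0 <= yield_reduction(yo, ys) <= 100.0


class TestEstimateReductions:
    def test_empty_calendar_yields_no_estimates(self):
        panel, _ = generate_yield_panel(["Long An"], (2000, 2005), EnsoCalendar(), 0.0, seed=1)
        est = estimate_reductions(panel, EnsoCalendar())
        assert est.empty

    def test_noiseless_truth_recovered_exactly(self):
        cal = EnsoCalendar.from_records(
            [(2000, "ElNino", "WS"), (2002, "ElNino", "WS"), (2004, "LaNina", "AW")]
        )
        panel, _ = generate_yield_panel(
            ["Long An"], (1999, 2005), cal, {"ElNino": 20.0, "LaNina": 12.0},
            noise_sd=0.0, seed=1,
        )
        est = estimate_reductions(panel, cal)
        ws = est[est["season"] == "WS"]
        aw = est[est["season"] == "AW"]
        assert np.allclose(ws["d"], 20.0)
        assert np.allclose(aw["d"], 12.0)

    def test_summer_autumn_forced_to_zero(self):
        cal = EnsoCalendar.from_records([(2000, "ElNino", "WS")])
        panel, _ = generate_yield_panel(["Long An"], (1999, 2001), cal, 20.0, noise_sd=0.0, seed=1)
        est = estimate_reductions(panel, cal)
        sa = est[est["season"] == "SA"]
        assert len(sa) == 1 and (sa["d"] == 0.0).all()

    def test_pest_years_excluded(self):
        cal = EnsoCalendar.from_records([(1992, "LaNina", "AW"), (1996, "LaNina", "AW")])
        panel, _ = generate_yield_panel(
            ["An Giang"], (1990, 1997), cal, 15.0,
            pest_years=[(1992, "AW")], noise_sd=0.0, seed=1,
        )
        est = estimate_reductions(panel, cal, exclusions=[(1992, "AW")])
        aw = est[est["season"] == "AW"]
        assert list(aw["year"]) == [1996]

    def test_missing_cells_skipped_with_warning(self, caplog):
        cal = EnsoCalendar.from_records([(2000, "ElNino", "WS")])
        panel = pd.DataFrame(
            {"province": ["Long An"], "season": ["WS"], "year": [1999],
             "yo": [5.0], "ys": [5.5]}
        )
        with caplog.at_level("WARNING", logger="ensorice.enso_reduction"):
            est = estimate_reductions(panel, cal)
        assert est.empty
        assert "skipped" in caplog.text

    def test_recovers_truth_within_two_points_under_noise(self):
        """Mean estimated D within +-2 pp of the generator truth (30 ENSO years)."""
        cal = EnsoCalendar.from_records(
            [(y, "ElNino", "WS") for y in range(1950, 2010, 2)]
        )
        panel, _ = generate_yield_panel(
            ["Long An"], (1950, 2009), cal, 20.0, noise_sd=0.1, seed=3
        )
        est = estimate_reductions(panel, cal)
        ws = est[est["season"] == "WS"]
        assert len(ws) == 30
        assert ws["d"].mean() == pytest.approx(20.0, abs=2.0)


class TestReductionCdf:
    def test_single_estimate(self):
        cdf = reduction_cdf([10.0])
        assert list(cdf["d"]) == [10.0] and list(cdf["cum_prob"]) == [1.0]

    def test_sort_and_count_oracle(self):
        cdf = reduction_cdf([30.0, 10.0, 20.0])
        assert list(cdf["d"]) == [10.0, 20.0, 30.0]
        assert np.allclose(cdf["cum_prob"], [1 / 3, 2 / 3, 1.0])

    def test_severe_year_maximum_reported(self):
        # a Tra Vinh-like record whose worst El Nino year lost 65%
        sample = [5.0, 12.0, 8.0, 65.0, 30.0]
        cdf = reduction_cdf(sample)
        assert cdf["d"].iloc[-1] == 65.0
        assert cdf["cum_prob"].iloc[-1] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reduction_cdf([])


class TestClassifyLevels:
    def test_equal_estimates_degenerate_to_single_band(self):
        levels = classify_levels([10.0, 10.0, 10.0])
        assert (levels["d"] == 10.0).all()
        assert (levels["d_lower"] == levels["d_upper"]).all()

    def test_tertile_split_oracle(self):
        levels = classify_levels(np.arange(1.0, 10.0)).set_index("level")
        assert levels.loc["low", "d_upper"] == 3.0
        assert levels.loc["medium", "d_lower"] == 4.0
        assert levels.loc["medium", "d_upper"] == 6.0
        assert levels.loc["high", "d_lower"] == 7.0
        assert levels.loc["high", "d"] == 9.0

    def test_separated_clusters_split_between_clusters(self):
        rng = np.random.default_rng(8)
        d = np.concatenate([
            rng.uniform(1, 3, 10), rng.uniform(20, 25, 10), rng.uniform(50, 60, 10)
        ])
        levels = classify_levels(d).set_index("level")
        assert levels.loc["low", "d_upper"] < 20
        assert 3 < levels.loc["medium", "d_lower"] < 50
        assert levels.loc["medium", "d_upper"] < 50
        assert levels.loc["high", "d_lower"] >= 50

    def test_bands_ordered_and_non_overlapping(self):
        levels = classify_levels([2.0, 5.0, 9.0, 14.0, 22.0, 35.0]).set_index("level")
        assert levels.loc["low", "d_upper"] < levels.loc["medium", "d_lower"] or \
            levels.loc["low", "d_upper"] <= levels.loc["medium", "d_lower"]
        assert levels.loc["medium", "d_upper"] <= levels.loc["high", "d_lower"]
        assert levels.loc["low", "d"] < levels.loc["medium", "d"] < levels.loc["high", "d"]


class TestApplyReduction:
    def _table(self, d_high=30.0):
        return pd.DataFrame(
            {"level": ["high", "medium", "low"], "d": [d_high, 10.0, 0.0]}
        )

    def test_arithmetic(self):
        table = self._table()
        assert apply_reduction(5.0, "low", table) == 5.0
        assert apply_reduction(5.0, "medium", table) == pytest.approx(4.5)
        assert apply_reduction(5.0, "high", self._table(20.0)) == pytest.approx(4.0)
        assert apply_reduction(5.0, "high", self._table(100.0)) == 0.0

    def test_unknown_level_rejected(self):
        with pytest.raises(UnknownLevelError):
            apply_reduction(5.0, "catastrophic", self._table())

    @given(ys=st.floats(0, 12), d=st.floats(0, 100))
    def test_yf_bounded_by_ys(self, ys, d):
        table = pd.DataFrame({"level": ["high"], "d": [d]})
        yf = apply_reduction(ys, "high", table)
        assert 0.0 <= yf <= ys
        if d == 0:
            assert yf == ys

    def test_estimate_classify_apply_round_trip(self):
        """The high-level D applied to the worst ENSO year's simulated yield
        reproduces that year's observed yield (band max = worst year)."""
        cal = EnsoCalendar.from_records(
            [(y, "ElNino", "WS") for y in range(1990, 2012, 2)]
        )
        panel, _ = generate_yield_panel(["Tra Vinh"], (1989, 2012), cal, 25.0,
                                        noise_sd=0.15, seed=13)
        est = estimate_reductions(panel, cal)
        ws = est[est["season"] == "WS"]
        levels = classify_levels(ws["d"])
        worst = ws.loc[ws["d"].idxmax()]
        cell = panel.set_index(["season", "year"]).loc[("WS", worst["year"])]
        yf = apply_reduction(float(cell["ys"]), "high", levels)
        assert yf == pytest.approx(float(cell["yo"]), abs=1e-9)
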