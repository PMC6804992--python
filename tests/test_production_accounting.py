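"""Production accounting: Eq-4/5 arithmetic, conservation, monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ensorice.io import round_half_up
from ensorice.production_accounting import (
    MissingProvinceError,
    StrataError,
    annual_production,
    build_report,
    derive_demo_areas,
    loss_percent,
    mrd_total,
    production_table,
    seasonal_production,
)
from ensorice.seasons import MRD_PROVINCES


class TestSeasonalProduction:
    def test_direct_arithmetic(self):
        assert seasonal_production({"high": 5.0}, {"high": 1000.0}) == 5000.0
        assert seasonal_production(
            {"high": 5.0, "none": 4.0}, {"high": 100.0, "none": 50.0}
        ) == pytest.approx(700.0)

    def test_zero_areas(self):
        assert seasonal_production({"high": 5.0, "low": 4.0}, {"high": 0.0, "low": 0.0}) == 0.0

    def test_mismatched_strata_rejected(self):
        with pytest.raises(StrataError):
            seasonal_production({"high": 5.0}, {"low": 100.0})
        with pytest.raises(StrataError):
            seasonal_production({"high": 5.0}, {"high": -1.0})


class TestAnnualProduction:
    def test_summation(self):
        assert annual_production({"WS": 100.0, "SA": 200.0, "AW": 300.0}) == 600.0
        assert annual_production([150.0]) == 150.0

    def test_absent_season_equivalent_to_explicit_zero(self):
        assert annual_production({"SA": 200.0, "AW": 300.0}) == annual_production(
            {"WS": 0.0, "SA": 200.0, "AW": 300.0}
        )

    def test_no_seasons_rejected(self):
        with pytest.raises(ValueError):
            annual_production({})


class TestMrdTotal:
    def test_printed_present_production_sums_exactly(self, production_tables):
        provincial, _ = production_tables
        totals = dict(zip(provincial["province"], provincial["present"]))
        assert round_half_up(mrd_total(totals)) == 22.79

    def test_missing_province_named(self):
        with pytest.raises(MissingProvinceError, match="Ca Mau"):
            mrd_total({p: 1.0 for p in MRD_PROVINCES if p != "Ca Mau"})

    def test_permutation_invariant(self, production_tables):
        provincial, _ = production_tables
        totals = dict(zip(provincial["province"], provincial["present"]))
        rev = dict(reversed(list(totals.items())))
        assert mrd_total(totals) == mrd_total(rev)


class TestLossPercent:
    def test_identities(self):
        assert loss_percent(100.0, 100.0) == 0.0
        assert loss_percent(100.0, 90.0) == pytest.approx(10.0)

    def test_printed_mrd_losses_within_tolerance(self, production_tables):
        """Losses recomputed from the printed regional totals match the
        printed loss row to 0.05 pp (the source used unrounded inputs)."""
        _, mrd = production_tables
        printed = {
            "rcp45_no_enso": 1.86, "rcp85_no_enso": 5.58,
            "rcp45_elnino": 10.29, "rcp45_lanina": 7.36,
            "rcp85_elnino": 13.62, "rcp85_lanina": 10.88,
        }
        for col, expect in printed.items():
            assert loss_percent(mrd["present"], mrd[col]) == pytest.approx(expect, abs=0.05)

    def test_nonpositive_present_rejected(self):
        with pytest.raises(ValueError):
            loss_percent(0.0, 1.0)


def test_risk_area_fixture_rows_sum_to_100(risk_table):
    sums = risk_table[["high", "medium", "low", "none"]].sum(axis=1)
    assert np.allclose(sums, 100.0, atol=0.1)


def _two_province_inputs(d_high=30.0, d_medium=10.0, d_low=5.0, future_equals_present=False):
    provinces = ["Alpha", "Beta"]
    present = pd.DataFrame(
        [(p, s, y) for p, s, y in [
            ("Alpha", "WS", 6.0), ("Alpha", "AW", 4.0),
            ("Beta", "WS", 5.0), ("Beta", "SA", 4.5),
        ]],
        columns=["province", "season", "yield"],
    )
    fut = present.copy()
    if not future_equals_present:
        fut["yield"] = fut["yield"] * 0.98
    future = fut.assign(scenario="RCP4.5")[["province", "scenario", "season", "yield"]]
    levels = pd.DataFrame(
        [(p, ph, lv, d) for p in provinces for ph in ("ElNino", "LaNina")
         for lv, d in (("high", d_high), ("medium", d_medium), ("low", d_low))],
        columns=["province", "phase", "level", "d"],
    )
    risk = pd.DataFrame(
        [(p, h, 20.0, 30.0, 10.0, 40.0) for p in provinces for h in ("salinity", "flood")],
        columns=["province", "hazard", "high", "medium", "low", "none"],
    )
    areas = present.assign(area_ha=1000.0)[["province", "season", "area_ha"]]
    return present, future, levels, risk, areas


class TestBuildReport:
    def test_identity_pipeline(self):
        """Zero reductions and an unchanged climate reproduce the present column."""
        present, future, levels, risk, areas = _two_province_inputs(
            0.0, 0.0, 0.0, future_equals_present=True
        )
        report = build_report(present, future, levels, risk, areas, scenarios=("RCP4.5",))
        wide = report.pivot_table(index="province", columns="condition", values="production_t")
        for cond in ("no_enso", "elnino", "lanina"):
            assert np.allclose(wide[cond], wide["present"])

    def test_hand_computed_oracle(self):
        """Single province, two seasons, explicit spreadsheet arithmetic."""
        present, future, levels, risk, areas = _two_province_inputs()
        report = build_report(present, future, levels, risk, areas, scenarios=("RCP4.5",))
        alpha = report[report["province"] == "Alpha"].set_index("condition")
        y_ws, y_aw = 6.0 * 0.98, 4.0 * 0.98
        no_enso = (y_ws + y_aw) * 1000.0
        assert alpha.loc["no_enso", "production_t"] == pytest.approx(no_enso)
        # El Nino: WS stratified 20% @ D=30, 30% @ D=10, 10% @ D=5, 40% untouched
        ws_factor = 0.2 * 0.7 + 0.3 * 0.9 + 0.1 * 0.95 + 0.4 * 1.0
        elnino = (y_ws * ws_factor + y_aw) * 1000.0
        assert alpha.loc["elnino", "production_t"] == pytest.approx(elnino)
        lanina = (y_ws + y_aw * ws_factor) * 1000.0  # same fractions for flood here
        assert alpha.loc["lanina", "production_t"] == pytest.approx(lanina)

    def test_monotone_in_reduction_severity(self):
        present, future, levels, risk, areas = _two_province_inputs()
        mild = build_report(present, future, levels, risk, areas, scenarios=("RCP4.5",))
        p2, f2, severe_levels, r2, a2 = _two_province_inputs(60.0, 30.0, 10.0)
        severe = build_report(p2, f2, severe_levels, r2, a2, scenarios=("RCP4.5",))
        for cond in ("elnino", "lanina"):
            m = mild[mild["condition"] == cond]["production_t"].to_numpy()
            s = severe[severe["condition"] == cond]["production_t"].to_numpy()
            assert (s <= m + 1e-9).all()

    def test_enso_columns_between_no_enso_and_nothing(self):
        present, future, levels, risk, areas = _two_province_inputs()
        report = build_report(present, future, levels, risk, areas, scenarios=("RCP4.5",))
        wide = report.pivot_table(index="province", columns="condition", values="production_t")
        assert (wide["elnino"] <= wide["no_enso"] + 1e-9).all()
        assert (wide["lanina"] <= wide["no_enso"] + 1e-9).all()
        assert (wide["no_enso"] <= wide["present"] + 1e-9).all()

    def test_all_area_no_risk_neutralises_enso(self):
        present, future, levels, risk, areas = _two_province_inputs()
        risk[["high", "medium", "low"]] = 0.0
        risk["none"] = 100.0
        report = build_report(present, future, levels, risk, areas, scenarios=("RCP4.5",))
        wide = report.pivot_table(index="province", columns="condition", values="production_t")
        assert np.allclose(wide["elnino"], wide["no_enso"])
        assert np.allclose(wide["lanina"], wide["no_enso"])

    def test_missing_province_rejected(self):
        present, future, levels, risk, areas = _two_province_inputs()
        with pytest.raises(MissingProvinceError, match="Beta"):
            build_report(
                present, future, levels, risk[risk["province"] != "Beta"], areas,
                scenarios=("RCP4.5",),
            )

    def test_conservation_in_pivot(self):
        """MRD row equals the provincial sum; losses derive from totals."""
        present, future, levels, risk, areas = _two_province_inputs()
        report = build_report(present, future, levels, risk, areas, scenarios=("RCP4.5",))
        wide = production_table(report, scale=1.0)
        body = wide.drop(index=["MRD", "Rice lost (%)"])
        assert np.allclose(wide.loc["MRD"], body.sum(axis=0))
        for col in wide.columns:
            if col == "present":
                continue
            expect = loss_percent(wide.loc["MRD", "present"], wide.loc["MRD", col])
            assert wide.loc["Rice lost (%)", col] == pytest.approx(expect)


def test_demo_areas_reproduce_present_production(production_tables, yield_changes):
    provincial, _ = production_tables
    present = (
        yield_changes[yield_changes["scenario"] == "RCP4.5"]
        .rename(columns={"present": "yield"})[["province", "season", "yield"]]
    )
    areas = derive_demo_areas(provincial, present)
    merged = areas.merge(present, on=["province", "season"])
    merged["pp"] = merged["area_ha"] * merged["yield"]
    recomputed = merged.groupby("province")["pp"].sum() / 1e6
    printed = provincial.set_index("province")["present"]
    assert np.allclose(recomputed[printed.index], printed)
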