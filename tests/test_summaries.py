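import math
from datetime import date

import pandas as pd
import pytest

from pzp_range.data_model import StudyWindow, make_table
from pzp_range.published import load_published_counts
from pzp_range.summaries import (
    annual_foal_summary,
    annual_treatment_summary,
    conception_proportion,
    fertility_control_index,
    foaling_reduction,
    lesion_prevalence,
    lesion_prevalence_pct,
    monthly_birth_series,
    percent_mature_vaccinated,
    pregnant_mare_series,
)

from conftest import build_dataset, horse

PUBLISHED = load_published_counts()
BIRTHS = {2019: 392, 2020: 488, 2021: 267, 2022: 205}
MATURE = {2019: 1528, 2020: 1794, 2021: 1993, 2022: 1963}


class TestCoveragePercent:
    @pytest.mark.parametrize(
        "vaccinated,total,expected",
        [(760, 1528, 49.7), (1070, 1794, 59.6), (0, 100, 0.0)],
    )
    def test_printed_values(self, vaccinated, total, expected):
        assert percent_mature_vaccinated(vaccinated, total) == expected

    def test_zero_denominator_undefined(self):
        assert math.isnan(percent_mature_vaccinated(5, 0))


class TestLesionPrevalence:
    # denominator = all treatments that year, mature + immature combined
    @pytest.mark.parametrize(
        "year,granuloma_pct,abscess_pct",
        [(2019, 0.00, 0.58), (2020, 0.06, 0.96), (2021, 0.27, 1.20),
         (2022, 0.59, 1.28)],
    )
    def test_all_eight_published_cells(self, year, granuloma_pct, abscess_pct):
        tr = PUBLISHED["annual_treatments"].loc[year]
        le = PUBLISHED["annual_lesions"].loc[year]
        total = int(tr["mature_treatments"] + tr["immature_treatments"])
        assert lesion_prevalence_pct(int(le["granulomas"]), total) == granuloma_pct
        assert lesion_prevalence_pct(int(le["abscesses"]), total) == abscess_pct

    def test_zero_treatments_undefined(self):
        assert math.isnan(lesion_prevalence_pct(3, 0))


class TestFoalingReduction:
    def test_printed_reductions(self):
        assert foaling_reduction(BIRTHS, 2020, 2021) == 45.3
        assert foaling_reduction(BIRTHS, 2020, 2022) == 58.0
        assert foaling_reduction(BIRTHS, 2020, 2020) == 0.0

    def test_scale_invariance(self):
        scaled = {y: 7 * b for y, b in BIRTHS.items()}
        assert foaling_reduction(scaled, 2020, 2021) == foaling_reduction(
            BIRTHS, 2020, 2021
        )


class TestConceptionProportion:
    @pytest.mark.parametrize(
        "year,expected", [(2019, 31.9), (2020, 14.9), (2021, 10.3)]
    )
    def test_printed_values(self, year, expected):
        assert conception_proportion(BIRTHS, MATURE, year) == expected

    def test_missing_year_undefined(self):
        assert math.isnan(conception_proportion(BIRTHS, MATURE, 2022))


class TestFertilityControlIndex:
    def test_product(self):
        assert fertility_control_index(0.7, 0.9) == pytest.approx(0.63)
        assert fertility_control_index(1.0, 0.42) == 0.42

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fertility_control_index(1.2, 0.5)
        with pytest.raises(ValueError):
            fertility_control_index(0.5, -0.1)


def _panel_row(hid, month, mature=True):
    return dict(horse_id=hid, month_index=month, mature=mature, pregnant=False,
                conceived=False, foaled=False, herd_area="main",
                granuloma_active=False, abscess_active=False)


class TestAnnualTreatmentSummary:
    def test_distinct_mares_vs_event_counts(self, window):
        ds = build_dataset(
            horses=[horse("m1", dob="2015-04-10"), horse("m2", dob="2015-04-10")],
            vaccinations=[
                dict(event_id="v1", horse_id="m1", date="2019-05-01", action="P",
                     confirmed=True),
                dict(event_id="v2", horse_id="m1", date="2019-05-20", action="B",
                     confirmed=True),
            ],
        )
        panel = pd.DataFrame(
            [_panel_row(h, t) for h in ("m1", "m2") for t in range(1, 13)]
        )
        s = annual_treatment_summary(panel, ds, 2019, window)
        assert (s.mature_vaccinated, s.mature_treatments) == (1, 2)
        assert s.mature_total == 2

    def test_published_scale_2019_row(self, window):
        """A herd generated to match the published 2019 totals reproduces
        them: 1528 mature mares, 760 vaccinated, 1195 treatments."""
        panel_rows = [_panel_row(f"m{i}", 4) for i in range(1528)]
        events = []
        k = 0
        for i in range(760):
            events.append(dict(event_id=f"v{k}", horse_id=f"m{i}",
                               date="2019-04-15", action="P", confirmed=True))
            k += 1
        for i in range(1195 - 760):  # extra boosters on already-treated mares
            events.append(dict(event_id=f"v{k}", horse_id=f"m{i % 760}",
                               date="2019-05-15", action="B", confirmed=True))
            k += 1
        ds = build_dataset(
            horses=[horse(f"m{i}", dob="2015-04-10") for i in range(1528)],
            vaccinations=events,
        )
        panel = pd.DataFrame(
            panel_rows + [_panel_row(f"m{i}", 5) for i in range(1528)]
        )
        s = annual_treatment_summary(panel, ds, 2019, window)
        assert s.mature_total == 1528
        assert s.mature_vaccinated == 760
        assert s.mature_treatments == 1195
        assert percent_mature_vaccinated(s.mature_vaccinated, s.mature_total) == 49.7

    def test_year_with_no_events(self, window):
        ds = build_dataset(horses=[horse("m1", dob="2015-04-10")])
        panel = pd.DataFrame([_panel_row("m1", t) for t in range(1, 49)])
        s = annual_treatment_summary(panel, ds, 2020, window)
        assert (s.mature_vaccinated, s.mature_treatments) == (0, 0)

    def test_unconfirmed_events_not_counted(self, window):
        ds = build_dataset(
            horses=[horse("m1", dob="2015-04-10")],
            vaccinations=[dict(event_id="v1", horse_id="m1", date="2019-05-01",
                               action="P", confirmed=False)],
        )
        panel = pd.DataFrame([_panel_row("m1", t) for t in range(1, 13)])
        s = annual_treatment_summary(panel, ds, 2019, window)
        assert s.mature_treatments == 0

    def test_event_level_lesion_prevalence(self, window):
        ds = build_dataset(
            horses=[horse("m1", dob="2015-04-10")],
            vaccinations=[dict(event_id=f"v{i}", horse_id="m1",
                               date=f"2019-0{i}-01", action="P", confirmed=True)
                          for i in range(1, 5)],
            lesions=[dict(horse_id="m1", event_id="v1", lesion_type="granuloma",
                          first_observed="2019-01-20", resolved=None)],
        )
        panel = pd.DataFrame([_panel_row("m1", t) for t in range(1, 13)])
        ts = annual_treatment_summary(panel, ds, 2019, window)
        lp = lesion_prevalence(ds, ts, 2019)
        assert lp.granulomas == 1
        assert lp.granuloma_pct == 25.0


def _foal_rows(year, n, sex, die_same_year=0):
    rows = []
    for i in range(n):
        birth = date(year, 3 + (i % 6), 1 + (i % 27))
        death = date(year, 11, 1 + (i % 27)) if i < die_same_year else None
        rows.append(dict(foal_id=f"{sex}{year}{i}", dam_id=f"d{year}{sex}{i}",
                         birth_date=str(birth), foal_sex=sex,
                         death_date=str(death) if death else None,
                         removed_date=None))
    return rows


class TestAnnualFoalSummary:
    def test_published_scale_2022_mortality(self):
        """Births 205 (96 m / 108 f / 1 unknown) with 129 recorded foal
        deaths gives the published 62.9% mortality."""
        rows = (_foal_rows(2022, 96, "male", die_same_year=57)
                + _foal_rows(2022, 108, "female", die_same_year=72)
                + _foal_rows(2022, 1, "unknown"))
        f = make_table("foalings", rows)
        s = annual_foal_summary(f, 2022)
        assert s.births == (96, 108, 1)
        assert s.deaths == (57, 72, 0)
        assert s.mortality_pct == 62.9

    def test_no_deaths_zero_mortality(self):
        f = make_table("foalings", _foal_rows(2020, 10, "female"))
        assert annual_foal_summary(f, 2020).mortality_pct == 0.0

    def test_december_birth_january_death_counted_in_death_year(self):
        f = make_table("foalings", [dict(
            foal_id="f1", dam_id="d1", birth_date="2020-12-10", foal_sex="male",
            death_date="2021-01-20", removed_date=None)])
        assert annual_foal_summary(f, 2021).deaths == (1, 0, 0)
        assert annual_foal_summary(f, 2020).deaths == (0, 0, 0)

    def test_yearling_death_not_foal_mortality(self):
        f = make_table("foalings", [dict(
            foal_id="f1", dam_id="d1", birth_date="2020-03-10", foal_sex="male",
            death_date="2021-06-20", removed_date=None)])
        assert annual_foal_summary(f, 2021).deaths == (0, 0, 0)

    def test_sex_components_sum_to_totals(self, sim_result):
        _, ds, _ = sim_result
        for year in (2019, 2020, 2021, 2022):
            s = annual_foal_summary(ds.foalings, year)
            assert s.total_births == sum(s.births)
            assert s.total_deaths == sum(s.deaths)


class TestMonthlySeries:
    def test_births_only_in_birth_months(self, window):
        f = make_table("foalings", [
            dict(foal_id=f"f{i}", dam_id=f"d{i}", birth_date=f"202{y}-04-1{i}",
                 foal_sex="male", death_date=None, removed_date=None)
            for y in (0, 1) for i in range(3)
        ])
        series = monthly_birth_series(f, window)
        nonzero = series.loc[series["births"] > 0, "month_index"]
        assert set(nonzero) == {window.index_of(2020, 4), window.index_of(2021, 4)}

    def test_sum_over_months_equals_annual_births(self, sim_result, window):
        _, ds, _ = sim_result
        series = monthly_birth_series(ds.foalings, window)
        in_window = sum(
            1 for d in ds.foalings["birth_date"] if window.in_window(window.month_of(d.date()))
        )
        assert series["births"].sum() == in_window

    def test_conception_series_is_lagged_births(self, window):
        f = make_table("foalings", [dict(
            foal_id="f1", dam_id="d1", birth_date="2021-04-20", foal_sex="male",
            death_date=None, removed_date=None)])
        series = monthly_birth_series(f, window).set_index("month_index")
        assert series.loc[window.index_of(2021, 4), "births"] == 1
        assert series.loc[window.index_of(2020, 5), "conceptions"] == 1

    def test_pregnant_series_hand_count(self, window):
        ds = build_dataset(
            horses=[horse("m1", dob="2015-04-10"),
                    horse("f1", dam_id="m1", dob="2021-04-20")],
            foalings=[dict(foal_id="f1", dam_id="m1", birth_date="2021-04-20",
                           foal_sex="female", death_date=None, removed_date=None)],
        )
        from pzp_range.panel import build_panel

        panel = build_panel(ds, window)
        series = pregnant_mare_series(panel, window).set_index("month_index")
        conc, birth = window.index_of(2020, 5), window.index_of(2021, 4)
        for t in window.months:
            expected = 1 if conc <= t <= birth else 0
            assert series.loc[t, "pregnant_mares"] == expected

    def test_pregnant_never_exceeds_total(self, sim_panel, window):
        _, panel = sim_panel
        series = pregnant_mare_series(panel, window)
        assert (series["pregnant_mares"] <= series["total_mares"]).all()
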