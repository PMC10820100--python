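"""Annual and monthly program summaries.

Two layers live here.  Count-level functions operate on published-style
aggregate counts (mares vaccinated, treatments, births, lesions per year)
and compute the derived percentages a program report prints: coverage of
the mature herd, lesion prevalence per treatment, year-on-year foaling
reduction, and the conception proportion implied by the foaling-as-
conception proxy.  Event-level functions reduce a dataset + panel to those
same aggregate counts, so the two layers compose into a full pipeline.

Conventions that matter:

* Lesion prevalence divides by ALL treatments given that year, mature and
  immature mares combined.
* The conception proportion for year Y divides the births of year Y+1
  (conceptions back-dated 354 days) by the mature-mare total of year Y.
* Foal mortality for a year counts deceased foals under one year old whose
  death was recorded in that year, even when the birth fell in the
  preceding year; the denominator is that same year's births.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .data_model import Dataset, StudyWindow
from .panel import conception_date

__all__ = [
    "AnnualTreatmentSummary",
    "AnnualFoalSummary",
    "LesionPrevalence",
    "annual_treatment_summary",
    "percent_mature_vaccinated",
    "lesion_prevalence",
    "lesion_prevalence_pct",
    "annual_foal_summary",
    "foaling_reduction",
    "conception_proportion",
    "monthly_birth_series",
    "pregnant_mare_series",
    "fertility_control_index",
]


@dataclass(frozen=True)
class AnnualTreatmentSummary:
    year: int
    mature_total: int
    mature_vaccinated: int
    mature_treatments: int
    immature_total: int
    immature_vaccinated: int
    immature_treatments: int

    @property
    def total_treatments(self) -> int:
        return self.mature_treatments + self.immature_treatments


@dataclass(frozen=True)
class AnnualFoalSummary:
    year: int
    births: tuple[int, int, int]    # (male, female, unknown)
    deaths: tuple[int, int, int]    # recorded in year, foals < 1 year old
    removed: tuple[int, int, int]
    mortality_pct: float
    sex_ratio: float                # male births / female births

    @property
    def total_births(self) -> int:
        return sum(self.births)

    @property
    def total_deaths(self) -> int:
        return sum(self.deaths)


@dataclass(frozen=True)
class LesionPrevalence:
    year: int
    granulomas: int
    abscesses: int
    total_treatments: int
    granuloma_pct: float
    abscess_pct: float


# ----------------------------------------------------------------- counts


def percent_mature_vaccinated(vaccinated: int, total: int) -> float:
    """Coverage of the mature herd, percent to 1 decimal; NaN if no mares."""
    if total <= 0:
        return math.nan
    return round(100.0 * vaccinated / total, 1)


def lesion_prevalence_pct(occurrences: int, total_treatments: int) -> float:
    """Lesion occurrences per treatment given that year, percent to 2
    decimals; NaN when no treatments were given."""
    if total_treatments <= 0:
        return math.nan
    return round(100.0 * occurrences / total_treatments, 2)


def foaling_reduction(
    births: Mapping[int, int], ref_year: int, year: int
) -> float:
    """Percent reduction in births relative to a reference year (1 dp)."""
    ref = births[ref_year]
    if ref <= 0:
        return math.nan
    return round(100.0 * (ref - births[year]) / ref, 1)


def conception_proportion(
    births: Mapping[int, int],
    mature_totals: Mapping[int, int],
    conception_year: int,
) -> float:
    """Percent of the mature herd conceiving in a year, via the 354-day
    foaling proxy: births of the following calendar year over the mature
    total of the conception year (1 dp)."""
    if conception_year + 1 not in births or conception_year not in mature_totals:
        return math.nan
    total = mature_totals[conception_year]
    if total <= 0:
        return math.nan
    return round(100.0 * births[conception_year + 1] / total, 1)


def fertility_control_index(coverage_proportion: float, efficacy: float) -> float:
    """Coverage x per-mare efficacy: the expected proportional suppression
    of conception at the population level.  Both arguments in [0, 1]."""
    for name, v in [("coverage_proportion", coverage_proportion), ("efficacy", efficacy)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return coverage_proportion * efficacy


# ----------------------------------------------------------------- events


def _event_maturity(panel: pd.DataFrame) -> dict[tuple[str, int], bool]:
    return {
        (hid, int(t)): bool(m)
        for hid, t, m in zip(panel["horse_id"], panel["month_index"], panel["mature"])
    }


def annual_treatment_summary(
    panel: pd.DataFrame, ds: Dataset, year: int, w: StudyWindow
) -> AnnualTreatmentSummary:
    """Treatment totals for one calendar year, split by maturity.

    Treatments are confirmed events; each is classed mature/immature by the
    mare's panel maturity in the treatment month.  Totals of mares are
    distinct mares with at least one active panel row of that maturity in
    the year; "vaccinated" counts distinct treated mares per class.
    """
    maturity = _event_maturity(panel)
    months = [t for t in w.months if w.year_of(t) == year]
    in_year = panel["month_index"].isin(months)
    mature_total = panel.loc[in_year & panel["mature"], "horse_id"].nunique()
    immature_total = panel.loc[in_year & ~panel["mature"], "horse_id"].nunique()

    v = ds.vaccinations.loc[ds.vaccinations["confirmed"]]
    mat_mares, imm_mares = set(), set()
    mat_treat = imm_treat = 0
    for hid, d in zip(v["horse_id"], v["date"]):
        if d.year != year:
            continue
        t = w.month_of(d.date())
        is_mature = maturity.get((hid, t))
        if is_mature is None:
            continue  # treated outside her activity period: not in panel
        if is_mature:
            mat_treat += 1
            mat_mares.add(hid)
        else:
            imm_treat += 1
            imm_mares.add(hid)
    return AnnualTreatmentSummary(
        year=year,
        mature_total=int(mature_total),
        mature_vaccinated=len(mat_mares),
        mature_treatments=mat_treat,
        immature_total=int(immature_total),
        immature_vaccinated=len(imm_mares),
        immature_treatments=imm_treat,
    )


def lesion_prevalence(
    ds: Dataset, treatments: AnnualTreatmentSummary, year: int
) -> LesionPrevalence:
    """Lesion occurrences (by first-observation year) over all treatments
    given that year, mature and immature combined."""
    le = ds.lesions
    in_year = le["first_observed"].dt.year == year
    gran = int((in_year & (le["lesion_type"] == "granuloma")).sum())
    absc = int((in_year & (le["lesion_type"] == "abscess")).sum())
    total = treatments.total_treatments
    return LesionPrevalence(
        year=year,
        granulomas=gran,
        abscesses=absc,
        total_treatments=total,
        granuloma_pct=lesion_prevalence_pct(gran, total),
        abscess_pct=lesion_prevalence_pct(absc, total),
    )


def _sex_split(frame: pd.DataFrame) -> tuple[int, int, int]:
    c = frame["foal_sex"].value_counts()
    return int(c.get("male", 0)), int(c.get("female", 0)), int(c.get("unknown", 0))


def annual_foal_summary(foalings: pd.DataFrame, year: int) -> AnnualFoalSummary:
    """Births, foal deaths and removals for one calendar year.

    Deaths and removals count foals under one year of age at the event,
    recorded within the year regardless of birth year.
    """
    f = foalings
    born = f.loc[f["birth_date"].dt.year == year]

    def _young_in_year(col: str) -> pd.DataFrame:
        has = f[col].notna()
        sub = f.loc[has]
        young = sub[col] < sub["birth_date"] + pd.DateOffset(years=1)
        return sub.loc[young & (sub[col].dt.year == year)]

    births = _sex_split(born)
    deaths = _sex_split(_young_in_year("death_date"))
    removed = _sex_split(_young_in_year("removed_date"))
    total_births = sum(births)
    mortality = (
        round(100.0 * sum(deaths) / total_births, 1) if total_births else math.nan
    )
    sex_ratio = births[0] / births[1] if births[1] else math.nan
    return AnnualFoalSummary(
        year=year,
        births=births,
        deaths=deaths,
        removed=removed,
        mortality_pct=mortality,
        sex_ratio=sex_ratio,
    )


def monthly_birth_series(foalings: pd.DataFrame, w: StudyWindow) -> pd.DataFrame:
    """Birth counts per study month plus the back-dated conception series.

    Columns: month_index, births, conceptions — conceptions in month t are
    the births whose implied conception (birth - 354 days) falls in t, so
    the two series are the same counts shifted by the gestation lag.
    """
    birth_counts: dict[int, int] = {}
    conc_counts: dict[int, int] = {}
    for d in foalings["birth_date"]:
        b = w.month_of(d.date())
        c = w.month_of(conception_date(d.date()))
        birth_counts[b] = birth_counts.get(b, 0) + 1
        conc_counts[c] = conc_counts.get(c, 0) + 1
    return pd.DataFrame({
        "month_index": list(w.months),
        "births": [birth_counts.get(t, 0) for t in w.months],
        "conceptions": [conc_counts.get(t, 0) for t in w.months],
    })


def pregnant_mare_series(panel: pd.DataFrame, w: StudyWindow) -> pd.DataFrame:
    """Active and pregnant mare counts per study month."""
    rows = []
    grouped = dict(tuple(panel.groupby("month_index")))
    for t in w.months:
        grp = grouped.get(t)
        total = int(grp["horse_id"].nunique()) if grp is not None else 0
        pregnant = int(grp["pregnant"].sum()) if grp is not None else 0
        rows.append({"month_index": t, "total_mares": total, "pregnant_mares": pregnant})
    return pd.DataFrame(rows)
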