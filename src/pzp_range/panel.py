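"""Mare-month panel construction.

The analysis unit is the mare-month: every retained female contributes one
row per month of her activity period (from enrollment to death, removal or
the window end).  Each row carries maturity, pregnancy, conception and
foaling flags, the herd area, and active-lesion flags.

Pregnancy is reconstructed from observed foalings using the 354-day
equine gestation: a birth implies a conception 354 days earlier, the mare
is flagged pregnant from the conception month through the birth month, and
`conceived` / `foaled` are true exactly in those two months.  Pregnancies
lost before term are invisible to this proxy, so true conception rates are
understated.

Geographic exclusions mirror program rules: females resident outside the
darting-permission boundary for any continuous 12-month stretch are
removed (boundary-crossers with all stretches under 12 months are kept),
as are residents of configured excluded areas.
"""

from __future__ import annotations

from datetime import date, timedelta

import pandas as pd
from dateutil.relativedelta import relativedelta

from .data_model import Dataset, StudyWindow

__all__ = [
    "GESTATION_DAYS",
    "MATURITY_AGE_MONTHS",
    "maturity_status",
    "conception_month",
    "conception_date",
    "pregnancy_flags",
    "apply_exclusions",
    "activity_periods",
    "build_panel",
    "PanelIntegrityError",
]

GESTATION_DAYS = 354
MATURITY_AGE_MONTHS = 12  # mature = strictly older than one year

PANEL_COLUMNS = [
    "horse_id", "month_index", "mature", "pregnant", "conceived", "foaled",
    "herd_area", "granuloma_active", "abscess_active",
]


class PanelIntegrityError(ValueError):
    """Event records are mutually inconsistent (e.g. overlapping gestations)."""


def maturity_status(
    dob: date | None, dob_known: bool, month_index: int, w: StudyWindow
) -> str:
    """"mature" iff the mare is strictly older than 12 months on the first
    day of the month; unknown date of birth counts as mature from the first
    evaluated month."""
    if dob is None or not dob_known:
        return "mature"
    first_day = w.month_start(month_index)
    return "mature" if first_day > dob + relativedelta(months=MATURITY_AGE_MONTHS) else "immature"


def conception_date(birth_date: date) -> date:
    return birth_date - timedelta(days=GESTATION_DAYS)


def conception_month(birth_date: date, w: StudyWindow) -> int:
    """Month index of the implied conception (may be pre-window, i.e. <= 0)."""
    return w.month_of(conception_date(birth_date))


def pregnancy_flags(
    foalings: pd.DataFrame, month_index: int, w: StudyWindow
) -> tuple[bool, bool, bool]:
    """(pregnant, conceived, foaled) for one mare in one month.

    ``foalings`` holds that mare's foaling events (birth_date column).
    Raises :class:`PanelIntegrityError` if two reconstructed gestations
    overlap in any month.
    """
    intervals = _gestation_intervals(foalings, w)
    pregnant = conceived = foaled = False
    for conc_idx, birth_idx in intervals:
        if conc_idx <= month_index <= birth_idx:
            pregnant = True
        if month_index == conc_idx:
            conceived = True
        if month_index == birth_idx:
            foaled = True
    return pregnant, conceived, foaled


def _gestation_intervals(
    foalings: pd.DataFrame, w: StudyWindow
) -> list[tuple[int, int]]:
    births = sorted(pd.to_datetime(foalings["birth_date"]).dt.date)
    intervals = [(w.month_of(conception_date(b)), w.month_of(b)) for b in births]
    for (c1, b1), (c2, b2) in zip(intervals, intervals[1:]):
        if c2 <= b1:
            raise PanelIntegrityError(
                f"overlapping gestations: months {c1}-{b1} and {c2}-{b2}"
            )
    return intervals


def _consecutive_runs(months: list[int]) -> list[int]:
    """Lengths of maximal runs of consecutive integers."""
    runs, current = [], 0
    prev = None
    for m in sorted(months):
        current = current + 1 if prev is not None and m == prev + 1 else 1
        runs.append(current)
        prev = m
    # runs holds running lengths; maximal lengths are enough for a >=k test
    return runs


def apply_exclusions(
    ds: Dataset,
    excluded_areas: set[str] | frozenset[str] = frozenset(),
    max_unpermitted_run: int = 12,
) -> Dataset:
    """Drop horses excluded by the program's geographic rules.

    A horse is excluded if (a) any continuous run of >= ``max_unpermitted_run``
    residency months has darting_permitted false, or (b) it is a resident of
    a configured excluded area (registry herd area or any residency record).
    Idempotent; returns a new Dataset.
    """
    excluded_areas = set(excluded_areas)
    excluded_ids: set[str] = set()

    in_excluded = ds.horses["herd_area"].isin(excluded_areas)
    excluded_ids |= set(ds.horses.loc[in_excluded, "horse_id"])
    if len(ds.residency):
        res_excl = ds.residency["herd_area"].isin(excluded_areas)
        excluded_ids |= set(ds.residency.loc[res_excl, "horse_id"])

    for hid, grp in ds.residency.groupby("horse_id"):
        not_ok = grp.loc[~grp["darting_permitted"]]
        if not_ok.empty:
            continue
        months = (not_ok["year"] * 12 + not_ok["month"]).tolist()
        if any(r >= max_unpermitted_run for r in _consecutive_runs(months)):
            excluded_ids.add(hid)

    keep = ~ds.horses["horse_id"].isin(excluded_ids)
    out = Dataset(
        horses=ds.horses.loc[keep].reset_index(drop=True),
        vaccinations=ds.vaccinations.loc[
            ~ds.vaccinations["horse_id"].isin(excluded_ids)
        ].reset_index(drop=True),
        foalings=ds.foalings.loc[
            ~ds.foalings["dam_id"].isin(excluded_ids)
        ].reset_index(drop=True),
        lesions=ds.lesions.loc[
            ~ds.lesions["horse_id"].isin(excluded_ids)
        ].reset_index(drop=True),
        residency=ds.residency.loc[
            ~ds.residency["horse_id"].isin(excluded_ids)
        ].reset_index(drop=True),
    )
    return out


def _first_observation_month(ds: Dataset, hid: str, w: StudyWindow) -> int | None:
    """Earliest month the horse appears in any event or residency table."""
    candidates: list[int] = []
    v = ds.vaccinations.loc[ds.vaccinations["horse_id"] == hid, "date"]
    candidates += [w.month_of(d.date()) for d in v]
    f = ds.foalings.loc[ds.foalings["dam_id"] == hid, "birth_date"]
    candidates += [w.month_of(d.date()) for d in f]
    le = ds.lesions.loc[ds.lesions["horse_id"] == hid, "first_observed"]
    candidates += [w.month_of(d.date()) for d in le]
    r = ds.residency.loc[ds.residency["horse_id"] == hid]
    candidates += [w.index_of(int(y), int(m)) for y, m in zip(r["year"], r["month"])]
    return min(candidates) if candidates else None


def activity_periods(ds: Dataset, w: StudyWindow) -> pd.DataFrame:
    """Enrollment interval per female: (horse_id, first_month, last_month).

    first_month = max(window start, birth month) when the date of birth is
    known, else the first month the mare appears in any table (fallback:
    window start).  last_month = window end, truncated at the death/removal
    month.  Females whose interval is empty (e.g. died pre-window) get no
    row.
    """
    rows = []
    females = ds.horses.loc[ds.horses["sex"] == "female"]
    for _, h in females.iterrows():
        if pd.notna(h["dob"]) and h["dob_known"]:
            first = max(1, w.month_of(h["dob"].date()))
        else:
            obs = _first_observation_month(ds, h["horse_id"], w)
            first = max(1, obs) if obs is not None else 1
        last = w.n_months
        if h["status"] in {"removed", "deceased"} and pd.notna(h["status_date"]):
            last = min(last, w.month_of(h["status_date"].date()))
        if first <= last and first <= w.n_months and last >= 1:
            rows.append(
                {"horse_id": h["horse_id"], "first_month": first, "last_month": last}
            )
    return pd.DataFrame(rows, columns=["horse_id", "first_month", "last_month"])


def build_panel(ds: Dataset, w: StudyWindow) -> pd.DataFrame:
    """One row per retained female per active month.

    Exclusions are the caller's responsibility (see
    :func:`apply_exclusions`); the panel includes every female in the
    dataset it is given.
    """
    periods = activity_periods(ds, w)
    horses = ds.horses.set_index("horse_id")
    res_area = {
        (hid, int(y), int(m)): area
        for hid, y, m, area in zip(
            ds.residency["horse_id"], ds.residency["year"],
            ds.residency["month"], ds.residency["herd_area"],
        )
    }

    rows = []
    for _, p in periods.iterrows():
        hid = p["horse_id"]
        h = horses.loc[hid]
        dob = h["dob"].date() if pd.notna(h["dob"]) else None
        foalings = ds.foalings.loc[ds.foalings["dam_id"] == hid]
        intervals = _gestation_intervals(foalings, w)
        lesions = ds.lesions.loc[ds.lesions["horse_id"] == hid]
        lesion_spans: dict[str, list[tuple[int, int]]] = {"granuloma": [], "abscess": []}
        for _, le in lesions.iterrows():
            start = w.month_of(le["first_observed"].date())
            end = (
                w.month_of(le["resolved"].date())
                if pd.notna(le["resolved"])
                else w.n_months
            )
            lesion_spans.setdefault(le["lesion_type"], []).append((start, end))

        for t in range(int(p["first_month"]), int(p["last_month"]) + 1):
            ms = w.month_start(t)
            pregnant = any(c <= t <= b for c, b in intervals)
            conceived = any(t == c for c, _ in intervals)
            foaled = any(t == b for _, b in intervals)
            rows.append({
                "horse_id": hid,
                "month_index": t,
                "mature": maturity_status(dob, bool(h["dob_known"]), t, w) == "mature",
                "pregnant": pregnant,
                "conceived": conceived,
                "foaled": foaled,
                "herd_area": res_area.get((hid, ms.year, ms.month), h["herd_area"]),
                "granuloma_active": any(s <= t <= e for s, e in lesion_spans["granuloma"]),
                "abscess_active": any(s <= t <= e for s, e in lesion_spans["abscess"]),
            })
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)
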