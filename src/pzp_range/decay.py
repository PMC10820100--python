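"""Cumulative vaccination coverage under rectangular efficacy windows.

Field data cannot reveal how long a pZP dose stays contraceptively active,
so coverage is computed under a sweep of efficacy scenarios: a vaccination
given in month ``m`` counts as active for months ``m .. m+W-1`` (window
``W`` of 6, 12 or 18 months) or for every month from ``m`` on (permanent
efficacy).  A mare first vaccinated in study month 8 under the 6-month
scenario therefore carries a count of 1 for months 8-13 and reverts to 0
in month 14.

The per-month herd summary is the mean active count over mares with a
mature panel row that month; immature mares are excluded from numerator
and denominator alike.  Pre-window vaccinations participate with their
true (non-positive) month indices, so permanent-efficacy counts include a
mare's pre-program history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .data_model import Dataset, StudyWindow

__all__ = [
    "EfficacyScenario",
    "PERMANENT",
    "DEFAULT_SCENARIOS",
    "active_count",
    "coverage_series",
    "scenario_sweep",
    "vaccination_months",
]


@dataclass(frozen=True)
class EfficacyScenario:
    """Rectangular efficacy window; ``window_months=None`` means permanent."""

    window_months: int | None

    def __post_init__(self) -> None:
        if self.window_months is not None and self.window_months < 1:
            raise ValueError("window_months must be positive or None")

    @property
    def permanent(self) -> bool:
        return self.window_months is None

    @property
    def label(self) -> str:
        return "permanent" if self.permanent else f"{self.window_months}m"

    @classmethod
    def parse(cls, token: str | int | None) -> "EfficacyScenario":
        if token is None:
            return cls(None)
        if isinstance(token, int):
            return cls(token)
        t = str(token).strip().lower().rstrip("m")
        if t in {"permanent", "inf", "none", ""}:
            return cls(None)
        return cls(int(t))


PERMANENT = EfficacyScenario(None)
DEFAULT_SCENARIOS = (
    PERMANENT,
    EfficacyScenario(18),
    EfficacyScenario(12),
    EfficacyScenario(6),
)


def active_count(
    vaccination_months: Sequence[int], t: int, s: EfficacyScenario
) -> int:
    """Number of vaccinations still active in month ``t``.

    A vaccination in month ``m`` is active when ``m <= t`` (permanent) or
    ``m <= t <= m + W - 1`` (window ``W``); the administration month is
    inside the window.
    """
    if s.permanent:
        return sum(1 for m in vaccination_months if m <= t)
    w = s.window_months
    return sum(1 for m in vaccination_months if m <= t <= m + w - 1)


def vaccination_months(ds: Dataset, w: StudyWindow) -> dict[str, list[int]]:
    """Sorted confirmed-vaccination month indices per mare (pre-window
    months are kept, as negative/zero indices)."""
    v = ds.vaccinations.loc[ds.vaccinations["confirmed"]]
    out: dict[str, list[int]] = {}
    for hid, d in zip(v["horse_id"], v["date"]):
        out.setdefault(hid, []).append(w.month_of(d.date()))
    return {hid: sorted(ms) for hid, ms in out.items()}


def coverage_series(
    panel: pd.DataFrame,
    ds: Dataset,
    s: EfficacyScenario,
    w: StudyWindow,
) -> pd.DataFrame:
    """Mean active vaccinations per mature mare, by study month.

    Returns a frame with columns (month_index, scenario, mature_mares,
    active_total, mean_per_mature_mare); the mean is NaN for months with no
    mature mare.
    """
    months_by_mare = vaccination_months(ds, w)
    mature = panel.loc[panel["mature"], ["horse_id", "month_index"]]
    rows = []
    grouped = {
        t: grp["horse_id"].tolist() for t, grp in mature.groupby("month_index")
    }
    for t in w.months:
        mares = grouped.get(t, [])
        total = sum(active_count(months_by_mare.get(hid, ()), t, s) for hid in mares)
        rows.append({
            "month_index": t,
            "scenario": s.label,
            "mature_mares": len(mares),
            "active_total": total,
            "mean_per_mature_mare": total / len(mares) if mares else math.nan,
        })
    return pd.DataFrame(rows)


def scenario_sweep(
    panel: pd.DataFrame,
    ds: Dataset,
    w: StudyWindow,
    scenarios: Iterable[EfficacyScenario] = DEFAULT_SCENARIOS,
) -> pd.DataFrame:
    """Coverage series for every scenario, concatenated long-form."""
    frames = [coverage_series(panel, ds, s, w) for s in scenarios]
    return pd.concat(frames, ignore_index=True)
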