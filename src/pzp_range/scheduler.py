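"""Darting-protocol state machine.

The field protocol for native pZP delivery is a primer/booster course:

* a never-treated mare older than eight months receives a primer (P);
* a booster (B) follows at least 14 days after the primer (or repeat
  primer), and thereafter boosters recur on an 8–12 month cycle;
* the course restarts with a repeat primer (RP) if the mare was primed but
  never boosted for >= 12 months, if >= 14 months elapsed between boosters,
  or if she foaled / appeared obviously pregnant after her last course
  start.

Given one mare's confirmed treatment history and a query date,
:func:`next_action` returns the action the protocol prescribes on that
date, with a machine-readable reason code.  It is a pure function: the
daily "mares requiring vaccination" report is just this function mapped
over the herd.

Intervals given in months are calendar months (dateutil arithmetic);
intervals given in weeks/days are exact day counts.  Unconfirmed deliveries
(misfires) are invisible here: the mare's record is as if the dart never
flew, so she is simply prescribed the same action again.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

from dateutil.relativedelta import relativedelta

__all__ = [
    "TreatmentHistory",
    "ActionRequirement",
    "ChronologyError",
    "is_eligible",
    "next_action",
    "ELIGIBILITY_AGE_MONTHS",
    "BOOSTER_MIN_DAYS",
    "PRIMED_UNBOOSTED_EXPIRY_MONTHS",
    "BOOSTER_GAP_EXPIRY_MONTHS",
    "ANNUAL_BOOSTER_DUE_MONTHS",
]

ELIGIBILITY_AGE_MONTHS = 8
BOOSTER_MIN_DAYS = 14            # ">= 2 weeks post-P or RP"
PRIMED_UNBOOSTED_EXPIRY_MONTHS = 12
BOOSTER_GAP_EXPIRY_MONTHS = 14
ANNUAL_BOOSTER_DUE_MONTHS = 8    # next annual booster due from 8 months on

PRIMER_ACTIONS = {"P", "RP"}


class ChronologyError(ValueError):
    """Query date precedes the mare's last recorded event."""


@dataclass(frozen=True)
class TreatmentEvent:
    date: date
    action: str  # P, RP or B


@dataclass
class TreatmentHistory:
    """Confirmed treatments and reproductive reset triggers for one mare.

    ``events`` holds only confirmed deliveries, ascending by date.
    ``reproductive_resets`` holds dates at which a foaling or an obvious
    pregnancy was observed; a reset is consumed by the next course start
    (P or RP), so only resets after the last course start still trigger.
    """

    events: list[TreatmentEvent] = field(default_factory=list)
    reproductive_resets: list[date] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.date)
        self.reproductive_resets = sorted(self.reproductive_resets)
        for e in self.events:
            if e.action not in {"P", "RP", "B"}:
                raise ValueError(f"unknown action {e.action!r}")

    @property
    def last_event(self) -> TreatmentEvent | None:
        return self.events[-1] if self.events else None

    @property
    def last_course_start(self) -> date | None:
        starts = [e.date for e in self.events if e.action in PRIMER_ACTIONS]
        return starts[-1] if starts else None

    def pending_reset(self, as_of: date | None = None) -> date | None:
        """Latest unconsumed reset trigger on or before ``as_of``, if any."""
        anchor = self.last_course_start
        live = [
            d
            for d in self.reproductive_resets
            if (anchor is None or d > anchor) and (as_of is None or d <= as_of)
        ]
        return live[-1] if live else None

    def with_event(self, d: date, action: str) -> "TreatmentHistory":
        return TreatmentHistory(
            self.events + [TreatmentEvent(d, action)], list(self.reproductive_resets)
        )


@dataclass(frozen=True)
class ActionRequirement:
    action: str  # "P", "B", "RP" or "none"
    reason: str

    def __post_init__(self) -> None:
        none_reasons = {"not_eligible", "up_to_date"}
        if (self.action == "none") != (self.reason in none_reasons):
            raise ValueError(f"inconsistent requirement {self.action}/{self.reason}")


def is_eligible(dob: date | None, query: date) -> bool:
    """True iff the mare is older than eight months on the query date.

    Females with no recorded date of birth are treated as adults of unknown
    age and are always eligible.
    """
    if dob is None:
        return True
    return query > dob + relativedelta(months=ELIGIBILITY_AGE_MONTHS)


def next_action(h: TreatmentHistory, dob: date | None, query: date) -> ActionRequirement:
    """Prescribe the protocol action for one mare on ``query``.

    Rule precedence, top wins: chronology guard; eligibility; reproductive
    reset; never treated; primed-but-never-boosted expiry (>= 12 months);
    booster-gap expiry (>= 14 months since the last booster); booster due
    (>= 14 days after a primer, or >= 8 months after the last booster);
    otherwise up to date.  A booster given 12-14 months after the previous
    one is a late booster, not a restart: only the >= 14-month gap restarts
    the course.
    """
    last = h.last_event
    if last is not None and query < last.date:
        raise ChronologyError(
            f"query {query} precedes last recorded event on {last.date}"
        )
    if not is_eligible(dob, query):
        return ActionRequirement("none", "not_eligible")
    if not h.events:
        return ActionRequirement("P", "never_treated")
    if h.pending_reset(as_of=query) is not None:
        return ActionRequirement("RP", "reproductive_reset")

    assert last is not None
    if last.action in PRIMER_ACTIONS:
        if query >= last.date + relativedelta(months=PRIMED_UNBOOSTED_EXPIRY_MONTHS):
            return ActionRequirement("RP", "primed_unboosted_expired")
        if query >= last.date + timedelta(days=BOOSTER_MIN_DAYS):
            return ActionRequirement("B", "booster_due")
        return ActionRequirement("none", "up_to_date")

    # last action was a booster
    if query >= last.date + relativedelta(months=BOOSTER_GAP_EXPIRY_MONTHS):
        return ActionRequirement("RP", "booster_gap_expired")
    if query >= last.date + relativedelta(months=ANNUAL_BOOSTER_DUE_MONTHS):
        return ActionRequirement("B", "booster_due")
    return ActionRequirement("none", "up_to_date")
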