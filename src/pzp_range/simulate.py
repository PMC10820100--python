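"""Individual-based monthly-step herd simulator.

Emulates the data-generating process behind a remote-darting
immunocontraception program on a free-roaming horse range: seasonal
conception with a 354-day gestation, age-structured maturity and
mortality, opportunistic darting driven by the primer/booster protocol in
:mod:`pzp_range.scheduler`, misfires, injection-site lesions, and
herd-area residency with a darting-permission boundary.  Its purpose is to
exercise every pipeline stage against a known ground truth; it makes no
claim to demographic realism beyond the rates in :class:`SimulationConfig`.

Within a month, steps run in a fixed order: mortality, births due that
month, residency/darting, conception.  Event dates get day resolution by
uniform draws within the month, so the 354-day gestation and the
protocol's day- and month-based intervals are exact.  The vaccine acts as
a rectangular hazard multiplier: a confirmed treatment in month ``m``
multiplies the conception hazard by ``1 - e`` for months ``m .. m+W-1``.

A single seeded generator drives every draw in a deterministic order, so
equal seeds give byte-identical datasets.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from . import scheduler
from .data_model import Dataset, StudyWindow, make_table

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigError",
    "simulate",
    "seasonal_hazard",
    "recovery_experiment",
]

# Monthly baseline conception probability per at-risk mare, Jan..Dec;
# spring peak in May, quiet late autumn/winter.
DEFAULT_HAZARD = (
    0.01, 0.02, 0.05, 0.10, 0.15, 0.10, 0.05, 0.02, 0.01, 0.005, 0.005, 0.005,
)


class ConfigError(ValueError):
    """Simulation configuration is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """All rates, probabilities and sizes governing one synthetic herd."""

    seed: int = 0
    n_initial_females: int = 500
    n_initial_males: int = 100
    initial_age_mean_years: float = 6.0
    initial_age_max_years: float = 20.0
    dob_known_prob: float = 0.9
    initial_pregnant_prob: float = 0.25
    monthly_conception_hazard: tuple = DEFAULT_HAZARD
    gestation_days: int = 354
    vaccine_efficacy: float = 0.9
    protection_window_months: int = 12
    foal_monthly_mortality: float = 0.045
    adult_monthly_mortality: float = 0.005
    foal_removal_monthly_prob: float = 0.001
    foal_male_prob: float = 0.49
    foal_female_prob: float = 0.49
    darting_encounter_prob: float = 0.15
    darting_start_index: int = 4        # program approval: study month 4
    misfire_prob: float = 0.05
    granuloma_prob: float = 0.003
    abscess_prob: float = 0.010
    lesion_mean_duration_months: float = 2.0
    excluded_area_prob: float = 0.05    # home area on the range edge
    unpermitted_area_prob: float = 0.10 # home area beyond the darting boundary
    boundary_cross_prob: float = 0.05   # monthly off-home-side observation
    annual_policy_interval_months: int | None = None
    window: StudyWindow = field(default_factory=StudyWindow)

    def validate(self) -> None:
        probs = {
            "dob_known_prob": self.dob_known_prob,
            "initial_pregnant_prob": self.initial_pregnant_prob,
            "vaccine_efficacy": self.vaccine_efficacy,
            "foal_monthly_mortality": self.foal_monthly_mortality,
            "adult_monthly_mortality": self.adult_monthly_mortality,
            "foal_removal_monthly_prob": self.foal_removal_monthly_prob,
            "darting_encounter_prob": self.darting_encounter_prob,
            "misfire_prob": self.misfire_prob,
            "granuloma_prob": self.granuloma_prob,
            "abscess_prob": self.abscess_prob,
            "excluded_area_prob": self.excluded_area_prob,
            "unpermitted_area_prob": self.unpermitted_area_prob,
            "boundary_cross_prob": self.boundary_cross_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if len(self.monthly_conception_hazard) != 12:
            raise ConfigError("monthly_conception_hazard must have 12 entries")
        if any(not 0.0 <= h <= 1.0 for h in self.monthly_conception_hazard):
            raise ConfigError("conception hazards must be in [0, 1]")
        if self.foal_male_prob + self.foal_female_prob > 1.0 + 1e-12:
            raise ConfigError("foal sex probabilities exceed 1")
        if self.gestation_days < 1:
            raise ConfigError("gestation_days must be positive")
        if self.protection_window_months < 1:
            raise ConfigError("protection_window_months must be positive")
        if (
            self.annual_policy_interval_months is not None
            and self.annual_policy_interval_months < 1
        ):
            raise ConfigError("annual_policy_interval_months must be positive")
        if self.n_initial_females < 0 or self.n_initial_males < 0:
            raise ConfigError("population sizes must be non-negative")


@dataclass
class GroundTruth:
    """What the simulator knows that the emitted tables do not say."""

    config: SimulationConfig
    protection_intervals: dict[str, list[tuple[int, int]]]
    conceptions: pd.DataFrame   # horse_id, date, month_index, protected
    monthly: pd.DataFrame       # per-month at-risk/protection/conception totals


def seasonal_hazard(month_of_year: int, cfg: SimulationConfig) -> float:
    """Baseline conception probability for a calendar month (1..12)."""
    if not 1 <= month_of_year <= 12:
        raise ValueError(f"month_of_year must be 1..12, got {month_of_year}")
    return float(cfg.monthly_conception_hazard[month_of_year - 1])


@dataclass
class _Horse:
    horse_id: str
    sex: str
    dob: date
    dob_known: bool
    home_area: str
    dam_id: str | None = None
    alive: bool = True
    status: str = "living"
    status_date: date | None = None
    history: scheduler.TreatmentHistory = field(
        default_factory=scheduler.TreatmentHistory
    )
    protection: list[tuple[int, int]] = field(default_factory=list)
    due_date: date | None = None
    conception_date: date | None = None
    last_treatment_month: int | None = None
    last_foaling_month: int | None = None
    is_window_foal: bool = False


def _uniform_day(rng: np.random.Generator, year: int, month: int) -> date:
    return date(year, month, int(rng.integers(1, calendar.monthrange(year, month)[1] + 1)))


def _age_months(dob: date, on: date) -> int:
    return (on.year - dob.year) * 12 + (on.month - dob.month) - (on.day < dob.day)


def simulate(cfg: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Run one herd and emit the five analysis tables plus ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    w = cfg.window
    W = cfg.protection_window_months
    e = cfg.vaccine_efficacy
    start = w.month_start(1)

    horses: dict[str, _Horse] = {}
    vaccination_rows: list[dict] = []
    foaling_rows: list[dict] = []
    lesion_rows: list[dict] = []
    residency_rows: list[dict] = []
    conception_log: list[dict] = []
    monthly_log: list[dict] = []
    counters = {"event": 0, "foal": 0}

    def draw_area() -> str:
        u = rng.random()
        if u < cfg.excluded_area_prob:
            return "edge"
        if u < cfg.excluded_area_prob + cfg.unpermitted_area_prob:
            return "south"
        return "main"

    def initial_age_months() -> int:
        a = rng.exponential(cfg.initial_age_mean_years)
        a = min(a, cfg.initial_age_max_years)
        return max(13, int(round(a * 12)))  # initial animals are adults

    for i in range(cfg.n_initial_females + cfg.n_initial_males):
        sex = "female" if i < cfg.n_initial_females else "male"
        hid = f"h{i + 1:05d}"
        months_old = initial_age_months()
        dob = start - timedelta(days=int(months_old * 30.44))
        horses[hid] = _Horse(
            horse_id=hid,
            sex=sex,
            dob=dob,
            dob_known=bool(rng.random() < cfg.dob_known_prob),
            home_area=draw_area(),
        )

    # Pre-window conceptions so year-one births carry the seasonal shape.
    hazard = np.asarray(cfg.monthly_conception_hazard, dtype=float)
    for h in horses.values():
        if h.sex != "female":
            continue
        if rng.random() >= cfg.initial_pregnant_prob:
            continue
        back = int(rng.choice(12, p=hazard / hazard.sum()))
        # conception in one of the 12 pre-window months, weighted seasonally
        y, m = divmod((start.year - 1) * 12 + back, 12)
        conc = _uniform_day(rng, y, m + 1)
        if conc >= start or conc + timedelta(days=cfg.gestation_days) < start:
            continue  # conception must be pre-window, the birth inside it
        if _age_months(h.dob, conc) <= 12:
            continue  # dam must already have been mature at conception
        h.conception_date = conc
        h.due_date = conc + timedelta(days=cfg.gestation_days)

    def record_death(h: _Horse, d: date) -> None:
        h.alive = False
        h.status = "deceased"
        h.status_date = d

    def protected_in(h: _Horse, t: int) -> bool:
        return any(a <= t <= b for a, b in h.protection)

    for t in w.months:
        ms = w.month_start(t)
        # --- mortality ---------------------------------------------------
        for h in list(horses.values()):
            if not h.alive:
                continue
            young = _age_months(h.dob, ms) < 12
            p = cfg.foal_monthly_mortality if young else cfg.adult_monthly_mortality
            if rng.random() < p:
                record_death(h, _uniform_day(rng, ms.year, ms.month))
            elif young and h.is_window_foal and rng.random() < cfg.foal_removal_monthly_prob:
                h.alive = False
                h.status = "removed"
                h.status_date = _uniform_day(rng, ms.year, ms.month)

        # --- births due this month ---------------------------------------
        for h in list(horses.values()):
            if h.sex != "female" or h.due_date is None:
                continue
            if w.month_of(h.due_date) != t:
                continue
            if not h.alive:
                h.due_date = h.conception_date = None
                continue
            counters["foal"] += 1
            fid = f"f{counters['foal']:05d}"
            u = rng.random()
            if u < cfg.foal_male_prob:
                fsex, hsex = "male", "male"
            elif u < cfg.foal_male_prob + cfg.foal_female_prob:
                fsex, hsex = "female", "female"
            else:
                fsex = "unknown"
                hsex = "female" if rng.random() < 0.5 else "male"
            foal = _Horse(
                horse_id=fid,
                sex=hsex,
                dob=h.due_date,
                dob_known=True,
                home_area=h.home_area,
                dam_id=h.horse_id,
                is_window_foal=True,
            )
            horses[fid] = foal
            foaling_rows.append({
                "foal_id": fid,
                "dam_id": h.horse_id,
                "birth_date": h.due_date,
                "foal_sex": fsex,
                "death_date": None,
                "removed_date": None,
            })
            h.history.reproductive_resets.append(h.due_date)
            h.last_foaling_month = t
            h.due_date = h.conception_date = None

        # --- residency and darting ---------------------------------------
        for h in horses.values():
            if not h.alive or h.sex != "female":
                continue
            crossed = rng.random() < cfg.boundary_cross_prob
            if h.home_area == "south":
                area = "main" if crossed else "south"
            elif h.home_area == "main":
                area = "south" if crossed else "main"
            else:
                area = "edge"
            permitted = area != "south"
            residency_rows.append({
                "horse_id": h.horse_id,
                "year": ms.year,
                "month": ms.month,
                "herd_area": area,
                "darting_permitted": permitted,
            })
            if t < cfg.darting_start_index or not permitted or area == "edge":
                continue
            interval = cfg.annual_policy_interval_months
            if (
                interval is not None
                and h.last_treatment_month is not None
                and t < h.last_treatment_month + interval
            ):
                continue  # fixed-interval policy: not due yet
            if rng.random() >= cfg.darting_encounter_prob:
                continue
            d = _uniform_day(rng, ms.year, ms.month)
            last = h.history.last_event
            if last is not None and d < last.date:
                d = last.date
            req = scheduler.next_action(
                h.history, h.dob if h.dob_known else None, d
            )
            if req.action == "none":
                continue
            counters["event"] += 1
            confirmed = rng.random() >= cfg.misfire_prob
            vaccination_rows.append({
                "event_id": f"v{counters['event']:05d}",
                "horse_id": h.horse_id,
                "date": d,
                "action": req.action,
                "confirmed": confirmed,
            })
            if not confirmed:
                continue
            h.history = h.history.with_event(d, req.action)
            h.protection.append((t, t + W - 1))
            h.last_treatment_month = t
            for lesion_type, p_lesion in (
                ("granuloma", cfg.granuloma_prob),
                ("abscess", cfg.abscess_prob),
            ):
                if rng.random() < p_lesion:
                    onset = d + timedelta(days=int(rng.integers(3, 22)))
                    dur = rng.exponential(cfg.lesion_mean_duration_months)
                    resolved = onset + timedelta(days=int(dur * 30.44) + 7)
                    lesion_rows.append({
                        "horse_id": h.horse_id,
                        "event_id": f"v{counters['event']:05d}",
                        "lesion_type": lesion_type,
                        "first_observed": onset,
                        "resolved": resolved,
                    })

        # --- conception ---------------------------------------------------
        base = seasonal_hazard(ms.month, cfg)
        n_at_risk = n_prot = n_conc = n_conc_prot = 0
        hz_sum = hz_prot = 0.0
        for h in horses.values():
            if not h.alive or h.sex != "female":
                continue
            if h.due_date is not None:
                continue
            if _age_months(h.dob, ms) <= 12:
                continue  # mature only: strictly older than one year
            if h.last_foaling_month is not None and h.last_foaling_month >= t:
                continue  # post-partum gap: available from the next month
            prot = protected_in(h, t)
            p = base * (1.0 - e) if prot else base
            n_at_risk += 1
            hz_sum += base  # counterfactual (untreated) hazard
            if prot:
                n_prot += 1
                hz_prot += base
            if rng.random() < p:
                conc = _uniform_day(rng, ms.year, ms.month)
                h.conception_date = conc
                h.due_date = conc + timedelta(days=cfg.gestation_days)
                n_conc += 1
                n_conc_prot += int(prot)
                conception_log.append({
                    "horse_id": h.horse_id,
                    "date": conc,
                    "month_index": t,
                    "protected": prot,
                })
        monthly_log.append({
            "month_index": t,
            "at_risk": n_at_risk,
            "at_risk_protected": n_prot,
            "hazard_sum": hz_sum,
            "hazard_sum_protected": hz_prot,
            "conceptions": n_conc,
            "conceptions_protected": n_conc_prot,
        })

    # --- propagate foal fates into the foaling table ----------------------
    fate = {
        h.horse_id: (h.status, h.status_date)
        for h in horses.values()
        if h.is_window_foal and h.status != "living"
    }
    for row in foaling_rows:
        status, d = fate.get(row["foal_id"], ("living", None))
        if status == "deceased":
            row["death_date"] = d
        elif status == "removed":
            row["removed_date"] = d

    horse_rows = [
        {
            "horse_id": h.horse_id,
            "sex": h.sex,
            "dob": h.dob if h.dob_known else None,
            "dob_known": h.dob_known,
            "status": h.status,
            "status_date": h.status_date,
            "herd_area": h.home_area,
            "dam_id": h.dam_id,
        }
        for h in horses.values()
    ]
    ds = Dataset(
        horses=make_table("horses", horse_rows),
        vaccinations=make_table("vaccinations", vaccination_rows),
        foalings=make_table("foalings", foaling_rows),
        lesions=make_table("lesions", lesion_rows),
        residency=make_table("residency", residency_rows),
    )
    gt = GroundTruth(
        config=cfg,
        protection_intervals={
            h.horse_id: list(h.protection) for h in horses.values() if h.protection
        },
        conceptions=pd.DataFrame(
            conception_log, columns=["horse_id", "date", "month_index", "protected"]
        ),
        monthly=pd.DataFrame(monthly_log),
    )
    return ds, gt


def recovery_experiment(
    cfg: SimulationConfig,
    replicates: int = 20,
    burn_in_months: int = 16,
) -> dict:
    """Simulate repeatedly and measure how well the pipeline recovers the
    configured truth.

    Per replicate (seeds ``cfg.seed + r``), runs the full pipeline
    (simulate -> exclusions -> panel -> coverage) and records

    * the 12-month-window coverage plateau: the mean of the
      mean-vaccinations-per-mature-mare series over the post-burn-in months;
    * the realised conception suppression: one minus observed conceptions
      over the counterfactual untreated expectation (the summed baseline
      hazard of the same at-risk mare-months);
    * the fertility-control-index prediction for that run: vaccine efficacy
      times the hazard-weighted protected fraction of at-risk mare-months.

    Returns per-replicate arrays plus means and standard errors.
    """
    from .panel import apply_exclusions, build_panel
    from .decay import EfficacyScenario, coverage_series

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    w = cfg.window
    post = [t for t in w.months if t > burn_in_months]
    plateaus, reductions, fci_preds, births = [], [], [], []
    for r in range(replicates):
        rcfg = replace(cfg, seed=cfg.seed + r)
        ds, gt = simulate(rcfg)
        ds = apply_exclusions(ds, excluded_areas={"edge"})
        panel = build_panel(ds, w)
        cov = coverage_series(
            panel, ds, EfficacyScenario(cfg.protection_window_months), w
        )
        plateaus.append(
            float(cov.loc[cov["month_index"].isin(post), "mean_per_mature_mare"].mean())
        )
        m = gt.monthly.loc[gt.monthly["month_index"].isin(post)]
        hz = float(m["hazard_sum"].sum())
        hz_prot = float(m["hazard_sum_protected"].sum())
        conc = float(m["conceptions"].sum())
        reductions.append(1.0 - conc / hz if hz > 0 else float("nan"))
        fci_preds.append(cfg.vaccine_efficacy * (hz_prot / hz) if hz > 0 else float("nan"))
        births.append(int(len(ds.foalings)))

    def _summ(xs: list[float]) -> dict:
        a = np.asarray(xs, dtype=float)
        return {
            "values": a.tolist(),
            "mean": float(np.nanmean(a)),
            "se": float(np.nanstd(a, ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0,
        }

    return {
        "replicates": replicates,
        "burn_in_months": burn_in_months,
        "plateau_mean_vaccinations": _summ(plateaus),
        "conception_reduction": _summ(reductions),
        "fci_predicted": _summ(fci_preds),
        "births": _summ([float(b) for b in births]),
    }
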