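"""Published Virginia Range program summaries and their verification.

The program's published annual report prints aggregate counts — mature and
immature mares, mares vaccinated, treatments given, lesion occurrences,
and foal births/deaths/removals by year (2019–2022) — together with
derived percentages (herd coverage, lesion prevalence, year-on-year
foaling reduction, conception proportion, foal mortality).  The counts are
shipped here as small CSV fixtures; :func:`verify` recomputes every
derived percentage from the counts with the functions in
:mod:`pzp_range.summaries` and compares each against the printed value at
its printed precision.  Any disagreement indicates a regression in the
summary arithmetic or its conventions (e.g. the combined mature+immature
lesion denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .summaries import (
    conception_proportion,
    foaling_reduction,
    lesion_prevalence_pct,
    percent_mature_vaccinated,
)

__all__ = ["load_published_counts", "compute_derived", "verify", "PRINTED_VALUES"]

FIXTURE_FILES = ("annual_treatments.csv", "annual_lesions.csv", "annual_foals.csv")

# Derived values as printed in the published report, with a comparison
# tolerance of half a unit in the last printed digit.
PRINTED_VALUES: dict[str, tuple[float, float]] = {
    "pct_mature_vaccinated_2019": (49.7, 0.05),
    "pct_mature_vaccinated_2020": (59.6, 0.05),
    "pct_mature_vaccinated_2022": (64.0, 0.5),
    "granuloma_prevalence_2019": (0.00, 0.005),
    "granuloma_prevalence_2020": (0.06, 0.005),
    "granuloma_prevalence_2021": (0.27, 0.005),
    "granuloma_prevalence_2022": (0.59, 0.005),
    "abscess_prevalence_2019": (0.58, 0.005),
    "abscess_prevalence_2020": (0.96, 0.005),
    "abscess_prevalence_2021": (1.20, 0.005),
    "abscess_prevalence_2022": (1.28, 0.005),
    "foaling_reduction_2021_vs_2020": (45.3, 0.05),
    "foaling_reduction_2022_vs_2020": (58.0, 0.5),
    "conception_pct_2019": (31.9, 0.05),
    "conception_pct_2020": (14.9, 0.05),
    "conception_pct_2021": (10.3, 0.05),
    "foal_mortality_pct_2022": (63.0, 0.5),
}


def load_published_counts(fixture_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Load the annual count tables, indexed by year.

    Reads from ``fixture_dir`` when given (all three files must exist),
    otherwise from the copies packaged with the library.
    """
    frames: dict[str, pd.DataFrame] = {}
    for fname in FIXTURE_FILES:
        key = fname.removesuffix(".csv")
        if fixture_dir is not None:
            p = Path(fixture_dir) / fname
            if not p.exists():
                raise FileNotFoundError(f"missing published-count fixture: {p}")
            df = pd.read_csv(p)
        else:
            with resources.files("pzp_range.data").joinpath(fname).open("rb") as fh:
                df = pd.read_csv(fh)
        frames[key] = df.set_index("year")
    return frames


def compute_derived(counts: dict[str, pd.DataFrame]) -> dict[str, float]:
    """Recompute every printed derived percentage from the raw counts."""
    tr = counts["annual_treatments"]
    le = counts["annual_lesions"]
    fo = counts["annual_foals"]
    births = {
        int(y): int(r["births_male"] + r["births_female"] + r["births_unknown"])
        for y, r in fo.iterrows()
    }
    deaths = {
        int(y): int(r["dead_male"] + r["dead_female"] + r["dead_unknown"])
        for y, r in fo.iterrows()
    }
    mature_totals = {int(y): int(r["mature_total"]) for y, r in tr.iterrows()}

    out: dict[str, float] = {}
    for y in tr.index:
        out[f"pct_mature_vaccinated_{y}"] = percent_mature_vaccinated(
            int(tr.loc[y, "mature_vaccinated"]), int(tr.loc[y, "mature_total"])
        )
        total_treatments = int(
            tr.loc[y, "mature_treatments"] + tr.loc[y, "immature_treatments"]
        )
        out[f"granuloma_prevalence_{y}"] = lesion_prevalence_pct(
            int(le.loc[y, "granulomas"]), total_treatments
        )
        out[f"abscess_prevalence_{y}"] = lesion_prevalence_pct(
            int(le.loc[y, "abscesses"]), total_treatments
        )
    out["foaling_reduction_2021_vs_2020"] = foaling_reduction(births, 2020, 2021)
    out["foaling_reduction_2022_vs_2020"] = foaling_reduction(births, 2020, 2022)
    for y in (2019, 2020, 2021):
        out[f"conception_pct_{y}"] = conception_proportion(births, mature_totals, y)
    for y, b in births.items():
        out[f"foal_mortality_pct_{y}"] = round(100.0 * deaths[y] / b, 1) if b else float("nan")
    return out


@dataclass(frozen=True)
class VerificationRow:
    name: str
    computed: float
    printed: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.printed) <= self.tolerance


def verify(fixture_dir: str | Path | None = None) -> list[VerificationRow]:
    """Recompute all printed derived values and compare; one row each."""
    derived = compute_derived(load_published_counts(fixture_dir))
    return [
        VerificationRow(name, derived[name], printed, tol)
        for name, (printed, tol) in PRINTED_VALUES.items()
    ]
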