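from datetime import date

import pytest

from pzp_range.data_model import Dataset, StudyWindow, make_table
from pzp_range.simulate import SimulationConfig, simulate


@pytest.fixture
def window() -> StudyWindow:
    return StudyWindow()


def build_dataset(horses=(), vaccinations=(), foalings=(), lesions=(), residency=()):
    """Assemble a schema-conforming Dataset from plain dicts."""
    return Dataset(
        horses=make_table("horses", horses),
        vaccinations=make_table("vaccinations", vaccinations),
        foalings=make_table("foalings", foalings),
        lesions=make_table("lesions", lesions),
        residency=make_table("residency", residency),
    )


def horse(hid, sex="female", dob=None, dob_known=None, status="living",
          status_date=None, herd_area="main", dam_id=None):
    return dict(
        horse_id=hid, sex=sex, dob=dob,
        dob_known=(dob is not None) if dob_known is None else dob_known,
        status=status, status_date=status_date, herd_area=herd_area,
        dam_id=dam_id,
    )


@pytest.fixture
def tiny_dataset() -> Dataset:
    """Three horses, two confirmed treatments, one foaling, one lesion."""
    return build_dataset(
        horses=[
            horse("m1", dob="2015-04-10"),
            horse("m2"),
            horse("f1", dob="2021-04-20", dam_id="m1"),
        ],
        vaccinations=[
            dict(event_id="v1", horse_id="m1", date="2019-05-01", action="P",
                 confirmed=True),
            dict(event_id="v2", horse_id="m1", date="2019-05-20", action="B",
                 confirmed=True),
        ],
        foalings=[
            dict(foal_id="f1", dam_id="m1", birth_date="2021-04-20",
                 foal_sex="female", death_date=None, removed_date=None),
        ],
        lesions=[
            dict(horse_id="m1", event_id="v1", lesion_type="abscess",
                 first_observed="2019-05-10", resolved="2019-07-15"),
        ],
        residency=[
            dict(horse_id="m1", year=2019, month=1, herd_area="main",
                 darting_permitted=True),
            dict(horse_id="m2", year=2019, month=1, herd_area="main",
                 darting_permitted=True),
        ],
    )


SIM_CONFIG = SimulationConfig(seed=11, n_initial_females=150, n_initial_males=20)


@pytest.fixture(scope="session")
def sim_result():
    """One medium simulated herd shared across the suite."""
    ds, gt = simulate(SIM_CONFIG)
    return SIM_CONFIG, ds, gt


@pytest.fixture(scope="session")
def sim_panel(sim_result):
    from pzp_range.panel import apply_exclusions, build_panel

    cfg, ds, _ = sim_result
    excluded = apply_exclusions(ds, excluded_areas={"edge"})
    return excluded, build_panel(excluded, cfg.window)
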