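import numpy as np
import pandas as pd
import pytest

from tagtelem import PeriodCalendar
from tagtelem.simulate import SimDesign, simulate_telemetry, small_design


@pytest.fixture(scope="session")
def calendar():
    return PeriodCalendar(2008, 6)


@pytest.fixture(scope="session")
def sections_fixture():
    """Four sections with unique areas and distinct receiver counts."""
    sections = pd.DataFrame([
        {"section_id": "S01", "n_receivers": 2, "area_ha": 1200.0,
         "north_arm_top": False, "west_arm_head": False,
         "south_arm_bottom": False, "trout_lake_outflow": False,
         "upper_north": False},
        {"section_id": "S02", "n_receivers": 1, "area_ha": 300.0,
         "north_arm_top": False, "west_arm_head": False,
         "south_arm_bottom": False, "trout_lake_outflow": True,
         "upper_north": False},
        {"section_id": "S07", "n_receivers": 1, "area_ha": 900.0,
         "north_arm_top": True, "west_arm_head": False,
         "south_arm_bottom": False, "trout_lake_outflow": False,
         "upper_north": True},
        {"section_id": "S08", "n_receivers": 2, "area_ha": 950.0,
         "north_arm_top": False, "west_arm_head": False,
         "south_arm_bottom": False, "trout_lake_outflow": False,
         "upper_north": True},
    ])
    receivers = pd.DataFrame(
        [{"receiver_id": f"R{s}{j}", "section_id": s}
         for s, k in zip(sections["section_id"], sections["n_receivers"])
         for j in range(k)])
    return sections, receivers


@pytest.fixture(scope="session")
def telemetry_bundle():
    """Full-size synthetic bundle with ground truth (built once)."""
    design = SimDesign(seed=20_080_401)
    return simulate_telemetry(design)


@pytest.fixture()
def tiny_encounters():
    from tagtelem.simulate import simulate_encounters
    return simulate_encounters(small_design(n_fish=3, n_years=1, seed=5))


def make_captures(rows):
    defaults = {"species": "BullTrout", "fork_length_mm": 650.0,
                "tag_life_days": 1239.0, "reward1": 100, "reward2": 10,
                "release_section": "S01"}
    out = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)
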