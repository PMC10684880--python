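import pandas as pd
import pytest

import sustdiet as sd
from sustdiet.io_cli import load_fcs_config


@pytest.fixture(scope="session")
def anchors():
    return sd.generate_anchors()


@pytest.fixture(scope="session")
def fixtures():
    return sd.load_fixtures()


@pytest.fixture(scope="session")
def synthetic_world():
    """Default-seed synthetic foods, impact factors and group->food map."""
    return sd.generate_foods(sd.SynthConfig())


@pytest.fixture(scope="session")
def fcs_config():
    return load_fcs_config()


@pytest.fixture(scope="session")
def override_scenarios(anchors):
    return sd.build_scenarios(anchors, schedule=sd.default_schedule())


@pytest.fixture(scope="session")
def linear_scenarios(anchors):
    return sd.build_scenarios(anchors, schedule=sd.StepSchedule(mode="linear"))


def ladder_ids(model_id: str, include_anchors: bool = False) -> list[str]:
    """Scenario ids of one model's substitution ladder, in order."""
    ids = [f"S{k}{model_id}" for k in (2, 3, 4)]
    ids += ["S5"]
    ids += [f"S{k}{model_id}" for k in (6, 7, 8, 9)]
    if include_anchors:
        ids = ["S1"] + ids + ["S10"]
    return ids


@pytest.fixture(scope="session")
def uniform_composition():
    """All 14 groups at equal shares of the 1800 g day."""
    n = len(sd.FOOD_GROUPS)
    return sd.validate_composition(
        sd.DietComposition({g: 1.0 / n for g in sd.FOOD_GROUPS})
    )
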