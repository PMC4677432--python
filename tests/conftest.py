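import numpy as np
import pytest

import osteoecon as oe
from osteoecon.engine import EngineInputs


@pytest.fixture(scope="session")
def reference_scenario():
    return oe.make_reference_scenario(seed=1)


@pytest.fixture(scope="session")
def population_tables():
    return oe.load_population_tables()


def constant_life_table(qx: float, sex: str = "women", max_age: int = 105) -> oe.LifeTable:
    table = {age: qx for age in range(50, max_age)}
    table[max_age] = 1.0
    return oe.LifeTable(sex=sex, max_age=max_age, qx=table)


def flat_inputs(
    p_site=None,
    qx: float = 0.0,
    modifiers: oe.RiskModifiers | None = None,
    excess: oe.ExcessMortality | None = None,
    start_history=None,
    sex: str = "women",
) -> EngineInputs:
    """Engine inputs with age-constant site probabilities and mortality."""
    p_site = p_site or {s: 0.0 for s in oe.SITES}
    return EngineInputs(
        site_base={s: (lambda p: (lambda age: p))(p_site.get(s, 0.0)) for s in oe.SITES},
        modifiers=modifiers or oe.RiskModifiers(),
        life_table=constant_life_table(qx, sex=sex),
        excess=excess or oe.ExcessMortality(),
        start_history=start_history or {frozenset(): 1.0},
    )
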