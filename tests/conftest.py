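import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from truthsdt import CohortConfig, generate_cohort

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def cohort():
    """A default-condition cohort (300 participants, 20 items/cell)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def scored(cohort):
    from truthsdt import score_cohort
    groups = cohort.participants["group"]
    return {split: score_cohort(cohort.judgments, cohort.bank, groups,
                                split=split)
            for split in ("all", "odd", "even")}


@pytest.fixture()
def tiny_bank():
    """A handmade 8-item bank (2 per veracity x slant cell) whose odd/even
    halves contain identical cell counts."""
    rows = []
    order = 1
    for veracity in (True, False):
        for slant in ("side_A", "side_B"):
            for _ in range(2):
                rows.append((f"i{order}", veracity, slant, order))
                order += 1
    return pd.DataFrame(rows,
                        columns=["item_id", "veracity", "slant", "order_index"])
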