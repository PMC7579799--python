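import numpy as np
import pandas as pd
import pytest

from difagree import (
    ResponseMatrix,
    generate_dyads,
    pedsql_generic_core,
    preset_scenarios,
)
from difagree.simulate import default_item_params, make_subscale_instrument


@pytest.fixture(scope="session")
def pedsql():
    return pedsql_generic_core()


@pytest.fixture(scope="session")
def small_instrument():
    return make_subscale_instrument(5)


@pytest.fixture(scope="session")
def small_params(small_instrument):
    return default_item_params(small_instrument)


@pytest.fixture(scope="session")
def null_matrix():
    """500 dyads, 5 items, no DIF (fixed seed)."""
    return generate_dyads(preset_scenarios(seed=11)["null"])


@pytest.fixture()
def tiny_frame(pedsql):
    """4 complete respondents (2 dyads) on the full instrument."""
    rng = np.random.default_rng(0)
    rows = []
    for d in range(2):
        for g in ("child", "parent"):
            row = {"respondent_id": f"{g}{d}", "dyad_id": f"d{d}", "group": g}
            row.update({iid: int(v) for iid, v in
                        zip(pedsql.item_ids, rng.integers(0, 5, 23))})
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture()
def tiny_matrix(tiny_frame, pedsql):
    return ResponseMatrix(tiny_frame, pedsql)
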