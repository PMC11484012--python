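import numpy as np
import pandas as pd
import pytest

from ventplume import synthetic as syn


@pytest.fixture(scope="session")
def polaris():
    return syn.preset("polaris", seed=1)


@pytest.fixture(scope="session")
def aurora():
    return syn.preset("aurora", seed=1)


@pytest.fixture(scope="session")
def polaris_casts(polaris):
    refs, plumes, truth = syn.generate_casts(polaris)
    return refs, plumes, truth


@pytest.fixture(scope="session")
def polaris_bottles(polaris):
    table, truth = syn.generate_bottles(polaris)
    return table, truth


@pytest.fixture(scope="session")
def aurora_bottles(aurora):
    table, truth = syn.generate_bottles(aurora)
    return table, truth


def make_cast(depths, cast_id="c", **columns):
    """Build a minimal CtdCast from parallel arrays."""
    from ventplume.ctd import CtdCast

    data = {"depth_m": np.asarray(depths, dtype=float)}
    data.setdefault("temperature_C", columns.pop("temperature_C", np.zeros(len(data["depth_m"]))))
    data.update({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    return CtdCast(cast_id=cast_id, data=pd.DataFrame(data))
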