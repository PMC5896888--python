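import numpy as np
import pandas as pd
import pytest

from deeppca import scoring as sc
from deeppca import thermo as th
from deeppca.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_params() -> th.ThermoParams:
    return th.ThermoParams(1.30, 1.25, 0.700)


@pytest.fixture(scope="session")
def small_experiment():
    """A small sampled trans experiment reused across test modules."""
    cfg = SimConfig(
        n_positions=8, n_doubles=5000, depth=3_000_000, neutral_scale=0.35
    )
    return simulate_experiment(cfg, rng=123)


@pytest.fixture(scope="session")
def small_scored(small_experiment):
    """Raw scores of the small experiment, split singles/doubles."""
    res = small_experiment
    raw, filt = sc.ppi_scores(res.counts, res.realized_doublings)
    singles = raw.loc[raw.index.str.count(":") == 0]
    doubles = raw.loc[raw.index.str.count(":") == 1]
    return res, raw, singles, doubles


def make_count_table(rows: dict[str, list[float]]) -> pd.DataFrame:
    """Tiny count table helper: variant key -> [in1 in2 in3 out1 out2 out3]."""
    cols = ["input_r1", "input_r2", "input_r3", "output_r1", "output_r2", "output_r3"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).rename_axis(
        "variant"
    )
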