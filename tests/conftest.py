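import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ctsrt import default_config, default_tree, filter_trials, simulate_cohort
from ctsrt.context_tree import ContextTree


@pytest.fixture(scope="session")
def tree() -> ContextTree:
    return default_tree()


@pytest.fixture(scope="session")
def cohort():
    """One default-size cohort, simulated once per session."""
    return simulate_cohort(default_config(seed=20240901))


@pytest.fixture(scope="session")
def kept_trials(cohort):
    kept, _ = filter_trials(cohort)
    return kept


@pytest.fixture(scope="session")
def small_config():
    """Five subjects per group; same trial structure and effect sizes."""
    return replace(default_config(seed=424242), n_per_group=5)


def random_rm_table(rng: np.random.Generator, n=4, a=3, b=2) -> pd.DataFrame:
    rows = [
        {"subject_id": f"s{s}", "A": f"a{i}", "B": f"b{j}",
         "mean_rt": rng.normal(500, 50)}
        for s in range(n) for i in range(a) for j in range(b)
    ]
    return pd.DataFrame(rows)


def random_mixed_table(rng: np.random.Generator, n_per_group=3, g=2, w=2) -> pd.DataFrame:
    rows = [
        {"subject_id": f"g{k}s{s}", "group": f"g{k}", "event": f"e{j}",
         "mean_rt": rng.normal(500, 50)}
        for k in range(g) for s in range(n_per_group) for j in range(w)
    ]
    return pd.DataFrame(rows)
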