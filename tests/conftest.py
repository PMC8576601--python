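import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from actimood import CohortConfig, generate_cohort
from actimood.features import extract_features
from actimood.pipeline import run_qc


@pytest.fixture(scope="session")
def small_cohort():
    """A small but full-featured cohort shared across test modules."""
    cfg = CohortConfig(n_participants=12, days_per_participant=7,
                       wear_compliance=0.95, seed=42)
    streams, outcomes = generate_cohort(cfg)
    return cfg, streams, outcomes


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, streams, outcomes = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qc, _ = run_qc(streams, min_days=5)
        included = qc.index[qc["included"]]
        feats = pd.DataFrame([extract_features(streams[p]) for p in included])
    return feats, outcomes.loc[included]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
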