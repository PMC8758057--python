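import numpy as np
import pandas as pd
import pytest

from bladderpheno import (
    PhenotypeClustering,
    default_cohort_config,
    generate_cohort_frame,
)
from bladderpheno.calibration import ORDINAL_PARAMS, BINARY_PARAMS

COHORT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized synthetic cohort (145 cases + 69 controls)."""
    cohort, labels = generate_cohort_frame(default_cohort_config(seed=COHORT_SEED))
    return cohort, labels


@pytest.fixture(scope="session")
def fitted(default_cohort):
    """Three-cluster K-means fit on the default cohort's cases."""
    cohort, labels = default_cohort
    model = PhenotypeClustering.from_dataframe(cohort)
    return model.fit(k=3, seed=0), labels[labels != "CONTROL"]


@pytest.fixture(scope="session")
def mean_profiles():
    """Per-phenotype mean answer profiles from the calibration table."""
    out = {}
    for group in ("MFP", "BPS", "NUPP"):
        answers = {item: params[group][0] for item, params in ORDINAL_PARAMS.items()}
        answers.update({item: p[group] for item, p in BINARY_PARAMS.items()})
        out[group] = answers
    return out


def blobs(n_per=20, centers=((0, 0), (8, 0), (0, 8)), sd=0.3, seed=0):
    """Well-separated Gaussian blobs for clustering oracles."""
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(c, sd, size=(n_per, 2)) for c in centers])
    y = np.repeat(np.arange(1, len(centers) + 1), n_per)
    return X, y
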