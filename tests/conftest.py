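import warnings

import numpy as np
import pandas as pd
import pytest

import smoltpanel as sp
from smoltpanel.simulate import SyntheticConfig, trial_config


@pytest.fixture(scope="session")
def survey():
    """Default synthetic monthly survey (4 groups x 5 months x 10 fish)."""
    return sp.generate(seed=1)


@pytest.fixture(scope="session")
def normalized(survey):
    """Survey normalized to log2 relative expression + the fitted normalizer."""
    norm = sp.DeltaDeltaCtNormalizer()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr = norm.fit(survey.ct, meta=survey.meta, assays=survey.assays).transform(
            survey.ct, meta=survey.meta
        )
    return expr, norm


@pytest.fixture(scope="session")
def candidate_expr(survey, normalized):
    """Samples x genes log2 expression restricted to candidate (non-HK) genes."""
    expr, _ = normalized
    cand = [
        a for a in survey.assays.index if not survey.assays.loc[a, "is_housekeeping"]
    ]
    return expr.subset_assays(cand).to_samples_by_genes()


@pytest.fixture(scope="session")
def trials():
    """Labelled trial cohorts for classifier training (emulated seawater trials)."""
    ds = sp.generate(trial_config(seed=7))
    norm = sp.DeltaDeltaCtNormalizer()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr = norm.fit(ds.ct, meta=ds.meta, assays=ds.assays).transform(
            ds.ct, meta=ds.meta
        )
    cand = [a for a in ds.assays.index if not ds.assays.loc[a, "is_housekeeping"]]
    X = expr.subset_assays(cand).to_samples_by_genes()
    y = ds.truth.samples.loc[X.index, "status"]
    return ds, X, y


@pytest.fixture
def small_ct():
    """Tiny handmade Ct matrix with two groups and designated calibrators."""
    ct = sp.CtMatrix(
        pd.DataFrame(
            {
                "a1": [20.0, 22.0, 25.0],
                "a2": [21.0, 22.0, 25.0],
                "b1": [19.0, 23.0, 25.0],
                "b2": [20.5, 21.0, 25.0],
            },
            index=["gene1", "gene2", "ref"],
        ),
        "ct",
    )
    meta = sp.data.validate_sample_meta(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "group": ["coho", "coho", "sockeye", "sockeye"],
                "set_label": ["h", "h", "w", "w"],
                "month_index": [0, 1, 0, 1],
                "environment": ["FW"] * 4,
                "is_calibrator": [True, False, True, False],
            }
        )
    )
    assays = sp.data.validate_assay_table(
        pd.DataFrame(
            {
                "assay_id": ["gene1", "gene2", "ref"],
                "efficiency": [2.0, 2.0, 2.0],
                "is_housekeeping": [False, False, True],
            }
        )
    )
    return ct, meta, assays
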