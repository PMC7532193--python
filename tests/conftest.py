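"""Shared fixtures: synthetic cohorts extracted once per session."""

import numpy as np
import pandas as pd
import pytest

from phonoavf import features, synthesis

COHORT_SEED = 7


def _cohort_table(spec: synthesis.CohortSpec) -> pd.DataFrame:
    recs = synthesis.generate_cohort_recordings(spec)
    return features.extract_cohort(recs)


@pytest.fixture(scope="session")
def default_cohort_features() -> pd.DataFrame:
    """Feature table of the default 38-patient cohort (patient effects on)."""
    return _cohort_table(synthesis.CohortSpec(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def nosd_cohort_features() -> pd.DataFrame:
    """Same cohort structure with per-patient idiosyncrasy switched off."""
    return _cohort_table(synthesis.CohortSpec(seed=COHORT_SEED, patient_effect_sd=0.0))


@pytest.fixture(scope="session")
def selection_cohort_features() -> pd.DataFrame:
    """Smaller cohort (one 15-s recording per patient) for wrapper selection."""
    return _cohort_table(
        synthesis.CohortSpec(seed=COHORT_SEED, recordings_per_patient=1, duration_s=15.0)
    )


def split_xyg(table: pd.DataFrame, feature_names):
    X = table[list(feature_names)].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    groups = table["patient_id"].to_numpy()
    return X, y, groups


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
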