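import numpy as np
import pandas as pd
import pytest

from qeegnorm import normative as nm
from qeegnorm import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """Modest cohort for unit tests (120/sex, default generator settings)."""
    return syn.sample_cohort(syn.CohortConfig(n_per_sex=120, seed=31))


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    return small_cohort.band_power_table(), small_cohort.demographics()


@pytest.fixture(scope="session")
def train_cohort():
    """Default-condition training cohort: 400 per sex."""
    return syn.sample_cohort(syn.CohortConfig(n_per_sex=400, seed=42))


@pytest.fixture(scope="session")
def fitted_models(train_cohort):
    """Sex-stratified and pooled normative models on the training cohort."""
    bp, demo = train_cohort.band_power_table(), train_cohort.demographics()
    return {
        mode: nm.NormativeDB(sex_mode=mode).fit(bp, demo)
        for mode in ("male", "female", "pooled")
    }


@pytest.fixture(scope="session")
def heldout_cohort():
    """200 fresh normative subjects from the same generator settings."""
    return syn.sample_cohort(syn.CohortConfig(n_per_sex=100, seed=43))


def zscore_by_sex(models: dict, cohort) -> pd.DataFrame:
    """Z-score a cohort's subjects against their sex-matched models."""
    bp, demo = cohort.band_power_table(), cohort.demographics()
    frames = []
    for sex in ("male", "female"):
        sub = demo[demo["sex"] == sex]
        frames.append(
            models[sex].zscore(bp[bp["subject_id"].isin(set(sub["subject_id"]))], sub)
        )
    return pd.concat(frames, ignore_index=True)
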