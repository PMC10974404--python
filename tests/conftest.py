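"""Shared fixtures: small synthetic signals and session-scoped cohorts.

The two cohort fixtures are the expensive ones (250 two-minute eight-channel
records each); they are built once per session and shared by the recovery and
stability tests.
"""

import numpy as np
import pytest

from hemoppg import (
    NoiseConfig,
    OpticalConfig,
    PhysioState,
    Standardizer,
    SubjectRecord,
    feature_table,
    generate_cohort,
    generate_ppg,
)

COHORT_SEED = 1


@pytest.fixture(scope="session")
def optics():
    return OpticalConfig()


@pytest.fixture(scope="session")
def state_normal():
    """A typical subject: Hb 14 g/dL, SpO2 97%, 72 bpm."""
    return PhysioState(hb_total=14.0, spo2=0.97, heart_rate=72.0)


@pytest.fixture(scope="session")
def clean_record(state_normal, optics):
    """One noiseless two-minute subject record."""
    ppg = generate_ppg(state_normal, optics, NoiseConfig.noiseless(),
                       duration=120.0, seed=COHORT_SEED)
    return SubjectRecord("clean0", ppg, age=40.0, gender=1, hb_ref=14.0,
                         spo2=0.97, heart_rate=72.0)


def _cohort_xy(noise):
    records = generate_cohort(250, noise=noise, seed=COHORT_SEED)
    table = feature_table(records)
    X = table.drop(columns="hb_ref").to_numpy()
    y = table["hb_ref"].to_numpy()
    return X, y


@pytest.fixture(scope="session")
def noiseless_cohort_xy():
    """Features and reference Hb for 250 noiseless synthetic subjects."""
    return _cohort_xy(NoiseConfig.noiseless())


@pytest.fixture(scope="session")
def noisy_cohort_xy():
    """Features and reference Hb for 250 subjects under the full noise model."""
    return _cohort_xy(NoiseConfig())


@pytest.fixture(scope="session")
def noiseless_split(noiseless_cohort_xy):
    """Standardized 200/50 train/test split of the noiseless cohort."""
    X, y = noiseless_cohort_xy
    std = Standardizer().fit(X[:200])
    return std.transform(X[:200]), y[:200], std.transform(X[200:]), y[200:]
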