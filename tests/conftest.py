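import pandas as pd
import pytest
from hypothesis import settings

from cdst_hru.cohort import build_cohort
from cdst_hru.synthetic import SimulationConfig, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def claims_frame(rows):
    """Hand-built claims table: rows of (pid, date, code_type, code, setting, paid)."""
    df = pd.DataFrame(rows, columns=["patient_id", "service_date", "code_type", "code", "setting", "paid_amount"])
    df["service_date"] = pd.to_datetime(df["service_date"])
    df["service_year"] = df["service_date"].dt.year.astype("int64")
    return df


def enrollment_frame(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "start_date", "end_date"])
    for col in ("start_date", "end_date"):
        df[col] = pd.to_datetime(df[col])
    return df


def labs_frame(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "collection_date", "analyte", "value", "unit"])
    df["collection_date"] = pd.to_datetime(df["collection_date"])
    return df


@pytest.fixture(scope="session")
def small_sim():
    cfg = SimulationConfig(n_patients=150, seed=7)
    dataset, truth = generate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    _, dataset, _ = small_sim
    return build_cohort(dataset)
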