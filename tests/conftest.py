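"""Shared fixtures: hand-built toy claims plus a session-scoped synthetic run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tmcohort import (
    ClaimsDataset,
    SimulationConfig,
    StudyDesignConfig,
    assemble_cohort,
    generate_claims,
)
from tmcohort.config import MissingSpec


def make_patients(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "sex", "birth_date", "observable_start", "observable_end"]
    )


def make_dx(rows):
    frame = pd.DataFrame(
        rows, columns=["patient_id", "date", "code", "facility_id", "setting", "hospitalization_id"]
    )
    frame["hospitalization_id"] = frame["hospitalization_id"].astype("Int64")
    return frame


def make_rx(rows):
    frame = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "date",
            "code",
            "days_supply",
            "daily_dose",
            "facility_id",
            "setting",
            "hospitalization_id",
        ],
    )
    frame["hospitalization_id"] = frame["hospitalization_id"].astype("Int64")
    return frame


def make_hosp(rows):
    return pd.DataFrame(
        rows, columns=["hospitalization_id", "patient_id", "admission_date", "discharge_date"]
    )


def make_meas(rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "kind", "value"])


@pytest.fixture
def design():
    return StudyDesignConfig(cutoff_date="2018-06-01", seed=0)


@pytest.fixture
def toy_claims():
    """Six hand-enumerable patients around the day-182 cutoff (2018-06-01).

    birth_date -14610 corresponds to roughly 40 years before the epoch.
    """
    adult = -20000  # ~54.8 years before epoch
    minor = -6000  # ~16.4 years before epoch
    patients = make_patients(
        [
            # p1: eligible exposed; first dx day 400, pema at 500 (X=100)
            (1, "F", adult, 100, 1900),
            # p2: first dx before cutoff -> ineligible
            (2, "M", adult, 0, 1900),
            # p3: eligible control candidate (dx 420, no pema)
            (3, "F", adult, 100, 1900),
            # p4: pema before first dx -> exclusion 4
            (4, "M", adult, 100, 1900),
            # p5: fibrate during baseline -> exclusion 2 as exposed
            (5, "F", adult, 100, 1900),
            # p6: under 20 at index -> exclusion 6
            (6, "M", minor, 100, 1900),
        ]
    )
    diagnoses = make_dx(
        [
            (1, 400, "E780", "F0", "outpatient", None),
            (1, 500, "E785", "F0", "outpatient", None),
            (2, 100, "E780", "F0", "outpatient", None),
            (2, 400, "E780", "F0", "outpatient", None),
            (3, 420, "E780", "F0", "outpatient", None),
            (4, 400, "E780", "F0", "outpatient", None),
            (5, 400, "E780", "F0", "outpatient", None),
            (6, 400, "E780", "F0", "outpatient", None),
        ]
    )
    prescriptions = make_rx(
        [
            (1, 500, "C10A2P01", 30, 0.2, "F0", "outpatient", None),
            (2, 500, "C10A2P01", 30, 0.2, "F0", "outpatient", None),
            (4, 350, "C10A2P01", 30, 0.2, "F0", "outpatient", None),
            (4, 450, "C10A2P01", 30, 0.2, "F0", "outpatient", None),
            (5, 450, "C10A2B01", 30, 400.0, "F0", "outpatient", None),
            (5, 520, "C10A2P01", 30, 0.2, "F0", "outpatient", None),
            (6, 500, "C10A2P01", 30, 0.2, "F0", "outpatient", None),
        ]
    )
    return ClaimsDataset(
        patients=patients,
        diagnoses=diagnoses,
        prescriptions=prescriptions,
        hospitalizations=make_hosp([]),
        measurements=make_meas([]),
    )


@pytest.fixture(scope="session")
def small_sim_config():
    return SimulationConfig(n_patients=4000, seed=42)


@pytest.fixture(scope="session")
def small_claims(small_sim_config):
    return generate_claims(small_sim_config)


@pytest.fixture(scope="session")
def small_cohort(small_claims):
    design = StudyDesignConfig(seed=42)
    members, attrition = assemble_cohort(small_claims, design, np.random.default_rng(42))
    return members, attrition, design


@pytest.fixture(scope="session")
def complete_claims():
    """Confounded dataset with missingness disabled (complete covariates)."""
    config = SimulationConfig(n_patients=6000, seed=7, missing_spec=MissingSpec(target=0.0))
    return config, generate_claims(config)
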