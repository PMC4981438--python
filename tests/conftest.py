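"""Shared fixtures: one noiseless simulated subject reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from qgm.acquisition import AcquisitionProtocol, BiasFields, simulate_subject
from qgm.phantom import CohortSpec, SubjectTruth, sample_subject
from qgm.pipeline import default_bias_fields
from qgm.relaxometry import map_subject


@pytest.fixture(scope="session")
def cohort_spec() -> CohortSpec:
    return CohortSpec()


@pytest.fixture(scope="session")
def control_subject(cohort_spec) -> SubjectTruth:
    return sample_subject(cohort_spec, "control", seed=5, subject_id="ctl")


@pytest.fixture(scope="session")
def patient_subject(cohort_spec) -> SubjectTruth:
    return sample_subject(cohort_spec, "patient", seed=11, subject_id="pat")


@pytest.fixture(scope="session")
def noiseless_protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol(noise_sd=0.0)


@pytest.fixture(scope="session")
def mapped_subject(patient_subject) -> SubjectTruth:
    """Subject used for the mapping round trips (a patient: all 8 tissues)."""
    return patient_subject


@pytest.fixture(scope="session")
def bias_fields(mapped_subject) -> BiasFields:
    return default_bias_fields(mapped_subject.labels.shape)


@pytest.fixture(scope="session")
def noiseless_signals(mapped_subject, noiseless_protocol, bias_fields):
    return simulate_subject(mapped_subject, noiseless_protocol, bias_fields, seed=3)


@pytest.fixture(scope="session")
def oracle_maps(mapped_subject, noiseless_protocol, noiseless_signals, bias_fields):
    """Noiseless maps with the true receive field supplied (oracle bias)."""
    return map_subject(
        noiseless_signals,
        noiseless_protocol,
        csf_mask=mapped_subject.labels == 1,
        brain_mask=mapped_subject.labels > 0,
        voxel_size=mapped_subject.voxel_size,
        oracle_receive=bias_fields.receive_field,
    )


@pytest.fixture(scope="session")
def estimated_maps(mapped_subject, noiseless_protocol, noiseless_signals):
    """Noiseless maps with the receive field estimated from the data."""
    return map_subject(
        noiseless_signals,
        noiseless_protocol,
        csf_mask=mapped_subject.labels == 1,
        brain_mask=mapped_subject.labels > 0,
        voxel_size=mapped_subject.voxel_size,
    )


@pytest.fixture(scope="session")
def uniform_bias(control_subject) -> BiasFields:
    return BiasFields.uniform(control_subject.labels.shape)
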