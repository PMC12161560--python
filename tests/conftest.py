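import numpy as np
import pytest

from dsvae import (
    SubjectRecord,
    SyntheticSpec,
    WindowSpec,
    generate_dataset,
    make_windows,
    split_subjects,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small synthetic cohort shared by read-only tests: 2x8 subjects,
    6 channels, 96 timesteps."""
    spec = SyntheticSpec(
        n_subjects_per_group=8, n_components=6, n_timesteps=96, seed=11
    )
    records, truth = generate_dataset(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def tiny_windows(tiny_cohort):
    _, records, _ = tiny_cohort
    spec = WindowSpec(width=32, stride=8)
    windows = [w for r in records for w in make_windows(r, spec)]
    split = split_subjects(records, seed=3)
    diagnoses = {r.subject_id: r.diagnosis for r in records}
    return windows, split, diagnoses


def make_record(data, subject_id="s0", diagnosis="control", **kw):
    return SubjectRecord(subject_id=subject_id, diagnosis=diagnosis, data=data, **kw)
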