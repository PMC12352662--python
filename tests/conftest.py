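import numpy as np
import pytest

from fcmanifold.design import EPOCHS
from fcmanifold.synth import SyntheticDesign, generate_parcel_metadata, \
    generate_subject_dataset


def random_spd(rng, n, cond=10.0):
    """Random SPD matrix with bounded condition number."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    w = np.exp(rng.uniform(0, np.log(cond), n))
    return (Q * w) @ Q.T


@pytest.fixture(scope="session")
def metadata():
    return generate_parcel_metadata(60, 6, seed=1)


@pytest.fixture(scope="session")
def small_cohort(metadata):
    """One default-condition synthetic cohort (12 subjects x 6 epochs)."""
    design = SyntheticDesign(seed=7)
    return generate_subject_dataset(design, metadata)


@pytest.fixture(scope="session")
def small_cohort_pipeline(small_cohort):
    """Eccentricity panel for the shared cohort (computed once)."""
    from fcmanifold.pipeline import eccentricity_pipeline

    panel, subjects, extras = eccentricity_pipeline(
        small_cohort.timeseries, return_intermediates=True
    )
    return panel, subjects, extras
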