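import numpy as np
import pytest

from solocase.synthdata import CohortSpec, SubjectImage, generate_cohort


def make_image(values, voxel_size=(3.0, 3.0, 3.0), age=21.0, gender=0, subject_id="sub"):
    return SubjectImage(
        values=np.asarray(values, dtype=float),
        voxel_size=voxel_size,
        age=age,
        gender=gender,
        subject_id=subject_id,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """12 Gaussian-marginal subjects on a 12^3 grid; shared across tests."""
    spec = CohortSpec(n_subjects=12, grid_shape=(12, 12, 12), seed=42)
    images, covariates = generate_cohort(spec)
    return spec, images, covariates


@pytest.fixture
def toy_cohort():
    """3 hand-built positive 2x2x2 volumes for brute-force oracle checks."""
    rng = np.random.default_rng(7)
    images = [
        make_image(1.0 + 0.3 * rng.random((2, 2, 2)), subject_id=f"toy-{i}")
        for i in range(3)
    ]
    return images
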