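import numpy as np
import pytest

from sbmorph import CohortDesign, assemble_matrix, make_mask, simulate_study
from sbmorph.preprocess import volumes_from_array

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def study_matrix(study, fwhm_mm: float = 0.0, threshold: float = 0.05):
    """Assemble the subjects x voxels matrix of a simulated study."""
    from sbmorph import smooth_volume

    vols = volumes_from_array(
        study.volumes, study.affine, list(study.participants["id"])
    )
    if fwhm_mm > 0:
        vols = [smooth_volume(v, fwhm_mm) for v in vols]
    mask = make_mask(vols, threshold)
    return assemble_matrix(vols, mask, list(study.participants["id"]))


@pytest.fixture(scope="session")
def small_study():
    """Compact cohort (20 subjects, 3 sources, 16^3 grid) with a strong
    planted group effect, shared across fast unit tests."""
    design = CohortDesign(
        n_control=12, n_patient=8, affected_component=2,
        effect_size_d=1.5, score_rho=0.6, seed=42,
    )
    return simulate_study(design, k=3, grid_shape=(16, 16, 16), snr=10.0)


@pytest.fixture(scope="session")
def small_matrix(small_study):
    return study_matrix(small_study)


@pytest.fixture(scope="session")
def paper_study():
    """Study-sized cohort: 50 controls + 32 patients, 8 sources, 24^3 grid."""
    design = CohortDesign(seed=0)
    return simulate_study(design, k=8, snr=5.0)


@pytest.fixture(scope="session")
def paper_matrix(paper_study):
    return study_matrix(paper_study)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
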