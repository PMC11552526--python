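import numpy as np
import pytest

from bilatdot import Cohort, ScanBlock, SimulationParams, SubjectRecord, generate_cohort


def make_block(values, wavelength_nm=760, side="left", n_sources=None, n_detectors=None):
    """ScanBlock from a plain nested list, inferring a 1 x R source layout."""
    values = np.asarray(values, dtype=float)
    if n_sources is None and n_detectors is None:
        n_sources, n_detectors = 1, values.shape[0]
    return ScanBlock(values=values, wavelength_nm=wavelength_nm, side=side,
                     n_sources=n_sources, n_detectors=n_detectors)


def make_record(left, right, subject_id="s0", cancer_positive=False, tumor_side="none",
                n_sources=None, n_detectors=None):
    """SubjectRecord with identical data at both wavelengths per side."""
    blocks = {}
    for side, values in (("left", left), ("right", right)):
        for wl in (760, 830):
            blocks[(side, wl)] = make_block(values, wavelength_nm=wl, side=side,
                                            n_sources=n_sources, n_detectors=n_detectors)
    return SubjectRecord(subject_id=subject_id, blocks=blocks,
                         cancer_positive=cancer_positive, tumor_side=tumor_side)


@pytest.fixture(scope="session")
def demo_block():
    """The 2x2 worked example used throughout the operator tests."""
    return make_block([[1.0, 3.0], [5.0, 7.0]])


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject cohort at toy scale (4x8 channels, 48 frames)."""
    params = SimulationParams(n_subjects=12, prevalence=4 / 12, n_sources=4,
                              n_detectors=8, n_frames=48, seed=11)
    return generate_cohort(params)


@pytest.fixture(scope="session")
def study_scale_cohort():
    """A 63-subject cohort at the reduced 8x16x100 analysis scale."""
    params = SimulationParams(n_subjects=63, n_sources=8, n_detectors=16,
                              n_frames=100, seed=5)
    return generate_cohort(params)
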