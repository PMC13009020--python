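import numpy as np
import pytest

from bpemri.imaging_io import DCEStudy, MaskSet
from bpemri.synthetic_data import CohortSpec, PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free two-breast phantom with designed BPE 0.4 * 0.5 = 0.20."""
    spec = PhantomSpec(
        fgt_fraction=0.5, enhancing_fraction=0.4, enhancement_amplitude=80.0,
        noise_sd=0.0, seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated cohort at the default study conditions (n=300, k*=55)."""
    return generate_cohort(CohortSpec(n=300, seed=11))


def random_study_and_masks(rng, max_dim=8):
    """A random small DCE study plus consistent masks, for oracle checks."""
    shape = tuple(rng.integers(2, max_dim + 1, size=3))
    s0 = rng.uniform(0.0, 200.0, size=shape)
    s0[rng.random(shape) < 0.05] = 0.0  # some undefined-ratio voxels
    s1 = rng.uniform(0.0, 400.0, size=shape)
    spacing = rng.uniform(0.5, 2.0, size=3)
    study = DCEStudy("rnd", "T0", [s0, s1], spacing)
    breast = rng.random(shape) < 0.7
    if not breast.any():
        breast.ravel()[0] = True
    fgt = breast & (rng.random(shape) < 0.5)
    masks = MaskSet(breast=breast, fgt=fgt, spacing=spacing)
    return study, masks
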