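import numpy as np
import pytest

from seqmotor.datatypes import BOLDDataset
from seqmotor.synthetic import gen_behaviour_cohort, gen_ref_lrn
from seqmotor.synthetic.blocks import gen_block_phantom as make_random_phantom

__all__ = ["make_random_phantom"]


@pytest.fixture(scope="session")
def ref_trace():
    return gen_ref_lrn(seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """2 subjects per group, 2 days; scored downstream by tests."""
    traces, meta, truth = gen_behaviour_cohort(
        n_per_group=2, days=("d1", "d2"), seed=11
    )
    return traces, meta, truth


@pytest.fixture()
def tiny_bold(rng_seed=3):
    rng = np.random.default_rng(rng_seed)
    grid = (6, 6, 6)
    t = 80
    brain = np.zeros(grid, bool)
    brain[1:5, 1:5, 1:5] = True
    wm = np.zeros(grid, bool)
    wm[0, :, :] = True
    csf = np.zeros(grid, bool)
    csf[5, :, :] = True
    data = rng.normal(0, 1, grid + (t,))
    motion = np.cumsum(rng.normal(0, 0.01, (t, 6)), axis=0)
    return BOLDDataset(
        data=data, tr=1.13, voxel_size=2.4, brain_mask=brain,
        wm_mask=wm, csf_mask=csf, motion_params=motion,
    )
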