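import numpy as np
import pytest

from microhet import synthetic as syn
from microhet.imaging import ImageStack


@pytest.fixture()
def rng():
    """Fresh seeded generator per test: results independent of order."""
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_plate():
    """A small, fast plate time-lapse (8 colonies) with ground truth."""
    cfg = syn.PlateSimConfig(plate_diameter_px=256, n_colonies=8,
                             n_frames=40, rng_seed=5)
    stack_arr, gt = syn.gen_plate_timelapse(cfg)
    stack = ImageStack(stack_arr, gt.meta["frame_times_min"],
                       gt.meta["plate_center"], gt.meta["plate_radius"])
    return stack, gt


@pytest.fixture(scope="session")
def protein_table():
    return syn.gen_protein_noise_table(400, deviation_sd=0.5, seed=3)
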