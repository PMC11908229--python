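import numpy as np
import pytest

from lickwave import (
    HistamineKernel,
    LickTrainParams,
    PhotometryParams,
    Session,
    generate_lick_train,
    generate_photometry,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """A small synthetic PVH session (fs=50 Hz, 6 bouts) for pipeline tests."""
    lick_params = LickTrainParams(
        n_bouts=6, bout_duration_mean_s=10.0, bout_duration_sd_s=1.0,
        session_length_s=220.0,
    )
    licks = generate_lick_train(lick_params, seed=7)
    phot = PhotometryParams(fs_hz=50.0)
    f465, f405, truth = generate_photometry(
        licks, HistamineKernel.pvh(), phot, seed=8, session_length_s=220.0
    )
    session = Session(
        mouse_id="m01", region="PVH", condition="Restricted",
        licks=licks, f465=f465, f405=f405, fs_hz=50.0,
    )
    return session, truth
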