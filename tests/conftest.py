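import numpy as np
import pytest

import lagcvr as lc


@pytest.fixture(scope="session")
def anatomy():
    return lc.make_phantom_anatomy()


@pytest.fixture(scope="session")
def paradigm():
    return lc.default_paradigm()


@pytest.fixture(scope="session")
def co2_clean(paradigm):
    return lc.simulate_co2_trace(paradigm, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def rest_phantom_noisefree(anatomy):
    truth = lc.make_ground_truth(anatomy, seed=21)
    bold = lc.simulate_rest_bold(anatomy, truth)
    return bold, truth


@pytest.fixture(scope="session")
def rest_phantom_snr3(anatomy):
    # amplitude 0.01 on a ~1000-unit baseline gives a ~10-unit signal SD,
    # so noise_sd = 10/3 puts the per-voxel SNR near 3
    truth = lc.make_ground_truth(anatomy, noise_sd=10.0 / 3.0, seed=22)
    bold = lc.simulate_rest_bold(anatomy, truth)
    return bold, truth


@pytest.fixture(scope="session")
def bh_phantom_pure(anatomy, paradigm, co2_clean):
    """Breath-hold phantom with only the CO2-driven response (a = 0)."""
    truth = lc.make_ground_truth(anatomy, amplitude=0.0, seed=23)
    bold = lc.simulate_bh_bold(anatomy, truth, co2_clean, paradigm)
    return bold, truth


@pytest.fixture(scope="session")
def etco2_and_baseline(co2_clean, paradigm, bh_phantom_pure):
    bold, _ = bh_phantom_pure
    peak_t, peak_v = lc.end_tidal_detect(co2_clean)
    etco2 = lc.end_tidal_interpolate(peak_t, peak_v, bold.n_frames * bold.tr)
    baseline = lc.petco2_baseline(peak_t, peak_v, paradigm.hold_windows()[0, 0])
    return etco2, baseline


def flat_bold(data_2d, mask, tr=2.0, voxel_size=(2.0, 2.0, 2.0)):
    """Wrap an (n_vox, t) matrix into a BoldSeries on the mask's grid."""
    data = np.zeros(mask.shape + (data_2d.shape[1],))
    data[mask] = data_2d
    return lc.BoldSeries(
        data=data,
        tr=tr,
        frame_valid=np.ones(data_2d.shape[1], dtype=bool),
        brain_mask=mask,
        voxel_size_mm=voxel_size,
    )
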