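import numpy as np
import pytest

from nirscmd.montage import build_montage, build_roi_map, build_schedule
from nirscmd.preprocess import PreprocessConfig, preprocess_chain
from nirscmd.simulate import SubjectProfile, simulate_subject


@pytest.fixture(scope="session")
def montage():
    return build_montage()


@pytest.fixture(scope="session")
def roi_map():
    return build_roi_map()


@pytest.fixture(scope="session")
def schedule():
    return build_schedule()


@pytest.fixture(scope="session")
def noisefree_responder():
    """Noise-free responder simulation plus its ground truth."""
    profile = SubjectProfile("clean_resp", "HC", True, noise_scale=0.0)
    return simulate_subject(profile, seed=1234)


@pytest.fixture(scope="session")
def noisefree_hb(noisefree_responder):
    """Concentrations recovered from the noise-free responder without the
    data-dependent stages (no motion flagging, no band-pass)."""
    rec, _ = noisefree_responder
    hb, _ = preprocess_chain(rec, PreprocessConfig(motion=None, band_hz=None))
    return hb


@pytest.fixture(scope="session")
def noisy_subject():
    """Default-SNR responder simulation."""
    profile = SubjectProfile("noisy_resp", "HC", True)
    return simulate_subject(profile, seed=99)


def baseline_align(series: np.ndarray, schedule, fs: float) -> np.ndarray:
    """Remove the arbitrary constant introduced by mean-referenced optical
    density by zeroing the pre-baseline mean (the planted signal is zero
    there)."""
    n_pre = int(round(schedule.pre_baseline_s * fs))
    return series - series[:n_pre].mean()
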