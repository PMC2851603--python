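import numpy as np
import pytest

from pcans.types import AlignmentParams, Peak, PeakProfile, Spectrum


def lorentzian(x, x0, h, gamma):
    return h / (1.0 + ((x - x0) / gamma) ** 2)


def make_peak(pid, position, height=10.0, width=0.004, origin="p"):
    return Peak(pid, position, height, width, origin=origin)


def make_profile(profile_id, positions, heights=None, widths=None):
    n = len(positions)
    heights = heights if heights is not None else [10.0] * n
    widths = widths if widths is not None else [0.004] * n
    peaks = [
        Peak(f"{profile_id}:{k}", float(p), float(h), float(w), origin=profile_id)
        for k, (p, h, w) in enumerate(zip(positions, heights, widths))
    ]
    return PeakProfile(profile_id, peaks, kind="leaf")


def random_profile(rng, profile_id, n_peaks, lo=2.0, hi=4.1):
    positions = np.sort(rng.uniform(lo, hi, n_peaks))
    heights = rng.lognormal(np.log(5.0), 0.8, n_peaks)
    widths = np.clip(rng.normal(0.004, 0.0015, n_peaks), 0.0015, None)
    return make_profile(profile_id, positions, heights, widths)


@pytest.fixture
def params():
    return AlignmentParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
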