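import numpy as np
import pytest

from endorecycle.core import AnalysisConfig, TimeLapseMovie
from endorecycle.simulate import SortingSimParams, simulate_sorting_assay


@pytest.fixture(scope="session")
def sorting_movie():
    """One pulse-chase sorting movie at the standard study conditions
    (200 vesicles, k_entry 0.02/s, k_exit 0.005/s, SNR 5), shared across
    tests that only read it."""
    params = SortingSimParams()
    movie, truth = simulate_sorting_assay(params, seed=1)
    return params, movie, truth


@pytest.fixture()
def fixed_cfg():
    return AnalysisConfig(threshold_method="fixed", fixed_threshold=0.5, min_object_px=1)


def make_movie(data, *, pixel_size_nm=100.0, frame_interval_s=1.0, pa_frames=(), names=None):
    """Small helper: wrap a (T, C, H, W) array into a calibrated movie."""
    data = np.asarray(data, dtype=float)
    names = names or [f"ch{i}" for i in range(data.shape[1])]
    return TimeLapseMovie(
        data=data,
        channel_names=names,
        pixel_size_nm=pixel_size_nm,
        frame_times_s=np.arange(data.shape[0]) * frame_interval_s,
        pa_frames=list(pa_frames),
    )
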