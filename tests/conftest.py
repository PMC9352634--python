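"""Shared fixtures: a small random movie and a standard synthetic SLS session.

The standard session is the package's reference study condition: a 80x80 FOV
with 6 blurred-disk somata, shared neuropil/background, Gaussian noise, slow
drift, scanned along a GA-designed trajectory with a 4 px surround and a 10x10
reference box at 30 Hz line rate for 45 s.
"""

import numpy as np
import pytest

from smartline.io import AcquisitionMetadata, RasterMovie
from smartline import synthetic as syn
from smartline import trajectory as td


@pytest.fixture
def meta():
    return AcquisitionMetadata(pixel_size=1.0, frame_period=0.1,
                               line_period=0.033, dwell_time=1.0)


@pytest.fixture
def small_movie(meta):
    rng = np.random.default_rng(42)
    frames = rng.random((20, 16, 16)) * 100
    return RasterMovie(frames=frames, meta=meta)


def build_session(seed=3, drift_sd=0.02, duration_s=45.0, rate_hz=30.0,
                  large_shift=None, surround_width=4, **scene_kwargs):
    """One synthetic SLS session with ground truth (shared study conditions)."""
    _, seg, gt = syn.make_scene(syn.SceneConfig(seed=seed, **scene_kwargs))
    syn.simulate_traces(gt, duration_s, rate_hz)
    traj = td.build_trajectory(
        seg, td.GAConfig(seed=1, n_generations=200),
        surround_width=surround_width, refbox=(60, 60, 10, 10),
        line_period=1.0 / rate_hz)
    motion = syn.MotionConfig(drift_sd=drift_sd, large_shift=large_shift)
    rec = syn.render_sls(gt, traj, motion)
    return rec, seg, gt


@pytest.fixture(scope="session")
def standard_session():
    return build_session()
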