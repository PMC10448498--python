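import numpy as np
import pytest

from duospot.optics import CameraGeometry
from duospot.simulate import (DetectionSlab, FilterConfig, N_A, cluster_spec,
                              simulate_stack)


@pytest.fixture(scope="session")
def small_geom():
    return CameraGeometry(frame_size_px=256)


@pytest.fixture(scope="session")
def lp_filter():
    return FilterConfig("longpass", cutoff_nm=600.0)


@pytest.fixture(scope="session")
def small_slab(small_geom):
    return DetectionSlab.for_geometry(small_geom)


def conc_for_mean(mean_count: float, volume_fL: float) -> float:
    """Concentration giving a target mean emitter count in a volume."""
    return mean_count / (N_A * volume_fL * 1e-15)


@pytest.fixture(scope="session")
def cluster_stack(small_geom, lp_filter, small_slab):
    """20 frames of 256 px with ~8 true double spots per frame."""
    spec = cluster_spec(lp_filter)
    c = conc_for_mean(8.0, small_slab.volume_fL)
    stack, truth = simulate_stack([(spec, c)], 20, small_slab, small_geom,
                                  lp_filter, seed=42)
    return stack, truth


def truth_pair_midpoints(truth, frame_index):
    """Ground-truth double-spot midpoints of one frame, (n, 2)."""
    sub = truth[truth.frame == frame_index]
    mids = []
    for _, grp in sub.groupby("emitter_id"):
        if len(grp) == 2:
            mids.append([(grp.row + grp.d_row).mean(),
                         (grp.col + grp.d_col).mean()])
    return np.array(mids).reshape(-1, 2)
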