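import numpy as np
import pandas as pd
import pytest

from pdquant.image_quant import SpotSet
from pdquant.synthetic_data import make_cell_mosaic, render_membrane_stack


@pytest.fixture(scope="session")
def mosaic12():
    """A 256x256 mosaic of 12 cells shared across image tests."""
    return make_cell_mosaic(256, 256, 12, seed=3)


# Scenario constants used by detection tests: puncta over a dim membrane
# ridge at ~10:1 peak-amplitude-to-noise ratio.
SNR10_RENDER = dict(
    n_z=7,
    pd_per_100um=8.3,
    pd_index_true=14.5,
    pm_intensity=8.0,
    psf_sigma=1.0,
    read_noise_sd=2.0,
)


def render_snr10(mosaic, seed):
    return render_membrane_stack(mosaic, seed=seed, **SNR10_RENDER)


def truth_spotset(truth):
    """Build an annotated SpotSet from generator ground truth."""
    rows = [
        {"z": z, "y": y, "x": x, "voxels": 1, "integrated": a, "mean": a}
        for z, y, x, a in truth.spot_truth
    ]
    return SpotSet(pd.DataFrame(rows))


def match_spots(detected_zyx, truth_zyx, tol=2.0):
    """Greedy matching of detections to truth; returns (n_matched, n_false)."""
    detected_zyx = np.asarray(detected_zyx, dtype=float).reshape(-1, 3)
    truth_zyx = np.asarray(truth_zyx, dtype=float).reshape(-1, 3)
    matched = set()
    false_pos = 0
    for d in detected_zyx:
        if len(truth_zyx) == 0:
            false_pos += 1
            continue
        dist = np.sqrt(((truth_zyx - d) ** 2).sum(axis=1))
        j = int(np.argmin(dist))
        if dist[j] <= tol and j not in matched:
            matched.add(j)
        else:
            false_pos += 1
    return len(matched), false_pos
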