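import numpy as np
import pytest

import cswater as cw


@pytest.fixture(scope="session")
def label_volume():
    return cw.build_label_volume((32, 32, 16), voxel_size=(1.3, 1.3, 5.0), seed=7)


@pytest.fixture(scope="session")
def tissue_truth():
    return cw.default_tissue_truth()


@pytest.fixture(scope="session")
def clean_volume(label_volume, tissue_truth):
    return cw.forward_signal(tissue_truth, label_volume)


@pytest.fixture(scope="session")
def true_wf(label_volume, tissue_truth):
    """Ground-truth fraction maps implied by the per-label amplitudes."""
    shape = label_volume.labels.shape
    maps = {k: np.zeros(shape) for k in ("mwf", "iewf", "csff")}
    for lab, amps in tissue_truth.amplitudes.items():
        total = sum(amps)
        sel = label_volume.labels == lab
        for k, a in zip(("mwf", "iewf", "csff"), amps):
            maps[k][sel] = a / total
    return maps


def three_pool_signal(amps, t2s, te):
    """Independent scalar oracle for the three-exponential decay."""
    te = np.asarray(te, dtype=float)
    out = np.zeros_like(te)
    for a, t in zip(amps, t2s):
        out = out + a * np.exp(-te / t)
    return out
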