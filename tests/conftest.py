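from __future__ import annotations

import numpy as np
import pytest

from salirad.imaging import CtVolume, DiscretisedRoi, RoiMask, SliceSelection


def pad_to_common(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad two run-length matrices to a common number of columns."""
    cols = max(a.shape[1], b.shape[1])
    pa = np.zeros((a.shape[0], cols))
    pb = np.zeros((b.shape[0], cols))
    pa[:, : a.shape[1]] = a
    pb[:, : b.shape[1]] = b
    return pa, pb


def roi_from_plane(plane: np.ndarray) -> DiscretisedRoi:
    """Wrap a 2D label array as a single-slice discretised ROI."""
    labels = np.asarray(plane, dtype=np.uint8)[:, :, None]
    return DiscretisedRoi(labels, SliceSelection((0,), 0.0))


def roi_from_labels(labels: np.ndarray) -> DiscretisedRoi:
    """Wrap a 3D label array as a fully retained discretised ROI."""
    labels = np.asarray(labels, dtype=np.uint8)
    bearing = tuple(int(k) for k in np.flatnonzero(labels.any(axis=(0, 1))))
    return DiscretisedRoi(labels, SliceSelection(bearing, 0.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20221216)


@pytest.fixture
def small_volume() -> tuple[CtVolume, RoiMask]:
    """A 12x12x6 volume, uniform 40 HU, with a centred box mask on slices 1..4."""
    vox = np.full((12, 12, 6), 40, dtype=np.int16)
    flags = np.zeros((12, 12, 6), dtype=bool)
    flags[3:9, 3:9, 1:5] = True
    return CtVolume(vox), RoiMask(flags, "parotid")
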