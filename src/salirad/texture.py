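"""Grey-level texture matrices and the named radiomics features.

Implements the grey-level co-occurrence matrix (GLCM) and grey-level
run-length matrix (GLRLM) on discretised regions of interest, and the
three features carried through the toxicity models:

* ``sre`` — Short Run Emphasis, ``(1/Nr) * sum_ij r(i,j) / j**2`` on a
  GLRLM; 1 iff every run has length 1, small for coarse texture.
* ``inverse_difference_moment`` — ``sum_ij p(i,j) / (1 + (i-j)**2)`` on a
  symmetric GLCM; 1 for a homogeneous region.
* ``max_hu`` — maximum raw (unclamped) HU inside the mask on retained
  slices.

Two computation modes are provided.  In the 2D mode, matrices are built
per retained axial slice in the four in-plane directions and the feature
is the unweighted mean over all non-empty (slice, direction) pairs —
runs never cross slices, so excluding artifacted slices cannot create
spurious out-of-plane runs.  In the 3D mode (artifact-free ROIs only),
one matrix per direction is accumulated over the whole ROI for the 13
unique directions of the 26-neighbourhood and the per-direction feature
values are averaged with the same skip-empty rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, Iterator, Optional

import numpy as np

from .imaging import CtVolume, DiscretisedRoi, N_BINS, RoiMask, SliceSelection

__all__ = [
    "IN_PLANE_DIRECTIONS",
    "DIRECTIONS_3D",
    "GlcmMatrix",
    "GlrlmMatrix",
    "FeatureValue",
    "EmptyMatrixError",
    "build_glcm",
    "build_glrlm",
    "sre",
    "inverse_difference_moment",
    "max_hu",
    "aggregate_2d",
    "compute_2d",
    "compute_3d",
    "register_feature",
    "FEATURES",
]

#: The four unique in-plane offsets (0, 45, 90, 135 degrees) as steps
#: along array axes 0 and 1 of an axial slice.
IN_PLANE_DIRECTIONS: tuple[tuple[int, int], ...] = ((1, 0), (1, 1), (0, 1), (-1, 1))

#: The 13 unique directions of the 26-connected 3D neighbourhood
#: (one representative per +/- pair).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13


class EmptyMatrixError(ValueError):
    """A texture matrix holds no pairs/runs; its feature is undefined."""


@dataclass(frozen=True)
class GlcmMatrix:
    """Symmetric co-occurrence counts for one offset (both orderings counted)."""

    counts: np.ndarray  # (N_BINS, N_BINS)

    @property
    def n_pairs(self) -> float:
        return float(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_pairs == 0

    def probabilities(self) -> np.ndarray:
        if self.is_empty:
            raise EmptyMatrixError("GLCM has no co-occurring pairs")
        return self.counts / self.counts.sum()


@dataclass(frozen=True)
class GlrlmMatrix:
    """Run counts ``r(i, j)`` — grey level i (rows), run length j (columns, 1-based)."""

    counts: np.ndarray  # (N_BINS, Lmax)

    @property
    def n_runs(self) -> float:
        return float(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_runs == 0


@dataclass(frozen=True)
class FeatureValue:
    name: str
    gland: str
    mode: str  # "2d" | "3d"
    value: float


# ---------------------------------------------------------------------------
# matrix construction


def _crop(labels: np.ndarray) -> np.ndarray:
    """Crop to the bounding box of non-zero labels (no-op when empty)."""
    nz = np.nonzero(labels)
    if nz[0].size == 0:
        return labels[tuple(slice(0, 0) for _ in labels.shape)]
    sl = tuple(slice(int(ax.min()), int(ax.max()) + 1) for ax in nz)
    return labels[sl]


def _pair_counts(labels: np.ndarray, direction: tuple[int, ...]) -> np.ndarray:
    """Ordered pair counts for one offset, accumulated symmetrically."""
    sl_a, sl_b = [], []
    for dim, step in zip(labels.shape, direction):
        if step >= 0:
            sl_a.append(slice(0, max(dim - step, 0)))
            sl_b.append(slice(step, dim))
        else:
            sl_a.append(slice(-step, dim))
            sl_b.append(slice(0, max(dim + step, 0)))
    a = labels[tuple(sl_a)]
    b = labels[tuple(sl_b)]
    valid = (a > 0) & (b > 0)
    counts = np.zeros((N_BINS, N_BINS))
    if valid.any():
        np.add.at(counts, (a[valid].astype(int) - 1, b[valid].astype(int) - 1), 1.0)
    return counts + counts.T


def _iter_lines(shape: tuple[int, ...], direction: tuple[int, ...]) -> Iterator[tuple]:
    """Yield index tuples for every maximal lattice line along ``direction``."""
    moving = [ax for ax, s in enumerate(direction) if s != 0]
    if not moving:
        raise ValueError("direction must be non-zero")
    # start cells: stepping backwards leaves the grid
    grids = np.indices(shape)
    start = np.zeros(shape, dtype=bool)
    for ax in moving:
        if direction[ax] > 0:
            start |= grids[ax] == 0
        else:
            start |= grids[ax] == shape[ax] - 1
    for s in np.argwhere(start):
        length = min(
            (shape[ax] - s[ax]) if direction[ax] > 0 else (s[ax] + 1) for ax in moving
        )
        yield tuple(
            s[ax] + direction[ax] * np.arange(length) if direction[ax] != 0
            else np.full(length, s[ax])
            for ax in range(len(shape))
        )


def _run_counts(labels: np.ndarray, direction: tuple[int, ...]) -> np.ndarray:
    """GLRLM counts: maximal runs of equal non-zero labels along lattice lines.

    Runs break at mask boundaries (label 0), label changes and grid edges.
    """
    parts: list[np.ndarray] = []
    zero = np.zeros(1, dtype=labels.dtype)
    for coords in _iter_lines(labels.shape, direction):
        parts.append(labels[coords])
        parts.append(zero)
    if not parts:
        return np.zeros((N_BINS, 1))
    seq = np.concatenate(parts).astype(int)
    change = np.flatnonzero(np.diff(seq)) + 1
    bounds = np.concatenate(([0], change, [seq.size]))
    vals = seq[bounds[:-1]]
    lengths = np.diff(bounds)
    keep = vals > 0
    vals, lengths = vals[keep], lengths[keep]
    lmax = int(lengths.max()) if lengths.size else 1
    counts = np.zeros((N_BINS, lmax))
    if vals.size:
        np.add.at(counts, (vals - 1, lengths - 1), 1.0)
    return counts


def _max_line_length(shape: tuple[int, ...], direction: tuple[int, ...]) -> int:
    moving = [ax for ax, s in enumerate(direction) if s != 0]
    if not moving or 0 in shape:
        return 0
    return min(shape[ax] for ax in moving)


def build_glcm(
    roi: DiscretisedRoi, slice_index: int, direction: tuple[int, int]
) -> GlcmMatrix:
    """Symmetric GLCM of one retained slice at one in-plane offset."""
    if direction not in IN_PLANE_DIRECTIONS:
        raise ValueError(f"direction {direction} not one of {IN_PLANE_DIRECTIONS}")
    if slice_index not in roi.selection.retained:
        raise ValueError(f"slice {slice_index} is not retained")
    plane = _crop(roi.labels[:, :, slice_index])
    return GlcmMatrix(_pair_counts(plane, direction))


def build_glrlm(
    roi: DiscretisedRoi, slice_index: int, direction: tuple[int, int]
) -> GlrlmMatrix:
    """GLRLM of one retained slice at one in-plane direction."""
    if direction not in IN_PLANE_DIRECTIONS:
        raise ValueError(f"direction {direction} not one of {IN_PLANE_DIRECTIONS}")
    if slice_index not in roi.selection.retained:
        raise ValueError(f"slice {slice_index} is not retained")
    plane = _crop(roi.labels[:, :, slice_index])
    return GlrlmMatrix(_run_counts(plane, direction))


# ---------------------------------------------------------------------------
# features


def sre(m: GlrlmMatrix) -> float:
    """Short Run Emphasis: ``(1/Nr) sum_ij r(i,j)/j**2``."""
    if m.is_empty:
        raise EmptyMatrixError("GLRLM has no runs")
    lengths = np.arange(1, m.counts.shape[1] + 1, dtype=float)
    return float((m.counts / lengths**2).sum() / m.n_runs)


def inverse_difference_moment(m: GlcmMatrix) -> float:
    """``sum_ij p(i,j) / (1 + (i-j)**2)``; 1 for a homogeneous region."""
    p = m.probabilities()
    i, j = np.indices(p.shape)
    return float((p / (1.0 + (i - j) ** 2)).sum())


def max_hu(volume: CtVolume, mask: RoiMask, selection: SliceSelection) -> int:
    """Maximum raw HU over in-mask voxels on retained slices (no clamping)."""
    mask.validate_for(volume)
    if len(selection) == 0:
        raise ValueError("empty slice selection")
    keep = np.zeros(volume.voxels.shape, dtype=bool)
    keep[:, :, list(selection.retained)] = True
    keep &= mask.flags
    if not keep.any():
        raise ValueError("mask has no voxels on the retained slices")
    return int(volume.voxels[keep].max())


def aggregate_2d(fragments: list[Optional[float]]) -> Optional[float]:
    """Unweighted mean over non-empty (slice, direction) fragments.

    ``None`` fragments (empty matrices) are excluded from numerator and
    denominator; returns ``None`` when every fragment is empty.
    """
    values = [v for v in fragments if v is not None]
    if not values:
        return None
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# feature registry and the two aggregation modes


@dataclass(frozen=True)
class FeatureDef:
    name: str
    matrix: str  # "glcm" | "glrlm"
    func: Callable


FEATURES: dict[str, FeatureDef] = {}


def register_feature(name: str, matrix: str, func: Callable) -> FeatureDef:
    """Add a texture feature to the registry (matrix kind + scalarisation)."""
    if matrix not in ("glcm", "glrlm"):
        raise ValueError(f"matrix kind must be 'glcm' or 'glrlm', got {matrix!r}")
    fd = FeatureDef(name, matrix, func)
    FEATURES[name] = fd
    return fd


register_feature("sre", "glrlm", sre)
register_feature("inverse_difference_moment", "glcm", inverse_difference_moment)


def _matrix_for(labels: np.ndarray, kind: str, direction: tuple[int, ...]):
    if kind == "glcm":
        return GlcmMatrix(_pair_counts(labels, direction))
    return GlrlmMatrix(_run_counts(labels, direction))


def compute_2d(roi: DiscretisedRoi, feature: str) -> Optional[float]:
    """Slice-wise feature: per (retained slice, in-plane direction), then mean."""
    fd = FEATURES[feature]
    fragments: list[Optional[float]] = []
    for k in roi.selection.retained:
        plane = _crop(roi.labels[:, :, k])
        for d in IN_PLANE_DIRECTIONS:
            m = _matrix_for(plane, fd.matrix, d)
            fragments.append(None if m.is_empty else fd.func(m))
    return aggregate_2d(fragments)


def compute_3d(roi: DiscretisedRoi, feature: str) -> Optional[float]:
    """Volumetric feature over the 13 unique 3D directions, averaged.

    Requires an artifact-free ROI (no excluded slices): runs must not jump
    across missing planes.  Directions along which the ROI bounding box
    cannot host any line of length >= 2 are geometrically degenerate and
    skipped — on a one-slice ROI this leaves exactly the four in-plane
    directions.
    """
    if roi.selection.excluded_fraction > 0:
        raise ValueError("3D mode requires a contiguous ROI (no excluded slices)")
    fd = FEATURES[feature]
    box = _crop(roi.labels)
    fragments: list[Optional[float]] = []
    for d in DIRECTIONS_3D:
        if _max_line_length(box.shape, d) < 2:
            continue
        m = _matrix_for(box, fd.matrix, d)
        fragments.append(None if m.is_empty else fd.func(m))
    return aggregate_2d(fragments)
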