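"""Volume/mask data model, metal-artifact slice exclusion and intensity discretisation.

CT volumes carry Hounsfield units (HU) on a regular grid; the axial
(superior-inferior) direction is the third array axis throughout the
package.  Dental implants produce bright streak artifacts on individual
axial slices; any slice whose in-plane maximum exceeds a configurable HU
threshold is dropped from the analysis of every gland it intersects.
Retained in-mask voxels are then discretised into fixed-width intensity
bins (25 HU wide, spanning [-200, 200] HU, i.e. 16 bins) for the texture
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "BIN_WIDTH",
    "BIN_RANGE",
    "N_BINS",
    "DEFAULT_ARTIFACT_HU",
    "CtVolume",
    "RoiMask",
    "SliceSelection",
    "DiscretisedRoi",
    "EmptyRoiError",
    "exclude_artifact_slices",
    "discretise",
]

HU_MIN = -1024
HU_MAX = 3071
BIN_WIDTH = 25
BIN_RANGE = (-200, 200)
N_BINS = (BIN_RANGE[1] - BIN_RANGE[0]) // BIN_WIDTH  # 16
DEFAULT_ARTIFACT_HU = 2000.0


class EmptyRoiError(ValueError):
    """Raised when artifact exclusion removes every mask-bearing slice."""


@dataclass(frozen=True)
class CtVolume:
    """A 3D CT intensity grid in Hounsfield units.

    Parameters
    ----------
    voxels
        Integer HU values, shape ``(nx, ny, nz)``; axis 2 is axial.
    spacing
        Voxel size ``(dx, dy, dz)`` in millimetres; all components positive.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.074, 1.074, 3.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D voxel grid, got ndim={vox.ndim}")
        if not np.issubdtype(vox.dtype, np.integer):
            raise ValueError("HU voxels must be an integer array")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if vox.size and (vox.min() < HU_MIN or vox.max() > HU_MAX):
            raise ValueError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: "
                f"range [{vox.min()}, {vox.max()}]"
            )
        object.__setattr__(self, "voxels", vox)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    @classmethod
    def from_nifti(cls, path) -> "CtVolume":
        img = nib.load(str(path))
        vox = np.asarray(img.dataobj).astype(np.int16)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(vox, zooms)

    def to_nifti(self, path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.voxels.astype(np.int16), affine), str(path))


@dataclass(frozen=True)
class RoiMask:
    """A binary region-of-interest mask on the same grid as its volume."""

    flags: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=bool)
        if flags.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={flags.ndim}")
        if not flags.any():
            raise ValueError(f"mask '{self.label}' contains no voxels")
        object.__setattr__(self, "flags", flags)

    def validate_for(self, volume: CtVolume) -> None:
        if self.flags.shape != volume.voxels.shape:
            raise ValueError(
                f"mask shape {self.flags.shape} != volume shape {volume.voxels.shape}"
            )

    @property
    def bearing_slices(self) -> np.ndarray:
        """Axial slice indices that contain at least one mask voxel."""
        return np.flatnonzero(self.flags.any(axis=(0, 1)))

    @classmethod
    def from_nifti(cls, path, label: str = "roi") -> "RoiMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) > 0, label)

    def to_nifti(self, path, spacing=(1.074, 1.074, 3.0)) -> None:
        affine = np.diag([*spacing, 1.0])
        nib.save(nib.Nifti1Image(self.flags.astype(np.uint8), affine), str(path))


@dataclass(frozen=True)
class SliceSelection:
    """Axial slices retained after artifact exclusion.

    ``excluded_fraction`` is the fraction of mask-bearing slices removed.
    """

    retained: tuple[int, ...]
    excluded_fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "retained", tuple(sorted(int(k) for k in self.retained)))
        if not 0.0 <= self.excluded_fraction <= 1.0:
            raise ValueError(f"excluded_fraction {self.excluded_fraction} not in [0, 1]")

    def __len__(self) -> int:
        return len(self.retained)


@dataclass(frozen=True)
class DiscretisedRoi:
    """Bin labels 1..16 on in-mask voxels of retained slices; 0 elsewhere."""

    labels: np.ndarray
    selection: SliceSelection

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.size and labels.max(initial=0) > N_BINS:
            raise ValueError("bin labels exceed the number of bins")
        object.__setattr__(self, "labels", labels)


def exclude_artifact_slices(
    volume: CtVolume,
    mask: RoiMask,
    hu_threshold: float = DEFAULT_ARTIFACT_HU,
) -> SliceSelection:
    """Drop axial slices containing metal-artifact intensities.

    A slice is excluded iff *any* voxel on it — anywhere in-plane, not only
    inside the mask — exceeds ``hu_threshold``.  Streaks from dental
    implants corrupt the whole plane, so in-mask intensities on such slices
    cannot be trusted even when the implant itself lies outside the gland.

    Raises
    ------
    EmptyRoiError
        If every mask-bearing slice is artifacted.
    """
    mask.validate_for(volume)
    if hu_threshold <= BIN_RANGE[1]:
        raise ValueError(f"hu_threshold must exceed {BIN_RANGE[1]} HU, got {hu_threshold}")
    bearing = mask.bearing_slices
    slice_max = volume.voxels.max(axis=(0, 1))
    retained = tuple(int(k) for k in bearing if slice_max[k] <= hu_threshold)
    if not retained:
        raise EmptyRoiError(
            f"empty ROI after exclusion: all {bearing.size} mask-bearing slices "
            f"of '{mask.label}' exceed {hu_threshold} HU"
        )
    frac = 1.0 - len(retained) / bearing.size
    return SliceSelection(retained, frac)


def discretise(volume: CtVolume, mask: RoiMask, selection: SliceSelection) -> DiscretisedRoi:
    """Assign 25-HU-wide bin labels to in-mask voxels on retained slices.

    Intensities are clamped into [-200, 200] HU; bins are left-closed,
    right-open except the top bin which also includes 200 HU.  Out-of-mask
    voxels and voxels on excluded slices carry label 0.
    """
    mask.validate_for(volume)
    if len(selection) == 0:
        raise EmptyRoiError("cannot discretise an empty slice selection")
    lo, hi = BIN_RANGE
    clamped = np.clip(volume.voxels, lo, hi)
    bins = np.minimum((clamped - lo) // BIN_WIDTH + 1, N_BINS).astype(np.uint8)
    keep = np.zeros(volume.voxels.shape, dtype=bool)
    keep[:, :, list(selection.retained)] = True
    keep &= mask.flags
    labels = np.where(keep, bins, 0).astype(np.uint8)
    return DiscretisedRoi(labels, selection)
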