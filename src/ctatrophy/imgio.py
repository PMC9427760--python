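"""NIfTI volume I/O and CT preprocessing.

Volumes are held in memory as ``(slices, rows, cols)`` arrays with the
axial slice axis first and slice index 0 at the most superior slice
("looking at the brain from top to bottom").  ``voxel_size_mm`` follows
NIfTI ``(x, y, z)`` order, so its third component is the slice thickness.

Preprocessing implements the standard brain-CT conditioning chain:
intensity windowing to the brain-tissue HU range, linear normalization
to [0, 1], masked histogram equalization, removal of brain-invisible
slices, and downsizing to the segmentation network's input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage import exposure
from skimage.transform import resize

__all__ = [
    "CTVolume",
    "LabelVolume",
    "SliceStack",
    "VALID_LABELS",
    "LABEL_BACKGROUND",
    "LABEL_CSF",
    "LABEL_GM",
    "LABEL_WM",
    "read_nifti",
    "write_nifti",
    "window_normalize",
    "equalize_histogram",
    "extract_slices",
    "resize_slice",
]

LABEL_BACKGROUND = 0
LABEL_CSF = 1
LABEL_GM = 2
LABEL_WM = 3
VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_CSF, LABEL_GM, LABEL_WM})

#: Tissue-class names used throughout the package, keyed by label value.
TISSUE_NAMES = {LABEL_CSF: "CSF", LABEL_GM: "GM", LABEL_WM: "WM"}


@dataclass
class _BaseVolume:
    """Shared geometry fields for CT and label volumes."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 3.3)
    axial_axis: int = 0
    superior_first: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if any(d < 1 for d in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be three positive reals, got {self.voxel_size_mm}")
        self.voxel_size_mm = vs
        if self.axial_axis != 0:
            raise ValueError("in-memory volumes are slice-major; axial_axis must be 0")

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.axial_axis]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass
class CTVolume(_BaseVolume):
    """3D grid of scalar CT intensities (HU or normalized)."""


@dataclass
class LabelVolume(_BaseVolume):
    """3D grid of tissue labels: 0=background, 1=CSF, 2=GM, 3=WM."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data, dtype=np.int16)
        present = set(np.unique(self.data).tolist())
        bad = present - VALID_LABELS
        if bad:
            raise ValueError(
                f"label volume contains out-of-set values {sorted(bad)}; "
                f"allowed labels are {sorted(VALID_LABELS)}"
            )


@dataclass
class SliceStack:
    """Ordered 2D axial slices retained from a volume.

    ``source_indices[i]`` is the slice index in the original volume from
    which ``slices[i]`` was taken (superior-first ordering preserved).
    """

    slices: np.ndarray  # (n, rows, cols)
    source_indices: np.ndarray  # (n,) strictly increasing
    n_source_slices: int = 0

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        self.source_indices = np.asarray(self.source_indices, dtype=int)
        if len(self.slices) != len(self.source_indices):
            raise ValueError("slices and source_indices must have equal length")
        if len(self.source_indices) > 1 and not np.all(np.diff(self.source_indices) > 0):
            raise ValueError("source_indices must be strictly increasing")
        if self.n_source_slices == 0 and len(self.source_indices):
            self.n_source_slices = int(self.source_indices[-1]) + 1

    def __len__(self) -> int:
        return len(self.slices)


def _to_disk_order(data: np.ndarray) -> np.ndarray:
    # memory (slice, row, col) superior-first -> file (x=col, y=row, z) with z
    # ascending inferior->superior (RAS+).
    return np.ascontiguousarray(data[::-1].transpose(2, 1, 0))


def _from_disk_order(data: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(data.transpose(2, 1, 0)[::-1])


def write_nifti(vol: _BaseVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (.nii or .nii.gz), honoring voxel sizes."""
    path = Path(path)
    affine = np.diag([*vol.voxel_size_mm, 1.0])
    data = _to_disk_order(vol.data)
    if isinstance(vol, LabelVolume):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path, *, label: bool = False) -> CTVolume | LabelVolume:
    """Read a NIfTI-1 volume; ``label=True`` validates the tissue-label set.

    The file's z axis is assumed RAS-oriented (z ascending toward the
    vertex, as written by :func:`write_nifti`); it is flipped so that
    in-memory slice 0 is the most superior slice.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    try:
        img = nib.load(str(path))
        raw = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several types for bad files
        raise OSError(f"could not read {path} as NIfTI: {exc}") from exc
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = _from_disk_order(raw)
    if label:
        return LabelVolume(np.rint(data).astype(np.int16), voxel_size_mm=zooms)
    return CTVolume(data, voxel_size_mm=zooms)


def window_normalize(vol: CTVolume, window_lo: float = 0.0, window_hi: float = 80.0) -> CTVolume:
    """Clip intensities to ``[window_lo, window_hi]`` and rescale to [0, 1].

    The default window covers the brain-tissue HU range (CSF through
    GM/WM).  Rejects a degenerate window.
    """
    if not window_lo < window_hi:
        raise ValueError(f"degenerate window: lo={window_lo} must be < hi={window_hi}")
    clipped = np.clip(vol.data.astype(np.float64), window_lo, window_hi)
    scaled = (clipped - window_lo) / (window_hi - window_lo)
    return replace(vol, data=scaled)


def equalize_histogram(vol: CTVolume, brain_mask: np.ndarray, n_bins: int = 256) -> CTVolume:
    """CDF-based histogram equalization over in-brain voxels only.

    Input intensities must already be normalized to [0, 1]; background
    (out-of-mask) voxels are excluded from the histogram and zeroed in
    the output.  The mapping is the empirical CDF, so the rank order of
    distinct in-brain intensities is preserved.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != vol.data.shape:
        raise ValueError("brain_mask shape must match volume")
    if not mask.any():
        raise ValueError("all-background volume: histogram equalization undefined")
    data = vol.data
    if data.min() < 0 or data.max() > 1:
        raise ValueError("equalize_histogram expects intensities in [0, 1]; window_normalize first")
    eq = exposure.equalize_hist(data, nbins=n_bins, mask=mask)
    out = np.where(mask, eq, 0.0)
    return replace(vol, data=out)


def extract_slices(
    vol: _BaseVolume, brain_mask: np.ndarray, min_brain_fraction: float = 0.01
) -> SliceStack:
    """Retain axial slices whose in-mask pixel fraction meets the threshold.

    Removes "brain-invisible" slices before 2D processing.  Raises if no
    slice passes rather than returning a silent empty stack.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != vol.data.shape:
        raise ValueError("brain_mask shape must match volume")
    if not 0.0 <= min_brain_fraction <= 1.0:
        raise ValueError("min_brain_fraction must be in [0, 1]")
    per_slice = mask.reshape(mask.shape[0], -1).mean(axis=1)
    keep = np.flatnonzero(per_slice >= min_brain_fraction)
    if keep.size == 0:
        raise ValueError(
            f"no slice has brain fraction >= {min_brain_fraction} "
            f"(max observed {per_slice.max():.4f})"
        )
    return SliceStack(vol.data[keep], keep, n_source_slices=vol.n_slices)


def resize_slice(
    slice2d: np.ndarray, target_shape: tuple[int, int] = (128, 128), *, is_label: bool = False
) -> np.ndarray:
    """Resize one axial slice to the network input resolution.

    Intensity slices use linear interpolation with anti-aliasing when
    shrinking; label slices use nearest-neighbor so no new label values
    are created.
    """
    arr = np.asarray(slice2d)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {arr.shape}")
    if arr.shape == tuple(target_shape):
        return arr
    if is_label:
        out = resize(
            arr, target_shape, order=0, preserve_range=True, anti_aliasing=False
        )
        return np.rint(out).astype(arr.dtype)
    shrinking = arr.shape[0] > target_shape[0] or arr.shape[1] > target_shape[1]
    return resize(
        arr.astype(np.float64), target_shape, order=1, preserve_range=True,
        anti_aliasing=shrinking,
    )
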