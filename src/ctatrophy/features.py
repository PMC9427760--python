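"""Eight global-cortical-atrophy features from a segmented label volume.

3D features are whole-brain tissue ratios plus the ventricle voxel
count; 2D features repeat the ratios on one reference axial slice (the
visible slice just superior to the first ventricle-containing slice,
scanning top to bottom) and count ventricle pixels on the "butterfly"
slice — the slice where the ventricle is largest.

The ventricle is separated from total CSF as the largest interior
CSF-labeled connected components: 6-connected components none of whose
voxels touch the brain-mask boundary, taken in decreasing size up to
two components (the two lateral lobes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imgio import LabelVolume, LABEL_CSF, LABEL_GM, LABEL_WM

__all__ = [
    "FeatureVector",
    "VentricleMask",
    "extract_ventricle",
    "select_reference_slice",
    "select_butterfly_slice",
    "compute_features",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureVector:
    """The eight atrophy features for one subject.

    Ratios share the whole-brain (or reference-slice) mask count as
    denominator, so GMWMR = GMR + WMR exactly.  Ventricle features stay
    raw voxel/pixel counts; scaling is handled downstream by the grader's
    feature standardization.
    """

    GMR3D: float
    WMR3D: float
    GMWMR3D: float
    Ven3D: int
    GMR2D: float
    WMR2D: float
    GMWMR2D: float
    Ven2D: int
    reference_slice_index: int
    butterfly_slice_index: int

    def __post_init__(self) -> None:
        for name in ("GMR3D", "WMR3D", "GMWMR3D", "GMR2D", "WMR2D", "GMWMR2D"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.Ven3D < 0 or self.Ven2D < 0:
            raise ValueError("ventricle counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([
            self.GMR3D, self.WMR3D, self.GMWMR3D, self.Ven3D,
            self.GMR2D, self.WMR2D, self.GMWMR2D, self.Ven2D,
        ], dtype=np.float64)


@dataclass
class VentricleMask:
    mask: np.ndarray
    n_components_used: int
    method_tag: str = "interior-csf-components"


def _mask_boundary(brain_mask: np.ndarray) -> np.ndarray:
    """Voxels of the mask with a 6-neighbor outside it (or on the grid edge)."""
    eroded = ndimage.binary_erosion(
        brain_mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return brain_mask & ~eroded


def extract_ventricle(
    labels: LabelVolume, brain_mask: np.ndarray, max_components: int = 2
) -> VentricleMask:
    """Interior CSF connected components, largest first, up to two.

    Components are 6-connected CSF voxels; a component touching the
    brain-mask boundary (sulcal CSF) stops the scan.  An empty result is
    returned with a warning, not raised: some atrophy-free volumes have
    no resolvable ventricle.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != labels.data.shape:
        raise ValueError("brain_mask shape must match labels")
    if not mask.any():
        raise ValueError("brain_mask is empty")
    csf = (labels.data == LABEL_CSF) & mask
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    comp, n_comp = ndimage.label(csf, structure=structure)
    boundary = _mask_boundary(mask)
    out = np.zeros(labels.data.shape, dtype=bool)
    used = 0
    if n_comp:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
        touches = np.zeros(n_comp, dtype=bool)
        touching_ids = np.unique(comp[boundary & (comp > 0)])
        touches[touching_ids - 1] = True
        for cid in np.argsort(-sizes, kind="stable") + 1:
            if touches[cid - 1]:
                continue  # sulcal CSF reaches the mask surface; not ventricle
            out |= comp == cid
            used += 1
            if used == max_components:
                break
    if used == 0:
        warnings.warn("no interior CSF component found; ventricle mask is empty", stacklevel=2)
    return VentricleMask(mask=out, n_components_used=used)


def _per_slice_counts(ventricle: VentricleMask) -> np.ndarray:
    return ventricle.mask.reshape(ventricle.mask.shape[0], -1).sum(axis=1)


def select_reference_slice(ventricle: VentricleMask) -> int:
    """The visible slice just prior to the ventricle, scanning top down.

    Slice index 0 is the most superior slice; if the ventricle already
    reaches it, the index clamps to 0 with a warning.  Fails on an empty
    ventricle mask (callers fall back explicitly).
    """
    counts = _per_slice_counts(ventricle)
    nonzero = np.flatnonzero(counts)
    if nonzero.size == 0:
        raise ValueError("empty ventricle mask: no reference slice defined")
    s_star = int(nonzero[0])
    if s_star == 0:
        warnings.warn("ventricle reaches the most superior slice; clamping reference to 0",
                      stacklevel=2)
        return 0
    return s_star - 1


def select_butterfly_slice(ventricle: VentricleMask) -> int:
    """The slice with the best-observed ventricle (maximum pixel count).

    Ties break toward the more superior (smaller) index.
    """
    counts = _per_slice_counts(ventricle)
    if counts.sum() == 0:
        raise ValueError("empty ventricle mask: no butterfly slice defined")
    return int(np.argmax(counts))  # argmax returns the first (most superior) maximum


def compute_features(
    labels: LabelVolume, brain_mask: np.ndarray, ventricle: VentricleMask
) -> FeatureVector:
    """Assemble the eight-feature vector for one subject.

    3D ratios divide tissue voxel counts by the brain-mask voxel count;
    2D ratios repeat this on the reference slice with its brain-mask
    pixel count as denominator.

    If the ventricle mask is empty (no resolvable ventricle), both
    ventricle counts are 0 and the mid-brain slice stands in for the
    reference and butterfly slices, with a warning.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != labels.data.shape:
        raise ValueError("brain_mask shape must match labels")
    n_brain = int(mask.sum())
    if n_brain == 0:
        raise ValueError("brain_mask is empty")
    gm3 = int(((labels.data == LABEL_GM) & mask).sum())
    wm3 = int(((labels.data == LABEL_WM) & mask).sum())
    ven3 = int(ventricle.mask.sum())

    if ventricle.mask.any():
        ref = select_reference_slice(ventricle)
        bfly = select_butterfly_slice(ventricle)
    else:
        brain_slices = np.flatnonzero(mask.reshape(mask.shape[0], -1).any(axis=1))
        ref = bfly = int(brain_slices[len(brain_slices) // 2])
        warnings.warn(
            f"empty ventricle mask: falling back to mid-brain slice {ref}", stacklevel=2
        )
    slice_mask = mask[ref]
    n_slice = int(slice_mask.sum())
    if n_slice == 0:
        raise ValueError(f"brain mask empty on reference slice {ref}")
    gm2 = int(((labels.data[ref] == LABEL_GM) & slice_mask).sum())
    wm2 = int(((labels.data[ref] == LABEL_WM) & slice_mask).sum())
    ven2 = int(ventricle.mask[bfly].sum())

    return FeatureVector(
        GMR3D=gm3 / n_brain,
        WMR3D=wm3 / n_brain,
        GMWMR3D=gm3 / n_brain + wm3 / n_brain,  # exact additivity by construction
        Ven3D=ven3,
        GMR2D=gm2 / n_slice,
        WMR2D=wm2 / n_slice,
        GMWMR2D=gm2 / n_slice + wm2 / n_slice,
        Ven2D=ven2,
        reference_slice_index=ref,
        butterfly_slice_index=bfly,
    )
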