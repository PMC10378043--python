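"""Reference-slice selection: the axial slice with maximal deep-grey-matter area.

The deep grey matter includes the thalamus, so the slice where its
cross-sectional area peaks approximates the clinical thalamic plane on which
the atrial width is measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import LabelVolume, axis_of

logger = logging.getLogger(__name__)


@dataclass
class ReferenceSlice:
    """Chosen axial slice: 0-based index along the superior-inferior axis."""

    index: int
    dgm_area_mm2: float
    profile: np.ndarray  # per-slice DGM area, mm^2

    def __post_init__(self):
        self.profile = np.asarray(self.profile, dtype=float)
        if self.index != int(np.argmax(self.profile)):
            raise ValueError("reference slice index is not the profile argmax")
        if self.dgm_area_mm2 <= 0:
            raise ValueError("reference slice has no deep grey matter area")


def dgm_area_profile(labels: LabelVolume) -> np.ndarray:
    """Deep-grey-matter area (mm^2) per axial slice.

    Axial slices are taken along the superior-inferior axis named by the
    volume's orientation code; the returned profile has one entry per slice.
    """
    ax_si = axis_of(labels.orientation, "SI")
    dgm = labels.mask_of("deep_grey_matter")
    in_plane = [labels.spacing[i] for i in range(3) if i != ax_si]
    pixel_area = in_plane[0] * in_plane[1]
    sum_axes = tuple(i for i in range(3) if i != ax_si)
    return dgm.sum(axis=sum_axes).astype(float) * pixel_area


def select_reference_slice(labels: LabelVolume) -> ReferenceSlice:
    """Pick the axial slice maximizing DGM area; ties break to the smallest index."""
    profile = dgm_area_profile(labels)
    if profile.max() <= 0:
        raise ValueError("cannot select reference slice: no deep grey matter voxels")
    index = int(np.argmax(profile))  # argmax returns the first (smallest) index on ties
    ax_si = axis_of(labels.orientation, "SI")
    vent = labels.mask_of("ventricles")
    if not np.take(vent, index, axis=ax_si).any():
        logger.warning("reference slice %d contains no ventricle voxels", index)
    return ReferenceSlice(index=index, dgm_area_mm2=float(profile[index]), profile=profile)


__all__ = ["ReferenceSlice", "dgm_area_profile", "select_reference_slice"]
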