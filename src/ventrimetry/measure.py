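"""Atrial-width measurement on the reference slice.

Pipeline per case: split the ventricle label on the reference axial slice
into connected components (left ventricle, right ventricle, and possibly the
cavum septum pellucidum), refine each lateral ventricle by mean-intensity
binarization (removing the dark choroid-plexus glomus and low-intensity
segmentation fringe), fit the minimum-area rotated rectangle to the refined
mask, and report the width in mm.

Two width definitions are provided.  ``minrect`` (default, deterministic)
reports the short side of the minimum-area rectangle — the diameter
perpendicular to the ventricle's long axis.  ``plexus_margin`` refines this
toward clinical practice: after rotating the ventricle so its long axis is
horizontal, the width is read at the posterior margin of the removed
(choroid-plexus) cluster, i.e. the vertical extent of the refined mask at
that station.  ``auto`` uses ``plexus_margin`` when a plexus was removed and
``minrect`` otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label, regionprops

from .core_io import LabelVolume, VolumeGrid, axis_of
from .geometry import min_area_rect_points
from .slice_select import ReferenceSlice, select_reference_slice

logger = logging.getLogger(__name__)

#: Connected components smaller than this (pixels) are treated as speckle.
MIN_COMPONENT_AREA = 4


class StageError(RuntimeError):
    """Pipeline failure carrying the name of the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PlanarMask:
    """A 2D boolean region on one axial slice.

    ``axes`` holds the two anatomical letters of the mask's row and column
    axes (e.g. ``"RA"``: rows grow toward subject right, columns toward
    anterior), inherited from the parent volume's orientation code.
    """

    mask: np.ndarray
    spacing: tuple[float, float]
    slice_index: int
    axes: str = "RA"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("planar mask must be 2D")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if any(s <= 0 for s in self.spacing):
            raise ValueError("planar spacing must be positive")

    @property
    def area_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def pitch_mm(self) -> float:
        """Isotropic in-plane pixel pitch; anisotropy leaves a scalar width ill-defined."""
        r, c = self.spacing
        if abs(r - c) > 0.01 * max(r, c):
            raise ValueError(f"anisotropic in-plane spacing {self.spacing}; "
                             "a scalar width is ill-defined")
        return (r + c) / 2.0

    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())

    def points_mm(self) -> np.ndarray:
        rr, cc = np.nonzero(self.mask)
        return np.column_stack([rr * self.spacing[0], cc * self.spacing[1]])


@dataclass
class RotatedRect:
    """Minimum-area rotated rectangle, sides in mm, center in pixel coordinates."""

    center: tuple[float, float]
    long_side_mm: float
    short_side_mm: float
    angle_deg: float  # orientation of the long side, [-90, 90); 0 = along columns

    def __post_init__(self):
        if not self.long_side_mm >= self.short_side_mm > 0:
            raise ValueError("rectangle sides must satisfy long >= short > 0")
        if not -90.0 <= self.angle_deg < 90.0:
            raise ValueError("angle must lie in [-90, 90)")


@dataclass
class VentricleMeasurement:
    """One ventricle's width with provenance."""

    side: str
    width_mm: float
    method: str
    slice_index: int
    plexus_detected: bool
    rect: RotatedRect
    threshold_used: float

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")
        if self.method not in ("minrect", "plexus_margin"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.width_mm <= 0:
            raise ValueError("width must be positive")
        if self.width_mm > self.rect.long_side_mm + 1e-9:
            raise ValueError("width exceeds the rectangle's long side")


@dataclass
class BinarizedSegment:
    """Result of mean-intensity refinement of one ventricle component."""

    mask: PlanarMask          # kept (refined) region
    removed: PlanarMask       # component minus kept region
    threshold: float          # the mean intensity m
    plexus_detected: bool     # a substantial below-mean cluster was removed


def _slice_axes(orientation: str) -> tuple[int, str]:
    ax_si = axis_of(orientation, "SI")
    in_plane = "".join(c for i, c in enumerate(orientation) if i != ax_si)
    return ax_si, in_plane


def extract_components(labels: LabelVolume, ref: ReferenceSlice,
                       min_area: int = MIN_COMPONENT_AREA) -> list[PlanarMask]:
    """8-connected ventricle components on the reference slice, largest first."""
    ax_si, axes = _slice_axes(labels.orientation)
    vent = np.take(labels.mask_of("ventricles"), ref.index, axis=ax_si)
    if not vent.any():
        raise StageError("extract_components", "no ventricle on reference slice")
    in_plane = tuple(labels.spacing[i] for i in range(3) if i != ax_si)
    lab = cc_label(vent, connectivity=2)
    comps = []
    for p in regionprops(lab):
        if p.area < min_area:
            logger.info("dropping %d-pixel speckle component on slice %d", p.area, ref.index)
            continue
        comps.append(PlanarMask(lab == p.label, in_plane, ref.index, axes))
    if not comps:
        raise StageError("extract_components",
                         f"all ventricle components below the {min_area}-pixel area floor")
    comps.sort(key=lambda m: -m.area_pixels)
    return comps


def _lr_axis(axes: str) -> tuple[int, int]:
    """(in-plane axis index of left-right, sign) with sign +1 if it grows toward right."""
    for i, letter in enumerate(axes):
        if letter in "LR":
            return i, (+1 if letter == "R" else -1)
    raise ValueError(f"in-plane axes {axes!r} carry no left-right direction")


def assign_laterality(components: list[PlanarMask],
                      axes: str | None = None) -> dict[str, PlanarMask]:
    """Name the two largest components left/right; a middle third one is the CSP.

    ``axes`` defaults to the components' own in-plane anatomical letters.
    """
    if len(components) < 2:
        raise StageError("assign_laterality", "cannot separate ventricles: "
                         f"found {len(components)} component(s), need 2")
    axes = axes if axes is not None else components[0].axes
    lr, sign = _lr_axis(axes)
    a, b = components[0], components[1]
    ca, cb = a.centroid()[lr], b.centroid()[lr]
    midline = (a.mask.shape[lr] - 1) / 2.0
    if (ca - midline) * (cb - midline) > 0:
        logger.warning("both large ventricle components lie on the same side of the "
                       "midline; assigning by relative position")
    # larger coordinate is subject-right when the axis grows toward R
    if (ca - cb) * sign > 0:
        right, left = a, b
        cr, cl = ca, cb
    else:
        right, left = b, a
        cr, cl = cb, ca
    out = {"right": right, "left": left}
    for extra in components[2:]:
        ce = extra.centroid()[lr]
        lo, hi = min(cl, cr), max(cl, cr)
        if lo < ce < hi and "csp" not in out:
            out["csp"] = extra
        else:
            logger.info("ignoring extra ventricle component at %s position %.1f",
                        axes[lr], ce)
    return out


def _intensity_slice(intensity: VolumeGrid, component: PlanarMask) -> np.ndarray:
    ax_si = axis_of(intensity.orientation, "SI")
    sl = np.take(intensity.data, component.slice_index, axis=ax_si)
    if sl.shape != component.mask.shape:
        raise ValueError("intensity volume is not co-registered with the component")
    return np.asarray(sl, dtype=float)


def binarize_segment(intensity: VolumeGrid, component: PlanarMask,
                     min_cluster_area: int = MIN_COMPONENT_AREA) -> BinarizedSegment:
    """Refine a component by keeping pixels at or above its mean intensity.

    The threshold m is the mean intensity over the component; pixels with
    intensity >= m are kept, and only the largest 8-connected piece of the
    kept set is retained.  The removed remainder typically holds the dark
    choroid plexus and segmentation fringe.  If nothing survives, the input
    component is returned unchanged with ``plexus_detected=False``.
    """
    if component.area_pixels == 0:
        raise ValueError("empty component")
    sl = _intensity_slice(intensity, component)
    m = float(sl[component.mask].mean())
    kept = component.mask & (sl >= m)
    if kept.any():
        lab = cc_label(kept, connectivity=2)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        kept = lab == int(np.argmax(sizes))
    if not kept.any():
        logger.info("binarization emptied the component; falling back to the input mask")
        return BinarizedSegment(
            mask=component,
            removed=PlanarMask(np.zeros_like(component.mask), component.spacing,
                               component.slice_index, component.axes),
            threshold=m, plexus_detected=False)
    removed = component.mask & ~kept
    plexus = False
    if removed.any():
        rlab = cc_label(removed, connectivity=2)
        rsizes = np.bincount(rlab.ravel())
        plexus = bool(len(rsizes) > 1 and rsizes[1:].max() >= min_cluster_area)
    return BinarizedSegment(
        mask=PlanarMask(kept, component.spacing, component.slice_index, component.axes),
        removed=PlanarMask(removed, component.spacing, component.slice_index,
                           component.axes),
        threshold=m, plexus_detected=plexus)


def min_area_rect(component: PlanarMask) -> RotatedRect:
    """Minimum-area rotated rectangle over the mask's pixel centers, in mm.

    Side lengths are augmented by one pixel pitch to account for pixel
    extent; a degenerate (collinear) mask yields a short side of one pitch.
    """
    if component.area_pixels == 0:
        raise ValueError("cannot fit a rectangle to an empty mask")
    pitch = component.pitch_mm
    pts = component.points_mm()
    center_mm, (e1, e2), d = min_area_rect_points(pts)
    s1, s2 = e1 + pitch, e2 + pitch
    if s1 >= s2:
        long_mm, short_mm, dlong = s1, s2, d
    else:
        long_mm, short_mm, dlong = s2, s1, np.array([-d[1], d[0]])
    angle = math.degrees(math.atan2(dlong[0], dlong[1]))
    angle = (angle + 90.0) % 180.0 - 90.0
    if angle == 90.0:  # fold the half-open interval
        angle = -90.0
    return RotatedRect(
        center=(float(center_mm[0] / component.spacing[0]),
                float(center_mm[1] / component.spacing[1])),
        long_side_mm=float(long_mm), short_side_mm=float(short_mm),
        angle_deg=float(angle))


def _posterior_vector(axes: str) -> np.ndarray:
    """In-plane (row, col) unit vector pointing toward subject posterior."""
    for i, letter in enumerate(axes):
        if letter in "AP":
            v = np.zeros(2)
            v[i] = -1.0 if letter == "A" else 1.0
            return v
    raise ValueError(f"in-plane axes {axes!r} carry no anterior-posterior direction")


def _plexus_margin_width(refined: PlanarMask, removed: PlanarMask,
                         rect: RotatedRect, min_cluster_area: int) -> float | None:
    """Width at the posterior plexus margin, or None when no usable cluster exists."""
    rlab = cc_label(removed.mask, connectivity=2)
    clusters = [p for p in regionprops(rlab) if p.area >= min_cluster_area]
    if not clusters:
        return None
    pitch = refined.pitch_mm
    post = _posterior_vector(refined.axes)
    # most-posterior removed cluster
    target = max(clusters, key=lambda p: float(np.dot(p.centroid, post)))
    cpts = np.column_stack(np.nonzero(rlab == target.label)) * np.array(refined.spacing)

    theta = math.radians(rect.angle_deg)
    dlong = np.array([math.sin(theta), math.cos(theta)])
    dshort = np.array([-dlong[1], dlong[0]])
    pts = refined.points_mm()
    x = pts @ dlong           # along the (horizontal) long axis
    y = pts @ dshort
    cx_cluster = cpts @ dlong
    centroid_x = float(x.mean())
    lo, hi = float(cx_cluster.min()), float(cx_cluster.max())
    station = lo if abs(lo - centroid_x) <= abs(hi - centroid_x) else hi
    for half in (pitch / 2, pitch):  # widen once if the exact column is empty
        col = np.abs(x - station) <= half + 1e-9
        if col.any():
            width = float(y[col].max() - y[col].min() + pitch)
            return min(width, rect.long_side_mm)
    return None  # pragma: no cover


def measure_width(intensity: VolumeGrid, component: PlanarMask,
                  mode: str = "minrect", side: str = "right",
                  min_cluster_area: int = MIN_COMPONENT_AREA) -> VentricleMeasurement:
    """Measure one ventricle component's width in mm."""
    if mode not in ("minrect", "plexus_margin", "auto"):
        raise ValueError(f"unknown measurement mode {mode!r}")
    seg = binarize_segment(intensity, component, min_cluster_area)
    if seg.mask.area_pixels == 0:
        raise StageError("measure_width", "empty refined mask")  # pragma: no cover
    rect = min_area_rect(seg.mask)
    method, width = "minrect", rect.short_side_mm
    if mode == "plexus_margin" or (mode == "auto" and seg.plexus_detected):
        w = _plexus_margin_width(seg.mask, seg.removed, rect, min_cluster_area)
        if w is not None:
            method, width = "plexus_margin", w
        else:
            logger.info("no removed cluster to anchor plexus_margin; using minrect")
    return VentricleMeasurement(
        side=side, width_mm=float(width), method=method,
        slice_index=component.slice_index, plexus_detected=seg.plexus_detected,
        rect=rect, threshold_used=seg.threshold)


def measure_case(intensity: VolumeGrid, labels: LabelVolume, mode: str = "minrect"
                 ) -> tuple[VentricleMeasurement, VentricleMeasurement, ReferenceSlice]:
    """Full per-case measurement: reference slice, components, laterality, widths."""
    if intensity.shape != labels.shape:
        raise StageError("measure_case", "intensity and label volumes differ in shape")
    if intensity.orientation != labels.orientation:
        raise StageError("measure_case", "intensity and label volumes differ in orientation")
    try:
        ref = select_reference_slice(labels)
    except ValueError as exc:
        raise StageError("select_reference_slice", str(exc)) from exc
    comps = extract_components(labels, ref)
    sides = assign_laterality(comps)
    out = {}
    for side in ("right", "left"):
        try:
            out[side] = measure_width(intensity, sides[side], mode=mode, side=side)
        except ValueError as exc:
            raise StageError("measure_width", f"{side}: {exc}") from exc
    return out["right"], out["left"], ref


__all__ = [
    "MIN_COMPONENT_AREA", "StageError", "PlanarMask", "RotatedRect",
    "VentricleMeasurement", "BinarizedSegment", "extract_components",
    "assign_laterality", "binarize_segment", "min_area_rect",
    "measure_width", "measure_case",
]
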