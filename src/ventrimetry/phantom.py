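"""Synthetic fetal-brain phantoms with known ventricle widths.

The phantom emulates the geometry the measurement pipeline relies on: a
white-matter brain ellipsoid wrapped in cortical grey matter and external
CSF, two ventricle-labeled ellipsoids whose axial cross-section at a chosen
reference slice has a known minor diameter (the atrial width), a deep-grey-
matter blob whose axial area peaks exactly at that slice, an optional
midline cavum-septum-pellucidum component carrying the ventricle label, and
an optional dark choroid-plexus glomus in each ventricle's posterior third.
Intensities follow a T2-like contrast: CSF spaces bright, parenchyma
mid-grey, plexus dark (well below half the within-ventricle mean, so the
mean-intensity binarization provably excludes it).

Geometry is generated on an RAS grid (axis 0 toward subject right, axis 1
anterior, axis 2 superior).  All randomness (additive Gaussian intensity
noise) is driven by the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

from .core_io import LabelVolume, VolumeGrid

#: T2-like mean intensities per tissue label (arbitrary units).
TISSUE_INTENSITY = {0: 0.0, 1: 180.0, 2: 80.0, 3: 100.0, 4: 200.0, 5: 90.0, 6: 85.0, 7: 90.0}
PLEXUS_INTENSITY = 40.0  # << 50% of the within-ventricle mean
VENTRICLE_HEIGHT_MM = 12.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    Widths are the target atrial (minor-axis) diameters in mm of the
    ventricle cross-section on the reference slice; the in-plane rotation is
    the angle of each ventricle's major axis away from the anterior-posterior
    axis, mirror-symmetric between the two sides.
    """

    shape: tuple[int, int, int] = (144, 144, 80)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    right_width_mm: float = 7.0
    left_width_mm: float = 7.0
    ventricle_length_mm: float = 24.0
    in_plane_rotation_deg: float = 0.0
    dgm_slice: int = 40
    plexus: bool = True
    csp: bool = True
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 8 for n in self.shape):
            raise ValueError(f"shape too small for a phantom: {self.shape}")
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for w in (self.right_width_mm, self.left_width_mm):
            if not w < self.ventricle_length_mm:
                raise ValueError("ventricle widths must be smaller than ventricle_length_mm")
            if w < 2 * max(self.spacing[0], self.spacing[1]):
                raise ValueError("ventricle widths must span at least two in-plane voxels")
        if not 0 <= self.dgm_slice < self.shape[2]:
            raise ValueError(f"dgm_slice {self.dgm_slice} outside z range 0..{self.shape[2] - 1}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PhantomTruth:
    """Ground truth realized by voxelization, recorded for downstream tests."""

    right_width_mm: float
    left_width_mm: float
    reference_slice: int
    plexus_centroids: dict = field(default_factory=dict)  # side -> (i, j, k) voxel coords
    component_count_on_slice: int = 0
    ventricle_centers_vox: dict = field(default_factory=dict)  # side -> (i, j) on slice
    rotation_deg: float = 0.0


def _snap_center(px: float, n_vox: int) -> float:
    """Snap a fractional index so an axis-aligned diameter of n_vox voxels is exact.

    An even voxel count wants the ellipse center between two voxel centers,
    an odd count wants it on a voxel center.
    """
    if n_vox % 2 == 0:
        return math.floor(px) + 0.5
    return float(round(px))


def _ellipsoid(grids, center_mm, semi_mm):
    gx, gy, gz = grids
    cx, cy, cz = center_mm
    ax, ay, az = semi_mm
    return ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2 <= 1.0


def _rotated_ellipsoid(grids, center_mm, u, semi_u, semi_v, semi_z):
    """In-plane-rotated ellipsoid; ``u`` is the in-plane major-axis unit vector."""
    gx, gy, gz = grids
    cx, cy, cz = center_mm
    dx, dy, dz = gx - cx, gy - cy, gz - cz
    pu = dx * u[0] + dy * u[1]
    pv = -dx * u[1] + dy * u[0]
    return (pu / semi_u) ** 2 + (pv / semi_v) ** 2 + (dz / semi_z) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, LabelVolume, PhantomTruth]:
    """Generate an intensity volume, label volume and ground truth."""
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    if abs(sx - sy) > 0.01 * max(sx, sy):
        raise ValueError("phantom requires isotropic in-plane spacing")
    gx = (np.arange(nx, dtype=float) * sx)[:, None, None]
    gy = (np.arange(ny, dtype=float) * sy)[None, :, None]
    gz = (np.arange(nz, dtype=float) * sz)[None, None, :]
    grids = (gx, gy, gz)

    cx, cy = (nx - 1) * sx / 2.0, (ny - 1) * sy / 2.0
    z_ref = spec.dgm_slice * sz

    theta = math.radians(spec.in_plane_rotation_deg)
    a = spec.ventricle_length_mm / 2.0
    c = min(VENTRICLE_HEIGHT_MM, min(z_ref, (nz - 1) * sz - z_ref) * 2 - sz) / 2.0
    if c <= 0:
        raise ValueError("dgm_slice too close to the volume boundary for a ventricle")

    b = {"right": spec.right_width_mm / 2.0, "left": spec.left_width_mm / 2.0}
    halfext = {
        s: math.sqrt((a * math.sin(theta)) ** 2 + (b[s] * math.cos(theta)) ** 2)
        for s in ("right", "left")
    }
    offset = max(halfext.values()) + 2.0
    yext = math.sqrt((a * math.cos(theta)) ** 2 +
                     (max(b.values()) * math.sin(theta)) ** 2)

    brain_semi = ((nx - 1) * sx / 2 - 1.5, (ny - 1) * sy / 2 - 1.5, (nz - 1) * sz / 2 - 1.0)
    if offset + max(halfext.values()) + 1.0 > brain_semi[0]:
        raise ValueError("ventricles do not fit inside the phantom shape (x extent)")

    # Ventricle centers, snapped so axis-aligned diameters voxelize exactly.
    y_c = round((cy - 2.0) / sy) * sy
    if abs(y_c) + yext + 1.0 > 2 * brain_semi[1]:
        raise ValueError("ventricles do not fit inside the phantom shape (y extent)")
    centers = {}
    for side, sign in (("right", +1), ("left", -1)):
        n_vox = round(2 * b[side] / sx)
        px = _snap_center((cx + sign * offset) / sx, n_vox)
        centers[side] = (px * sx, y_c, z_ref)
    u_vec = {"right": (math.sin(theta), math.cos(theta)),
             "left": (-math.sin(theta), math.cos(theta))}

    labels = np.zeros(spec.shape, dtype=np.int16)
    cz = (nz - 1) * sz / 2.0
    brain_c = (cx, cy, cz)
    csf = _ellipsoid(grids, brain_c, brain_semi)
    gm = _ellipsoid(grids, brain_c, tuple(s - 1.0 for s in brain_semi))
    wm = _ellipsoid(grids, brain_c, tuple(s - 2.5 for s in brain_semi))
    labels[csf] = 1
    labels[gm] = 2
    labels[wm] = 3
    labels[_ellipsoid(grids, (cx, y_c - 18.0, max(z_ref - 12.0, 4.0)), (8.0, 5.0, 4.0))] = 5
    labels[_ellipsoid(grids, (cx, y_c - 6.0, max(z_ref - 14.0, 4.0)), (4.0, 4.0, 5.0))] = 7
    labels[_ellipsoid(grids, (cx, y_c + 16.0, z_ref), (5.0, 4.0, 4.0))] = 6

    vent_masks = {}
    for side in ("right", "left"):
        m = _rotated_ellipsoid(grids, centers[side], u_vec[side], a, b[side], c)
        if (m[0, :, :].any() or m[-1, :, :].any() or m[:, 0, :].any()
                or m[:, -1, :].any() or m[:, :, 0].any() or m[:, :, -1].any()):
            raise ValueError(f"{side} ventricle does not fit inside the phantom shape")
        labels[m] = 4
        vent_masks[side] = m
    if spec.csp:
        csp_mask = _ellipsoid(grids, (cx, y_c + 4.0, z_ref), (1.0, 3.0, 2.5))
        labels[csp_mask] = 4

    # Choroid plexus: an interior posterior sub-region of each ventricle,
    # dark in intensity but still ventricle-labeled.
    plexus_masks = {}
    for side in ("right", "left"):
        ccx, ccy, ccz = centers[side]
        ux, uy = u_vec[side]
        pu = (gx - ccx) * ux + (gy - ccy) * uy
        pv = -(gx - ccx) * uy + (gy - ccy) * ux
        dz = gz - ccz
        inner = ((pu + 0.5 * a) / (0.2 * a)) ** 2 + (pv / (0.55 * b[side])) ** 2 \
            + (dz / (0.55 * c)) ** 2 <= 1.0
        plexus_masks[side] = inner & vent_masks[side]

    intensity = np.zeros(spec.shape, dtype=float)
    for value, mean in TISSUE_INTENSITY.items():
        intensity[labels == value] = mean
    if spec.plexus:
        for side in ("right", "left"):
            intensity[plexus_masks[side]] = PLEXUS_INTENSITY
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        intensity = np.clip(intensity + rng.normal(0.0, spec.noise_sd, spec.shape), 0.0, None)

    truth = PhantomTruth(
        right_width_mm=_realized_width(vent_masks["right"], spec, u_vec["right"]),
        left_width_mm=_realized_width(vent_masks["left"], spec, u_vec["left"]),
        reference_slice=spec.dgm_slice,
        component_count_on_slice=int(
            cc_label(labels[:, :, spec.dgm_slice] == 4, connectivity=2).max()
        ),
        ventricle_centers_vox={
            s: (centers[s][0] / sx, centers[s][1] / sy) for s in ("right", "left")
        },
        rotation_deg=spec.in_plane_rotation_deg,
    )
    if spec.plexus:
        for side in ("right", "left"):
            on_slice = plexus_masks[side][:, :, spec.dgm_slice]
            ii, jj = np.nonzero(on_slice)
            if ii.size == 0:
                raise RuntimeError(f"phantom {side} plexus missing from reference slice")
            truth.plexus_centroids[side] = (float(ii.mean()), float(jj.mean()),
                                            float(spec.dgm_slice))

    grid = VolumeGrid(intensity.astype(np.float32), spec.spacing, "RAS")
    lab = LabelVolume(labels, spec.spacing, "RAS")
    return grid, lab, truth


def _realized_width(vent_mask: np.ndarray, spec: PhantomSpec, u) -> float:
    """Minor-axis diameter actually realized on the reference slice.

    Independently of the measurement pipeline: project the voxel centers of
    the slice cross-section onto the known minor-axis direction; the width is
    the projection span plus one pixel pitch (pixel extent).
    """
    sl = vent_mask[:, :, spec.dgm_slice]
    ii, jj = np.nonzero(sl)
    if ii.size == 0:
        raise RuntimeError("ventricle missing from reference slice")
    v = (-u[1], u[0])  # in-plane unit vector perpendicular to the major axis
    proj = ii * spec.spacing[0] * v[0] + jj * spec.spacing[1] * v[1]
    return float(proj.max() - proj.min() + spec.spacing[0])


def dgm_profile_of_truth(truth: PhantomTruth, labels: LabelVolume) -> int:
    """Brute-force check that the deep-grey-matter area peaks at the truth slice."""
    dgm = labels.mask_of("deep_grey_matter")
    counts = dgm.sum(axis=(0, 1))
    if counts.sum() == 0:
        raise ValueError("no deep grey matter voxels in phantom")
    idx = int(np.argmax(counts))
    if idx != truth.reference_slice:
        raise AssertionError(
            f"DGM area peaks at slice {idx}, truth says {truth.reference_slice}"
        )
    return idx


__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "dgm_profile_of_truth",
           "TISSUE_INTENSITY", "PLEXUS_INTENSITY"]
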