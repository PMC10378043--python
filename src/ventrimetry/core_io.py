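"""Volume and measurement-table data model, NIfTI/CSV I/O, series ranking.

Volumes are held as plain numpy arrays plus a voxel spacing (mm) and a
three-letter anatomical orientation code in the nibabel convention: each
letter names the anatomical direction toward which the corresponding array
axis *increases* (``"RAS"`` = axis 0 grows toward subject Right, axis 1
toward Anterior, axis 2 toward Superior).  Laterality assignment and
reference-slice indexing both depend on this code, so it is carried
explicitly rather than re-derived downstream.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Seven-tissue label convention of the FeTA challenge data this tool consumes.
FETA_LABEL_SCHEME: dict[int, str] = {
    0: "background",
    1: "external_csf",
    2: "grey_matter",
    3: "white_matter",
    4: "ventricles",
    5: "cerebellum",
    6: "deep_grey_matter",
    7: "brainstem",
}

_AXIS_LETTERS = {"L": "LR", "R": "LR", "P": "AP", "A": "AP", "I": "SI", "S": "SI"}


def _validate_orientation(code: str) -> None:
    if len(code) != 3 or any(c not in _AXIS_LETTERS for c in code):
        raise ValueError(f"invalid orientation code {code!r}")
    pairs = [_AXIS_LETTERS[c] for c in code]
    if len(set(pairs)) != 3:
        raise ValueError(f"orientation {code!r} does not name three distinct anatomical axes")


def axis_of(orientation: str, anatomical: str) -> int:
    """Array axis index for an anatomical axis pair ('LR', 'AP' or 'SI')."""
    _validate_orientation(orientation)
    for i, c in enumerate(orientation):
        if _AXIS_LETTERS[c] == anatomical:
            return i
    raise ValueError(f"axis {anatomical} not in {orientation}")  # pragma: no cover


def axis_points_to(orientation: str, letter: str) -> bool:
    """True if the array axis carrying ``letter``'s pair increases toward ``letter``."""
    i = axis_of(orientation, _AXIS_LETTERS[letter])
    return orientation[i] == letter


@dataclass
class VolumeGrid:
    """A 3D scalar volume with voxel spacing (mm) and anatomical orientation."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    orientation: str = "RAS"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got {self.data.ndim} axes")
        if self.data.size == 0:
            raise ValueError("volume data has an empty shape")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        _validate_orientation(self.orientation)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3D integer tissue map sharing grid geometry with its intensity volume."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    orientation: str = "RAS"
    label_scheme: dict[int, str] = field(default_factory=lambda: dict(FETA_LABEL_SCHEME))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label data must be 3D, got {self.labels.ndim} axes")
        if self.labels.size == 0:
            raise ValueError("label data has an empty shape")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.labels, 1), 0)):
                raise ValueError("label data contains non-integer values")
            self.labels = self.labels.astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        _validate_orientation(self.orientation)
        present = np.unique(self.labels)
        unknown = [int(v) for v in present if int(v) not in self.label_scheme]
        if unknown:
            raise ValueError(
                f"label value {unknown[0]} is not in the label scheme "
                f"(known values: {sorted(self.label_scheme)})"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def value_of(self, tissue: str) -> int:
        """Integer code of a tissue name in this volume's scheme."""
        for value, name in self.label_scheme.items():
            if name == tissue:
                return value
        raise KeyError(f"tissue {tissue!r} not in label scheme")

    def mask_of(self, tissue: str) -> np.ndarray:
        return self.labels == self.value_of(tissue)


@dataclass
class SeriesStack:
    """One acquired series: its identifier, label volume and acquisition plane."""

    series_id: str
    label_volume: LabelVolume
    plane: str

    def __post_init__(self):
        if self.plane not in ("axial", "coronal", "sagittal"):
            raise ValueError(f"plane must be axial/coronal/sagittal, got {self.plane!r}")

    def segmented_volume_mm3(self) -> float:
        voxel = float(np.prod(self.label_volume.spacing))
        return int(np.count_nonzero(self.label_volume.labels)) * voxel


def _affine_from(spacing, orientation) -> np.ndarray:
    unit = {"R": (1, 0, 0), "L": (-1, 0, 0), "A": (0, 1, 0),
            "P": (0, -1, 0), "S": (0, 0, 1), "I": (0, 0, -1)}
    aff = np.eye(4)
    for i, letter in enumerate(orientation):
        aff[:3, i] = np.array(unit[letter], dtype=float) * spacing[i]
    return aff


def _geometry_from_header(img) -> tuple[tuple[float, float, float], str]:
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)) or np.linalg.det(affine[:3, :3]) == 0:
        warnings.warn("NIfTI header carries no usable affine; assuming RAS orientation")
        zooms = img.header.get_zooms()[:3]
        return tuple(float(z) for z in zooms), "RAS"
    orientation = "".join(nib.aff2axcodes(affine))
    spacing = tuple(float(s) for s in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
    return spacing, orientation


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI intensity volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got {data.ndim} axes")
    spacing, orientation = _geometry_from_header(img)
    return VolumeGrid(np.asarray(data, dtype=np.float32), spacing, orientation)


def read_label_volume(path, label_scheme: dict[int, str] | None = None) -> LabelVolume:
    """Read a NIfTI label volume; values must belong to the label scheme.

    Float-typed files are accepted only when every voxel is a whole number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D label volume in {path}, got {data.ndim} axes")
    spacing, orientation = _geometry_from_header(img)
    scheme = dict(label_scheme) if label_scheme is not None else dict(FETA_LABEL_SCHEME)
    return LabelVolume(data, spacing, orientation, scheme)


def write_label_volume(volume: LabelVolume, path) -> None:
    """Write a label volume as NIfTI, encoding spacing and orientation in the affine."""
    path = Path(path)
    affine = _affine_from(volume.spacing, volume.orientation)
    img = nib.Nifti1Image(volume.labels.astype(np.int16), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, path)


def write_volume(volume: VolumeGrid, path) -> None:
    path = Path(path)
    affine = _affine_from(volume.spacing, volume.orientation)
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, path)


def load_label_scheme(path) -> dict[int, str]:
    """Read a {integer: tissue name} scheme override from a JSON side-file."""
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): str(v) for k, v in raw.items()}


def rank_series_by_segmented_volume(stacks: list[SeriesStack], k: int) -> list[SeriesStack]:
    """Top-``k`` series by segmented (non-background) tissue volume.

    Mirrors the upstream series triage: stacks are sorted descending by the
    physical volume of labeled tissue; ties break by series_id ascending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not stacks:
        raise ValueError("no series stacks to rank")
    ranked = sorted(stacks, key=lambda s: (-s.segmented_volume_mm3(), s.series_id))
    return ranked[: min(k, len(ranked))]


@dataclass
class MeasurementTable:
    """Per-case, per-rater right/left ventricle widths (mm).

    Backed by a DataFrame with columns ``case_id``, ``group`` and a
    ``<rater>_right`` / ``<rater>_left`` pair per rater.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        cols = list(self.frame.columns)
        if "case_id" not in cols or "group" not in cols:
            raise ValueError("measurement table needs 'case_id' and 'group' columns")
        if len(self.frame) == 0:
            raise ValueError("no cases in measurement table")
        bad_group = set(self.frame["group"]) - {"normal", "abnormal"}
        if bad_group:
            raise ValueError(f"unknown group value(s): {sorted(bad_group)}")
        raters = self.raters
        if not raters:
            raise ValueError("no <rater>_right/<rater>_left column pairs found")
        for r in raters:
            for side in ("right", "left"):
                col = f"{r}_{side}"
                vals = pd.to_numeric(self.frame[col], errors="coerce")
                if vals.isna().any():
                    raise ValueError(f"non-numeric width in column {col}")
                if (vals <= 0).any():
                    raise ValueError(f"non-positive width in column {col}")
                self.frame[col] = vals.astype(float)

    @property
    def raters(self) -> list[str]:
        rights = {c[: -len("_right")] for c in self.frame.columns if c.endswith("_right")}
        lefts = {c[: -len("_left")] for c in self.frame.columns if c.endswith("_left")}
        cols = list(self.frame.columns)
        return sorted(rights & lefts, key=lambda r: cols.index(f"{r}_right"))

    def widths(self, rater: str, side: str) -> np.ndarray:
        if rater not in self.raters:
            raise KeyError(f"unknown rater {rater!r}; have {self.raters}")
        if side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {side!r}")
        return self.frame[f"{rater}_{side}"].to_numpy(dtype=float)

    def pooled_widths(self, rater: str) -> np.ndarray:
        """Right then left columns concatenated (44 values for 22 cases)."""
        return np.concatenate([self.widths(rater, "right"), self.widths(rater, "left")])

    @property
    def n_cases(self) -> int:
        return len(self.frame)


def read_measurement_table(path) -> MeasurementTable:
    """Read a CSV of per-case, per-rater widths (comma-separated, dot decimals)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"measurement table not found: {path}")
    frame = pd.read_csv(path, dtype={"case_id": str})
    return MeasurementTable(frame)


def load_reference_table() -> MeasurementTable:
    """The bundled 22-case benchmark table (two radiologists and the automated reader)."""
    from importlib.resources import files

    path = files("ventrimetry").joinpath("data/tables_2_3.csv")
    frame = pd.read_csv(path, dtype={"case_id": str})
    return MeasurementTable(frame)


__all__ = [
    "FETA_LABEL_SCHEME", "VolumeGrid", "LabelVolume", "SeriesStack",
    "MeasurementTable", "axis_of", "axis_points_to", "read_volume",
    "read_label_volume", "write_label_volume", "write_volume",
    "load_label_scheme", "rank_series_by_segmented_volume",
    "read_measurement_table", "load_reference_table",
]
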