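"""Volume data model, NIfTI I/O, and grid resampling.

Every stage of the pipeline works on :class:`VoxelGrid` objects — 3-D scalar
fields with voxel spacing and origin metadata. Axis order is fixed as
(slice, row, column) throughout the package, and ``spacing_mm`` is stored in
the same order, so an anisotropic whole-body grid is written
``spacing_mm=(3.0, 1.37, 1.37)`` (slice spacing first).

A :class:`PatientCase` bundles the co-registered channels of one scan: CT in
Hounsfield units, PET in SUV, an integer anatomical label mask, optional
reader segmentations and an optional ground-truth segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "UNIT_TAGS",
    "REGION_LABELS",
    "LABEL_NAMES",
    "SKELETAL_LABELS",
    "VoxelGrid",
    "PatientCase",
    "CoRegistrationError",
    "voxel_volume_ml",
    "resample_trilinear",
    "save_grid",
    "load_grid",
    "save_case",
    "load_case",
]

UNIT_TAGS = ("SUV", "HU", "probability", "label", "binary")

#: Anatomical region vocabulary used by the label mask. The regions are the
#: ones where either malignant uptake or physiological high uptake of
#: bone-seeking tracer is common, plus background.
REGION_LABELS: dict[str, int] = {
    "background": 0,
    "bones": 1,
    "joints": 2,
    "kidneys": 3,
    "lungs": 4,
    "brain": 5,
    "skull": 6,
    "spleen": 7,
    "heart": 8,
    "aorta": 9,
    "liver": 10,
}
LABEL_NAMES = {v: k for k, v in REGION_LABELS.items()}

#: Label codes counted as skeleton when computing skeletal volume.
SKELETAL_LABELS = (
    REGION_LABELS["bones"],
    REGION_LABELS["joints"],
    REGION_LABELS["skull"],
)


class CoRegistrationError(ValueError):
    """Raised when channels of one case do not share a common grid."""


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3:
        raise ValueError(f"{name} must have 3 components, got {v.size}")
    return v


@dataclass
class VoxelGrid:
    """A 3-D scalar field with spacing/origin metadata.

    Parameters
    ----------
    values
        3-D array, axis order (slice, row, column).
    spacing_mm
        Positive voxel spacing per axis, same order as ``values``.
    origin_mm
        Physical coordinate of voxel (0, 0, 0).
    unit_tag
        One of ``SUV``, ``HU``, ``probability``, ``label``, ``binary``.
    """

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    unit_tag: str = "SUV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        self.spacing_mm = _as_vec3(self.spacing_mm, "spacing_mm")
        self.origin_mm = _as_vec3(self.origin_mm, "origin_mm")
        if np.any(self.spacing_mm <= 0):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.unit_tag not in UNIT_TAGS:
            raise ValueError(f"unit_tag must be one of {UNIT_TAGS}, got {self.unit_tag!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.unit_tag == "probability":
            if self.values.min() < 0 or self.values.max() > 1:
                raise ValueError("probability values must lie in [0, 1]")
        if self.unit_tag in ("label", "binary"):
            vals = self.values
            if not np.issubdtype(vals.dtype, np.integer):
                if not np.all(vals == np.round(vals)):
                    raise ValueError(f"{self.unit_tag} values must be integers")
                self.values = vals.astype(np.int32)
            if self.values.min() < 0:
                raise ValueError(f"{self.unit_tag} values must be non-negative")
            if self.unit_tag == "binary" and self.values.max() > 1:
                raise ValueError("binary values must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_grid(self, other: "VoxelGrid", spacing_tol: float = 1e-3,
                  origin_tol: float = 1e-2) -> bool:
        """Whether two grids are co-registered within the declared tolerance."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=spacing_tol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=origin_tol)
        )

    def with_values(self, values: np.ndarray, unit_tag: str | None = None) -> "VoxelGrid":
        """New grid sharing this grid's geometry."""
        return VoxelGrid(values, self.spacing_mm.copy(), self.origin_mm.copy(),
                         unit_tag if unit_tag is not None else self.unit_tag)


def voxel_volume_ml(grid: VoxelGrid) -> float:
    """Volume of one voxel in millilitres (product of spacings / 1000)."""
    return float(np.prod(grid.spacing_mm) / 1000.0)


def resample_trilinear(grid: VoxelGrid, target_spacing_mm) -> VoxelGrid:
    """Resample a grid to a new voxel spacing, preserving physical extent.

    Scalar channels (SUV, HU, probability) are interpolated trilinearly;
    label and binary channels are always resampled nearest-neighbour so no
    fractional labels appear. The output shape is ``round(extent / spacing)``
    per axis and sample points are clamped to the source domain at the edges.
    """
    target = _as_vec3(target_spacing_mm, "target_spacing_mm")
    if np.any(target <= 0):
        raise ValueError(f"target spacing must be positive, got {target}")
    if grid.values.size == 0:
        raise ValueError("cannot resample an empty grid")

    src_shape = np.array(grid.shape, dtype=float)
    extent = src_shape * grid.spacing_mm
    out_shape = np.maximum(1, np.round(extent / target).astype(int))

    # voxel i sits at origin + i * spacing; map output index -> source index
    coords = [
        np.clip(np.arange(n) * target[ax] / grid.spacing_mm[ax], 0, src_shape[ax] - 1)
        for ax, n in enumerate(out_shape)
    ]
    mesh = np.meshgrid(*coords, indexing="ij")
    order = 0 if grid.unit_tag in ("label", "binary") else 1
    out = ndimage.map_coordinates(
        grid.values.astype(float), np.stack(mesh), order=order, mode="nearest"
    )
    if grid.unit_tag in ("label", "binary"):
        out = np.round(out).astype(np.int32)
    return VoxelGrid(out, target, grid.origin_mm.copy(), grid.unit_tag)


# ---------------------------------------------------------------------------
# NIfTI I/O. The affine is diagonal with the (slice, row, column) spacings on
# the diagonal; nibabel stores arrays in the same index order they are given.
# ---------------------------------------------------------------------------

def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing_mm
    aff[:3, 3] = grid.origin_mm
    return aff


def save_grid(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a grid to a NIfTI-1 file (.nii or .nii.gz)."""
    path = Path(path)
    dtype = np.int16 if grid.unit_tag in ("label", "binary") else np.float32
    img = nib.Nifti1Image(grid.values.astype(dtype), _affine(grid))
    img.header.set_zooms(tuple(grid.spacing_mm))
    img.header["descrip"] = grid.unit_tag.encode()
    nib.save(img, str(path))
    return path


def load_grid(path: str | Path, unit_tag: str | None = None) -> VoxelGrid:
    """Read a grid from a NIfTI-1 file.

    The unit tag is recovered from the header ``descrip`` field unless given
    explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    if unit_tag is None:
        tag = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "SUV"
    else:
        tag = unit_tag
    return VoxelGrid(values, spacing, origin, tag)


@dataclass
class PatientCase:
    """All co-registered channels of one whole-body scan."""

    case_id: str
    ct: VoxelGrid
    pet: VoxelGrid
    label_mask: VoxelGrid
    reader_segs: dict[str, VoxelGrid] = field(default_factory=dict)
    truth_seg: VoxelGrid | None = None

    def __post_init__(self) -> None:
        self.validate()

    def _channels(self):
        yield "ct", self.ct
        yield "pet", self.pet
        yield "label_mask", self.label_mask
        for name, seg in self.reader_segs.items():
            yield f"reader:{name}", seg
        if self.truth_seg is not None:
            yield "truth_seg", self.truth_seg

    def validate(self) -> None:
        if self.ct.unit_tag != "HU":
            raise ValueError("ct channel must carry HU values")
        if self.pet.unit_tag != "SUV":
            raise ValueError("pet channel must carry SUV values")
        if self.label_mask.unit_tag != "label":
            raise ValueError("label_mask channel must carry label values")
        ref = self.ct
        for name, grid in self._channels():
            if name.startswith(("reader", "truth")) and grid.unit_tag != "binary":
                raise ValueError(f"{name} must be a binary segmentation")
            if not grid.same_grid(ref):
                raise CoRegistrationError(
                    f"channel {name!r} is not co-registered with ct "
                    f"(shape {grid.shape} vs {ref.shape}, "
                    f"spacing {grid.spacing_mm} vs {ref.spacing_mm})"
                )
        codes = np.unique(self.label_mask.values)
        known = set(REGION_LABELS.values())
        bad = [int(c) for c in codes if int(c) not in known]
        if bad:
            raise ValueError(f"label mask contains codes outside the region vocabulary: {bad}")

    def resampled(self, target_spacing_mm) -> "PatientCase":
        """The same case with every channel resampled to one spacing."""
        return PatientCase(
            case_id=self.case_id,
            ct=resample_trilinear(self.ct, target_spacing_mm),
            pet=resample_trilinear(self.pet, target_spacing_mm),
            label_mask=resample_trilinear(self.label_mask, target_spacing_mm),
            reader_segs={k: resample_trilinear(v, target_spacing_mm)
                         for k, v in self.reader_segs.items()},
            truth_seg=(resample_trilinear(self.truth_seg, target_spacing_mm)
                       if self.truth_seg is not None else None),
        )


def save_case(case: PatientCase, directory: str | Path) -> Path:
    """Write a case as NIfTI volumes plus a JSON manifest naming channels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"case_id": case.case_id, "channels": {}, "readers": {}}
    for name, grid, key in [("ct", case.ct, "channels"),
                            ("pet", case.pet, "channels"),
                            ("label_mask", case.label_mask, "channels")]:
        fname = f"{name}.nii.gz"
        save_grid(grid, directory / fname)
        manifest[key][name] = fname
    for reader, seg in case.reader_segs.items():
        fname = f"reader_{reader}.nii.gz"
        save_grid(seg, directory / fname)
        manifest["readers"][reader] = fname
    if case.truth_seg is not None:
        save_grid(case.truth_seg, directory / "truth.nii.gz")
        manifest["channels"]["truth_seg"] = "truth.nii.gz"
    (directory / "case.json").write_text(json.dumps(manifest, indent=2))
    return directory / "case.json"


def load_case(manifest_path: str | Path) -> PatientCase:
    """Read a case from its JSON manifest; verifies co-registration."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "case.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no case manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    ch: Mapping[str, str] = manifest["channels"]
    ct = load_grid(root / ch["ct"], "HU")
    pet = load_grid(root / ch["pet"], "SUV")
    labels = load_grid(root / ch["label_mask"], "label")
    readers = {name: load_grid(root / fname, "binary")
               for name, fname in manifest.get("readers", {}).items()}
    truth = load_grid(root / ch["truth_seg"], "binary") if "truth_seg" in ch else None
    return PatientCase(manifest["case_id"], ct, pet, labels, readers, truth)
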