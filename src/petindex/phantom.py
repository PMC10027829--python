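"""Seeded synthetic whole-body [18F]fluoride PET/CT phantoms.

The generator emulates the statistical structure the segmentation pipeline
assumes: a CT with air / soft tissue / dense bone contrast, a PET volume with
low soft-tissue background, moderate diffuse skeletal uptake, physiological
high-uptake organs, degenerative-style focal joint uptake, and focal skeletal
lesions of configurable count, size and intensity. An anatomical label mask
covering the full region vocabulary and an exact ground-truth lesion
segmentation are produced on the same grid.

Simulated readers perturb the ground truth with boundary dilation/erosion,
per-lesion misses and spurious small marks, emulating the interreader
variability of human annotators.

Everything is deterministic under the spec/profile seeds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import REGION_LABELS, PatientCase, VoxelGrid, voxel_volume_ml

__all__ = [
    "PhantomSpec",
    "ReaderProfile",
    "GenerationError",
    "generate_phantom",
    "simulate_reader",
    "generate_cohort",
    "ellipsoid_structure",
]

_B = REGION_LABELS  # shorthand


class GenerationError(RuntimeError):
    """Raised when the requested lesion configuration cannot be placed."""


@dataclass
class PhantomSpec:
    """Configuration of one synthetic whole-body case.

    Defaults reflect [18F]fluoride imaging: diffuse bone uptake around
    SUV 5, degenerative joint foci well above it, and lesions whose SUV range
    straddles the classic threshold of 15 so that a fixed-threshold model
    misses part of them.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (3.0, 1.37, 1.37)
    n_lesions: int = 3
    lesion_radius_mm: tuple[float, float] = (4.0, 6.0)
    lesion_suv: tuple[float, float] = (10.0, 30.0)
    bone_suv_baseline: float = 5.0
    joint_suv: tuple[float, float] = (14.0, 25.0)
    organ_suv: dict[str, float] = field(default_factory=lambda: {
        "kidneys": 8.0, "lungs": 0.4, "brain": 0.3, "spleen": 1.5,
        "heart": 1.8, "aorta": 2.5, "liver": 1.5,
    })
    soft_tissue_suv: float = 1.0
    noise_sigma_suv: float = 0.5
    psf_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        for name, rng in [("lesion_radius_mm", self.lesion_radius_mm),
                          ("lesion_suv", self.lesion_suv),
                          ("joint_suv", self.joint_suv)]:
            lo, hi = rng
            if hi < lo:
                raise ValueError(f"{name} range is empty: {rng}")
        if self.lesion_suv[0] <= self.bone_suv_baseline:
            raise ValueError("lesion SUV lower bound must exceed the bone baseline")
        if self.noise_sigma_suv < 0:
            raise ValueError("noise_sigma_suv must be >= 0")


@dataclass
class ReaderProfile:
    """Behaviour of one simulated human reader.

    ``boundary_dilation_mm`` widens (positive) or shrinks (negative) each
    retained lesion outline; ``miss_rate`` is the probability a true lesion
    goes unmarked; ``false_mark_rate`` is the expected number of spurious
    small (>= 0.1 ml) marks per scan.
    """

    boundary_dilation_mm: float = 0.0
    miss_rate: float = 0.0
    false_mark_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate must be in [0, 1]")
        if self.false_mark_rate < 0:
            raise ValueError("false_mark_rate must be >= 0")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def ellipsoid_structure(radius_mm: float, spacing_mm) -> np.ndarray:
    """Binary structuring element: a ball of physical radius on an
    anisotropic grid."""
    spacing = np.asarray(spacing_mm, dtype=float)
    half = np.maximum(0, np.floor(radius_mm / spacing).astype(int))
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    zz, yy, xx = np.meshgrid(*ax, indexing="ij")
    return (zz**2 + yy**2 + xx**2) <= radius_mm**2 + 1e-9


def _ball_mask(shape, spacing, center_mm, radius_mm) -> np.ndarray:
    idx = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*idx, indexing="ij", sparse=True)
    c = center_mm
    return ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= radius_mm**2


def _ellipsoid_mask(shape, spacing, center_mm, semi_mm) -> np.ndarray:
    idx = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*idx, indexing="ij", sparse=True)
    c, a = center_mm, semi_mm
    return (((zz - c[0]) / a[0]) ** 2 + ((yy - c[1]) / a[1]) ** 2
            + ((xx - c[2]) / a[2]) ** 2) <= 1.0


def _cylinder_mask(shape, spacing, z_range_mm, center_rc_mm, radius_mm) -> np.ndarray:
    idx = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*idx, indexing="ij", sparse=True)
    inplane = (yy - center_rc_mm[0]) ** 2 + (xx - center_rc_mm[1]) ** 2
    return (zz >= z_range_mm[0]) & (zz <= z_range_mm[1]) & (inplane <= radius_mm**2)


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

_CT_HU = {
    "background": -1000.0, "soft": 40.0, "bones": 700.0, "joints": 500.0,
    "kidneys": 45.0, "lungs": -700.0, "brain": 35.0, "skull": 700.0,
    "spleen": 50.0, "heart": 45.0, "aorta": 50.0, "liver": 55.0,
}


def _anatomy(spec: PhantomSpec):
    """Label mask and body mask for the phantom torso."""
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    extent = np.array(shape) * spacing
    e0, e1, e2 = extent
    c12 = (e1 / 2, e2 / 2)

    labels = np.zeros(shape, dtype=np.int32)
    body = _ellipsoid_mask(shape, spacing, (e0 / 2, *c12),
                           (0.60 * e0, 0.46 * e1, 0.46 * e2))

    # paired organs in soft tissue
    organs = {
        "lungs": _ellipsoid_mask(shape, spacing, (0.30 * e0, c12[0], 0.24 * e2),
                                 (0.10 * e0, 0.13 * e1, 0.11 * e2))
        | _ellipsoid_mask(shape, spacing, (0.30 * e0, c12[0], 0.76 * e2),
                          (0.10 * e0, 0.13 * e1, 0.11 * e2)),
        "heart": _ball_mask(shape, spacing, (0.35 * e0, 0.76 * e1, 0.32 * e2),
                            0.09 * min(e1, e2)),
        "liver": _ellipsoid_mask(shape, spacing, (0.47 * e0, 0.55 * e1, 0.68 * e2),
                                 (0.07 * e0, 0.12 * e1, 0.12 * e2)),
        "spleen": _ball_mask(shape, spacing, (0.47 * e0, 0.55 * e1, 0.22 * e2),
                             0.07 * min(e1, e2)),
        "kidneys": _ball_mask(shape, spacing, (0.58 * e0, 0.30 * e1, 0.30 * e2),
                              0.08 * min(e1, e2))
        | _ball_mask(shape, spacing, (0.58 * e0, 0.30 * e1, 0.70 * e2),
                     0.08 * min(e1, e2)),
        "aorta": _cylinder_mask(shape, spacing, (0.25 * e0, 0.80 * e0),
                                (0.70 * e1, 0.70 * e2), 0.035 * min(e1, e2)),
    }
    for name, mask in organs.items():
        labels[mask & body] = _B[name]

    # skeleton: skull sphere with brain inside, spine cylinder below
    skull_c = (0.105 * e0, *c12)
    skull_r = min(0.10 * e0, 0.26 * min(e1, e2))
    skull = _ball_mask(shape, spacing, skull_c, skull_r) & body
    brain = _ball_mask(shape, spacing, skull_c, 0.62 * skull_r) & body
    spine = _cylinder_mask(shape, spacing, (0.22 * e0, e0), c12,
                           0.21 * min(e1, e2)) & body
    labels[spine] = _B["bones"]
    labels[skull] = _B["skull"]
    labels[brain] = _B["brain"]

    # degenerative joints: small blobs riding on the spine surface
    r_spine = 0.21 * min(e1, e2)
    r_joint = max(0.40 * r_spine, 1.05 * float(np.max(spacing)))
    for i, zf in enumerate((0.30, 0.45, 0.60, 0.75, 0.90)):
        side = 1 if i % 2 == 0 else -1
        center = (zf * e0, c12[0] + side * r_spine, c12[1])
        joint = _ball_mask(shape, spacing, center, r_joint) & body
        labels[joint] = _B["joints"]

    return labels, body


def _place_lesions(labels, spec: PhantomSpec, rng: np.random.Generator):
    """Sphere lesions fully inside the 'bones' region, pairwise disjoint."""
    shape = labels.shape
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    truth = np.zeros(shape, dtype=np.int32)
    if spec.n_lesions == 0:
        return truth, []

    bone = labels == _B["bones"]
    placed: list[tuple[np.ndarray, float, float]] = []
    max_sp = float(np.max(spacing))
    attempts = 0
    while len(placed) < spec.n_lesions:
        attempts += 1
        if attempts > 200 * spec.n_lesions:
            raise GenerationError(
                f"could not place {spec.n_lesions} disjoint lesions "
                f"(placed {len(placed)}) — enlarge the phantom or shrink lesions")
        radius = rng.uniform(*spec.lesion_radius_mm)
        eligible = ndimage.binary_erosion(
            bone, structure=ellipsoid_structure(radius + max_sp, spacing))
        sites = np.argwhere(eligible)
        if sites.size == 0:
            raise GenerationError(
                f"no bone site can host a lesion of radius {radius:.1f} mm")
        center = sites[rng.integers(len(sites))] * spacing
        if any(np.linalg.norm(center - c) < radius + r + 2.0 * max_sp
               for c, r, _ in placed):
            continue
        suv = rng.uniform(*spec.lesion_suv)
        placed.append((center, radius, suv))

    for center, radius, suv in placed:
        truth[_ball_mask(shape, spacing, center, radius)] = 1
    return truth, placed


def generate_phantom(spec: PhantomSpec) -> PatientCase:
    """Build one synthetic co-registered PET/CT case with ground truth.

    Identical spec and seed give bit-identical volumes.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)

    labels, body = _anatomy(spec)
    truth, lesions = _place_lesions(labels, spec, rng)

    # CT from the label/body geometry
    ct = np.full(shape, _CT_HU["background"], dtype=np.float32)
    ct[body] = _CT_HU["soft"]
    for name, code in _B.items():
        if code == 0:
            continue
        ct[labels == code] = _CT_HU[name]

    # PET: per-region uptake, lesion foci, Gaussian noise floored at 0
    pet = np.zeros(shape, dtype=np.float32)
    pet[body] = spec.soft_tissue_suv
    for name, suv in spec.organ_suv.items():
        pet[labels == _B[name]] = suv
    pet[labels == _B["bones"]] = spec.bone_suv_baseline
    pet[labels == _B["skull"]] = spec.bone_suv_baseline
    joint_rng = np.random.default_rng(spec.seed + 1)
    joint_lbl, n_joints = ndimage.label(labels == _B["joints"],
                                        structure=np.ones((3, 3, 3), bool))
    for j in range(1, n_joints + 1):
        pet[joint_lbl == j] = joint_rng.uniform(*spec.joint_suv)
    for center, radius, suv in lesions:
        pet[_ball_mask(shape, spacing, center, radius)] = suv

    if spec.psf_sigma_mm > 0:
        pet = ndimage.gaussian_filter(pet, spec.psf_sigma_mm / spacing)
    if spec.noise_sigma_suv > 0:
        pet = pet + rng.normal(0.0, spec.noise_sigma_suv, size=shape)
    pet = np.maximum(pet, 0.0).astype(np.float32)

    make = lambda v, tag: VoxelGrid(v, spacing.copy(), np.zeros(3), tag)
    return PatientCase(
        case_id=f"phantom-{spec.seed}",
        ct=make(ct, "HU"),
        pet=make(pet, "SUV"),
        label_mask=make(labels, "label"),
        truth_seg=make(truth, "binary"),
    )


# ---------------------------------------------------------------------------
# simulated readers
# ---------------------------------------------------------------------------

def _case_rng(profile: ReaderProfile, case_id: str) -> np.random.Generator:
    mix = zlib.crc32(case_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng((profile.seed, mix))


def simulate_reader(case: PatientCase, profile: ReaderProfile) -> VoxelGrid:
    """One simulated human segmentation of a case's true lesions.

    Each true lesion is retained with probability ``1 - miss_rate``; retained
    lesions are dilated or eroded by ``boundary_dilation_mm``; a
    Poisson(``false_mark_rate``) number of spurious >= 0.1 ml marks is added
    inside bone. Deterministic given profile seed and case id.
    """
    if case.truth_seg is None:
        raise ValueError("case has no ground-truth segmentation to read")
    rng = _case_rng(profile, case.case_id)
    truth = case.truth_seg.values.astype(bool)
    spacing = case.truth_seg.spacing_mm
    out = np.zeros_like(truth)

    lbl, n = ndimage.label(truth, structure=np.ones((3, 3, 3), bool))
    for i in range(1, n + 1):
        if rng.random() < profile.miss_rate:
            continue
        lesion = lbl == i
        d = profile.boundary_dilation_mm
        if d > 0:
            lesion = ndimage.binary_dilation(
                lesion, structure=ellipsoid_structure(d, spacing))
        elif d < 0:
            lesion = ndimage.binary_erosion(
                lesion, structure=ellipsoid_structure(-d, spacing))
        out |= lesion

    n_marks = rng.poisson(profile.false_mark_rate)
    if n_marks:
        bone = np.isin(case.label_mask.values,
                       (REGION_LABELS["bones"], REGION_LABELS["skull"]))
        vox_ml = voxel_volume_ml(case.truth_seg)
        # smallest ball radius whose voxelisation reaches 0.1 ml
        radius = 2.9
        while True:
            ball = ellipsoid_structure(radius, spacing)
            if ball.sum() * vox_ml >= 0.1:
                break
            radius += 0.5
        clear = bone & ~ndimage.binary_dilation(
            truth, structure=ellipsoid_structure(radius + 2 * float(np.max(spacing)),
                                                 spacing))
        sites = np.argwhere(clear)
        for _ in range(n_marks):
            if len(sites) == 0:
                break
            center = sites[rng.integers(len(sites))] * spacing
            out |= _ball_mask(truth.shape, spacing, center, radius)

    return case.truth_seg.with_values(out.astype(np.int32), "binary")


def generate_cohort(n: int, spec: PhantomSpec,
                    profiles: list[ReaderProfile] | None = None) -> list[PatientCase]:
    """A cohort of ``n`` phantoms with per-case derived seeds.

    Case ``i`` uses ``spec.seed + i``. Each reader profile contributes one
    simulated segmentation per case, named A, B, C, ... in profile order.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    profiles = profiles or []
    cases = []
    for i in range(n):
        case = generate_phantom(replace(spec, seed=spec.seed + i))
        case.case_id = f"case{i:03d}"
        for j, profile in enumerate(profiles):
            name = chr(ord("A") + j)
            case.reader_segs[name] = simulate_reader(case, profile)
        case.validate()
        cases.append(case)
    return cases
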