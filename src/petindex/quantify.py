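"""The PET index: fractional skeletal tumor burden.

The PET index of a scan is the summed volume of all voxels marked as
suspicious, divided by the total volume of the visualized skeleton, expressed
in percent. It is the PET/CT analogue of the automated Bone Scan Index:
an indexed measure that enables interpatient comparison of tumor burden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import SKELETAL_LABELS, VoxelGrid, voxel_volume_ml

__all__ = ["PetIndexResult", "UndefinedIndexError", "skeletal_volume_ml",
           "compute_pet_index"]


class UndefinedIndexError(ValueError):
    """Raised when the skeletal volume is zero and the index is undefined."""


@dataclass(frozen=True)
class PetIndexResult:
    lesion_volume_ml: float
    skeletal_volume_ml: float
    index_percent: float


def skeletal_volume_ml(label_mask: VoxelGrid) -> float:
    """Total skeletal volume in ml: bone, skull and joint voxels.

    Joint voxels count as skeleton — anatomically they sit at bone
    interfaces and belong to the visualized skeletal extent.
    """
    if label_mask.unit_tag != "label":
        raise ValueError("skeletal_volume_ml expects a label grid")
    n = int(np.isin(label_mask.values, SKELETAL_LABELS).sum())
    if n == 0:
        raise UndefinedIndexError("label mask contains no skeletal voxels; "
                                  "PET index is undefined")
    return n * voxel_volume_ml(label_mask)


def compute_pet_index(seg: VoxelGrid, label_mask: VoxelGrid) -> PetIndexResult:
    """PET index of a segmentation, in percent of skeletal volume.

    All marked voxels count toward the lesion volume whether or not they lie
    inside the skeleton — readers routinely mark cortical-edge voxels.
    """
    if not seg.same_grid(label_mask):
        raise ValueError("segmentation and label mask are not co-registered")
    skel = skeletal_volume_ml(label_mask)
    lesion = int(np.count_nonzero(seg.values)) * voxel_volume_ml(seg)
    return PetIndexResult(
        lesion_volume_ml=lesion,
        skeletal_volume_ml=skel,
        index_percent=100.0 * lesion / skel,
    )
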