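"""Fixed SUV-threshold baseline segmentation.

A global SUV cutoff of 15 is the classical automated way to segment
metastatic uptake in [18F]fluoride PET. It serves here as the baseline the
learned model is compared against: every voxel at or above the threshold is
marked, then connected components below a minimum volume are dropped. No
joint suppression is applied on this path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .postprocess import PostprocessConfig, filter_small_components
from .volumes import VoxelGrid

__all__ = ["ThresholdConfig", "threshold_segment"]


@dataclass
class ThresholdConfig:
    suv_threshold: float = 15.0
    min_component_ml: float = 0.1

    def __post_init__(self) -> None:
        if self.suv_threshold <= 0:
            raise ValueError("suv_threshold must be > 0")
        if self.min_component_ml <= 0:
            raise ValueError("min_component_ml must be > 0")


def threshold_segment(pet: VoxelGrid, cfg: ThresholdConfig | None = None) -> VoxelGrid:
    """Segment all voxels with SUV >= threshold, then drop tiny components.

    The comparison is inclusive (SUV exactly at the threshold is marked).
    """
    cfg = cfg or ThresholdConfig()
    if pet.unit_tag != "SUV":
        raise ValueError(f"threshold_segment expects an SUV grid, got {pet.unit_tag!r}")
    seg = pet.with_values((pet.values >= cfg.suv_threshold).astype(np.int32), "binary")
    return filter_small_components(
        seg, PostprocessConfig(min_component_ml=cfg.min_component_ml))
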