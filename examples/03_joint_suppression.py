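"""Suppress joint uptake with the watershed postprocessing step.

Every segmented voxel is attributed to a regional SUV maximum by a watershed
transform; voxels whose maximum lies inside the joint mask are cleared.
Applied to the threshold segmentation of a phantom, this removes the hot
degenerative joints while leaving true lesions untouched.
"""

import numpy as np

import petindex as pi
from petindex.postprocess import PostprocessConfig

case = pi.generate_phantom(pi.PhantomSpec(seed=7))
cfg = PostprocessConfig(joint_dilation_mm=3.0)

seg = pi.threshold_segment(case.pet)
joints = pi.build_joint_mask(case.label_mask, cfg)
cleaned = pi.watershed_joint_removal(seg, case.pet, joints, cfg)
cleaned = pi.filter_small_components(cleaned, cfg)

before = pi.lesion_detection_counts(seg, case.truth_seg)
after = pi.lesion_detection_counts(cleaned, case.truth_seg)
print(f"joint-mask voxels       : {int(joints.values.sum())}")
print(f"before joint removal    : TP={before.tp:.0f} FP={before.fp:.0f} "
      f"FN={before.fn:.0f}")
print(f"after joint removal     : TP={after.tp:.0f} FP={after.fp:.0f} "
      f"FN={after.fn:.0f}")
print("Joint-origin false positives disappear; components whose uptake peak "
      "is a true lesion survive.")
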