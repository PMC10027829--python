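"""Label-mask-conditioned lesion classifier: training and tiled inference.

The lesion network is a valid-convolution 3D U-Net that sees three input
modalities concatenated across the channel dimension — CT, PET (SUV) and a
one-hot encoding of the anatomical label mask — and emits per-voxel
probabilities of the two classes (bone metastasis vs background) over a
small window centred in the input patch. The label channels let the network
tell malignant uptake from physiological high uptake in organs and joints.

At the clinical working resolution of 3.0 x 1.37 x 1.37 mm the patch
contract is a 100x100x100 input predicting the central 12x12x12 window
(depth 3, two convolutions per block); test- and desk-scale runs shrink the
patch (36³ -> 12³ with depth 1, three convolutions per block) without
touching any other code path.

Training patches are drawn evenly from the two classes; within a class,
voxels with high SUV and voxels misclassified by an earlier version of the
network are drawn more often, focusing the optimisation on hard examples.
Inference tiles the whole volume with stride equal to the output window, so
every voxel is predicted exactly once.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._unet import Adam, UNet3D, output_size, softmax_cross_entropy
from .postprocess import (PostprocessConfig, build_joint_mask,
                          filter_small_components, watershed_joint_removal)
from .volumes import REGION_LABELS, PatientCase, VoxelGrid, resample_trilinear

__all__ = [
    "CnnConfig",
    "TrainingPatch",
    "LesionModel",
    "SamplingError",
    "encode_channels",
    "sample_training_patches",
    "train_model",
    "predict_volume",
    "segment_case",
    "tile_starts",
]

#: Region channels, one binary occupancy channel each (one-hot rather than a
#: single integer channel, avoiding false ordinality between region codes).
DEFAULT_REGIONS = ("bones", "joints", "kidneys", "lungs", "brain", "skull",
                   "spleen", "heart", "aorta", "liver")


class SamplingError(RuntimeError):
    """Raised when lesion-class patches are requested from a lesion-free case."""


@dataclass
class CnnConfig:
    """Geometry, sampling and optimisation settings of the lesion network."""

    input_patch: tuple[int, int, int] = (100, 100, 100)
    output_patch: tuple[int, int, int] = (12, 12, 12)
    working_spacing_mm: tuple[float, float, float] = (3.0, 1.37, 1.37)
    depth: int = 3
    convs_per_block: int = 2
    base_filters: int = 16
    regions: tuple[str, ...] = DEFAULT_REGIONS
    n_classes: int = 2
    lesion_prob_threshold: float = 0.5
    high_suv_reference: float = 10.0
    high_suv_boost: float = 5.0
    hard_example_boost: float = 5.0
    hard_example_refresh: bool = False
    epochs: int = 10
    batch_size: int = 4
    patches_per_epoch: int = 128
    learning_rate: float = 2e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("the lesion network is a two-class model")
        if not 0.0 < self.lesion_prob_threshold < 1.0:
            raise ValueError("lesion_prob_threshold must be in (0, 1)")
        for i, (inp, out) in enumerate(zip(self.input_patch, self.output_patch)):
            got = output_size(inp, self.depth, self.convs_per_block)
            if got != out:
                raise ValueError(
                    f"axis {i}: input {inp} with depth={self.depth}, "
                    f"convs_per_block={self.convs_per_block} yields output "
                    f"{got}, not the declared {out}")
            if (inp - out) % 2:
                raise ValueError("output window must be centred in the input patch")

    @property
    def in_channels(self) -> int:
        return 2 + len(self.regions)

    @classmethod
    def desk(cls, **overrides) -> "CnnConfig":
        """Reduced-scale configuration (36³ -> 12³) for desk-size phantoms."""
        kw = dict(input_patch=(36, 36, 36), output_patch=(12, 12, 12),
                  depth=1, convs_per_block=3, base_filters=8)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TrainingPatch:
    inputs: np.ndarray   # (C, *input_patch) float32
    target: np.ndarray   # (*output_patch) int8, 1 = lesion
    center_class: str    # "lesion" | "background"
    center: tuple[int, int, int] = (0, 0, 0)


# channel 0: CT clipped to [-1000, 1500] HU, scaled to [-1, 1]
# channel 1: SUV / 15, clipped at 4 (fixed scaling preserves SUV meaning)
_CT_PAD = -1.0
_SUV_PAD = 0.0


def encode_channels(case: PatientCase, cfg: CnnConfig) -> np.ndarray:
    """Stack normalised CT, SUV and one-hot region channels: (C, D, H, W)."""
    ct = np.clip(case.ct.values, -1000.0, 1500.0)
    ct = (ct - 250.0) / 1250.0
    suv = np.minimum(case.pet.values / 15.0, 4.0)
    labels = case.label_mask.values
    chans = [ct.astype(np.float32), suv.astype(np.float32)]
    for name in cfg.regions:
        chans.append((labels == REGION_LABELS[name]).astype(np.float32))
    return np.stack(chans)


def _pad_values(cfg: CnnConfig) -> np.ndarray:
    # border padding: CT with air, SUV with 0, label channels with background
    return np.array([_CT_PAD, _SUV_PAD] + [0.0] * len(cfg.regions),
                    dtype=np.float32)


def _pad_channels(channels: np.ndarray, before, after, cfg: CnnConfig) -> np.ndarray:
    pv = _pad_values(cfg)
    out = np.empty((channels.shape[0],) +
                   tuple(channels.shape[1 + i] + before[i] + after[i]
                         for i in range(3)), dtype=np.float32)
    out[...] = pv[:, None, None, None]
    sl = tuple(slice(b, b + s) for b, s in zip(before, channels.shape[1:]))
    out[(slice(None),) + sl] = channels
    return out


def _at_working_spacing(case: PatientCase, cfg: CnnConfig) -> PatientCase:
    if np.allclose(case.ct.spacing_mm, cfg.working_spacing_mm, atol=1e-6):
        return case
    return case.resampled(cfg.working_spacing_mm)


# ---------------------------------------------------------------------------
# training-patch sampler
# ---------------------------------------------------------------------------

def _class_weights(flat_suv, flat_mis, cfg: CnnConfig):
    w = 1.0 + cfg.high_suv_boost * (flat_suv > cfg.high_suv_reference)
    if flat_mis is not None:
        w = w + cfg.hard_example_boost * flat_mis
    return w


def _extract_patch(padded, center, cfg: CnnConfig, half_in):
    sl = tuple(slice(c, c + p) for c, p in zip(center, cfg.input_patch))
    return padded[(slice(None),) + sl]


def sample_training_patches(case: PatientCase, cfg: CnnConfig, n: int,
                            misclassified_map: VoxelGrid | None = None,
                            rng: np.random.Generator | None = None
                            ) -> list[TrainingPatch]:
    """Draw ``n`` class-balanced, hard-example-weighted training patches.

    The centre voxel's class is Bernoulli(1/2); within each class a voxel is
    drawn with probability proportional to
    ``1 + high_suv_boost·[SUV > ref] + hard_example_boost·[misclassified]``.
    Patches crossing the volume border are padded with air/zero/background.
    """
    if case.truth_seg is None:
        raise ValueError("training cases need a ground-truth segmentation")
    case = _at_working_spacing(case, cfg)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    channels = encode_channels(case, cfg)
    truth = case.truth_seg.values.astype(np.int8)
    suv = case.pet.values
    mis = None
    if misclassified_map is not None:
        mis = misclassified_map.values.astype(bool)

    flat_truth = truth.ravel().astype(bool)
    lesion_flat = np.flatnonzero(flat_truth)
    bg_flat = np.flatnonzero(~flat_truth)

    n_lesion_req = int(np.sum(rng.random(n) < 0.5))
    if n_lesion_req > 0 and lesion_flat.size == 0:
        raise SamplingError(
            f"case {case.case_id}: lesion-class patches requested but the "
            "case has no lesion voxels")

    def draw(pool, k):
        if k == 0:
            return np.empty(0, dtype=np.int64)
        w = _class_weights(suv.ravel()[pool],
                           None if mis is None else mis.ravel()[pool], cfg)
        p = w / w.sum()
        return rng.choice(pool, size=k, replace=True, p=p)

    picks = np.concatenate([draw(lesion_flat, n_lesion_req),
                            draw(bg_flat, n - n_lesion_req)])
    classes = ["lesion"] * n_lesion_req + ["background"] * (n - n_lesion_req)

    half_in = [p // 2 for p in cfg.input_patch]
    half_out = [p // 2 for p in cfg.output_patch]
    padded = _pad_channels(channels, half_in, half_in, cfg)
    t_padded = np.zeros(tuple(s + 2 * h for s, h in zip(truth.shape, half_out)),
                        dtype=np.int8)
    t_padded[tuple(slice(h, h + s) for h, s in zip(half_out, truth.shape))] = truth

    patches = []
    for flat, cls in zip(picks, classes):
        c = np.unravel_index(flat, truth.shape)
        inp = _extract_patch(padded, c, cfg, half_in)
        tsl = tuple(slice(ci, ci + p) for ci, p in zip(c, cfg.output_patch))
        patches.append(TrainingPatch(
            inputs=np.ascontiguousarray(inp),
            target=np.ascontiguousarray(t_padded[tsl]),
            center_class=cls,
            center=tuple(int(x) for x in c)))
    order = rng.permutation(n)
    return [patches[i] for i in order]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class LesionModel:
    """Trained lesion network plus its configuration and loss history."""

    net: UNet3D
    cfg: CnnConfig
    epoch_losses: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        """Checkpoint (npz) with a JSON config sidecar and CSV loss log."""
        path = Path(path)
        np.savez_compressed(path, **self.net.state_dict())
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(asdict(self.cfg), indent=2))
        log = path.with_suffix(".losses.csv")
        with open(log, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "loss"])
            for i, loss in enumerate(self.epoch_losses, start=1):
                writer.writerow([i, f"{loss:.6f}"])

    @classmethod
    def load(cls, path: str | Path) -> "LesionModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        for key in ("input_patch", "output_patch", "working_spacing_mm",
                    "regions"):
            sidecar[key] = tuple(sidecar[key])
        cfg = CnnConfig(**sidecar)
        model = _build(cfg)
        with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as st:
            model.net.load_state_dict(dict(st))
        return model


def _build(cfg: CnnConfig) -> LesionModel:
    net = UNet3D(cfg.in_channels, cfg.n_classes, cfg.depth,
                 cfg.convs_per_block, cfg.base_filters, seed=cfg.seed)
    return LesionModel(net=net, cfg=cfg)


def train_model(cases: list[PatientCase], cfg: CnnConfig) -> LesionModel:
    """Train the lesion network on annotated cases.

    Cases are brought to the working spacing, patches are drawn with the
    class-balanced hard-example sampler, and the network is optimised with
    Adam on categorical cross-entropy. Fully deterministic under
    ``cfg.seed``. With ``hard_example_refresh`` the misclassification maps
    are recomputed once at mid-training from the then-current network and
    fed back into the sampler.
    """
    if not cases:
        raise ValueError("train_model needs at least one annotated case")
    cases = [_at_working_spacing(c, cfg) for c in cases]
    for c in cases:
        if c.truth_seg is None:
            raise ValueError(f"case {c.case_id} lacks a ground-truth segmentation")

    rng = np.random.default_rng(cfg.seed)
    model = _build(cfg)
    opt = Adam(model.net.params(), lr=cfg.learning_rate)
    lesion_cases = [i for i, c in enumerate(cases)
                    if np.any(c.truth_seg.values)]
    mis_maps: dict[int, VoxelGrid] = {}

    for epoch in range(cfg.epochs):
        if cfg.hard_example_refresh and epoch == max(1, cfg.epochs // 2):
            for i, c in enumerate(cases):
                prob = predict_volume(model, c, cfg)
                pred = prob.values >= cfg.lesion_prob_threshold
                mis = pred != c.truth_seg.values.astype(bool)
                mis_maps[i] = c.truth_seg.with_values(mis.astype(np.int32),
                                                      "binary")
        patches: list[TrainingPatch] = []
        quota = np.bincount(rng.integers(len(cases), size=cfg.patches_per_epoch),
                            minlength=len(cases))
        for i, k in enumerate(quota):
            if k == 0:
                continue
            try:
                patches += sample_training_patches(
                    cases[i], cfg, int(k), mis_maps.get(i), rng)
            except SamplingError:
                if not lesion_cases:
                    raise
                j = lesion_cases[int(rng.integers(len(lesion_cases)))]
                patches += sample_training_patches(
                    cases[j], cfg, int(k), mis_maps.get(j), rng)
        order = rng.permutation(len(patches))
        losses = []
        for start in range(0, len(patches), cfg.batch_size):
            batch = [patches[i] for i in order[start:start + cfg.batch_size]]
            x = np.stack([p.inputs for p in batch])
            t = np.stack([p.target for p in batch]).astype(np.int64)
            logits = model.net.forward(x)
            loss, grad = softmax_cross_entropy(logits, t)
            model.net.backward(grad)
            opt.step()
            losses.append(loss)
        model.epoch_losses.append(float(np.mean(losses)))
    return model


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def tile_starts(shape, output_patch) -> list[tuple[int, int, int]]:
    """Output-window start indices tiling a volume with stride = window."""
    import itertools
    ranges = [range(0, -(-s // o) * o, o) for s, o in zip(shape, output_patch)]
    return list(itertools.product(*ranges))


def predict_volume(model: LesionModel, case: PatientCase,
                   cfg: CnnConfig | None = None,
                   batch_tiles: int = 8) -> VoxelGrid:
    """Lesion-class probability for every voxel of the case grid.

    The volume is resampled to the working spacing, tiled with stride equal
    to the output window (each voxel predicted exactly once), context-padded
    with air / zero-SUV / background labels, and the probability map is
    resampled back to the case's native grid.
    """
    cfg = cfg or model.cfg
    work = _at_working_spacing(case, cfg)
    channels = encode_channels(work, cfg)
    if channels.shape[0] != model.net.in_channels:
        raise ValueError(
            f"model expects {model.net.in_channels} channels, case encodes "
            f"{channels.shape[0]}")
    shape = work.ct.shape
    out_p = cfg.output_patch
    margin = [(i - o) // 2 for i, o in zip(cfg.input_patch, out_p)]
    starts = tile_starts(shape, out_p)
    cover = [-(-s // o) * o for s, o in zip(shape, out_p)]
    padded = _pad_channels(channels, margin,
                           [m + c - s for m, c, s in zip(margin, cover, shape)],
                           cfg)

    prob = np.zeros(cover, dtype=np.float32)
    for i in range(0, len(starts), batch_tiles):
        chunk = starts[i:i + batch_tiles]
        x = np.stack([
            padded[(slice(None),) + tuple(slice(s, s + p) for s, p
                                          in zip(st, cfg.input_patch))]
            for st in chunk])
        p = model.net.predict_proba(x)[:, 1]
        for st, block in zip(chunk, p):
            sl = tuple(slice(s, s + o) for s, o in zip(st, out_p))
            prob[sl] = block
    prob = np.clip(prob[tuple(slice(0, s) for s in shape)], 0.0, 1.0)
    grid = VoxelGrid(prob, work.ct.spacing_mm.copy(), work.ct.origin_mm.copy(),
                     "probability")
    if not np.allclose(case.ct.spacing_mm, cfg.working_spacing_mm, atol=1e-6):
        grid = resample_trilinear(grid, case.ct.spacing_mm)
        grid = _match_shape(grid, case.ct.shape)
    return grid


def _match_shape(grid: VoxelGrid, shape) -> VoxelGrid:
    """Crop/edge-pad to reconcile round(extent/spacing) with a native shape."""
    v = grid.values
    for ax, target in enumerate(shape):
        if v.shape[ax] > target:
            v = np.take(v, range(target), axis=ax)
        elif v.shape[ax] < target:
            pad = [(0, 0)] * 3
            pad[ax] = (0, target - v.shape[ax])
            v = np.pad(v, pad, mode="edge")
    return VoxelGrid(v, grid.spacing_mm.copy(), grid.origin_mm.copy(),
                     grid.unit_tag)


def segment_case(model: LesionModel, case: PatientCase,
                 post_cfg: PostprocessConfig | None = None,
                 cfg: CnnConfig | None = None) -> VoxelGrid:
    """Full learned-model segmentation path.

    Probability map -> binarisation -> small-component filter -> watershed
    joint removal -> second small-component filter (basin removal can
    fragment components).
    """
    cfg = cfg or model.cfg
    post_cfg = post_cfg or PostprocessConfig()
    prob = predict_volume(model, case, cfg)
    seg = prob.with_values(
        (prob.values >= cfg.lesion_prob_threshold).astype(np.int32), "binary")
    seg = filter_small_components(seg, post_cfg)
    joints = build_joint_mask(case.label_mask, post_cfg)
    seg = watershed_joint_removal(seg, case.pet, joints, post_cfg)
    return filter_small_components(seg, post_cfg)
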