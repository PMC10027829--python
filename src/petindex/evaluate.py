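"""Multi-reader detection and agreement statistics.

The evaluation framework compares candidate segmentations (readers, the
learned model, the SUV-threshold baseline) against each reader alternately
held as reference:

* patient level — a scan counts TP when both candidate and reference found
  any suspicious uptake (PET index > 0), FN when only the reference did, FP
  when only the candidate did; scans where both are empty contribute to no
  count, so no true-negative (and no specificity) is defined;
* lesion level — a reference lesion with any overlap from the candidate is
  TP, with zero overlap FN; a candidate component with zero overlap with the
  reference is FP;
* Spearman rank correlation between PET indices with the conventional
  interpretation bands (very strong / moderately strong / fair / poor);
* Bland–Altman limits of agreement on log10(x + 1)-transformed PET indices,
  back-transformed to index units.

Pairwise results are averaged over the choice of reference reader.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .postprocess import connectivity_structure
from .quantify import PetIndexResult
from .volumes import VoxelGrid

__all__ = [
    "DetectionCounts",
    "CorrelationResult",
    "BlandAltmanResult",
    "AgreementReport",
    "UndefinedCorrelationError",
    "patient_detection_counts",
    "lesion_detection_counts",
    "pairwise_reference_average",
    "spearman_with_band",
    "band_for_r",
    "bland_altman_log10",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested on a constant series."""


@dataclass
class DetectionCounts:
    """TP/FP/FN tallies with derived sensitivity and PPV.

    Sensitivity and PPV are ``None`` (absent), never silently 0, when their
    denominator is zero.
    """

    tp: float = 0.0
    fp: float = 0.0
    fn: float = 0.0
    n_patients: int | None = None

    @property
    def sensitivity_percent(self) -> float | None:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom > 0 else None

    @property
    def ppv_percent(self) -> float | None:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom > 0 else None

    def per_patient(self) -> tuple[float, float, float]:
        if not self.n_patients:
            raise ValueError("n_patients not set")
        return (self.tp / self.n_patients, self.fp / self.n_patients,
                self.fn / self.n_patients)

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        n = None
        if self.n_patients is not None or other.n_patients is not None:
            n = (self.n_patients or 0) + (other.n_patients or 0)
        return DetectionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, n)


#: Interpretation bands for |r|, closed on the left.
_BANDS = [(0.8, "very strong"), (0.6, "moderately strong"),
          (0.3, "fair"), (0.0, "poor")]


def band_for_r(r: float) -> str:
    a = abs(r)
    for lo, name in _BANDS:
        if a >= lo:
            return name
    return "poor"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    band: str


@dataclass(frozen=True)
class BlandAltmanResult:
    """Limits of agreement in log10(x+1) units with back-transformed bounds."""

    mean_diff: float
    loa_upper: float
    loa_lower: float
    back_upper: float
    back_lower: float
    sd_diff: float


def _as_index(value) -> float:
    return value.index_percent if isinstance(value, PetIndexResult) else float(value)


def patient_detection_counts(candidate_indices: Sequence,
                             reference_indices: Sequence) -> DetectionCounts:
    """Patient-level detection counts from case-aligned PET index lists.

    Scans where both candidate and reference have index 0 are excluded from
    every count.
    """
    if len(candidate_indices) != len(reference_indices):
        raise ValueError(
            f"candidate and reference lists differ in length "
            f"({len(candidate_indices)} vs {len(reference_indices)})")
    cand = np.array([_as_index(v) for v in candidate_indices])
    ref = np.array([_as_index(v) for v in reference_indices])
    return DetectionCounts(
        tp=float(np.sum((cand > 0) & (ref > 0))),
        fp=float(np.sum((cand > 0) & (ref == 0))),
        fn=float(np.sum((cand == 0) & (ref > 0))),
        n_patients=len(cand),
    )


def lesion_detection_counts(candidate_seg: VoxelGrid, reference_seg: VoxelGrid,
                            connectivity: int = 26) -> DetectionCounts:
    """Lesion-level detection counts between two binary segmentations.

    A reference component with at least one candidate-marked voxel is TP
    (full or partial overlap both count); zero overlap makes it FN. A
    candidate component with zero overlap with any reference marking is FP —
    one candidate blob may validate several reference lesions, and a
    candidate blob touching any reference marking is never FP.
    """
    if not candidate_seg.same_grid(reference_seg):
        raise ValueError("candidate and reference grids are not co-registered")
    structure = connectivity_structure(connectivity)
    cand = candidate_seg.values.astype(bool)
    ref = reference_seg.values.astype(bool)

    ref_lbl, n_ref = ndimage.label(ref, structure=structure)
    cand_lbl, n_cand = ndimage.label(cand, structure=structure)

    tp = fn = 0
    if n_ref:
        hit = np.unique(ref_lbl[cand & ref])
        tp = int(np.sum(hit > 0))
        fn = n_ref - tp
    fp = 0
    if n_cand:
        touched = np.unique(cand_lbl[cand & ref])
        fp = n_cand - int(np.sum(touched > 0))
    return DetectionCounts(tp=float(tp), fp=float(fp), fn=float(fn), n_patients=1)


def spearman_with_band(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with its interpretation band.

    Ties get average ranks; the coefficient is the Pearson correlation of
    the ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length series of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant series")
    r = float(stats.spearmanr(x, y).statistic)
    return CorrelationResult(r=r, band=band_for_r(r))


def bland_altman_log10(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Bland–Altman limits of agreement on log10(x+1)-transformed indices.

    Differences are log10(x_i + 1) − log10(y_i + 1); limits of agreement are
    mean ± 1.96 × sample SD (n − 1); back-transformed bounds are
    10^LoA − 1 in index units.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length series of length >= 2")
    if x.min() < 0 or y.min() < 0:
        raise ValueError("PET indices must be non-negative")
    d = np.log10(x + 1) - np.log10(y + 1)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    upper, lower = mean + 1.96 * sd, mean - 1.96 * sd
    return BlandAltmanResult(
        mean_diff=mean, loa_upper=upper, loa_lower=lower,
        back_upper=10.0 ** upper - 1.0, back_lower=10.0 ** lower - 1.0,
        sd_diff=sd,
    )


# ---------------------------------------------------------------------------
# alternating-reference agreement report
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Pairwise and reference-averaged agreement over a cohort.

    ``pairwise`` holds one row per (candidate, reference, level) with summed
    counts over cases; ``averaged`` holds, per candidate group, the mean over
    reference choices of both the pairwise sensitivities/PPVs and the per-
    pair counts, plus min/median/max of the pairwise values.
    """

    pairwise: pd.DataFrame
    averaged: pd.DataFrame
    spearman: pd.DataFrame
    bland_altman: dict[tuple[str, str], BlandAltmanResult]
    pet_indices: pd.DataFrame
    n_cases: int = 0

    def to_json(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "pairwise": self.pairwise.to_dict(orient="records"),
            "averaged": self.averaged.to_dict(orient="records"),
            "spearman": self.spearman.round(4).to_dict(),
            "bland_altman": {
                f"{c}|{r}": vars(v) for (c, r), v in self.bland_altman.items()
            },
        }

    def save(self, directory: str | Path) -> None:
        """Write the report as JSON plus per-pair CSV table."""
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "agreement.json").write_text(
            json.dumps(self.to_json(), indent=2, default=float))
        self.pairwise.to_csv(directory / "pairwise.csv", index=False)
        self.averaged.to_csv(directory / "averaged.csv", index=False)
        self.spearman.to_csv(directory / "spearman.csv")

    def plot(self, directory: str | Path) -> None:
        """Optional Bland–Altman and correlation-matrix figures."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fig, ax = plt.subplots()
        im = ax.imshow(self.spearman.values, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(self.spearman.columns)),
                      self.spearman.columns, rotation=45)
        ax.set_yticks(range(len(self.spearman.index)), self.spearman.index)
        fig.colorbar(im, ax=ax, label="Spearman r")
        fig.tight_layout()
        fig.savefig(directory / "spearman_matrix.png", dpi=120)
        plt.close(fig)

        for (cand, ref), ba in self.bland_altman.items():
            xi = np.log10(self.pet_indices[cand].values + 1)
            yi = np.log10(self.pet_indices[ref].values + 1)
            fig, ax = plt.subplots()
            ax.scatter((xi + yi) / 2, xi - yi, s=18)
            ax.axhline(ba.mean_diff, color="k")
            for v in (ba.loa_upper, ba.loa_lower):
                ax.axhline(v, color="k", linestyle=":")
            ax.set_xlabel("mean of log10(index+1)")
            ax.set_ylabel(f"{cand} − {ref}")
            fig.tight_layout()
            fig.savefig(directory / f"bland_altman_{cand}_vs_{ref}.png", dpi=120)
            plt.close(fig)


def _pair_counts(cand_segs, ref_segs, connectivity, indices_c, indices_r):
    lesion = DetectionCounts(n_patients=0)
    for cs, rs in zip(cand_segs, ref_segs):
        lesion = lesion + lesion_detection_counts(cs, rs, connectivity)
    patient = patient_detection_counts(indices_c, indices_r)
    return lesion, patient


def pairwise_reference_average(
    reader_segs: Mapping[str, Sequence[VoxelGrid]],
    model_segs: Mapping[str, Sequence[VoxelGrid]] | None = None,
    label_masks: Sequence[VoxelGrid] | None = None,
    connectivity: int = 26,
) -> AgreementReport:
    """Alternating-reference pairwise comparison over a cohort.

    Each reader is alternately held as reference; every other reader and
    every model is compared against it, at both lesion and patient level.
    Averaged rows take the arithmetic mean over the choices of reference.
    PET indices (hence patient-level counts, correlations and Bland–Altman)
    require ``label_masks``, one per case.
    """
    from .quantify import compute_pet_index

    model_segs = model_segs or {}
    readers = list(reader_segs)
    if len(readers) < 2:
        raise ValueError("need at least 2 readers for alternating-reference analysis")
    n_cases = len(next(iter(reader_segs.values())))
    for name, segs in {**reader_segs, **model_segs}.items():
        if len(segs) != n_cases:
            raise ValueError(f"participant {name!r} has {len(segs)} cases, "
                             f"expected {n_cases}")

    participants = {**reader_segs, **model_segs}
    indices: dict[str, list[float]] = {}
    if label_masks is not None:
        if len(label_masks) != n_cases:
            raise ValueError("need one label mask per case")
        for name, segs in participants.items():
            indices[name] = [compute_pet_index(s, m).index_percent
                             for s, m in zip(segs, label_masks)]

    rows = []
    for ref in readers:
        for cand in participants:
            if cand == ref:
                continue
            group = ("reader" if cand in reader_segs else cand)
            lesion = DetectionCounts(n_patients=0)
            for cs, rs in zip(participants[cand], reader_segs[ref]):
                lesion = lesion + lesion_detection_counts(cs, rs, connectivity)
            row = {"candidate": cand, "reference": ref, "group": group}
            for level, counts in [("lesion", lesion)]:
                row.update({f"{level}_tp": counts.tp, f"{level}_fp": counts.fp,
                            f"{level}_fn": counts.fn,
                            f"{level}_sensitivity": counts.sensitivity_percent,
                            f"{level}_ppv": counts.ppv_percent})
            if indices:
                pat = patient_detection_counts(indices[cand], indices[ref])
                row.update({"patient_tp": pat.tp, "patient_fp": pat.fp,
                            "patient_fn": pat.fn,
                            "patient_sensitivity": pat.sensitivity_percent,
                            "patient_ppv": pat.ppv_percent})
            rows.append(row)
    pairwise = pd.DataFrame(rows)

    # reference-averaged rows per comparison group
    metric_cols = [c for c in pairwise.columns
                   if c not in ("candidate", "reference", "group")]
    avg_rows = []
    for group, sub in pairwise.groupby("group", sort=False):
        row = {"group": f"{group} vs reader"}
        for col in metric_cols:
            vals = sub[col].dropna().astype(float)
            row[f"{col}_mean"] = vals.mean() if len(vals) else None
            row[f"{col}_min"] = vals.min() if len(vals) else None
            row[f"{col}_median"] = vals.median() if len(vals) else None
            row[f"{col}_max"] = vals.max() if len(vals) else None
        # sensitivity/PPV of the summed counts, which differ from the mean
        # of pairwise sensitivities
        for level in ("lesion", "patient"):
            if f"{level}_tp" in sub:
                pooled = DetectionCounts(sub[f"{level}_tp"].sum(),
                                         sub[f"{level}_fp"].sum(),
                                         sub[f"{level}_fn"].sum())
                row[f"{level}_sensitivity_pooled"] = pooled.sensitivity_percent
                row[f"{level}_ppv_pooled"] = pooled.ppv_percent
        row["n_pairs"] = len(sub)
        avg_rows.append(row)
    averaged = pd.DataFrame(avg_rows)

    # Spearman matrix and Bland–Altman set over PET indices
    names = list(participants)
    spearman = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    bland: dict[tuple[str, str], BlandAltmanResult] = {}
    pet_df = pd.DataFrame(indices) if indices else pd.DataFrame()
    if indices:
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    try:
                        r = spearman_with_band(indices[a], indices[b]).r
                    except UndefinedCorrelationError:
                        r = np.nan
                    spearman.loc[a, b] = spearman.loc[b, a] = r
        for cand in model_segs:
            for ref in readers:
                bland[(cand, ref)] = bland_altman_log10(indices[cand], indices[ref])

    return AgreementReport(pairwise=pairwise, averaged=averaged,
                           spearman=spearman, bland_altman=bland,
                           pet_indices=pet_df, n_cases=n_cases)
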