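"""Detection metrics, alternating-reference averaging, Spearman bands and
Bland–Altman limits of agreement."""

import numpy as np
import pytest

from petindex.evaluate import (DetectionCounts, UndefinedCorrelationError,
                               band_for_r, bland_altman_log10,
                               lesion_detection_counts,
                               pairwise_reference_average,
                               patient_detection_counts, spearman_with_band)
from petindex.volumes import REGION_LABELS, VoxelGrid

from oracles import lesion_pair_counts, spearman_rank_pearson


def binary(values, spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(values, dtype=np.int32), spacing,
                     unit_tag="binary")


class TestPatientLevel:
    def test_mixed_example(self):
        c = patient_detection_counts([0.5, 0, 0.2], [0.3, 0, 0])
        assert (c.tp, c.fn, c.fp) == (1, 0, 1)
        assert c.sensitivity_percent == 100.0
        assert c.ppv_percent == 50.0

    def test_identical_lists(self):
        c = patient_detection_counts([0.1, 0, 2.0, 0.3], [0.1, 0, 2.0, 0.3])
        assert (c.tp, c.fp, c.fn) == (3, 0, 0)

    def test_all_zero_candidate_has_zero_sensitivity(self):
        c = patient_detection_counts([0, 0, 0], [1.0, 0.5, 0])
        assert c.sensitivity_percent == 0.0

    def test_both_zero_scans_contribute_nothing(self):
        c = patient_detection_counts([0, 0], [0, 0])
        assert (c.tp, c.fp, c.fn) == (0, 0, 0)
        assert c.sensitivity_percent is None  # absent, not silently 0
        assert c.ppv_percent is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            patient_detection_counts([1.0], [1.0, 2.0])


class TestLesionLevel:
    def test_identity_is_perfect(self):
        rng = np.random.default_rng(1)
        seg = binary((rng.random((10, 10, 10)) < 0.2).astype(np.int32))
        c = lesion_detection_counts(seg, seg)
        assert c.fp == 0 and c.fn == 0
        assert c.sensitivity_percent == 100.0
        assert c.ppv_percent == 100.0

    def test_partial_overlap_counts_as_tp(self):
        ref = np.zeros((8, 8, 8), dtype=np.int32)
        ref[2:5, 2:5, 2:5] = 1
        cand = np.zeros((8, 8, 8), dtype=np.int32)
        cand[4:7, 4:7, 4:7] = 1  # touches one corner voxel of ref
        c = lesion_detection_counts(binary(cand), binary(ref))
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_one_candidate_blob_validates_two_reference_lesions(self):
        ref = np.zeros((12, 6, 6), dtype=np.int32)
        ref[1:3, 1:3, 1:3] = 1
        ref[8:10, 1:3, 1:3] = 1
        cand = np.zeros((12, 6, 6), dtype=np.int32)
        cand[0:12, 1:3, 1:3] = 1  # single blob spanning both
        c = lesion_detection_counts(binary(cand), binary(ref))
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            shape = tuple(rng.integers(4, 17, size=3))
            cand = (rng.random(shape) < rng.uniform(0.05, 0.3))
            ref = (rng.random(shape) < rng.uniform(0.05, 0.3))
            c = lesion_detection_counts(binary(cand.astype(np.int32)),
                                        binary(ref.astype(np.int32)))
            assert (c.tp, c.fp, c.fn) == lesion_pair_counts(cand, ref, 26)

    def test_worked_example_sensitivity_and_ppv(self):
        # TP=130, FN=61, FP=38 -> sensitivity 68%, PPV 77% (integers)
        c = DetectionCounts(tp=130, fp=38, fn=61, n_patients=26)
        assert round(c.sensitivity_percent) == 68
        assert round(c.ppv_percent) == 77
        tp_pp, fp_pp, fn_pp = c.per_patient()
        assert round(tp_pp, 1) == 5.0
        assert round(fp_pp, 1) == 1.5
        assert round(fn_pp, 1) == 2.3


class TestPairwiseReferenceAverage:
    def _toy_cohort(self):
        rng = np.random.default_rng(3)
        masks, readers_a, readers_b, model = [], [], [], []
        for _ in range(6):
            labels = np.zeros((10, 10, 10), dtype=np.int32)
            labels[:5] = REGION_LABELS["bones"]
            masks.append(VoxelGrid(labels, (2, 2, 2), unit_tag="label"))
            truth = (rng.random((10, 10, 10)) < 0.05).astype(np.int32)
            truth[7:] = 0
            readers_a.append(binary(truth, (2, 2, 2)))
            b = truth.copy()
            if rng.random() < 0.5:
                b[:] = 0
            readers_b.append(binary(b, (2, 2, 2)))
            model.append(binary(truth, (2, 2, 2)))
        return readers_a, readers_b, model, masks

    def test_two_identical_readers_agree_perfectly(self):
        a, _, _, masks = self._toy_cohort()
        rep = pairwise_reference_average({"A": a, "B": a}, {},
                                         label_masks=masks)
        for _, row in rep.pairwise.iterrows():
            assert row["lesion_sensitivity"] == 100.0
            assert row["lesion_ppv"] == 100.0

    def test_patient_level_fp_fn_symmetry(self):
        a, b, _, masks = self._toy_cohort()
        rep = pairwise_reference_average({"A": a, "B": b}, {},
                                         label_masks=masks)
        p = rep.pairwise.set_index(["candidate", "reference"])
        assert p.loc[("A", "B"), "patient_fp"] == p.loc[("B", "A"), "patient_fn"]
        assert p.loc[("A", "B"), "patient_fn"] == p.loc[("B", "A"), "patient_fp"]

    def test_averaged_row_is_mean_over_references(self):
        a, b, model, masks = self._toy_cohort()
        rep = pairwise_reference_average({"A": a, "B": b}, {"AI": model},
                                         label_masks=masks)
        sub = rep.pairwise[rep.pairwise["candidate"] == "AI"]
        avg = rep.averaged[rep.averaged["group"] == "AI vs reader"].iloc[0]
        assert avg["lesion_tp_mean"] == pytest.approx(sub["lesion_tp"].mean())
        assert avg["n_pairs"] == 2

    def test_single_reader_rejected(self):
        a, _, _, masks = self._toy_cohort()
        with pytest.raises(ValueError, match="2 readers"):
            pairwise_reference_average({"A": a}, {}, label_masks=masks)

    def test_report_is_deterministic(self):
        a, b, model, masks = self._toy_cohort()
        r1 = pairwise_reference_average({"A": a, "B": b}, {"AI": model}, masks)
        r2 = pairwise_reference_average({"A": a, "B": b}, {"AI": model}, masks)
        assert r1.pairwise.equals(r2.pairwise)
        assert r1.spearman.equals(r2.spearman)

    def test_report_saves_json_and_csv(self, tmp_path):
        a, b, model, masks = self._toy_cohort()
        rep = pairwise_reference_average({"A": a, "B": b}, {"AI": model}, masks)
        rep.save(tmp_path)
        assert (tmp_path / "agreement.json").exists()
        assert (tmp_path / "pairwise.csv").exists()

    def test_report_plots_figures(self, tmp_path):
        a, b, model, masks = self._toy_cohort()
        rep = pairwise_reference_average({"A": a, "B": b}, {"AI": model}, masks)
        rep.plot(tmp_path)
        assert (tmp_path / "spearman_matrix.png").exists()
        assert (tmp_path / "bland_altman_AI_vs_A.png").exists()


class TestSpearman:
    @pytest.mark.parametrize("r,band", [
        (0.69, "moderately strong"),
        (0.49, "fair"),
        (0.85, "very strong"),
        (0.1, "poor"),
        (-0.95, "very strong"),   # bands act on |r|
        (0.8, "very strong"),     # boundary: [0.8, 1] very strong
        (0.6, "moderately strong"),
        (0.3, "fair"),
        (0.2999, "poor"),
    ])
    def test_band_boundaries(self, r, band):
        assert band_for_r(r) == band

    def test_strictly_monotone_series_has_r_one(self):
        x = np.array([0.1, 0.5, 2.0, 3.3, 9.9])
        res = spearman_with_band(x, np.exp(x))
        assert res.r == pytest.approx(1.0)
        assert res.band == "very strong"

    def test_matches_rank_then_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 5, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            got = spearman_with_band(x, y).r
            assert got == pytest.approx(spearman_rank_pearson(x, y), abs=1e-12)

    def test_constant_series_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_with_band([1.0, 1.0, 1.0], [0.5, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_series_all_zero(self):
        x = [0.0, 1.2, 4.5, 0.3]
        res = bland_altman_log10(x, x)
        assert res.mean_diff == 0.0
        assert res.loa_upper == 0.0 and res.loa_lower == 0.0
        assert res.back_upper == 0.0 and res.back_lower == 0.0

    def test_log10_transform_reference_points(self):
        assert np.log10(0 + 1) == 0.0
        res = bland_altman_log10([9.0, 9.0], [0.0, 0.0])
        assert res.mean_diff == pytest.approx(1.0)  # log10(10) - log10(1)

    def test_back_transform_inverts_log(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 5, 20)
        y = rng.uniform(0, 5, 20)
        res = bland_altman_log10(x, y)
        assert res.back_upper == pytest.approx(10**res.loa_upper - 1)
        assert res.back_lower == pytest.approx(10**res.loa_lower - 1)

    def test_coverage_monte_carlo(self):
        # ~95% of normally distributed differences fall inside the LoA
        rng = np.random.default_rng(123)
        n = 10_000
        x = np.abs(rng.normal(2.0, 0.5, n))
        y = np.abs(x + rng.normal(0, 0.3, n))
        res = bland_altman_log10(x, y)
        d = np.log10(x + 1) - np.log10(y + 1)
        inside = np.mean((d >= res.loa_lower) & (d <= res.loa_upper))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            bland_altman_log10([-0.1, 1.0], [0.0, 1.0])
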