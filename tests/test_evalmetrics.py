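"""Suppression ratio, ROI scheme, lesion detection scoring and weighted kappa."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbsynth import phantom as ph
from bbsynth.evalmetrics import (
    DetectionReport,
    RatingTable,
    detect_lesions,
    kappa_interpretation,
    per_patient_summary,
    place_phantom_rois,
    roi_mean,
    suppression_report,
    vessel_suppression_ratio,
    weighted_kappa,
)
from bbsynth.preprocess import Volume3D


def oracle_weighted_kappa(table: np.ndarray, scheme: str = "linear") -> float:
    """Direct-formula weighted kappa, coded independently of the implementation."""
    table = np.asarray(table, float)
    n = table.sum()
    k = table.shape[0]
    i, j = np.indices((k, k))
    if scheme == "linear":
        w = 1.0 - np.abs(i - j) / (k - 1)
    elif scheme == "quadratic":
        w = 1.0 - (i - j) ** 2 / (k - 1) ** 2
    else:
        raise ValueError(scheme)
    p = table / n
    po = float((w * p).sum())
    pe = float((w * np.outer(p.sum(axis=1), p.sum(axis=0))).sum())
    return (po - pe) / (1.0 - pe)


class TestVesselSuppressionRatio:
    def test_complete_suppression_gives_two(self):
        assert vessel_suppression_ratio(0.5, 0.0) == 2.0

    def test_isointense_vessel_gives_one(self):
        assert vessel_suppression_ratio(0.37, 0.37) == 1.0

    def test_bright_vessel_arithmetic(self):
        assert vessel_suppression_ratio(0.4, 0.6) == pytest.approx(0.8)

    def test_nonpositive_wm_rejected(self):
        with pytest.raises(ValueError):
            vessel_suppression_ratio(0.0, 0.1)

    @settings(max_examples=200, deadline=None)
    @given(
        si_wm=st.floats(1e-6, 10.0),
        si_vessel=st.floats(0.0, 10.0),
        bump=st.floats(1e-6, 5.0),
    )
    def test_bounds_and_monotonicity(self, si_wm, si_vessel, bump):
        r = vessel_suppression_ratio(si_wm, si_vessel)
        assert 0.0 < r <= 2.0
        assert vessel_suppression_ratio(si_wm, si_vessel + bump) < r


@pytest.fixture(scope="module")
def rois(default_phantom):
    spec, truth, _, _ = default_phantom
    return place_phantom_rois(truth, spec)


class TestRoiScheme:

    def test_nine_vessel_rois_plus_wm(self, rois):
        assert sum(len(rois.vessel_rois[t]) for t in (1, 2, 3)) == 9
        assert len(rois.wm_roi) > 0

    def test_rois_pairwise_disjoint(self, rois):
        seen = set()
        for roi in rois.all_rois():
            vox = {tuple(v) for v in roi}
            assert not (seen & vox)
            seen |= vox

    def test_vessel_rois_sample_their_own_type(self, rois, default_phantom):
        _, truth, _, _ = default_phantom
        for t in (1, 2, 3):
            for roi in rois.vessel_rois[t]:
                assert truth.vessel_mask(t)[roi[:, 0], roi[:, 1], roi[:, 2]].all()

    def test_missing_vessel_type_rejected(self):
        spec = ph.PhantomSpec(seed=5, vessel_counts={1: 3, 2: 3, 3: 0})
        truth = ph.generate_truth(spec)
        with pytest.raises(ValueError, match="type 3"):
            place_phantom_rois(truth, spec)

    def test_roi_mean_arithmetic(self):
        vol = Volume3D(np.zeros((6, 6, 6)))
        vol.data[1, 1, 1] = 0.2
        vol.data[2, 2, 2] = 0.4
        assert roi_mean(vol, np.array([[1, 1, 1], [2, 2, 2]])) == pytest.approx(0.3)
        assert roi_mean(vol, np.array([[0, 0, 0]])) == 0.0

    def test_roi_mean_rejects_bad_rois(self):
        vol = Volume3D(np.zeros((6, 6, 6)))
        with pytest.raises(ValueError, match="empty"):
            roi_mean(vol, np.empty((0, 3), int))
        with pytest.raises(ValueError, match="bounds"):
            roi_mean(vol, np.array([[7, 0, 0]]))


class TestSuppressionReport:
    def test_noiseless_phantom_full_suppression(self):
        levels_bb = dict(ph.DEFAULT_LEVELS_BB, vessel=0.0)
        spec = ph.PhantomSpec(seed=4, noise_sd=0.0, bb_blur_sigma_vox=0.0,
                              tissue_levels_bb=levels_bb)
        truth, gre, bb = ph.generate_pair(spec)
        rois = place_phantom_rois(truth, spec)
        report = suppression_report([bb, gre], rois)
        for t in (1, 2, 3):
            assert report.r_s("BB", t) == pytest.approx(2.0)
            assert report.r_s("GRE", t) < 1.0

    def test_bb_beats_gre_on_default_phantom(self, default_phantom):
        spec, truth, gre, bb = default_phantom
        rois = place_phantom_rois(truth, spec)
        report = suppression_report([gre, bb], rois)
        for t in (1, 2, 3):
            assert report.r_s("BB", t) > report.r_s("GRE", t)

    def test_modality_order_preserved(self, default_phantom):
        spec, truth, gre, bb = default_phantom
        rois = place_phantom_rois(truth, spec)
        report = suppression_report([gre, bb], rois)
        assert [r["modality"] for r in report.rows] == ["GRE"] * 3 + ["BB"] * 3


class TestDetectLesions:
    def test_perfect_volume_perfect_score(self):
        # lesions of >=1.2 mm radius so every lesion spans >= min_size_vox voxels
        spec = ph.PhantomSpec(seed=31, lesion_radius_range_mm=(1.2, 5.5))
        truth = ph.generate_truth(spec)
        data = np.full(truth.label_map.shape, 0.3)
        data[truth.lesion_mask()] = 0.8
        report = detect_lesions(Volume3D(data), truth)
        assert report.sensitivity_pct == 100.0
        assert report.fp == 0
        assert report.tp + report.fn == report.n_true

    def test_missed_and_spurious_calls_counted(self, default_phantom):
        _, truth, _, _ = default_phantom
        data = np.full(truth.label_map.shape, 0.3)
        lesions = truth.lesion_mask()
        data[lesions] = 0.8
        # erase one lesion, add one spurious blob in clean WM
        big = max(truth.lesions, key=lambda l: l.radius_mm)
        c = np.rint(big.center_vox).astype(int)
        sl = tuple(slice(int(ci - big.radius_mm - 2), int(ci + big.radius_mm + 3)) for ci in c)
        data[sl] = 0.3
        spur = np.zeros_like(lesions)
        wm_free = truth.wm_mask() & ~lesions
        idx = np.argwhere(wm_free)[40]
        if truth.vessel_mask()[tuple(idx)] or True:
            data[idx[0] - 1 : idx[0] + 2, idx[1] - 1 : idx[1] + 2, idx[2] - 1 : idx[2] + 2] = 0.9
        report = detect_lesions(Volume3D(data), truth)
        assert report.fn >= 1
        assert report.fp >= 1
        assert report.tp + report.fn == report.n_true

    def test_empty_truth_flagged(self):
        spec = ph.PhantomSpec(seed=9, n_lesions=0)
        truth = ph.generate_truth(spec)
        data = np.full(truth.label_map.shape, 0.3)
        with pytest.warns(UserWarning, match="undefined"):
            report = detect_lesions(Volume3D(data), truth)
        assert report.undefined and report.sensitivity_pct is None and report.fp == 0

    def test_printed_count_arithmetic(self):
        r = DetectionReport.from_counts(tp=56, n_true=62, tp_ge2mm=49, n_true_ge2mm=50, fp=1)
        assert round(r.sensitivity_pct, 1) == 90.3
        assert round(r.sensitivity_ge2mm_pct, 1) == 98.0
        full = DetectionReport.from_counts(tp=18, n_true=18)
        assert full.sensitivity_pct == 100.0

    def test_per_patient_summary(self):
        reports = [
            DetectionReport.from_counts(tp=2, n_true=2),
            DetectionReport.from_counts(tp=1, n_true=3, fp=1),
            DetectionReport.from_counts(tp=0, n_true=0, fp=2),
        ]
        summary = per_patient_summary(reports)
        assert summary["per_patient_sensitivity_pct"] == 100.0
        assert summary["fp_volumes"] == 2
        assert summary["n_lesion_bearing"] == 2


class TestWeightedKappa:
    def test_perfect_agreement_gives_one(self):
        scores = np.tile([1, 2, 3, 2], 5)
        table = RatingTable(rater_a=scores, rater_b=scores.copy())
        assert weighted_kappa(table) == pytest.approx(1.0)

    @pytest.mark.parametrize("scheme", ["linear", "quadratic"])
    def test_matches_direct_formula_oracle(self, scheme, rng):
        for _ in range(50):
            table = rng.integers(0, 20, size=(3, 3)).astype(float)
            if table.sum() == 0 or oracle_weighted_kappa(table, scheme) != oracle_weighted_kappa(table, scheme):
                continue
            assert weighted_kappa(table, weighting=scheme) == pytest.approx(
                oracle_weighted_kappa(table, scheme), abs=1e-12
            )

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(77)
        a = rng.integers(1, 4, 100_000)
        b = rng.integers(1, 4, 100_000)
        kappa = weighted_kappa(RatingTable(rater_a=a, rater_b=b))
        assert abs(kappa) < 0.02

    def test_two_category_quadratic_equals_unweighted(self):
        from statsmodels.stats.inter_rater import cohens_kappa

        table = np.array([[12.0, 3.0], [4.0, 11.0]])
        unweighted = float(cohens_kappa(table, return_results=True).kappa)
        assert weighted_kappa(table, weighting="quadratic") == pytest.approx(unweighted, abs=1e-12)

    def test_single_category_flagged_undefined(self):
        a = np.ones(10, int)
        with pytest.warns(UserWarning, match="undefined"):
            kappa = weighted_kappa(RatingTable(rater_a=a, rater_b=a.copy()))
        assert np.isnan(kappa)

    def test_interpretation_bands(self):
        assert kappa_interpretation(0.9) == "excellent"
        assert kappa_interpretation(0.7) == "good"
        assert kappa_interpretation(0.5) == "moderate"
        assert kappa_interpretation(0.3) == "fair"
        assert kappa_interpretation(0.1) == "slight"
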