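"""Evaluation metrics: RMSE, parameter-map SNR, method and model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ivim3fit import (
    SimConfig,
    compare_methods,
    correlate_with_grades,
    fit_roi,
    map_snr,
    rmse,
    simulate_batch,
)
from ivim3fit.metrics import map_snr_table, normalised_rmse, rmse_table
from ivim3fit.models import ValidationError


class TestRmse:
    def test_zero_iff_identical(self, rng):
        truth = {"D": rng.uniform(1e-3, 3e-3, 100)}
        assert rmse(truth, truth)["D"] == 0.0
        assert rmse({"D": truth["D"] + 1e-6}, truth)["D"] > 0

    def test_constant_offset_gives_offset_magnitude(self, rng):
        truth = {"f1": rng.uniform(0.05, 0.3, 50)}
        pred = {"f1": truth["f1"] - 0.02}
        assert rmse(pred, truth)["f1"] == pytest.approx(0.02, rel=1e-12)

    def test_three_row_hand_example(self):
        pred = {"D": np.array([1.0, 2.0, 4.0])}
        truth = {"D": np.array([1.0, 1.0, 1.0])}
        # sqrt((0 + 1 + 9)/3)
        assert rmse(pred, truth)["D"] == pytest.approx(np.sqrt(10 / 3), rel=1e-12)

    def test_invariant_to_joint_permutation(self, rng):
        truth = rng.uniform(0, 1, 200)
        pred = truth + rng.normal(0, 0.1, 200)
        perm = rng.permutation(200)
        a = rmse({"x": pred}, {"x": truth})["x"]
        b = rmse({"x": pred[perm]}, {"x": truth[perm]})["x"]
        assert a == pytest.approx(b, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            rmse({"D": np.ones(3)}, {"D": np.ones(4)})

    def test_normalised_variant_scales_by_truth_mean(self):
        truth = {"D": np.full(10, 2.0)}
        pred = {"D": np.full(10, 2.5)}
        assert normalised_rmse(pred, truth)["D"] == pytest.approx(0.25)

    def test_rmse_table_layout(self):
        table = rmse_table(
            {("nn", 15): {"D": 1.0, "f1": 0.1}, ("lsq", 15): {"D": 2.0, "f1": 0.2}}
        )
        assert table.loc[("nn", 15), "D"] == 1.0
        assert list(table.index.names) == ["method", "snr_level"]


class TestMapSnr:
    def test_zero_variance_flagged_undefined(self):
        assert np.isnan(map_snr(np.array([1.0, 1.0, 1.0])))

    def test_direct_formula(self):
        # mean 2.0, sample SD 0.5
        assert map_snr(np.array([1.5, 2.0, 2.5])) == pytest.approx(4.0)

    def test_fewer_than_two_voxels_rejected(self):
        with pytest.raises(ValidationError):
            map_snr(np.array([1.0]))

    def test_scale_invariance(self, rng):
        values = rng.uniform(1, 2, 500)
        assert map_snr(values * 7.3) == pytest.approx(map_snr(values), rel=1e-12)

    def test_monte_carlo_matches_truth_over_sigma(self, rng):
        truth, sigma = 2.0, 0.1
        values = truth + rng.normal(0, sigma, 20000)
        assert map_snr(values) == pytest.approx(truth / sigma, rel=0.05)

    def test_roi_selection_and_table(self, rng):
        m = rng.uniform(1, 2, (6, 6, 3))
        roi = np.zeros((6, 6, 3), bool)
        roi[1:4, 1:4, 1] = True
        expected = map_snr(m[roi])
        assert map_snr(m, roi) == pytest.approx(expected)
        table = map_snr_table({"s1": {"D": m}}, {"s1": roi})
        assert table.loc["s1", "D"] == pytest.approx(expected)


class TestCompareMethods:
    def test_identical_methods_give_null_statistics(self, rng):
        frame = pd.DataFrame({"D": rng.uniform(1, 2, 12)})
        out = compare_methods({"a": frame, "b": frame.copy()})
        row = out.iloc[0]
        assert row["mean_diff"] == 0.0
        assert row["wilcoxon_stat"] == 0.0 and row["wilcoxon_p"] == 1.0

    def test_constructed_dominance_truth_vs_noisy(self, rng):
        # method A returns the truth map, method B adds noise: A's map SNR
        # exceeds B's in every replicate
        n_rep = 20
        snr_a, snr_b = [], []
        for _ in range(n_rep):
            truth = np.full(400, 1.5) + rng.normal(0, 0.01, 400)
            noisy = truth + rng.normal(0, 0.2, 400)
            snr_a.append(map_snr(truth))
            snr_b.append(map_snr(noisy))
        assert all(a > b for a, b in zip(snr_a, snr_b))
        out = compare_methods(
            {"A": pd.DataFrame({"snr": snr_a}), "B": pd.DataFrame({"snr": snr_b})}
        )
        row = out.iloc[0]
        assert row["direction"] == 1
        assert row["wilcoxon_p"] < 0.01

    def test_mismatched_subjects_rejected(self):
        a = pd.DataFrame({"D": [1.0, 2.0]}, index=["s1", "s2"])
        b = pd.DataFrame({"D": [1.0, 2.0]}, index=["s1", "s3"])
        with pytest.raises(ValidationError):
            compare_methods({"a": a, "b": b})

    def test_tri_beats_bi_adjusted_r2_on_tri_generated_rois(self):
        # directional analogue of the in-vivo model comparison: ROI-averaged
        # tri-exponential data should favour the tri model in nearly all
        # replicates at moderate noise
        wins = 0
        n_rep = 15
        for rep in range(n_rep):
            cfg = SimConfig(n_curves=300, snr_spec=30, seed=900 + rep)
            batch = simulate_batch(cfg)
            tri = fit_roi(batch.signals, None, cfg.bvalues, "tri")
            bi = fit_roi(batch.signals, None, cfg.bvalues, "bi")
            wins += tri.adjusted_r2 > bi.adjusted_r2
        assert wins >= 0.9 * n_rep


class TestCorrelateWithGrades:
    def test_perfect_anti_monotone_gives_minus_one(self):
        grades = np.array([0, 1, 2, 3, 4, 4, 3])
        params = {"f2": 10 - grades * 1.5}
        out = correlate_with_grades(params, grades)
        assert out.loc["f2", "rho"] == pytest.approx(-1.0)

    def test_independent_vectors_have_small_coefficient(self, rng):
        params = {"D": rng.normal(size=100)}
        grades = rng.integers(0, 5, 100)
        out = correlate_with_grades(params, grades)
        assert abs(out.loc["D", "rho"]) < 0.3

    def test_tie_correction_matches_rank_pearson(self):
        # six-subject example with tied grades: the tie-corrected Spearman
        # coefficient equals the Pearson correlation of midranks
        values = np.array([3.0, 2.5, 2.5, 1.8, 1.2, 1.0])
        grades = np.array([0, 1, 1, 2, 3, 3])
        out = correlate_with_grades({"p": values}, grades)
        expected = np.corrcoef(stats.rankdata(values), stats.rankdata(grades))[0, 1]
        assert out.loc["p", "rho"] == pytest.approx(expected, rel=1e-12)

    def test_constant_grades_rejected(self):
        with pytest.raises(ValidationError):
            correlate_with_grades({"D": np.arange(6.0)}, np.ones(6))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            correlate_with_grades({"D": np.arange(4.0)}, np.arange(4))
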