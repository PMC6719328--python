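from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from verdict_mri.analysis import (
    HistologyFOV,
    ROIMask,
    SubjectRecord,
    adc_map,
    cohort_report,
    dice,
    histology_cell_radius,
    ks_normality,
    roi_summary,
    shrinkage_factor,
    wilcoxon_rank_sum,
)


class TestADC:
    def test_closed_form(self):
        s0 = np.full((4, 4, 2), 2.0)
        sb = s0 * np.exp(-1.0)
        out = adc_map(s0, sb, b=1000.0)
        assert np.allclose(out, 1.0e-3)

    def test_no_attenuation_gives_zero(self):
        s0 = np.full((2, 2, 2), 3.0)
        assert np.allclose(adc_map(s0, s0), 0.0)

    def test_nonpositive_signal_masked(self):
        s0 = np.array([[[1.0, 0.0]]])
        sb = np.array([[[0.5, 0.5]]])
        out = adc_map(s0, sb)
        assert np.isfinite(out[0, 0, 0]) and np.isnan(out[0, 0, 1])

    def test_geometry_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            adc_map(np.ones((2, 2, 2)), np.ones((2, 2, 3)))


class TestRoiSummary:
    def test_constant_map(self):
        m = np.full((5, 5, 2), 3.7)
        s = roi_summary(m, np.ones_like(m, dtype=bool))
        assert s["median"] == pytest.approx(3.7)
        assert s["mean"] == pytest.approx(3.7)
        assert s["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_single_voxel(self):
        m = np.arange(8.0).reshape(2, 2, 2)
        mask = np.zeros_like(m, dtype=bool)
        mask[1, 0, 1] = True
        assert roi_summary(m, mask)["median"] == m[1, 0, 1]

    def test_median_robust_to_outlier(self):
        m = np.array([[[1.0, 2.0, 3.0, 4.0, 100.0]]])
        s = roi_summary(m, np.ones_like(m, dtype=bool))
        assert s["median"] == 3.0 and s["mean"] == 22.0

    def test_permutation_invariant_and_nan_excluded(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=50)
        vals[7] = np.nan
        a = vals.reshape(5, 5, 2)
        b = rng.permutation(vals).reshape(5, 5, 2)
        mask = np.ones((5, 5, 2), dtype=bool)
        sa, sb = roi_summary(a, mask), roi_summary(b, mask)
        assert sa["median"] == pytest.approx(sb["median"])
        assert sa["n_excluded"] == 1

    def test_empty_roi_is_error(self):
        with pytest.raises(ValueError):
            roi_summary(np.ones((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


def brute_force_ranksum_p(a, b):
    """Independent enumeration oracle: all C(n, n_a) rank partitions."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    mu = n_a * (len(pooled) + 1) / 2
    obs = abs(ranks[:n_a].sum() - mu)
    hits = total = 0
    for comb in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_fully_separated_triplets(self):
        # 2/20 partitions are at least as extreme -> p = 0.1 exactly
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_constant_groups(self):
        assert wilcoxon_rank_sum([5, 5, 5], [5, 5, 5]) == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 5)
        assert wilcoxon_rank_sum(a, b) == pytest.approx(wilcoxon_rank_sum(b, a))

    @pytest.mark.parametrize("n_a,n_b,seed", [(2, 2, 0), (3, 4, 1), (5, 5, 2), (4, 6, 3), (3, 3, 4)])
    def test_exact_p_matches_enumeration_oracle(self, n_a, n_b, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 6, n_a).astype(float)  # integer draws force ties
        b = rng.integers(0, 6, n_b).astype(float)
        assert wilcoxon_rank_sum(a, b) == pytest.approx(brute_force_ranksum_p(a, b))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 7), rng.normal(0.7, 1, 7)
        expected = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert wilcoxon_rank_sum(a, b) == pytest.approx(expected)

    def test_large_sample_normal_approximation_is_close(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        approx = wilcoxon_rank_sum(a, b)
        exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert approx == pytest.approx(exact, rel=0.15)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [2.0, 3.0])


class TestKSNormality:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(0)
        stat, p = ks_normality(rng.normal(10, 2, 500))
        assert 0 <= stat <= 1 and p > 0.05

    def test_two_point_mass_rejected(self):
        vals = np.array([0.0] * 25 + [1.0] * 25)
        stat, p = ks_normality(vals)
        assert p < 0.01

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])


class TestDice:
    def test_identity_is_one(self):
        m = np.zeros((6, 6, 3), dtype=bool)
        m[2:5, 2:5, 1] = True
        assert dice(m, m) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((4, 4, 2), dtype=bool)
        b = np.zeros_like(a)
        a[0, 0, 0] = True
        b[3, 3, 1] = True
        assert dice(a, b) == 0.0

    def test_known_overlap(self):
        a = np.zeros(300, dtype=bool)
        b = np.zeros(300, dtype=bool)
        a[:100] = True
        b[20:120] = True  # |A|=|B|=100, overlap 80
        assert dice(a.reshape(10, 10, 3), b.reshape(10, 10, 3)) == pytest.approx(0.8)

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        a = rng.random((8, 8, 4)) > 0.5
        b = rng.random((8, 8, 4)) > 0.5
        assert dice(a, b) == dice(b, a)

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2), dtype=bool), np.zeros((2, 2, 2), dtype=bool))

    def test_geometry_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2), dtype=bool), np.zeros((2, 2, 3), dtype=bool))


class TestHistology:
    def test_stated_axis_convention(self):
        fov = HistologyFOV(cell_count=40, axes_um=[(8.0, 12.0)] * 20)
        assert histology_cell_radius(fov) == pytest.approx(5.0)

    def test_spherical_cells_recover_radius(self):
        R = 4.3
        fov = HistologyFOV(cell_count=10, axes_um=[(2 * R, 2 * R)] * 20)
        assert histology_cell_radius(fov) == pytest.approx(R)

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            HistologyFOV(cell_count=5, axes_um=[(12.0, 8.0)])
        with pytest.raises(ValueError):
            HistologyFOV(cell_count=5, axes_um=[(-1.0, 8.0)])


class TestShrinkage:
    def test_published_red_blood_cell_ratio(self):
        # fixed 5.5 um vs fresh 7.6 um mean diameters
        rng = np.random.default_rng(0)
        fixed = rng.normal(5.5, 0.7, 200)
        fresh = rng.normal(7.6, 0.6, 200)
        ratio, p = shrinkage_factor(fixed, fresh)
        assert ratio == pytest.approx(5.5 / 7.6, abs=0.02)
        assert p < 0.001

    def test_identical_samples(self):
        vals = [5.0, 6.0, 7.0, 8.0]
        ratio, p = shrinkage_factor(vals, vals)
        assert ratio == 1.0 and p == pytest.approx(1.0, abs=0.15)

    def test_correction_round_trip(self):
        fresh = np.array([6.0, 7.0, 8.0])
        fixed = fresh * 0.72
        ratio, _ = shrinkage_factor(fixed, fresh)
        assert np.mean(fixed / ratio) == pytest.approx(np.mean(fresh))


def _records(grades):
    return [SubjectRecord(subject_id=f"S{i}", grade=g) for i, g in enumerate(grades)]


class TestCohortReport:
    def test_two_group_report_populated(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(5):
            rows.append(dict(subject_id=f"S{i}", grade="LGG", f_ic=rng.normal(0.08, 0.01)))
        for i in range(5, 10):
            rows.append(dict(subject_id=f"S{i}", grade="HGG", f_ic=rng.normal(0.13, 0.02)))
        out = cohort_report(pd.DataFrame(rows), _records(["LGG"] * 5 + ["HGG"] * 5))
        summ = out["group_summary"]
        row = summ[summ.metric == "f_ic"].iloc[0]
        assert 0.05 < row["LGG_median"] < 0.11 and 0.10 < row["HGG_median"] < 0.18
        assert 0 <= row["p_wilcoxon"] <= 1

    def test_single_group_keeps_summaries_drops_contrast(self):
        rows = [dict(subject_id=f"S{i}", grade="LGG", f_ic=0.08 + 0.001 * i) for i in range(4)]
        out = cohort_report(pd.DataFrame(rows), _records(["LGG"] * 4))
        summ = out["group_summary"]
        assert "LGG_median" in summ.columns
        assert "p_wilcoxon" not in summ.columns or summ["p_wilcoxon"].isna().all()

    def test_identical_groups_give_p_one(self):
        rows = []
        for i, g in enumerate(["LGG"] * 4 + ["HGG"] * 4):
            rows.append(dict(subject_id=f"S{i}", grade=g, f_ic=[0.1, 0.2, 0.3, 0.4][i % 4]))
        out = cohort_report(pd.DataFrame(rows), _records(["LGG"] * 4 + ["HGG"] * 4))
        assert out["group_summary"]["p_wilcoxon"].iloc[0] == pytest.approx(1.0)
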