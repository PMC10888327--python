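"""Scoring and statistics: worked examples and cross-checks against
independent implementations (scipy, sklearn, pingouin, hand ANOVA)."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from chromathresh.colorimetry import AxisName
from chromathresh.scoring_stats import (
    AxisThresholds,
    BlandAltmanResult,
    UndefinedKappaError,
    bland_altman,
    classify,
    cohens_kappa,
    gcs,
    icc_absolute_agreement,
    labels_to_table,
    paired_t,
    sensitivity_sample_size,
    severity,
    spearman_rho,
)


class TestGcs:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((4.44, 5.38, 8.45), 6.09),
            ((41.78, 17.69, 8.20), 22.56),
            ((14.38, 70.99, 12.00), 32.46),
            ((36.88, 38.17, 8.45), 27.83),
        ],
    )
    def test_group_mean_worked_examples(self, triple, expected):
        assert round(gcs(triple), 2) == expected

    def test_degenerate_zero(self):
        assert gcs((0.0, 0.0, 0.0)) == 0.0

    def test_equals_mean_of_any_permutation(self):
        vals = (3.0, 11.0, 19.0)
        assert gcs(vals) == gcs(vals[::-1]) == pytest.approx(11.0)


class TestClassify:
    def test_group_mean_profiles(self):
        assert classify((4.44, 5.38, 8.45)) == "trichromat"
        assert classify((41.78, 17.69, 8.20)) == "protan"
        assert classify((14.38, 70.99, 12.00)) == "deutan"

    def test_tritan_profile(self):
        assert classify((5.0, 6.0, 40.0)) == "tritan"

    def test_scale_consistency(self):
        cut = {AxisName.PROTAN: 11.0, AxisName.DEUTAN: 9.5, AxisName.TRITAN: 13.5}
        scaled = {k: 3.7 * v for k, v in cut.items()}
        t = (30.0, 25.0, 9.0)
        assert classify(t, cut) == classify(tuple(3.7 * v for v in t), scaled)

    def test_largest_relative_elevation_wins(self):
        # both red-green axes above cutoff; ratio decides
        assert classify((22.1, 28.6, 5.0)) == "deutan"  # 2.01 vs 3.01


class TestSeverity:
    @pytest.mark.parametrize("de,grade", [(22, "low"), (40, "mild"), (60, "high")])
    def test_anchors(self, de, grade):
        assert severity(de) == grade

    @pytest.mark.parametrize("de,grade", [(30.9, "low"), (31.1, "mild"), (49.9, "mild"), (50.1, "high")])
    def test_band_edges_at_anchor_midpoints(self, de, grade):
        assert severity(de) == grade


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa([[65, 0], [0, 35]]) == pytest.approx(1.0)

    def test_partial_agreement_worked_example(self):
        # p_o = 0.92, p_e = 0.569 -> 0.8144
        assert cohens_kappa([[65, 0], [8, 27]]) == pytest.approx(0.814, abs=5e-4)

    def test_degenerate_table_raises(self):
        with pytest.raises(UndefinedKappaError):
            cohens_kappa([[50, 0], [0, 0]])

    def test_matches_sklearn_on_random_labelings(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        for _ in range(10):
            a = rng.integers(0, 3, size=200)
            b = rng.integers(0, 3, size=200)
            ours = cohens_kappa(labels_to_table(a, b, [0, 1, 2]))
            assert ours == pytest.approx(sk.cohen_kappa_score(a, b), abs=1e-12)

    def test_relabeling_invariance(self):
        m = np.array([[30, 5, 1], [4, 40, 2], [0, 3, 15]])
        perm = [2, 0, 1]
        assert cohens_kappa(m) == pytest.approx(cohens_kappa(m[np.ix_(perm, perm)]))

    def test_bounds(self, rng):
        for _ in range(20):
            m = rng.integers(0, 30, size=(3, 3))
            if m.sum() == 0 or np.trace(m) == m.sum():
                continue
            assert -1.0 - 1e-12 <= cohens_kappa(m) <= 1.0 + 1e-12

    def test_kappa_one_iff_no_off_diagonal_mass(self):
        from hypothesis import given, settings, strategies as st

        @settings(derandomize=True, max_examples=80, deadline=None)
        @given(m=st.lists(st.lists(st.integers(0, 40), min_size=3, max_size=3),
                          min_size=3, max_size=3))
        def inner(m):
            m = np.array(m)
            total = m.sum()
            if total == 0:
                return
            try:
                k = cohens_kappa(m)
            except Exception:
                return
            assert -1 - 1e-12 <= k <= 1 + 1e-12
            assert (k == pytest.approx(1.0)) == (np.trace(m) == total)

        inner()


class TestBlandAltman:
    def test_identical_measurements(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mean_difference == 0 and r.sd_difference == 0
        assert r.loa_lower == r.loa_upper == 0

    def test_constant_shift(self):
        r = bland_altman([0.0, 2.0, 4.0], [1.0, 3.0, 5.0])
        assert r.mean_difference == pytest.approx(-1.0)
        assert r.sd_difference == pytest.approx(0.0)

    def test_loa_width(self, rng):
        x = rng.normal(size=100)
        y = x + rng.normal(scale=0.5, size=100)
        r = bland_altman(x, y)
        assert r.loa_upper - r.loa_lower == pytest.approx(2 * 1.96 * r.sd_difference)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestIcc:
    def test_duplicate_sessions_give_one(self, rng):
        x = rng.uniform(2, 70, size=30)
        assert icc_absolute_agreement(x, x.copy()) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        assert abs(icc_absolute_agreement(x, y)) < 0.15

    def test_hand_computed_anova_identity(self):
        # 5-subject table, worked through the two-way mean squares by hand
        s1 = np.array([10.0, 12.0, 18.0, 25.0, 40.0])
        s2 = np.array([11.0, 14.0, 16.0, 27.0, 38.0])
        data = np.column_stack([s1, s2])
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + grand) ** 2).sum()
            / ((n - 1) * (k - 1))
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_absolute_agreement(s1, s2) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(1)
        x = rng.uniform(2, 70, size=40)
        y = x + rng.normal(scale=3.0, size=40)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "rater": np.tile(["s1", "s2"], 40),
                "score": np.column_stack([x, y]).ravel(),
            }
        )
        res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc_a1 = float(res.loc[res.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_absolute_agreement(x, y) == pytest.approx(icc_a1, abs=1e-9)

    def test_decreases_with_noise(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(2, 70, size=60)
        iccs = [
            icc_absolute_agreement(x, x + rng.normal(scale=s, size=60))
            for s in (0.5, 3.0, 12.0)
        ]
        assert iccs[0] > iccs[1] > iccs[2]


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([3.0, 1.0, 7.0, 4.0, 9.0])
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_tied_example_matches_scipy(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 5.0]
        assert spearman_rho(x, y) == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ZeroDivisionError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairedT:
    def test_zero_mean_differences(self):
        t, p = paired_t([1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_identical_pairs_raise(self):
        with pytest.raises(ZeroDivisionError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_matches_scipy(self, rng):
        x = rng.normal(size=25)
        y = x + rng.normal(loc=0.3, scale=0.8, size=25)
        t, p = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestSampleSize:
    def test_study_configuration_gives_99(self):
        assert sensitivity_sample_size(0.90, 0.05, 0.35, 0.10) == 99

    def test_full_prevalence(self):
        assert sensitivity_sample_size(0.90, 0.05, 1.00, 0.10) == 35  # 34.57 -> ceil

    def test_inverse_proportionality_to_prevalence(self):
        z = sps.norm.ppf(0.975)
        exact = z**2 * 0.9 * 0.1 / (0.1**2 * 0.35)
        assert sensitivity_sample_size(0.90, 0.05, 0.35, 0.10) == math.ceil(exact)
        assert math.ceil(2 * exact) == sensitivity_sample_size(0.90, 0.05, 0.175, 0.10)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sensitivity_sample_size(1.5)


class TestAxisThresholds:
    def test_requires_positive(self):
        with pytest.raises(ValueError):
            AxisThresholds(0.0, 5.0, 5.0)
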