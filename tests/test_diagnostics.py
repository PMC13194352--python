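"""ROC/AUC machinery against brute-force oracles and closed forms."""

import numpy as np
import pytest
from scipy.stats import norm

from asdscreen import diagnostics as dx


def brute_force_auc(scores, labels):
    """Pairwise P(case > control) + 0.5 P(tie)."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = sum((c > controls).sum() + 0.5 * (c == controls).sum() for c in cases)
    return wins / (cases.size * controls.size)


def brute_force_youden(scores, labels):
    best = -np.inf
    n1 = (labels == 1).sum()
    n0 = (labels == 0).sum()
    for thr in np.concatenate([scores - 1e-6, scores + 1e-6]):
        pos = scores >= thr
        j = (pos & (labels == 1)).sum() / n1 + (~pos & (labels == 0)).sum() / n0 - 1
        best = max(best, j)
    return best


def _random_instance(rng):
    n = int(rng.integers(6, 60))
    scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
    labels = rng.integers(0, 2, n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return scores, labels


class TestRocAuc:
    def test_matches_pairwise_oracle_on_100_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            s, l = _random_instance(rng)
            assert dx.roc_auc(s, l) == pytest.approx(
                brute_force_auc(s, l), abs=1e-12
            )

    def test_known_small_examples(self):
        assert dx.roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert dx.roc_auc([1, 3, 2, 4], [0, 0, 1, 1]) == 0.75

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(4000)
        l = rng.integers(0, 2, 4000)
        assert dx.roc_auc(s, l) == pytest.approx(0.5, abs=0.03)

    def test_trapezoidal_area_equals_mann_whitney(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s, l = _random_instance(rng)
            pts = dx.roc_points(s, l)
            # descending thresholds: fpr and tpr both non-decreasing
            fpr = (1.0 - pts["specificity"].to_numpy())[::-1]
            tpr = pts["sensitivity"].to_numpy()[::-1]
            area = np.trapezoid(tpr, fpr)
            assert area == pytest.approx(dx.roc_auc(s, l), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            dx.roc_auc([1.0, 2.0], [1, 1])

    def test_binormal_closed_form_at_large_n(self):
        rng = np.random.default_rng(3)
        n = 100_000
        s = np.concatenate([rng.normal(28.20, 8.91, n), rng.normal(39.65, 8.37, n)])
        l = np.repeat([0, 1], n)
        expected = norm.cdf((39.65 - 28.20) / np.hypot(8.91, 8.37))
        assert dx.roc_auc(s, l) == pytest.approx(expected, abs=0.005)


class TestAucSeCi:
    def test_hanley_mcneil_se_bracket(self):
        se, _, _ = dx.auc_se_ci(0.831, 50, 50)
        assert 0.036 <= se <= 0.044

    def test_ci_from_reported_se(self):
        lo, hi = dx.ci_from_auc_se(0.776, 0.046)
        assert lo == pytest.approx(0.686, abs=5e-4)
        assert hi == pytest.approx(0.866, abs=5e-4)

    def test_se_vanishes_with_n(self):
        se_small, _, _ = dx.auc_se_ci(0.5, 50, 50)
        se_big, _, _ = dx.auc_se_ci(0.5, 50000, 50000)
        assert se_big < se_small / 10

    def test_delong_se_comparable_to_hanley_mcneil(self):
        rng = np.random.default_rng(4)
        s = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)])
        l = np.repeat([0, 1], 50)
        auc = dx.roc_auc(s, l)
        hm, _, _ = dx.auc_se_ci(auc, 50, 50)
        dl = dx.delong_se(s, l)
        assert dl == pytest.approx(hm, rel=0.35)

    def test_invalid_auc_raises(self):
        with pytest.raises(ValueError):
            dx.auc_se_ci(1.2, 10, 10)


class TestYoudenCutoff:
    def test_matches_exhaustive_search_on_100_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            s, l = _random_instance(rng)
            _, _, _, j = dx.youden_cutoff(s, l)
            assert j == pytest.approx(brute_force_youden(s, l), abs=1e-12)

    def test_perfect_separation_j_one(self):
        c, sens, spec, j = dx.youden_cutoff(
            np.array([1.0, 2.0, 10.0, 11.0]), np.array([0, 0, 1, 1])
        )
        assert j == 1.0 and sens == 1.0 and spec == 1.0
        assert 2.0 < c < 10.0  # midpoint convention

    def test_cutoff_is_midpoint_between_adjacent_scores(self):
        c, *_ = dx.youden_cutoff(
            np.array([30.0, 33.5, 40.0, 45.0]), np.array([0, 0, 1, 1])
        )
        assert c == pytest.approx((33.5 + 40.0) / 2)

    def test_ties_break_toward_sensitivity(self):
        # two thresholds reach the same J; the lower cut-off (higher
        # sensitivity) must be reported
        s = np.array([1.0, 2.0, 3.0, 4.0])
        l = np.array([0, 1, 0, 1])
        c, sens, spec, j = dx.youden_cutoff(s, l)
        assert sens == 1.0


class TestResampledAuc:
    @pytest.fixture(scope="class")
    def cohort_scores(self):
        rng = np.random.default_rng(6)
        s = np.concatenate([rng.normal(28.20, 8.91, 50), rng.normal(39.65, 8.37, 50)])
        return s, np.repeat([0, 1], 50)

    def test_crossval_perfect_scores(self):
        s = np.concatenate([np.arange(50.0), 100 + np.arange(50.0)])
        l = np.repeat([0, 1], 50)
        mean, _ = dx.crossval_auc(s, l, seed=0)
        assert mean == 1.0

    def test_crossval_stability_across_seeds(self, cohort_scores):
        s, l = cohort_scores
        m1, _ = dx.crossval_auc(s, l, seed=1)
        m2, _ = dx.crossval_auc(s, l, seed=2)
        assert abs(m1 - m2) <= 0.05

    def test_crossval_consistent_with_full_sample(self, cohort_scores):
        s, l = cohort_scores
        mean, _ = dx.crossval_auc(s, l, seed=3)
        assert abs(mean - dx.roc_auc(s, l)) <= 0.05

    def test_bootstrap_perfect_scores(self):
        s = np.concatenate([np.arange(50.0), 100 + np.arange(50.0)])
        l = np.repeat([0, 1], 50)
        bc, (lo, hi) = dx.bootstrap_auc(s, l, seed=0)
        assert bc == 1.0 and lo == 1.0 and hi == 1.0

    def test_bootstrap_deterministic_under_seed(self, cohort_scores):
        s, l = cohort_scores
        assert dx.bootstrap_auc(s, l, seed=9) == dx.bootstrap_auc(s, l, seed=9)

    def test_bootstrap_bias_correction_small(self, cohort_scores):
        s, l = cohort_scores
        bc, _ = dx.bootstrap_auc(s, l, seed=10)
        assert abs(bc - dx.roc_auc(s, l)) <= 0.02


class TestLogisticFit:
    def test_parameter_recovery_at_increasing_n(self):
        rng = np.random.default_rng(7)
        beta_true = np.array([0.171, 0.456])
        bias = []
        for n in (200, 1000, 5000):
            x = np.column_stack([rng.normal(34, 9, n), rng.normal(36, 3, n)])
            eta = -22.25 + x @ beta_true
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            res = dx.logistic_fit(x, y, names=["split", "sysfrac"])
            assert np.all(np.abs(res.beta - beta_true) < 3 * res.se)
            bias.append(np.abs(res.beta - beta_true).mean())
        assert bias[-1] < bias[0]

    def test_wald_is_squared_z(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(300, 2))
        y = (rng.random(300) < 1 / (1 + np.exp(-x[:, 0]))).astype(int)
        res = dx.logistic_fit(x, y)
        np.testing.assert_allclose(res.wald, (res.beta / res.se) ** 2)

    def test_constant_covariate_dropped_and_flagged(self):
        rng = np.random.default_rng(9)
        x = np.column_stack([rng.normal(size=200), np.zeros(200)])
        y = (rng.random(200) < 1 / (1 + np.exp(-x[:, 0]))).astype(int)
        res = dx.logistic_fit(x, y, names=["real", "allzero"])
        assert res.dropped == ["allzero"]
        assert res.names == ["real"]

    def test_perfect_separation_raises_diagnostic(self):
        x = np.concatenate([np.zeros(20), np.ones(20)]).reshape(-1, 1)
        y = np.concatenate([np.zeros(20), np.ones(20)]).astype(int)
        with pytest.raises(dx.PerfectSeparationError):
            dx.logistic_fit(x, y)


class TestOrFromBeta:
    @pytest.mark.parametrize(
        "beta,se,or_exp,lo_exp,hi_exp",
        [
            (0.171, 0.041, 1.19, 1.09, 1.29),
            (0.456, 0.121, 1.58, 1.24, 2.00),
        ],
    )
    def test_reference_coefficients(self, beta, se, or_exp, lo_exp, hi_exp):
        or_, lo, hi = dx.or_from_beta(beta, se)
        assert or_ == pytest.approx(or_exp, abs=5e-3)
        assert lo == pytest.approx(lo_exp, abs=5e-3)
        assert hi == pytest.approx(hi_exp, abs=5e-3)

    def test_zero_beta_unit_odds(self):
        or_, lo, hi = dx.or_from_beta(0.0, 0.5)
        assert or_ == 1.0 and lo < 1.0 < hi

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            dx.or_from_beta(0.1, 0.0)


class TestDiagnosticReport:
    def test_reference_style_report(self, reference_cohort):
        rep = dx.diagnostic_report(
            reference_cohort,
            ["s2_split_ms", "s1s2_rr_pct"],
            n_boot=200,
            seed=0,
        )
        for col in ("s2_split_ms", "s1s2_rr_pct"):
            r = rep["scores"][col]
            assert 0.6 <= r["auc"] <= 0.95
            assert r["ci95"][0] < r["auc"] < r["ci95"][1]
            assert r["youden_j"] == pytest.approx(
                r["sensitivity"] + r["specificity"] - 1.0, abs=1e-12
            )
        names = [row["variable"] for row in rep["logistic"]]
        assert names == ["s2_split_ms", "s1s2_rr_pct", "constant"]
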