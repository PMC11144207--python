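"""ROC/AUC, DeLong intervals, calibration, nomogram, chi-square tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ventidose.evaluation import (
    REFERENCE_FRACTIONATION_TABLE,
    REFERENCE_MACHINE_TABLE,
    ContingencyTable,
    calibrate_bootstrap,
    delong_ci,
    nomogram_points,
    pearson_chi2,
    roc_auc,
)
from ventidose.riskmodel import PUBLISHED_STEPWISE_MODEL, LogisticModel


def brute_force_auc(scores, labels):
    """Exhaustive pairwise concordance over all (event, non-event) pairs."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], ci=False)
        assert r.auc == 1.0

    def test_constant_scores_give_half(self):
        r = roc_auc([3.0] * 8, [1, 1, 1, 0, 0, 0, 0, 1], ci=False)
        assert r.auc == 0.5

    def test_worked_pairwise_example(self):
        # 1 concordant of 4 (event, non-event) pairs
        r = roc_auc([3, 2, 1, 4], [1, 0, 1, 0], ci=False)
        assert r.auc == 0.25

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        scores = np.round(rng.normal(size=n), 1)  # ties likely
        labels = rng.binomial(1, 0.5, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        r = roc_auc(scores, labels, ci=False)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = rng.binomial(1, 0.5, 40)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels, ci=False).auc
        b = roc_auc(np.exp(3 * scores) + 7, labels, ci=False).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            roc_auc([0.1, 0.2], [1, 1])


class TestDelongCi:
    def test_perfect_separation_returns_point_interval(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            lo, hi = delong_ci([4, 3, 2, 1], [1, 1, 0, 0])
        assert (lo, hi) == (1.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_interval_contains_point_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=60)
        labels = rng.binomial(1, 0.4, 60)
        labels[:4] = [0, 0, 1, 1]
        r = roc_auc(scores, labels)
        assert r.ci_low <= r.auc <= r.ci_high


class TestCalibration:
    def test_no_bootstrap_gives_apparent_only(self, cohort120):
        cal = calibrate_bootstrap(cohort120, ["V20", "V30"], n_boot=0)
        assert cal.bias_corrected is None
        assert cal.slope == 1.0 and cal.intercept == 0.0
        assert np.all((cal.apparent >= 0) & (cal.apparent <= 1))

    def test_saturated_model_apparent_curve_hits_group_frequencies(self):
        # grouped data: one binary covariate, saturated logistic model
        rng = np.random.default_rng(5)
        x = np.repeat([0.0, 1.0], 100)
        p = np.where(x == 0, 0.2, 0.7)
        y = rng.binomial(1, p)
        df = pd.DataFrame({"x": x, "rp_grade2plus": y})
        cal = calibrate_bootstrap(df, ["x"], n_boot=0)
        f0, f1 = y[x == 0].mean(), y[x == 1].mean()
        assert cal.apparent[0] == pytest.approx(min(f0, f1), abs=1e-12)
        assert cal.apparent[-1] == pytest.approx(max(f0, f1), abs=1e-12)

    def test_overfit_noise_model_has_positive_optimism(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            rng.normal(50, 10, (41, 12)), columns=[f"V{x}" for x in range(5, 65, 5)]
        )
        df["rp_grade2plus"] = rng.binomial(1, 0.4, 41)
        cal = calibrate_bootstrap(df, list(df.columns[:12]), n_boot=60, seed=9)
        optimism = cal.apparent - cal.bias_corrected
        assert float(np.mean(optimism)) > 0

    def test_negative_boot_count_rejected(self, cohort120):
        with pytest.raises(ValueError, match="n_boot"):
            calibrate_bootstrap(cohort120, ["V20"], n_boot=-1)


class TestNomogram:
    RANGES = {name: (0.0, 100.0) for name in PUBLISHED_STEPWISE_MODEL.coefficients}

    def test_zero_coefficient_gives_flat_scale(self):
        m = LogisticModel(intercept=0.0, coefficients={"V20": 1.0, "V30": 0.0})
        nomo = nomogram_points(m, {"V20": (0, 50), "V30": (0, 50)})
        assert nomo.points("V30", 0.0) == 0.0
        assert nomo.points("V30", 50.0) == 0.0

    def test_single_covariate_spans_exactly_100(self):
        m = LogisticModel(intercept=-1.0, coefficients={"V20": -0.2})
        nomo = nomogram_points(m, {"V20": (10, 60)})
        # negative coefficient: maximum points at the range minimum
        assert nomo.points("V20", 10.0) == pytest.approx(100.0)
        assert nomo.points("V20", 60.0) == pytest.approx(0.0)

    def test_published_model_top_variable_is_v25_on_equal_ranges(self):
        # |−0.38317|·100 is the largest |beta|·range product
        nomo = nomogram_points(PUBLISHED_STEPWISE_MODEL, self.RANGES)
        assert nomo.max_points_variable == "V25"
        assert nomo.points("V25", 0.0) == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_total_points_recover_model_probability(self, seed):
        rng = np.random.default_rng(seed)
        nomo = nomogram_points(PUBLISHED_STEPWISE_MODEL, self.RANGES)
        values = {name: float(rng.uniform(0, 100)) for name in self.RANGES}
        total = nomo.total_points(values)
        lp = PUBLISHED_STEPWISE_MODEL.intercept + sum(
            b * values[n] for n, b in PUBLISHED_STEPWISE_MODEL.coefficients.items()
        )
        assert nomo.probability_from_total(total) == pytest.approx(
            1 / (1 + np.exp(-lp)), abs=1e-10
        )

    def test_zero_range_rejected(self):
        m = LogisticModel(intercept=0.0, coefficients={"V20": 1.0})
        with pytest.raises(ValueError, match="range"):
            nomogram_points(m, {"V20": (30.0, 30.0)})


class TestPearsonChi2:
    def test_reference_machine_table(self):
        _, dof, p = pearson_chi2(REFERENCE_MACHINE_TABLE)
        assert dof == 1
        assert round(p, 3) == 0.707

    def test_reference_fractionation_table(self):
        _, dof, p = pearson_chi2(REFERENCE_FRACTIONATION_TABLE)
        assert dof == 2
        assert round(p, 3) == 0.929

    @pytest.mark.parametrize("seed", range(5))
    def test_2x2_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 30, 4)
        stat, dof, _ = pearson_chi2(np.array([[a, b], [c, d]]))
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(closed, abs=1e-12)
        assert dof == 1

    def test_identical_row_distributions_give_zero_statistic(self):
        stat, _, p = pearson_chi2(np.array([[10, 20], [5, 10]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            pearson_chi2(np.array([[0, 0], [3, 4]]))
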