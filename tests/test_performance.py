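"""Tests for diagnostic metrics, CIs, cutoffs, kappa and planning."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import brentq
from sklearn.metrics import cohen_kappa_score

from methylpanel.performance import (
    cohens_kappa,
    confusion_summary,
    pool_strata,
    proportion_ci,
    roc_logistic,
    sample_size_ci_width,
    stratified_rates,
    summary_from_counts,
    youden_cutoff,
)


def calls_frame(counts):
    """Call table from {group: (n_positive, n_total)}."""
    rows = []
    for group, (npos, n) in counts.items():
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{group}{i}",
                    "group": group,
                    "status": "POSITIVE" if i < npos else "NEGATIVE",
                }
            )
    return pd.DataFrame(rows)


class TestConfusionSummary:
    def test_screening_cohort_counts(self):
        calls = calls_frame({"CRC": (62, 75), "PL": (22, 40), "NED": (17, 171)})
        s = confusion_summary(calls)
        assert s.sensitivity.percent == pytest.approx(82.7, abs=0.05)
        assert s.specificity.percent == pytest.approx(90.1, abs=0.05)
        assert s.pl_detection.percent == pytest.approx(55.0, abs=0.05)
        # accuracy excludes the PL group: (62 + 154) / 246
        assert s.accuracy.successes == 216 and s.accuracy.n == 246
        assert s.accuracy.percent == pytest.approx(87.8, abs=0.05)

    def test_accuracy_from_unbalanced_counts(self):
        s = summary_from_counts(crc_positive=115, n_crc=137, ned_negative=107, n_ned=198)
        assert s.accuracy.successes == 222 and s.accuracy.n == 335
        assert s.accuracy.percent == pytest.approx(66.3, abs=0.05)

    def test_degenerate_all_positive(self):
        calls = calls_frame({"CRC": (5, 5), "PL": (3, 3), "NED": (4, 4)})
        s = confusion_summary(calls)
        assert s.sensitivity.estimate == 1.0
        assert s.specificity.estimate == 0.0

    def test_invalid_samples_excluded_and_counted(self):
        calls = calls_frame({"CRC": (2, 4), "NED": (0, 4), "PL": (0, 1)})
        calls.loc[0, "status"] = "INVALID"
        s = confusion_summary(calls)
        assert s.n_invalid == 1
        assert s.sensitivity.n == 3

    def test_labels_mapping_accepted(self):
        calls = pd.DataFrame(
            {"sample_id": ["a", "b"], "status": ["POSITIVE", "NEGATIVE"]}
        )
        s = confusion_summary(calls, labels={"a": "CRC", "b": "NED"})
        assert s.sensitivity.estimate == 1.0 and s.specificity.estimate == 1.0

    def test_empty_group_flagged_nan(self):
        calls = calls_frame({"CRC": (1, 2)})
        s = confusion_summary(calls)
        assert math.isnan(s.pl_detection.estimate)


def wilson_cc_by_inversion(x, n, confidence=0.95):
    """Independent check of the continuity-corrected Wilson interval:
    numerically invert the score test with continuity correction."""
    z = stats.norm.ppf(0.5 + confidence / 2)
    phat = x / n

    def score_low(p):
        return (phat - p - 0.5 / n) / math.sqrt(p * (1 - p) / n) - z

    def score_high(p):
        return (p - phat - 0.5 / n) / math.sqrt(p * (1 - p) / n) - z

    low = 0.0 if x == 0 else brentq(score_low, 1e-12, 1 - 1e-12)
    high = 1.0 if x == n else brentq(score_high, 1e-12, 1 - 1e-12)
    return low, high


class TestProportionCI:
    def test_zero_successes_lower_bound(self):
        low, high = proportion_ci(0, 10)
        assert low == 0.0 and 0 < high < 1

    def test_all_successes_upper_bound(self):
        low, high = proportion_ci(10, 10)
        assert high == 1.0 and 0 < low < 1

    @pytest.mark.parametrize("x,n", [(62, 75), (154, 171), (22, 40), (5, 53), (1, 30)])
    def test_wilson_cc_matches_independent_inversion(self, x, n):
        low, high = proportion_ci(x, n, method="wilson_cc")
        ref_low, ref_high = wilson_cc_by_inversion(x, n)
        assert low == pytest.approx(ref_low, abs=1e-6)
        assert high == pytest.approx(ref_high, abs=1e-6)
        assert low <= x / n <= high

    def test_bracket_contains_estimate_all_methods(self):
        for method in ("wilson", "wilson_cc", "clopper_pearson", "wald"):
            low, high = proportion_ci(62, 75, method=method)
            assert low <= 62 / 75 <= high

    def test_invalid_successes_raise(self):
        with pytest.raises(ValueError):
            proportion_ci(11, 10)

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("n", [40, 75, 171])
    def test_wilson_cc_coverage(self, p, n):
        rng = np.random.default_rng(100 + n)
        draws = rng.binomial(n, p, size=2000)
        covered = 0
        for x in draws:
            low, high = proportion_ci(int(x), n, method="wilson_cc")
            covered += low <= p <= high
        assert covered / 2000 >= 0.93


class TestStratifiedRates:
    def _setup(self):
        calls = calls_frame({"CRC": (62, 75), "PL": (22, 40), "NED": (17, 171)})
        rng = np.random.default_rng(0)
        strata = pd.DataFrame(
            {
                "sample_id": calls["sample_id"],
                "gender": rng.choice(["Male", "Female"], size=len(calls)),
                "age_band": rng.choice(["<55", ">=55"], size=len(calls)),
            }
        )
        return calls, strata

    def test_pooling_reproduces_group_totals(self):
        calls, strata = self._setup()
        rates = stratified_rates(calls, strata, ["gender", "age_band"])
        for col in ("gender", "age_band"):
            for group, expected in (("CRC", (62, 75)), ("PL", (22, 40)), ("NED", (17, 171))):
                assert pool_strata(rates, col, group) == expected

    def test_known_partition_rates(self):
        # gender split of a CRC group: 44/54 male + 18/21 female pools to 62/75
        calls = calls_frame({"CRC": (62, 75)})
        gender = ["Male"] * 44 + ["Female"] * 18 + ["Male"] * 10 + ["Female"] * 3
        strata = pd.DataFrame({"sample_id": calls["sample_id"], "gender": gender})
        rates = stratified_rates(calls, strata, ["gender"]).set_index("stratum")
        assert rates.loc["Male", ["positives", "tested"]].tolist() == [44, 54]
        assert rates.loc["Female", ["positives", "tested"]].tolist() == [18, 21]
        assert rates.loc["Male", "rate_percent"] == pytest.approx(81.5, abs=0.05)
        assert rates.loc["Female", "rate_percent"] == pytest.approx(85.7, abs=0.05)
        assert pool_strata(rates.reset_index(), "gender", "CRC") == (62, 75)

    def test_empty_stratum_absent(self):
        calls, strata = self._setup()
        strata["gender"] = "Male"
        rates = stratified_rates(calls, strata, ["gender"])
        assert set(rates["stratum"]) == {"Male"}


def youden_bruteforce(scores, labels, positive_below=True):
    """Exhaustive scan over a fine threshold grid."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    finite = scores[np.isfinite(scores)]
    candidates = np.unique(
        np.concatenate(
            [finite - 1e-9, finite + 1e-9, [finite.min() - 1, finite.max() + 1]]
        )
    )
    best_j = -1
    for c in candidates:
        called = scores < c if positive_below else scores > c
        sens = (called & (labels == 1)).mean() / max((labels == 1).mean(), 1e-12)
        spec = (~called & (labels == 0)).mean() / max((labels == 0).mean(), 1e-12)
        best_j = max(best_j, sens + spec)
    return best_j


class TestYoudenCutoff:
    def test_perfect_separation_returns_gap_midpoint(self):
        scores = [30.0, 31.0, 32.0, 40.0, 41.0, 42.0]
        labels = [1, 1, 1, 0, 0, 0]
        cutoff, sens, spec = youden_cutoff(scores, labels, positive_below=True)
        assert cutoff == pytest.approx(36.0)
        assert sens == 1.0 and spec == 1.0

    def test_single_observation_per_class(self):
        cutoff, sens, spec = youden_cutoff([35.0, 39.0], [1, 0])
        assert 35.0 < cutoff < 39.0
        assert sens == 1.0 and spec == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 100
        labels = rng.integers(0, 2, size=n)
        scores = np.where(
            labels == 1, rng.normal(35, 3, n), rng.normal(39, 3, n)
        ).round(1)
        cutoff, sens, spec = youden_cutoff(scores, labels)
        assert sens + spec == pytest.approx(
            youden_bruteforce(scores, labels), abs=1e-9
        )

    def test_tie_breaks_toward_more_specific(self):
        # both cutoffs 2.5 and 4.5 give J = 1.5; the more specific (lower,
        # for positive-below semantics) must win
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [1, 1, 0, 1]
        cutoff, sens, spec = youden_cutoff(scores, labels, positive_below=True)
        assert cutoff < 3.0

    def test_validation(self):
        with pytest.raises(ValueError):
            youden_cutoff([1.0, 2.0], [1, 1])


class TestCohensKappa:
    def test_identical_vectors(self):
        res = cohens_kappa([1, 0, 1, 0], [1, 0, 1, 0])
        assert res.kappa == pytest.approx(1.0)
        assert res.observed_agreement == 1.0

    def test_hand_computed_2x2(self):
        # a=40, b=10, c=10, d=40: po=0.8, pe=0.5, kappa = 0.6
        w1 = [1] * 50 + [0] * 50
        w2 = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        res = cohens_kappa(w1, w2)
        assert res.kappa == pytest.approx(0.6)
        assert res.observed_agreement == pytest.approx(0.8)
        assert res.ci_low < 0.6 < res.ci_high
        assert res.p_value < 0.001

    def test_matches_sklearn(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, 200)
        b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 2, 200))
        res = cohens_kappa(a, b)
        assert res.kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(3)
        res = cohens_kappa(rng.integers(0, 2, 5000), rng.integers(0, 2, 5000))
        assert abs(res.kappa) < 0.05

    def test_swapping_wells_is_symmetric(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 100)
        b = rng.integers(0, 2, 100)
        assert cohens_kappa(a, b).kappa == pytest.approx(cohens_kappa(b, a).kappa)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            cohens_kappa([1], [1, 0])


class TestSampleSize:
    def test_wald_closed_form(self):
        # n = ceil(4 z^2 p(1-p) / w^2) up to the discrete scan
        z = stats.norm.ppf(0.975)
        for p, w in [(0.5, 0.2), (0.83, 0.08), (0.9, 0.16)]:
            n = sample_size_ci_width(p, w, method="wald")
            closed = 4 * z * z * p * (1 - p) / (w * w)
            assert n == math.ceil(closed) or n == math.ceil(closed) + 1
            lo, hi = proportion_ci(p * n, n, method="wald")
            assert hi - lo <= w
            lo, hi = proportion_ci(p * (n - 1), n - 1, method="wald")
            assert hi - lo > w

    def test_huge_width_needs_one(self):
        assert sample_size_ci_width(0.5, 2.0) == 1

    def test_monotone_in_width(self):
        n_tight = sample_size_ci_width(0.83, 0.04)
        n_loose = sample_size_ci_width(0.83, 0.08)
        assert n_tight > n_loose

    def test_invalid_width_raises(self):
        with pytest.raises(ValueError):
            sample_size_ci_width(0.5, 0.0)


class TestRocLogistic:
    def _features(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        # disease lowers CT (more template); NED mostly undetermined
        ct = np.where(y == 1, rng.normal(33, 1, n), rng.normal(44, 1, n))
        return pd.DataFrame({"mSEPT9": ct, "noise": rng.normal(38, 2, n)}), y

    def test_separating_feature_auc_one(self):
        X, y = self._features()
        report = roc_logistic(X, y, n_repeats=5, seed=1)
        auc = report.per_gene_auc.set_index("gene")
        assert auc.loc["mSEPT9", "mean_auc"] == pytest.approx(1.0, abs=0.01)
        assert abs(auc.loc["noise", "mean_auc"] - 0.5) < 0.2

    def test_combined_rule_modes(self):
        # an any-marker-positive rule is only as good as its markers:
        # two informative CT channels keep the combined AUC high in both
        # cutoff modes
        rng = np.random.default_rng(4)
        n = 120
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame(
            {
                "mSEPT9": np.where(y == 1, rng.normal(33, 1, n), rng.normal(44, 1, n)),
                "mSDC2": np.where(y == 1, rng.normal(34, 1, n), rng.normal(43, 1, n)),
            }
        )
        youden = roc_logistic(X, y, n_repeats=5, seed=2, combined_mode="youden")
        fixed = roc_logistic(
            X,
            y,
            n_repeats=5,
            seed=2,
            combined_mode="fixed",
            fixed_cutoffs={"mSEPT9": 38.0, "mSDC2": 38.0},
        )
        assert youden.combined_auc_mean > 0.95
        assert fixed.combined_auc_mean > 0.95

    def test_undetermined_imputed_to_ceiling(self):
        X, y = self._features()
        X.loc[y == 0, "mSEPT9"] = np.nan
        report = roc_logistic(X, y, n_repeats=3, seed=3, ct_ceiling=50.0)
        assert report.per_gene_auc.set_index("gene").loc["mSEPT9", "mean_auc"] > 0.99

    def test_seeded_determinism(self):
        X, y = self._features()
        a = roc_logistic(X, y, n_repeats=4, seed=11)
        b = roc_logistic(X, y, n_repeats=4, seed=11)
        pd.testing.assert_frame_equal(a.per_gene_auc, b.per_gene_auc)
        assert a.combined_auc_mean == b.combined_auc_mean
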