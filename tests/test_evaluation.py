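"""Splits, metrics, DeLong AUROC, Spearman, subgroups, cohort summaries."""

import numpy as np
import pytest

from dualpet.datatypes import SubjectRecord, SUVrVector, TACMatrix, ALL_REGIONS
from dualpet.evaluation import (
    classification_metrics,
    cohort_summary,
    concordance_auroc,
    delong_auroc,
    largest_remainder,
    metrics_report,
    spearman_corr,
    stratified_split,
    subgroup_auroc,
)


def brute_force_auroc(scores, labels):
    """Independent oracle: enumerate all positive-negative pairs."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def _make_record(sid, dx, ab, mmse=25.0):
    t = np.array([10.0, 30.0])
    return SubjectRecord(
        subject_id=sid, diagnosis=dx, ab_reading=ab, mmse=mmse,
        tac=TACMatrix(np.ones((7, 2)), ALL_REGIONS, t),
        suvr=SUVrVector(np.ones(7), ALL_REGIONS),
    )


def _table_cohort():
    """Cohort with the reference composition: CN 59/15, AD 32/158."""
    recs = []
    k = 0
    for dx, ab, n in (("CN", "neg", 59), ("CN", "pos", 15),
                      ("AD", "neg", 32), ("AD", "pos", 158)):
        for _ in range(n):
            recs.append(_make_record(f"S{k:04d}", dx, ab))
            k += 1
    return recs


class TestSplit:
    @pytest.mark.parametrize("n,expect", [(10, [6, 1, 3]), (158, [95, 16, 47]),
                                          (59, [35, 6, 18]), (15, [9, 2, 4])])
    def test_largest_remainder_allocations(self, n, expect):
        assert largest_remainder(n, (0.6, 0.1, 0.3)) == expect

    def test_largest_remainder_is_exhaustive(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 300))
            assert sum(largest_remainder(n, (0.6, 0.1, 0.3))) == n

    def test_deterministic_and_exhaustive(self):
        recs = _table_cohort()
        s1 = stratified_split(recs, seed=9)
        s2 = stratified_split(recs, seed=9)
        assert s1.assignment == s2.assignment
        assert set(s1.assignment) == {r.subject_id for r in recs}

    def test_per_stratum_proportions_within_one(self):
        recs = _table_cohort()
        sp = stratified_split(recs, seed=4)
        strata = {}
        for r in recs:
            strata.setdefault((r.diagnosis, r.ab_reading), []).append(
                sp.assignment[r.subject_id]
            )
        for key, parts in strata.items():
            n = len(parts)
            for part, ratio in zip(("train", "validation", "test"), (0.6, 0.1, 0.3)):
                assert abs(parts.count(part) - n * ratio) < 1

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(_table_cohort(), ratios=(0.5, 0.1, 0.3))


class TestClassificationMetrics:
    def test_perfect_scores(self):
        m = classification_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert m["accuracy"] == m["f1"] == m["g_mean"] == 1.0

    def test_confusion_matrix_arithmetic(self):
        # TP=8, FN=2, TN=6, FP=4
        scores = [0.9] * 8 + [0.1] * 2 + [0.1] * 6 + [0.9] * 4
        labels = [1] * 10 + [0] * 10
        m = classification_metrics(scores, labels)
        assert m["accuracy"] == pytest.approx(0.70)
        assert m["f1"] == pytest.approx(16 / 22)
        assert m["g_mean"] == pytest.approx(np.sqrt(0.8 * 0.6))

    def test_degenerate_all_positive_prediction(self):
        m = classification_metrics([0.9, 0.9, 0.9], [1, 1, 0])
        assert m["specificity"] == 0.0
        assert m["g_mean"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [])


class TestDeLong:
    def test_perfect_separation(self):
        auc, se = delong_auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0 and se == 0.0

    def test_four_pair_enumeration(self):
        auc, _ = delong_auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_all_ties(self):
        auc, _ = delong_auroc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        assert auc == 0.5

    def test_frozen_reference_values(self):
        # independently computed with the standard DeLong implementation in R
        scores = [0.2, 0.3, 0.5, 0.6, 0.7, 0.8, 0.45, 0.55, 0.15, 0.9]
        labels = [0, 0, 0, 0, 1, 1, 1, 1, 0, 1]
        auc, se = delong_auroc(scores, labels)
        assert auc == pytest.approx(0.88, abs=1e-10)
        assert se == pytest.approx(0.1131370850, abs=1e-9)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 50))
            labels = np.zeros(n, int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            auc, _ = delong_auroc(scores, labels)
            assert auc == pytest.approx(brute_force_auroc(scores, labels), abs=1e-12)

    def test_se_close_to_bootstrap(self, rng):
        n = 80
        labels = np.array([1] * 50 + [0] * 30)
        scores = np.where(labels == 1, rng.normal(0.7, 0.2, n), rng.normal(0.4, 0.2, n))
        _, se = delong_auroc(scores, labels)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if 0 < labels[idx].sum() < n:
                boots.append(delong_auroc(scores[idx], labels[idx])[0])
        assert se == pytest.approx(np.std(boots, ddof=1), rel=0.15)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            delong_auroc([0.1, 0.2], [1, 1])


class TestSpearman:
    def test_strict_monotone(self):
        assert spearman_corr([1, 2, 3, 4], [2, 5, 9, 11]) == 1.0
        assert spearman_corr([1, 2, 3, 4], [9, 7, 3, 1]) == -1.0

    def test_tied_midranks(self):
        rho = spearman_corr([1, 2, 3, 4], [10, 10, 30, 40])
        assert rho == pytest.approx(0.9486833, abs=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 2, 3], [5, 5, 5])


class TestMonotoneInvariance:
    def test_rank_metrics_invariant_threshold_metrics_not(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:3] = [0, 1, 0]
        scores = rng.random(40)
        auc1, _ = delong_auroc(scores, labels)
        auc2, _ = delong_auroc(np.exp(4 * scores), labels)  # strictly monotone
        assert auc1 == pytest.approx(auc2, abs=1e-12)
        rho1 = spearman_corr(scores, labels + rng.random(40) * 0.1)
        cov = labels + rng.random(40) * 0.1
        assert spearman_corr(np.exp(scores), cov) == pytest.approx(
            spearman_corr(scores, cov), abs=1e-12
        )
        acc1 = classification_metrics(scores, labels)["accuracy"]
        acc2 = classification_metrics(scores * 0.25, labels)["accuracy"]
        assert acc1 != acc2  # shrinking scores crosses the fixed threshold


class TestSubgroups:
    def test_full_cohort_subgroup_matches_global(self, rng):
        scores, labels = rng.random(30), rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        readings = np.array(["neg"] * 30)
        out = subgroup_auroc(scores, labels, readings)
        assert out["ab_neg"] == delong_auroc(scores, labels)
        assert out["ab_pos"] is None  # empty side signalled, other computed

    def test_amyloid_only_signal_vanishes_within_strata(self, rng):
        """Scores driven purely by the reading: stratified AUROC ~ 0.5,
        unstratified well above."""
        n = 400
        readings = np.array(["pos" if i < n // 2 else "neg" for i in range(n)])
        # diagnosis mostly agrees with the reading
        labels = (readings == "pos").astype(int)
        flip = rng.random(n) < 0.15
        labels[flip] = 1 - labels[flip]
        scores = np.where(readings == "pos", 0.6, 0.2) + rng.random(n) * 0.05
        full, _ = delong_auroc(scores, labels)
        sub = subgroup_auroc(scores, labels, readings)
        assert full > 0.7
        assert abs(sub["ab_neg"][0] - 0.5) < 0.1
        assert abs(sub["ab_pos"][0] - 0.5) < 0.1

    def test_concordance_partition(self, rng):
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        readings = np.where(rng.random(20) < 0.5, "pos", "neg")
        out = concordance_auroc(scores, labels, readings)
        assert set(out) == {"concordant", "discordant"}


class TestCohortSummary:
    def test_reference_counts(self):
        s = cohort_summary(_table_cohort())
        assert s["total"] == 264
        assert (s["ab_neg_total"], s["ab_pos_total"]) == (91, 173)
        assert s["pct_abneg_ad"] == pytest.approx(16.84, abs=0.005)
        assert s["pct_abpos_cn"] == pytest.approx(20.27, abs=0.005)

    def test_single_subject_sd_undefined(self):
        s = cohort_summary([_make_record("a", "AD", "pos")])
        assert s["AD"]["n"] == 1
        assert np.isnan(s["AD"]["mmse_sd"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])


def test_metrics_report_bundles_everything(rng):
    labels = np.array([1] * 12 + [0] * 8)
    scores = np.clip(labels * 0.5 + rng.random(20) * 0.4, 0, 1)
    readings = np.where(labels == 1, "pos", "neg")
    readings[0], readings[-1] = "neg", "pos"
    mmse = 28 - labels * 8 + rng.random(20)
    rep = metrics_report(scores, labels, readings=readings, mmse=mmse)
    d = rep.as_dict()
    assert 0 <= d["accuracy"] <= 1 and 0 <= d["auroc"] <= 1
    assert -1 <= d["spearman_rho"] <= 1
    assert set(d["subgroups"]) == {"ab_neg", "ab_pos"}
    assert d["n_positive"] == 12 and d["n_negative"] == 8
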