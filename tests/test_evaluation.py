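"""KS testing, ROC analysis, cross-validated classifier, reader-study analytics."""

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import norm

from ggnforge.evaluation import (
    KSReport,
    VTTRecord,
    compare_cohorts,
    ks_two_sample,
    real_vs_fake_auc,
    reference_ks_table,
    roc_auc,
    vtt_summary,
)
from ggnforge.radiomics import extract_features


def exact_ks_pvalue(a, b):
    """Oracle: enumerate every split of the pooled sample into |a| and |b|
    and count splits whose KS statistic is at least the observed one."""
    a, b = np.asarray(a, float), np.asarray(b, float)

    def ks_stat(x, y):
        allv = np.sort(np.concatenate([x, y]))
        cdf_x = np.searchsorted(np.sort(x), allv, side="right") / len(x)
        cdf_y = np.searchsorted(np.sort(y), allv, side="right") / len(y)
        return np.max(np.abs(cdf_x - cdf_y))

    observed = ks_stat(a, b)
    pooled = np.concatenate([a, b])
    n = len(a)
    idx = range(len(pooled))
    count = total = 0
    for chosen in combinations(idx, n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(chosen)] = True
        d = ks_stat(pooled[mask], pooled[~mask])
        count += d >= observed - 1e-12
        total += 1
    return observed, count / total


def pair_count_auc(scores, labels):
    """Oracle: concordant pairs + half ties over n_pos * n_neg."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestKSTwoSample:
    def test_identical_multisets_give_zero_statistic(self):
        d, p = ks_two_sample([1.0, 2.0, 2.0, 3.0], [3.0, 2.0, 1.0, 2.0])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports_give_one(self):
        d, _ = ks_two_sample([0.0, 1.0], [2.0, 3.0])
        assert d == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_small_sample_p_matches_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 4)
        b = rng.normal(0.5, 1, 4)
        d, p = ks_two_sample(a, b)
        d_oracle, p_oracle = exact_ks_pvalue(a, b)
        assert d == pytest.approx(d_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.1, 2, 15)
        b = rng.uniform(0.1, 2, 12)
        d1, _ = ks_two_sample(a, b)
        d2, _ = ks_two_sample(np.log(a), np.log(b))
        d3, _ = ks_two_sample(a ** 3, b ** 3)
        assert d1 == pytest.approx(d2) == pytest.approx(d3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestCompareCohorts:
    @pytest.fixture()
    def cohort(self, phantom_dataset):
        vecs = []
        for sl, anns, _ in phantom_dataset[:4]:
            mask = np.zeros(sl.shape, dtype=bool)
            r0, c0, r1, c1 = anns[0].bbox
            mask[r0:r1, c0:c1] = True
            vecs.append(extract_features(sl, mask))
        return vecs

    def test_identical_cohorts_all_nonsignificant(self, cohort):
        report = compare_cohorts(cohort, list(cohort), alpha=0.05)
        assert report.n_total == 93
        assert report.n_nonsignificant == 93
        assert all(rec[2] == 0.0 for rec in report.records)

    def test_report_sorted_by_descending_p(self, cohort):
        rng = np.random.default_rng(0)
        other = [
            {k: v + rng.normal(0, abs(v) * 0.2 + 0.01) for k, v in fv.items()}
            for fv in cohort
        ]
        report = compare_cohorts(cohort, other, alpha=0.05)
        ps = [rec[3] for rec in report.records]
        assert ps == sorted(ps, reverse=True)

    def test_cohort_size_and_key_errors(self, cohort):
        with pytest.raises(ValueError):
            compare_cohorts(cohort[:1], cohort)
        broken = [dict(fv) for fv in cohort]
        broken[0].pop(("NGTDM", "Busyness"))
        with pytest.raises(ValueError):
            compare_cohorts(cohort, broken)


class TestReferenceTable:
    def test_published_table_shape_and_families(self):
        tab = reference_ks_table()
        assert len(tab) == 93
        assert tab["family"].value_counts().to_dict() == {
            "GLCM": 24, "firstorder": 18, "GLRLM": 16, "GLSZM": 16,
            "GLDM": 14, "NGTDM": 5,
        }


class TestRocAuc:
    def test_perfect_and_null_orderings(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=4000)
        labels = rng.integers(0, 2, 4000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 20)
        scores = rng.integers(0, 5, n).astype(float)  # force ties
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=rng.integers(1, n - 1), replace=False)] = 1
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            pair_count_auc(scores, labels), abs=1e-12)

    def test_complement_identity(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        labels = (rng.uniform(size=30) > 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestRealVsFakeAuc:
    def test_no_signal_gives_half(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 6))
        y = rng.integers(0, 2, 120)
        cv = real_vs_fake_auc(X, y, k=4, seed=1)
        assert cv.pooled_auc == pytest.approx(0.5, abs=0.15)

    def test_perfect_feature_gives_one(self):
        X = np.concatenate([np.zeros((20, 1)), np.ones((20, 1))])
        y = [0] * 20 + [1] * 20
        cv = real_vs_fake_auc(X, y, k=4, seed=0)
        assert cv.pooled_auc == 1.0
        assert cv.pooled_accuracy == 1.0

    def test_binormal_auc_matches_closed_form(self):
        # two unit-variance Gaussians at separation d: AUC = Phi(d / sqrt(2))
        d = 1.5
        rng = np.random.default_rng(7)
        n = 300
        X = np.concatenate([rng.normal(0, 1, (n, 1)), rng.normal(d, 1, (n, 1))])
        y = [0] * n + [1] * n
        cv = real_vs_fake_auc(X, y, k=4, seed=2)
        assert cv.pooled_auc == pytest.approx(norm.cdf(d / np.sqrt(2)), abs=0.04)

    def test_fold_partition_invariants(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(41, 3))
        y = np.array([0, 1] * 20 + [0])
        cv = real_vs_fake_auc(X, y, k=4, seed=5)
        folds = np.array([cv.fold_assignment[i] for i in range(41)])
        assert set(cv.fold_assignment) == set(range(41))
        sizes = np.bincount(folds, minlength=4)
        assert sizes.max() - sizes.min() <= 1


def make_vtt_records():
    """The synthetic-arm composition: 51 cases, 8 confidently real,
    11 leaning real, the rest called fake."""
    recs = (
        [VTTRecord(f"s{i}", "synthetic", "confidently real") for i in range(8)]
        + [VTTRecord(f"s{i}", "synthetic", "leaning real") for i in range(8, 19)]
        + [VTTRecord(f"s{i}", "synthetic", "leaning fake") for i in range(19, 36)]
        + [VTTRecord(f"s{i}", "synthetic", "confidently fake") for i in range(36, 51)]
    )
    return recs


class TestVTT:
    def test_fraction_called_real_from_counts(self):
        recs = make_vtt_records() + [
            VTTRecord("r0", "real", "confidently real"),
            VTTRecord("r1", "real", "leaning fake"),
        ]
        s = vtt_summary(recs)
        assert s.fraction_called_real("synthetic") == pytest.approx(19 / 51)
        assert s.confusion[("synthetic", "real")] == 19
        assert s.confusion[("synthetic", "fake")] == 32

    def test_proportions_sum_to_one_per_truth(self):
        s = vtt_summary(make_vtt_records())
        assert sum(s.proportions["synthetic"].values()) == pytest.approx(1.0)

    def test_one_class_auc_not_computable(self):
        s = vtt_summary(make_vtt_records())
        assert s.auc is None

    def test_auc_equals_mann_whitney_oracle(self):
        rng = np.random.default_rng(0)
        levels = ["confidently fake", "leaning fake", "leaning real",
                  "confidently real"]
        recs = [
            VTTRecord(f"c{i}", rng.choice(["real", "synthetic"]),
                      levels[rng.integers(0, 4)])
            for i in range(10)
        ]
        truths = [r.truth for r in recs]
        if len(set(truths)) < 2:
            recs[0] = VTTRecord("c0", "real", "confidently real")
            recs[1] = VTTRecord("c1", "synthetic", "leaning fake")
        s = vtt_summary(recs)
        scores = [r.score for r in recs]
        labels = [1 if r.truth == "real" else 0 for r in recs]
        assert s.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_unknown_rating_rejected(self):
        with pytest.raises(ValueError):
            VTTRecord("x", "real", "maybe real")

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            vtt_summary([])
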