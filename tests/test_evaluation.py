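"""Confusion analytics, rank AUC, CV aggregation, ANOVA and the
volume-decile analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fuzzyrad import (
    aggregate_cv,
    anova_compare,
    compute_auc,
    confusion_metrics,
    volume_percentile_accuracy,
)
from fuzzyrad.evaluation import volume_to_voxels


def brute_force_auc(scores, labels):
    """Pair-enumeration AUC with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_hand_computed_counts(self):
        m = confusion_metrics(3, 2, 1, 2)
        assert m["SNS"] == pytest.approx(0.6)
        assert m["SPC"] == pytest.approx(2 / 3)
        assert m["PPV"] == pytest.approx(0.75)
        assert m["NPV"] == pytest.approx(0.5)
        assert m["ACC"] == pytest.approx(0.625)

    def test_perfect_classifier(self):
        m = confusion_metrics(5, 5, 0, 0)
        assert all(v == 1.0 for v in m.values())

    def test_balanced_test_accuracy_equals_balanced_accuracy(self):
        # SNS 0.8, SPC 0.6 on a balanced test: ACC = BACC = 0.7
        m = confusion_metrics(8, 6, 4, 2)
        assert m["ACC"] == pytest.approx(0.7)
        assert m["BACC"] == pytest.approx(0.7)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = confusion_metrics(0, 5, 0, 0)
        assert np.isnan(m["SNS"]) and np.isnan(m["PPV"])


class TestAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.2, 0.8], [0, 1], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1], 0.5),
            ([0.2, 0.6, 0.4, 0.8], [0, 0, 1, 1], 0.75),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert compute_auc(scores, labels) == pytest.approx(expected)

    def test_matches_brute_force_enumeration(self, rng):
        """Rank-based AUC equals pair enumeration on vote-score-like
        data (6-valued scores, heavy ties)."""
        for _ in range(10):
            n = int(rng.integers(10, 200))
            scores = rng.choice([0, 0.2, 0.4, 0.6, 0.8, 1.0], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert compute_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([0.1, 0.9], [1, 1])


def _preds(fold_aucs_like):
    """Prediction frames engineered to give chosen per-fold AUCs."""
    rows = []
    for fold_id, auc in enumerate(fold_aucs_like, start=1):
        # two test samples per class; scores arranged for target AUC
        if auc == 1.0:
            sc = [(0, 0.2), (0, 0.2), (1, 0.8), (1, 0.8)]
        elif auc == 0.5:
            sc = [(0, 0.5), (0, 0.5), (1, 0.5), (1, 0.5)]
        else:  # 0.75
            sc = [(0, 0.2), (0, 0.6), (1, 0.6), (1, 0.8)]
        for y, s in sc:
            rows.append(
                {"lesion_id": f"L{len(rows)}", "fold_id": fold_id,
                 "delineation": "Ref-B", "true": y,
                 "predicted": int(s > 0.5), "vote_score": s}
            )
    return pd.DataFrame(rows)


class TestAggregateCv:
    def test_identical_folds_have_zero_width_ci(self):
        s = aggregate_cv(_preds([1.0, 1.0, 1.0]))
        assert s.mean_auc == 1.0
        assert s.auc_ci == (1.0, 1.0)

    def test_mean_of_two_folds(self):
        s = aggregate_cv(_preds([1.0, 0.5]))
        assert s.mean_auc == pytest.approx(0.75)

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cv(_preds([1.0]))


class TestAnova:
    def test_identical_groups_give_p_one(self):
        a = np.full(20, 0.7)
        assert anova_compare({"Ref-B": a, "Ref-F": a})["Ref-F"] == 1.0

    def test_large_shift_is_significant(self, rng):
        a = rng.normal(0.6, 0.01, 100)
        b = rng.normal(0.9, 0.01, 100)
        p = anova_compare({"Ref-B": a, "Ref-F": b})["Ref-F"]
        assert p < 1e-6

    def test_two_group_anova_equals_t_test(self, rng):
        a = rng.normal(0.7, 0.05, 50)
        b = rng.normal(0.72, 0.05, 50)
        p_anova = anova_compare({"Ref-B": a, "Ref-F": b})["Ref-F"]
        p_t = stats.ttest_ind(a, b).pvalue
        assert p_anova == pytest.approx(p_t, rel=1e-9)


class TestVolumeDeciles:
    def _preds_with_volumes(self, n=20, correct=True):
        rows = []
        vols = {}
        for i in range(n):
            lid = f"L{i:02d}"
            vols[lid] = 1000.0 + 1000.0 * i
            y = i % 2
            rows.append(
                {"lesion_id": lid, "fold_id": 1, "delineation": "Ref-B",
                 "true": y, "predicted": y if correct else 1 - y,
                 "vote_score": 0.8 if y else 0.2}
            )
        return pd.DataFrame(rows), pd.Series(vols)

    def test_uniform_volumes_fill_deciles_evenly(self):
        preds, vols = self._preds_with_volumes()
        out = volume_percentile_accuracy(preds, vols, range_mm3=(500, 25_000))
        assert list(out["n"]) == [2] * 10

    def test_all_correct_counts_equal_decile_sizes(self):
        preds, vols = self._preds_with_volumes(correct=True)
        out = volume_percentile_accuracy(preds, vols, range_mm3=(500, 25_000))
        assert (out["correct"] == out["n"]).all()
        assert out["correct"].sum() == len(preds)

    def test_lower_bound_is_closed(self):
        preds, vols = self._preds_with_volumes()
        vols[:] = np.linspace(938.0, 10_000.0, len(vols))
        out = volume_percentile_accuracy(preds, vols)
        assert out["n"].sum() == len(preds)  # the 938 lesion is included

    def test_common_range_lower_bound_voxel_equivalent(self):
        assert volume_to_voxels(938.0, (2.0, 2.0, 2.0)) == 117


class TestSummaryInvariants:
    def test_decile_counts_partition_in_range_predictions(self, rng):
        n = 50
        rows = []
        vols = {}
        for i in range(n):
            lid = f"L{i}"
            vols[lid] = float(rng.uniform(500, 40_000))
            y = int(rng.integers(0, 2))
            rows.append(
                {"lesion_id": lid, "fold_id": 1 + i % 5, "delineation": "Ref-B",
                 "true": y, "predicted": int(rng.integers(0, 2)),
                 "vote_score": float(rng.choice([0, 0.2, 0.4, 0.6, 0.8, 1.0]))}
            )
        preds = pd.DataFrame(rows)
        vols = pd.Series(vols)
        out = volume_percentile_accuracy(preds, vols, range_mm3=(938.0, 30_000.0))
        in_range = ((vols.loc[preds["lesion_id"]] >= 938.0)
                    & (vols.loc[preds["lesion_id"]] <= 30_000.0)).sum()
        assert out["n"].sum() == in_range
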