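"""Harmonization and Spearman redundancy reduction."""

import numpy as np
import pandas as pd
import pytest

from fuzzyrad import FeatureTable, reduce_redundancy, validate_and_harmonize
from fuzzyrad.errors import HarmonizationError

DELINEATIONS = ("Ref-B", "Ref-F", "Ext-B", "Ext-F")


def _table(values: dict, delineation: str, n: int) -> FeatureTable:
    data = pd.DataFrame(
        {
            "lesion_id": [f"L{i}" for i in range(n)],
            "patient_id": [f"P{i}" for i in range(n)],
            "label": [i % 2 for i in range(n)],
            "lesion_volume_mm3": np.full(n, 1000.0),
            **values,
        }
    )
    return FeatureTable(data, delineation)


class TestHarmonization:
    def test_invalid_lesion_dropped_everywhere(self):
        """A lesion invalid in one table disappears from all four."""
        tables = []
        for name in DELINEATIONS:
            vals = {"f1": [1.0, 2.0], "f2": [3.0, 4.0]}
            if name == "Ext-F":
                vals["f2"] = [3.0, np.nan]
            tables.append(_table(vals, name, 2))
        out = validate_and_harmonize(tables)
        for t in out:
            assert list(t.data.index) == ["L0"]
            assert t.feature_names == ["f1", "f2"]

    def test_constant_feature_dropped_everywhere(self):
        """A feature without variation in one table is dropped from all."""
        tables = []
        for name in DELINEATIONS:
            vals = {"f1": [1.0, 2.0, 3.0], "f2": [3.0, 4.0, 5.0]}
            if name == "Ref-B":
                vals["f1"] = [7.0, 7.0, 7.0]
            tables.append(_table(vals, name, 3))
        out = validate_and_harmonize(tables)
        for t in out:
            assert t.feature_names == ["f2"]
            assert len(t.data) == 3
            assert t.dropped_features == ["f1"]

    def test_all_valid_is_identity(self):
        tables = [
            _table({"f1": [1.0, 2.0, 3.0], "f2": [5.0, 4.0, 6.0]}, n, 3)
            for n in DELINEATIONS
        ]
        out = validate_and_harmonize(tables)
        for before, after in zip(tables, out):
            pd.testing.assert_frame_equal(before.data, after.data)

    def test_order_independence_via_fixed_point(self):
        """Dropping a lesion may make a feature constant; the fixed
        point resolves the interaction regardless of rule order."""
        tables = []
        for name in DELINEATIONS:
            vals = {"f1": [1.0, 2.0, 1.0, 1.0], "f2": [1.0, 5.0, 6.0, 7.0]}
            if name == "Ext-B":
                vals["f2"] = [np.nan, 5.0, 6.0, 7.0]
                vals["f1"] = [1.0, 2.0, 2.0, 2.0]  # constant once L0 departs
            tables.append(_table(vals, name, 4))
        out = validate_and_harmonize(tables)
        for t in out:
            assert t.feature_names == ["f2"]
            assert list(t.data.index) == ["L1", "L2", "L3"]

    def test_everything_invalid_raises(self):
        tables = [_table({"f1": [np.nan, np.nan]}, n, 2) for n in DELINEATIONS]
        with pytest.raises(HarmonizationError):
            validate_and_harmonize(tables)


class TestRedundancyReduction:
    def _correlated_table(self, rng, n=40):
        a = rng.normal(0, 1.0, n)
        c = rng.normal(0, 1.0, n)
        return _table(
            {"A": a, "B": 2.0 * a, "C": c}, "Ref-B", n
        )

    def test_keeps_highest_variance_of_perfectly_correlated_pair(self, rng):
        t = self._correlated_table(rng)
        out = reduce_redundancy(t, 0.9)
        assert set(out.feature_names) == {"B", "C"}  # var(B) = 4 var(A)
        assert set(out.clusters["B"]) == {"A", "B"}

    def test_independent_features_untouched(self, rng):
        x = rng.normal(size=(50, 4))
        t = _table({f"f{i}": x[:, i] for i in range(4)}, "Ref-B", 50)
        out = reduce_redundancy(t, 0.9)
        assert out.feature_names == t.feature_names

    def test_idempotent_and_survivors_below_threshold(self, rng):
        n = 60
        base = rng.normal(size=n)
        t = _table(
            {
                "A": base,
                "B": base + rng.normal(0, 0.01, n),
                "C": rng.normal(size=n),
                "D": -base + rng.normal(0, 0.01, n),
            },
            "Ref-B",
            n,
        )
        once = reduce_redundancy(t, 0.9)
        twice = reduce_redundancy(once, 0.9)
        assert once.feature_names == twice.feature_names
        from itertools import combinations

        from scipy import stats

        for a, b in combinations(once.feature_names, 2):
            rho = stats.spearmanr(once.features[a], once.features[b]).statistic
            assert abs(rho) < 0.9, (a, b)

    def test_too_few_rows_rejected(self):
        t = _table({"f1": [1.0, 2.0]}, "Ref-B", 2)
        with pytest.raises(ValueError):
            reduce_redundancy(t)
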