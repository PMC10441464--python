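"""Normalization, variance filtering, splits, and clinical encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autosurv.data import (
    ClinicalEncoder,
    MinMaxNormalizer,
    SplitPlan,
    VarianceFilter,
    make_splits,
    minmax_normalize,
    variance_filter,
)


def _df(values, columns=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    columns = columns or [f"f{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=columns)


class TestMinMaxNormalize:
    def test_linear_rescale(self):
        out = minmax_normalize(_df([[0.0], [5.0], [10.0]]))
        assert out["f0"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_feature_maps_to_zero(self):
        out = minmax_normalize(_df([[3.0], [3.0], [3.0]]))
        assert (out["f0"] == 0.0).all()

    def test_every_column_attains_bounds(self):
        rng = np.random.default_rng(0)
        out = minmax_normalize(pd.DataFrame(rng.normal(size=(20, 5))))
        for col in out:
            vals = out[col].to_numpy()
            # brute-force per-column min/max check
            assert vals.min() == 0.0 and vals.max() == 1.0
            assert (vals == 0.0).sum() >= 1 and (vals == 1.0).sum() >= 1

    def test_rejects_nonfinite_naming_feature(self):
        df = _df([[1.0, np.nan], [2.0, 3.0]], columns=["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            minmax_normalize(df)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=20, unique=True))
    def test_idempotent_on_normalized_data(self, values):
        once = minmax_normalize(_df([[v] for v in values]))
        twice = minmax_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())

    def test_tuning_stats_mode_clips_new_data(self):
        norm = MinMaxNormalizer().fit(_df([[0.0], [10.0]]))
        out = norm.transform(_df([[-5.0], [15.0]]), clip=True)
        assert out["f0"].tolist() == [0.0, 1.0]


class TestVarianceFilter:
    def test_low_variance_feature_removed(self):
        # one 1 among 99 zeros: unbiased sample variance 0.99/99 = 0.01 < 0.02
        vals = np.zeros((100, 1))
        vals[-1] = 1.0
        df = _df(vals)
        assert float(df["f0"].var(ddof=1)) == pytest.approx(0.01)
        with pytest.raises(ValueError):
            variance_filter(df, 0.02)  # sole feature removed -> empty result

    def test_alternating_feature_retained(self):
        vals = np.tile([0.0, 1.0], 50)[:, None]
        df = _df(vals)
        assert float(df["f0"].var(ddof=1)) == pytest.approx(100 * 0.25 / 99)
        assert list(variance_filter(df, 0.02).columns) == ["f0"]

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((30, 6)))
        assert list(variance_filter(df, 0.0).columns) == list(df.columns)

    def test_feature_set_frozen_after_fit(self):
        rng = np.random.default_rng(2)
        tuning = pd.DataFrame(rng.random((50, 5)))
        tuning[3] *= 1e-3  # low variance on the tuning set
        vf = VarianceFilter(0.02).fit(tuning)
        test = pd.DataFrame(rng.random((20, 5)))  # feature 3 has high variance here
        assert list(vf.transform(test).columns) == vf.features_
        assert 3 not in vf.features_


class TestMakeSplits:
    def test_sizes_match_protocol(self):
        ids = [f"s{i}" for i in range(100)]
        events = (np.arange(100) % 3 == 0).astype(int)
        plan = make_splits(ids, events, seed=5)
        assert len(plan.test_ids) == 20 and len(plan.tuning_ids) == 80
        assert len(plan.divisions) == 10
        for train, valid in plan.divisions:
            assert len(train) == 64 and len(valid) == 16

    def test_exact_set_partitions(self):
        ids = [f"s{i}" for i in range(60)]
        events = (np.arange(60) % 4 == 0).astype(int)
        plan = make_splits(ids, events, seed=1)
        assert set(plan.test_ids) | set(plan.tuning_ids) == set(ids)
        assert set(plan.test_ids) & set(plan.tuning_ids) == set()
        for train, valid in plan.divisions:
            assert set(train) | set(valid) == set(plan.tuning_ids)
            assert set(train) & set(valid) == set()

    def test_stratification_keeps_events_everywhere(self):
        ids = [f"s{i}" for i in range(100)]
        events = np.zeros(100, int)
        events[:30] = 1
        plan = make_splits(ids, events, seed=3)
        dead = {i for i, e in zip(ids, events) if e}
        assert dead & set(plan.test_ids)
        for train, valid in plan.divisions:
            assert dead & set(train) and dead & set(valid)

    def test_deterministic_and_seed_sensitive(self):
        ids = [f"s{i}" for i in range(80)]
        events = (np.arange(80) % 2).astype(int)
        a = make_splits(ids, events, seed=7)
        b = make_splits(ids, events, seed=7)
        c = make_splits(ids, events, seed=8)
        assert a == b
        assert set(a.test_ids) != set(c.test_ids)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            make_splits([f"s{i}" for i in range(10)], np.ones(10, int))

    def test_json_round_trip(self, tmp_path):
        ids = [f"s{i}" for i in range(40)]
        plan = make_splits(ids, np.ones(40, int), seed=0)
        plan.to_json(tmp_path / "splits.json")
        assert SplitPlan.from_json(tmp_path / "splits.json") == plan


class TestClinicalEncoder:
    @staticmethod
    def _table():
        return pd.DataFrame(
            {
                "age": [50.0, 60.0, 70.0, 80.0],
                "stage": ["i", "ii", "iii", "iv"],
                "race": ["white", "white", "black", "white"],
            },
            index=["a", "b", "c", "d"],
        )

    def test_reference_level_dropped(self):
        out = ClinicalEncoder(reference={"stage": "iv"}).fit_transform(self._table())
        stage_cols = [c for c in out.columns if c.startswith("stage_")]
        assert stage_cols == ["stage_i", "stage_ii", "stage_iii"]
        assert out.loc["d", stage_cols].sum() == 0  # reference row all zero
        assert out.loc["b", "stage_ii"] == 1.0

    def test_one_hot_groups_sum_at_most_one(self):
        out = ClinicalEncoder().fit_transform(self._table())
        stage_cols = [c for c in out.columns if c.startswith("stage_")]
        assert (out[stage_cols].sum(axis=1) <= 1).all()

    def test_constant_column_yields_no_indicators(self):
        table = self._table().assign(race="white")
        out = ClinicalEncoder().fit_transform(table)
        assert not [c for c in out.columns if c.startswith("race_")]

    def test_unseen_category_named_in_error(self):
        enc = ClinicalEncoder().fit(self._table())
        bad = self._table().assign(stage=["i", "ii", "x", "iv"])
        with pytest.raises(ValueError, match="x"):
            enc.transform(bad)

    def test_missing_value_fails_fast(self):
        table = self._table()
        table.loc["b", "stage"] = None
        with pytest.raises(ValueError, match="stage"):
            ClinicalEncoder().fit_transform(table)

    def test_missing_indicator_mode(self):
        table = self._table()
        table.loc["b", "stage"] = None
        out = ClinicalEncoder(allow_missing=True).fit_transform(table)
        assert out.loc["b", "stage___missing__"] == 1.0

    def test_standardize_numeric(self):
        out = ClinicalEncoder(standardize=True).fit_transform(self._table())
        assert out["age"].mean() == pytest.approx(0.0)
        assert out["age"].std(ddof=0) == pytest.approx(1.0)
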