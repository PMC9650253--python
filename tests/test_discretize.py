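"""Rank-quartile encoding: exact counts, tie guards, rank invariance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from omnirule.discretize import (
    HIGH,
    LOW,
    QuartileEncoding,
    build_transactions,
    encode_within_sample,
    encode_within_strata,
    quartile_encode,
)


class TestQuartileEncode:
    @pytest.mark.parametrize("n", [8, 9, 10, 11])
    def test_floor_quarter_counts_on_distinct_values(self, n):
        rng = np.random.default_rng(n)
        values = rng.permutation(np.arange(n, dtype=float))
        labels = quartile_encode(values)
        assert labels.count(HIGH) == n // 4
        assert labels.count(LOW) == n // 4
        assert labels.count(None) == n - 2 * (n // 4)

    def test_high_and_low_are_the_ranking_extremes(self):
        values = [5.0, 1.0, 8.0, 3.0, 7.0, 2.0, 6.0, 4.0]
        labels = quartile_encode(values)
        assert [v for v, l in zip(values, labels) if l == HIGH] == [8.0, 7.0]
        assert [v for v, l in zip(values, labels) if l == LOW] == [1.0, 2.0]

    def test_ceil_mode(self):
        labels = quartile_encode(list(range(9, 0, -1)), quarter="ceil")
        assert labels.count(HIGH) == 3 and labels.count(LOW) == 3

    def test_all_tied_yields_no_labels_with_warning(self):
        with pytest.warns(UserWarning, match="ties"):
            labels = quartile_encode([2.0] * 8)
        assert set(labels) == {None}

    def test_tie_straddling_cut_suppresses_tied_block_only(self):
        # descending: 9, 8, 8, 8, ... cut after rank 2 falls inside the 8-block
        values = [9.0, 8.0, 8.0, 8.0, 5.0, 4.0, 3.0, 2.0, 1.0]
        with pytest.warns(UserWarning, match="High"):
            labels = quartile_encode(values)
        assert labels[0] == HIGH  # 9 is above the tied block
        assert labels[1] is labels[2] is labels[3] is None
        assert labels.count(LOW) == 2

    def test_fewer_than_four_values_all_null(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            assert quartile_encode([1.0, 2.0, 3.0]) == [None] * 3

    def test_nan_never_labelled(self):
        values = [np.nan, 8, 7, 6, 5, 4, 3, 2, 1]
        labels = quartile_encode(values)
        assert labels[0] is None
        assert labels.count(HIGH) == 2  # n=8 valid values

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=4, max_size=30, unique=True
        ),
        st.floats(0.1, 10.0),
        st.floats(-100.0, 100.0),
    )
    def test_invariant_under_strictly_monotone_transform(self, values, a, b):
        """Rank-based: y = a*x + b (a>0) must encode identically."""
        transformed = [a * v + b for v in values]
        # float rounding may merge near-equal inputs; monotonicity then breaks
        assume(len(set(transformed)) == len(transformed))
        assert quartile_encode(values) == quartile_encode(transformed)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=4, max_size=30, unique=True
        )
    )
    def test_high_low_counts_balance_on_distinct_values(self, values):
        labels = quartile_encode(values)
        assert labels.count(HIGH) == labels.count(LOW) == len(values) // 4


class TestEncodeWithinStrata:
    def _pheno(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(16)]
        pheno = pd.DataFrame(
            {"weight": rng.permutation(16).astype(float),
             "length": rng.permutation(16).astype(float)},
            index=idx,
        )
        strata = pd.Series(["x"] * 8 + ["y"] * 8, index=idx)
        return pheno, strata

    def test_counts_per_stratum_per_variable(self):
        pheno, strata = self._pheno()
        enc = encode_within_strata(pheno, strata)
        for name in ("x", "y"):
            block = enc.labels.loc[strata == name]
            for var in pheno.columns:
                assert (block[var] == HIGH).sum() == 2
                assert (block[var] == LOW).sum() == 2

    def test_small_stratum_all_null(self):
        pheno = pd.DataFrame({"v": [1.0, 2.0, 3.0]}, index=list("abc"))
        with pytest.warns(UserWarning, match="fewer than 4"):
            enc = encode_within_strata(pheno, pd.Series("z", index=list("abc")))
        assert enc.labels["v"].isna().all()

    def test_sample_order_invariance(self):
        pheno, strata = self._pheno()
        enc = encode_within_strata(pheno, strata)
        perm = np.random.default_rng(1).permutation(len(pheno))
        shuffled = encode_within_strata(pheno.iloc[perm], strata.iloc[perm])
        pd.testing.assert_frame_equal(
            enc.labels.sort_index(), shuffled.labels.sort_index()
        )

    def test_missing_stratum_raises(self):
        pheno, strata = self._pheno()
        with pytest.raises(ValueError, match="without a stratum"):
            encode_within_strata(pheno, strata.iloc[:-1])


class TestEncodeWithinSample:
    def test_descending_values_label_extremes(self):
        comp = pd.DataFrame(
            {"s1": [8.0, 7, 6, 5, 4, 3, 2, 1]},
            index=[f"f{i}" for i in range(1, 9)],
        )
        enc = encode_within_sample(comp, namespace="nmr")
        row = enc.labels.loc["s1"]
        assert list(row[row == HIGH].index) == ["f1", "f2"]
        assert list(row[row == LOW].index) == ["f7", "f8"]

    def test_per_sample_high_count_is_quarter_of_features(self, small_dataset):
        enc = encode_within_sample(small_dataset.nmr, namespace="nmr")
        q = small_dataset.nmr.shape[0] // 4
        counts = (enc.labels == HIGH).sum(axis=1)
        assert (counts == q).all()

    def test_uniform_sample_tie_guard(self):
        comp = pd.DataFrame({"s1": [0.125] * 8}, index=[f"f{i}" for i in range(8)])
        with pytest.warns(UserWarning, match="ties"):
            enc = encode_within_sample(comp, namespace="nmr")
        assert enc.labels.loc["s1"].isna().all()

    def test_across_samples_mode_ranks_each_feature(self):
        rng = np.random.default_rng(3)
        comp = pd.DataFrame(
            rng.random((5, 12)),
            index=[f"f{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(12)],
        )
        enc = encode_within_sample(comp, namespace="x", mode="across_samples")
        # each feature (column of labels) has floor(12/4)=3 High across samples
        assert ((enc.labels == HIGH).sum(axis=0) == 3).all()

    def test_unknown_mode_raises(self, small_dataset):
        with pytest.raises(ValueError, match="mode"):
            encode_within_sample(small_dataset.nmr, namespace="x", mode="bogus")


class TestBuildTransactions:
    def _encoding(self):
        labels = pd.DataFrame(
            {"m1": [HIGH, None], "m2": [HIGH, None], "m3": [LOW, None]},
            index=["s1", "s2"],
        )
        return QuartileEncoding(labels=labels, namespace="nmr")

    def test_item_count_and_naming(self):
        meta = pd.DataFrame({"habitat": ["lake_or_pond", "river"]}, index=["s1", "s2"])
        classes = {"NMR_class": pd.Series([2, 1], index=["s1", "s2"])}
        tx = build_transactions([self._encoding()], metadata=meta, classes=classes)
        t1 = tx.itemsets[0]
        assert t1 == {
            "nmr:m1=High", "nmr:m2=High", "nmr:m3=Low",
            "habitat=lake_or_pond", "NMR_class=2",
        }
        assert len(t1) == 5

    def test_all_null_sample_kept_empty_or_dropped(self):
        enc = self._encoding()
        tx = build_transactions([enc])
        assert tx.itemsets[1] == frozenset()
        tx2 = build_transactions([enc], drop_empty=True)
        assert len(tx2) == 1

    def test_lossless_for_non_null_labels(self, small_dataset):
        enc = encode_within_sample(small_dataset.nmr, namespace="nmr")
        tx = build_transactions([enc])
        n_labels = (enc.labels == HIGH).sum().sum() + (enc.labels == LOW).sum().sum()
        assert sum(len(t) for t in tx.itemsets) == n_labels

    def test_index_mismatch_raises_with_samples_named(self):
        enc = self._encoding()
        meta = pd.DataFrame({"habitat": ["x"]}, index=["s1"])
        with pytest.raises(ValueError, match="s2"):
            build_transactions([enc], metadata=meta)

    def test_nothing_to_encode_raises(self):
        with pytest.raises(ValueError, match="nothing"):
            build_transactions([])
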