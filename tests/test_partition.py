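import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairddg.records import Dataset, MutationRecord
from pairddg.partition import (
    edit_distance,
    leakage_report,
    select_anchor_subset,
    sequence_identity,
    split_by_uniprot,
    split_random,
)


def make_grouped_dataset(sizes: dict[str, int], smiles="CCO") -> Dataset:
    records = []
    for g, n in sizes.items():
        for j in range(n):
            records.append(
                MutationRecord(
                    record_id=f"{g}_{j}",
                    uniprot_id=g,
                    wild_seq="ACDEFGHIKL",
                    mutation_spec="A1C",
                    smiles=smiles,
                    ddg=float(j),
                )
            )
    return Dataset(records)


class TestSplitRandom:
    @pytest.mark.parametrize(
        "n,expected",
        [(4179, (3343, 418, 418)), (10, (8, 1, 1)), (12, (9, 1, 2)), (3, (2, 0, 1))],
    )
    def test_split_sizes(self, n, expected):
        sp = split_random([f"r{i}" for i in range(n)], seed=0)
        assert sp.sizes() == expected

    def test_same_seed_identical(self):
        ids = [f"r{i}" for i in range(100)]
        assert split_random(ids, 5).assignment == split_random(ids, 5).assignment

    def test_different_seeds_differ(self):
        ids = [f"r{i}" for i in range(100)]
        distinct = {
            tuple(sorted(split_random(ids, s).test_ids)) for s in range(30)
        }
        assert len(distinct) > 25  # collisions astronomically unlikely

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            split_random(["a", "b"], 0)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            split_random(["a", "a", "b"], 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(3, 400), seed=st.integers(0, 2**16))
    def test_exhaustive_partition_property(self, n, seed):
        ids = [f"r{i}" for i in range(n)]
        sp = split_random(ids, seed)
        assert sorted(sp.assignment) == sorted(ids)
        tr, va, te = sp.sizes()
        assert tr + va + te == n
        assert tr == int(np.floor(0.8 * n))


class TestSplitByUniprot:
    def test_ten_groups_8_1_1(self):
        ds = make_grouped_dataset({f"G{i}": 3 for i in range(10)})
        sp = split_by_uniprot(ds, seed=0)

        def groups_of(ids):
            return {ds.by_id(i).uniprot_id for i in ids}

        assert len(groups_of(sp.train_ids)) == 8
        assert len(groups_of(sp.val_ids)) == 1
        assert len(groups_of(sp.test_ids)) == 1

    def test_group_disjointness(self):
        ds = make_grouped_dataset({f"G{i}": i + 1 for i in range(7)})
        for seed in range(5):
            sp = split_by_uniprot(ds, seed=seed)
            per_subset = {
                s: {ds.by_id(i).uniprot_id for i in sp.ids(s)}
                for s in ("train", "val", "test")
            }
            assert not (per_subset["train"] & per_subset["test"])
            assert not (per_subset["train"] & per_subset["val"])
            assert not (per_subset["val"] & per_subset["test"])

    def test_record_counts_follow_group_shuffle(self):
        sizes = {"A": 5, "B": 4, "C": 3, "D": 2, "E": 1, "F": 6}
        ds = make_grouped_dataset(sizes)
        seed = 11
        sp = split_by_uniprot(ds, seed=seed)
        # recompute expected membership with the same shuffle
        group_ids = ds.uniprot_ids
        order = np.random.default_rng(seed).permutation(len(group_ids))
        shuffled = [group_ids[i] for i in order]
        n_train_groups = 4  # floor(0.8 * 6)
        expected_train = sum(sizes[g] for g in shuffled[:n_train_groups])
        expected_val = sizes[shuffled[4]]  # holdout dealt val first
        expected_test = sizes[shuffled[5]]
        assert sp.sizes() == (expected_train, expected_val, expected_test)

    def test_three_groups_hard_error_and_flag(self):
        ds = make_grouped_dataset({"A": 2, "B": 2, "C": 2})
        with pytest.raises(ValueError, match="empty test set"):
            split_by_uniprot(ds, seed=0)
        sp = split_by_uniprot(ds, seed=0, test_first=True)
        assert len(sp.test_ids) > 0

    def test_too_few_groups(self):
        ds = make_grouped_dataset({"A": 5, "B": 5})
        with pytest.raises(ValueError, match="3 distinct"):
            split_by_uniprot(ds, seed=0)


class TestAnchorSelection:
    def test_ratio_zero_all_queries(self, small_dataset):
        sel = select_anchor_subset(small_dataset, 0.0, seed=0)
        assert sel.anchor_ids == []
        assert sorted(sel.query_ids) == sorted(small_dataset.record_ids)

    def test_single_group_counting(self):
        ds = make_grouped_dataset({"A": 100})
        sel = select_anchor_subset(ds, 0.3, seed=0)
        assert len(sel.anchor_ids) == 30
        assert len(sel.query_ids) == 70

    def test_stratified_per_group_rounding(self):
        ds = make_grouped_dataset({"A": 50, "B": 30, "C": 20})
        sel = select_anchor_subset(ds, 0.2, seed=0)
        per_group = {g: 0 for g in "ABC"}
        for rid in sel.anchor_ids:
            per_group[rid.split("_")[0]] += 1
        assert per_group == {"A": 10, "B": 6, "C": 4}

    def test_anchor_query_partition_of_test(self):
        ds = make_grouped_dataset({"A": 13, "B": 7})
        sel = select_anchor_subset(ds, 0.4, seed=3)
        assert set(sel.anchor_ids) | set(sel.query_ids) == set(ds.record_ids)
        assert not set(sel.anchor_ids) & set(sel.query_ids)

    def test_ratio_out_of_range(self):
        ds = make_grouped_dataset({"A": 5})
        with pytest.raises(ValueError):
            select_anchor_subset(ds, 0.95, seed=0)


class TestLeakage:
    def test_edit_distance_examples(self):
        assert edit_distance("AAAA", "AAAT") == 1
        assert edit_distance("AAAA", "AAAA") == 0
        assert edit_distance("ACGT", "") == 4
        assert edit_distance("kitten", "sitting") == 3

    def test_identity_examples(self):
        assert sequence_identity("AAAA", "AAAT") == pytest.approx(75.0)
        assert sequence_identity("AAAA", "AAAA") == pytest.approx(100.0)

    def test_identical_sequence_and_smiles_reach_100(self):
        train = make_grouped_dataset({"A": 3})
        test = make_grouped_dataset({"B": 2})
        rep = leakage_report(train, test)
        assert (rep.per_record["max_seq_identity_pct"] == 100.0).all()
        assert (rep.per_record["max_smiles_tanimoto_pct"] == 100.0).all()

    def test_uniprot_split_reduces_identity_vs_random(self, small_dataset):
        """Group-disjoint holdout caps test-to-train sequence identity on
        families of near-duplicate sequences (the leakage phenomenon)."""
        ds = small_dataset
        rnd = split_random(ds.record_ids, seed=1)
        grp = split_by_uniprot(ds, seed=1)

        def max_median_identity(split):
            rep = leakage_report(
                ds.subset(split.train_ids), ds.subset(split.test_ids),
                fingerprint_backend="hashed-fallback",
            )
            return rep.per_record["max_seq_identity_pct"].median()

        assert max_median_identity(grp) < max_median_identity(rnd)
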