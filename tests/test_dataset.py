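import numpy as np
import pandas as pd
import pytest

from rsslearn import dataset as ds
from rsslearn.sequences import H4S2_POSITIONS, enumerate_library


@pytest.fixture
def toy_table():
    return pd.DataFrame({"sequence": ["AAAAAA", "ACGTAC", "TTTTTT"],
                         "count": [0, 5, 10]})


class TestLoadReadCounts:
    def test_round_trip(self, toy_table, tmp_path):
        path = tmp_path / "counts.tsv"
        ds.save_read_counts(toy_table, path)
        loaded = ds.load_read_counts(path)
        pd.testing.assert_frame_equal(loaded, toy_table)

    def test_csv_dialect(self, toy_table, tmp_path):
        path = tmp_path / "counts.csv"
        ds.save_read_counts(toy_table, path)
        pd.testing.assert_frame_equal(ds.load_read_counts(path), toy_table)

    @pytest.mark.parametrize("bad_count", ["-1", "2.5", "x"])
    def test_bad_count_rejected(self, tmp_path, bad_count):
        path = tmp_path / "bad.tsv"
        path.write_text(f"sequence\tcount\nAAAAAA\t{bad_count}\n")
        with pytest.raises(ValueError, match="line 2"):
            ds.load_read_counts(path)

    def test_bad_sequence_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sequence\tcount\nAAXAAA\t3\n")
        with pytest.raises(ValueError, match="line 2"):
            ds.load_read_counts(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sequence\nAAAAAA\n")
        with pytest.raises(ValueError, match="count"):
            ds.load_read_counts(path)

    def test_full_library_round_trip_bit_identical(self, tmp_path, h4s2_library):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"sequence": [v.sequence for v in h4s2_library],
                              "count": rng.integers(0, 1000, size=4096)})
        path = tmp_path / "full.tsv"
        ds.save_read_counts(table, path)
        ds.save_read_counts(ds.load_read_counts(path), tmp_path / "again.tsv")
        assert path.read_bytes() == (tmp_path / "again.tsv").read_bytes()


class TestCompleteWithZeros:
    def test_fills_missing_with_zero(self):
        library = enumerate_library(H4S2_POSITIONS, {"S1": "A", "S2": "TG"})  # 512
        observed = pd.DataFrame({
            "sequence": [v.sequence for v in library[:500]],
            "count": np.arange(1, 501),
        })
        out = ds.complete_with_zeros(observed, library)
        assert len(out) == 512
        added = out[~out["sequence"].isin(observed["sequence"])]
        assert len(added) == 12 and (added["count"] == 0).all()

    def test_idempotent(self, toy_table):
        library = ["AAAAAA", "ACGTAC", "TTTTTT"]
        once = ds.complete_with_zeros(toy_table, library)
        twice = ds.complete_with_zeros(once, library)
        pd.testing.assert_frame_equal(once, twice)

    def test_outside_library_rejected(self, toy_table):
        with pytest.raises(ValueError, match="TTTTTT"):
            ds.complete_with_zeros(toy_table, ["AAAAAA", "ACGTAC"])

    def test_per_replicate_completion(self):
        table = pd.DataFrame({
            "sequence": ["AAAAAA", "ACGTAC"], "count": [3, 4],
            "replicate": ["r1", "r2"],
        })
        out = ds.complete_with_zeros(table, ["AAAAAA", "ACGTAC"])
        assert len(out) == 4
        assert sorted(out["replicate"].unique()) == ["r1", "r2"]


class TestAverageReplicates:
    def test_mean(self):
        t1 = pd.DataFrame({"sequence": ["AAAAAA"], "count": [10]})
        t2 = pd.DataFrame({"sequence": ["AAAAAA"], "count": [20]})
        out = ds.average_replicates([t1, t2])
        assert out["count"].iloc[0] == 15.0

    def test_single_replicate_identity(self, toy_table):
        out = ds.average_replicates([toy_table])
        assert list(out.sort_values("sequence")["count"]) == \
            list(toy_table.sort_values("sequence")["count"])

    def test_mismatched_sets_rejected(self, toy_table):
        other = toy_table.iloc[:2]
        with pytest.raises(ValueError, match="different variant sets"):
            ds.average_replicates([toy_table, other])


class TestMinmaxNormalize:
    def test_affine_map(self, toy_table):
        out = ds.minmax_normalize(toy_table)
        assert list(out["target"]) == [0.0, 0.5, 1.0]

    def test_dataset_wide_two_groups(self):
        table = pd.DataFrame({
            "sequence": ["AAAAAA", "ACGTAC", "TTTTTT", "GGGGGG"],
            "count": [0, 40, 0, 10],
            "nonamer": ["a", "a", "b", "b"],
        })
        out = ds.minmax_normalize(table, mode="dataset-wide")
        assert out.loc[out["sequence"] == "GGGGGG", "target"].iloc[0] == 0.25

    def test_nonamer_wise_per_group_max(self):
        table = pd.DataFrame({
            "sequence": ["AAAAAA", "ACGTAC", "TTTTTT", "GGGGGG"],
            "count": [0, 40, 0, 10],
            "nonamer": ["a", "a", "b", "b"],
        })
        out = ds.minmax_normalize(table, mode="nonamer-wise")
        assert out.groupby("nonamer")["target"].max().eq(1.0).all()

    def test_constant_group_zeroed(self, caplog):
        table = pd.DataFrame({"sequence": ["AAAAAA", "ACGTAC"], "count": [5, 5]})
        with caplog.at_level("WARNING"):
            out = ds.minmax_normalize(table)
        assert (out["target"] == 0).all()
        assert "constant" in caplog.text

    def test_rank_preservation(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 500, size=100)
        table = pd.DataFrame({"sequence": [f"{'A' * 6}"] * 100, "count": counts})
        out = ds.minmax_normalize(table)
        assert (np.argsort(out["target"].to_numpy(), kind="stable")
                == np.argsort(counts, kind="stable")).all()


class TestSummarizeDistribution:
    def test_all_zero(self):
        table = pd.DataFrame({"sequence": ["AAAAAA"] * 3, "count": [0, 0, 0]})
        comp = ds.summarize_distribution(table)
        assert (comp["pct_at_or_above_threshold"], comp["pct_below_threshold"],
                comp["pct_zero"]) == (0, 0, 100)

    def test_planted_composition(self):
        counts = [0] * 43 + [5] * 21 + [100] * 36
        table = pd.DataFrame({"sequence": ["AAAAAA"] * 100, "count": counts})
        comp = ds.summarize_distribution(table, threshold=10)
        assert (comp["pct_at_or_above_threshold"], comp["pct_below_threshold"],
                comp["pct_zero"]) == (36, 21, 43)

    def test_rounding_half_away_from_zero(self):
        # 1 of 8 above = 12.5% -> 13
        counts = [20] + [0] * 7
        table = pd.DataFrame({"sequence": ["AAAAAA"] * 8, "count": counts})
        comp = ds.summarize_distribution(table)
        assert comp["pct_at_or_above_threshold"] == 13


@pytest.fixture(scope="module")
def norm_table():
    rng = np.random.default_rng(2)
    counts = np.concatenate([np.zeros(400, dtype=int),
                             rng.integers(1, 1000, size=600)])
    table = pd.DataFrame({"sequence": [f"s{i}" for i in range(1000)],
                          "count": counts})
    return ds.minmax_normalize(table)


class TestStratifiedRotations:

    def test_rotation_structure(self, norm_table):
        rotations = ds.stratified_rotations(norm_table, k=20, seed=0)
        assert len(rotations) == 20
        for rot in rotations:
            masks = rot.role_masks()
            n = masks["train"].sum() + masks["validation"].sum() + masks["test"].sum()
            assert n == 1000
            assert masks["validation"].sum() > 0 and masks["test"].sum() > 0

    def test_each_fold_once_validation_once_test(self, norm_table):
        rotations = ds.stratified_rotations(norm_table, k=20, seed=0)
        assert sorted(r.validation_fold for r in rotations) == list(range(20))
        assert sorted(r.test_fold for r in rotations) == list(range(20))
        for r in rotations:
            assert r.validation_fold != r.test_fold

    def test_folds_partition_dataset(self, norm_table):
        folds = ds.stratified_rotations(norm_table, k=20, seed=0)[0].folds
        assert set(folds) == set(range(20))
        assert folds.index.is_unique

    def test_per_bin_fold_balance(self, norm_table):
        folds = ds.stratified_rotations(norm_table, k=10, seed=0)[0].folds
        bins = ds.assign_bins(norm_table.set_index("sequence")["target"],
                              min_bin_size=10)
        for _, members in bins.groupby(bins):
            sizes = folds.loc[members.index].value_counts()
            assert sizes.max() - sizes.min() <= 1

    def test_seeded_reproducibility(self, norm_table):
        a = ds.stratified_rotations(norm_table, k=5, seed=4)[0].folds
        b = ds.stratified_rotations(norm_table, k=5, seed=4)[0].folds
        pd.testing.assert_series_equal(a, b)

    def test_k_lower_bound(self, norm_table):
        with pytest.raises(ValueError):
            ds.stratified_rotations(norm_table, k=2)

    def test_stratified_fold_distribution_matches_whole(self, norm_table):
        rot = ds.stratified_rotations(norm_table, k=20, seed=0)[0]
        targets = norm_table.set_index("sequence")["target"]
        val = targets.loc[rot.sequences("validation")]
        stat, p = ds.ks_two_sample(val, targets)
        assert p > 0.5


class TestKSTwoSample:
    def test_identical_samples(self):
        x = np.arange(50, dtype=float)
        stat, p = ds.ks_two_sample(x, x)
        assert stat == 0.0

    def test_fully_separated(self):
        stat, p = ds.ks_two_sample(np.arange(10), np.arange(100, 110))
        assert stat == 1.0
        assert p < 1e-4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ds.ks_two_sample([], [1.0])
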