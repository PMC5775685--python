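"""OTU table container, I/O dialect, filtering and subsampling rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from riverbiome import (
    OtuTable,
    OtuTableFormatError,
    filter_otus,
    occupancy,
    read_otu_table,
    relative_abundance,
    subsample_to_depth,
    write_otu_table,
)

count_matrices = arrays(
    np.int64,
    st.tuples(st.integers(1, 6), st.integers(1, 4)),
    elements=st.integers(0, 500),
)


class TestContainer:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(OtuTableFormatError, match="shape"):
            OtuTable(["a", "b"], ["s1"], np.zeros((1, 1), dtype=int))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(OtuTableFormatError, match="duplicate OTU id"):
            OtuTable(["a", "a"], ["s1"], np.zeros((2, 1), dtype=int))
        with pytest.raises(OtuTableFormatError, match="duplicate sample id"):
            OtuTable(["a"], ["s1", "s1"], np.zeros((1, 2), dtype=int))

    def test_negative_counts_rejected(self):
        with pytest.raises(OtuTableFormatError, match="negative count"):
            OtuTable(["a"], ["s1"], np.array([[-1]]))

    def test_taxonomy_length_checked(self):
        with pytest.raises(OtuTableFormatError, match="taxonomy"):
            OtuTable(["a", "b"], ["s1"], np.ones((2, 1), dtype=int), ["Bacteria"])

    def test_phylum_extraction(self, tiny_table):
        assert tiny_table.phyla == ["Proteobacteria", "Bacteroidetes", "Proteobacteria"]


class TestIO:
    def test_round_trip_is_identical(self, tiny_table, tmp_path):
        path = tmp_path / "table.tsv"
        write_otu_table(tiny_table, path)
        back = read_otu_table(path)
        assert back.otu_ids == tiny_table.otu_ids
        assert back.sample_ids == tiny_table.sample_ids
        assert np.array_equal(back.counts, tiny_table.counts)
        assert back.taxonomy == tiny_table.taxonomy
        # and the file itself round-trips byte-for-byte
        path2 = tmp_path / "again.tsv"
        write_otu_table(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    @given(counts=count_matrices)
    def test_round_trip_random_tables(self, counts, tmp_path):
        table = OtuTable(
            [f"o{i}" for i in range(counts.shape[0])],
            [f"s{j}" for j in range(counts.shape[1])],
            counts,
        )
        path = tmp_path / "t.tsv"
        write_otu_table(table, path)
        back = read_otu_table(path)
        assert np.array_equal(back.counts, table.counts)

    def test_duplicate_sample_header_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("#OTU ID\tsA\tsA\no1\t1\t2\n")
        with pytest.raises(OtuTableFormatError, match="sA"):
            read_otu_table(p)

    def test_negative_cell_names_position(self, tmp_path):
        p = tmp_path / "neg.tsv"
        p.write_text("#OTU ID\tsA\tsB\no1\t1\t-1\n")
        with pytest.raises(OtuTableFormatError, match=r"o1.*sB|sB.*o1"):
            read_otu_table(p)

    def test_ragged_row_rejected(self, tmp_path):
        p = tmp_path / "ragged.tsv"
        p.write_text("#OTU ID\tsA\tsB\no1\t1\n")
        with pytest.raises(OtuTableFormatError, match="line 2"):
            read_otu_table(p)

    def test_non_integer_count_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("#OTU ID\tsA\no1\tx\n")
        with pytest.raises(OtuTableFormatError, match="non-integer"):
            read_otu_table(p)


class TestFilterOtus:
    def test_singletons_and_doubletons_removed(self):
        t = OtuTable(["single", "double", "keep"], ["s1", "s2"],
                     np.array([[1, 0], [1, 1], [2, 1]]))
        out = filter_otus(t, min_rel_abundance=0.0)
        assert out.otu_ids == ["keep"]

    def test_rel_abundance_threshold_arithmetic(self):
        # table totals 100,000 reads: 9 reads (9e-5) drops, 10 reads (1e-4) stays
        filler = 100_000 - 9 - 10
        t = OtuTable(["rare9", "rare10", "big"], ["s1"],
                     np.array([[9], [10], [filler]]))
        out = filter_otus(t, min_rel_abundance=1e-4, drop_singletons_doubletons=False)
        assert out.otu_ids == ["rare10", "big"]

    def test_disabled_filters_are_identity(self, tiny_table):
        out = filter_otus(tiny_table, min_rel_abundance=0.0,
                          drop_singletons_doubletons=False)
        assert out.otu_ids == tiny_table.otu_ids
        assert np.array_equal(out.counts, tiny_table.counts)

    def test_no_survivors_is_an_error(self):
        t = OtuTable(["a"], ["s1"], np.array([[1]]))
        with pytest.raises(ValueError, match="no OTUs survive"):
            filter_otus(t)

    @given(counts=count_matrices)
    def test_idempotent(self, counts):
        t = OtuTable(
            [f"o{i}" for i in range(counts.shape[0])],
            [f"s{j}" for j in range(counts.shape[1])],
            counts,
        )
        try:
            once = filter_otus(t)
        except ValueError:
            return  # nothing survives: idempotence is vacuous
        twice = filter_otus(once)
        assert once.otu_ids == twice.otu_ids
        assert np.array_equal(once.counts, twice.counts)


class TestRelativeAbundance:
    def test_per_sample_columns_sum_to_one(self):
        t = OtuTable(["a", "b", "c"], ["s1"], np.array([[2], [2], [6]]))
        rel = relative_abundance(t, per="sample")
        assert np.allclose(rel[:, 0], [0.2, 0.2, 0.6])

    def test_per_table_vector(self):
        t = OtuTable(["a", "b"], ["s1"], np.array([[10], [30]]))
        assert np.allclose(relative_abundance(t, per="table"), [0.25, 0.75])

    def test_zero_total_sample_named(self):
        t = OtuTable(["a"], ["good", "empty"], np.array([[3, 0]]))
        with pytest.raises(ValueError, match="empty"):
            relative_abundance(t, per="sample")


class TestSubsample:
    def test_full_depth_is_identity(self, tiny_table):
        depth = int(tiny_table.sample_totals.min())
        out = subsample_to_depth(tiny_table, depth, seed=0, drop_shallow=True)
        for j, sid in enumerate(out.sample_ids):
            orig = tiny_table.sample_ids.index(sid)
            if tiny_table.sample_totals[orig] == depth:
                assert np.array_equal(out.counts[:, j], tiny_table.counts[:, orig])

    def test_column_sums_equal_depth_and_no_new_otus(self, rng):
        counts = rng.integers(0, 200, size=(20, 6))
        counts[:, 0] += 10
        t = OtuTable([f"o{i}" for i in range(20)], [f"s{j}" for j in range(6)], counts)
        depth = int(t.sample_totals.min())
        out = subsample_to_depth(t, depth, seed=1)
        assert (out.sample_totals == depth).all()
        assert (out.counts <= t.counts).all()

    def test_same_seed_reproduces(self, tiny_table):
        a = subsample_to_depth(tiny_table, 5, seed=42, drop_shallow=True)
        b = subsample_to_depth(tiny_table, 5, seed=42, drop_shallow=True)
        assert np.array_equal(a.counts, b.counts)
        assert a.sample_ids == b.sample_ids

    def test_depth_beyond_all_samples_errors(self, tiny_table):
        with pytest.raises(ValueError, match="depth"):
            subsample_to_depth(tiny_table, 10_000, seed=0)

    def test_shallow_sample_errors_unless_dropped(self, tiny_table):
        with pytest.raises(ValueError, match="drop_shallow"):
            subsample_to_depth(tiny_table, 20, seed=0)
        out = subsample_to_depth(tiny_table, 20, seed=0, drop_shallow=True)
        assert "s1" not in out.sample_ids  # s1 totals 16 < 20, dropped
        assert (out.sample_totals == 20).all()

    def test_matches_hypergeometric_mean(self):
        # drawing 1000 of [5000, 5000]: mean count of OTU 1 is 500, and the
        # Monte-Carlo mean over 1000 replicates must sit within 3 SE of it
        t = OtuTable(["a", "b"], ["s"], np.array([[5000], [5000]]))
        rng_master = np.random.default_rng(7)
        draws = [
            subsample_to_depth(t, 1000, seed=rng_master).counts[0, 0]
            for _ in range(1000)
        ]
        n, big_n = 1000, 10000
        var = n * 0.5 * 0.5 * (big_n - n) / (big_n - 1)
        se_mean = np.sqrt(var / len(draws))
        assert abs(np.mean(draws) - 500.0) < 3 * se_mean


class TestOccupancy:
    def test_counting(self):
        counts = np.zeros((1, 97), dtype=int)
        counts[0, :33] = 5
        t = OtuTable(["a"], [f"s{j}" for j in range(97)], counts)
        assert occupancy(t).iloc[0] == pytest.approx(33 / 97)

    def test_extremes(self):
        t = OtuTable(["zero", "full"], ["s1", "s2"], np.array([[0, 0], [1, 9]]))
        occ = occupancy(t)
        assert occ["zero"] == 0.0
        assert occ["full"] == 1.0

    @given(counts=count_matrices, scales=st.lists(st.integers(1, 50), min_size=4, max_size=4))
    def test_invariant_under_per_sample_rescaling(self, counts, scales):
        t = OtuTable(
            [f"o{i}" for i in range(counts.shape[0])],
            [f"s{j}" for j in range(counts.shape[1])],
            counts,
        )
        factors = np.array(scales[: counts.shape[1]] + [1] * max(0, counts.shape[1] - 4))
        scaled = OtuTable(t.otu_ids, t.sample_ids, counts * factors[None, : counts.shape[1]])
        assert np.array_equal(occupancy(t).to_numpy(), occupancy(scaled).to_numpy())
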