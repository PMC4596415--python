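import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dectico.features import (
    FeatureMatrix,
    build_feature_matrix,
    composition_vector,
    count_kmers,
    ico_dimension,
    ico_feature_names,
    ico_vector,
    minmax_normalize,
)
from dectico.seq_io import ReadSet, read_manifest


def naive_kmer_counts(sequences, k):
    """Brute-force oracle: enumerate every substring window."""
    counts = {}
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            win = seq[i : i + k]
            if all(c in "ACGT" for c in win):
                counts[win] = counts.get(win, 0) + 1
    return counts


class TestCountKmers:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("ACGT", 2, {"AC": 1, "CG": 1, "GT": 1}),
            ("AAAA", 2, {"AA": 3}),
            ("ACGNACG", 2, {"AC": 2, "CG": 2}),
            ("ACGT", 1, {"A": 1, "C": 1, "G": 1, "T": 1}),
        ],
    )
    def test_hand_examples(self, seq, k, expected):
        assert count_kmers(ReadSet("s", [seq]), k).to_dict() == expected

    def test_oracle_equivalence_random_strings(self):
        rng = np.random.default_rng(11)
        alphabet = np.array(list("ACGTN"))
        for _ in range(100):
            n_reads = int(rng.integers(1, 4))
            seqs = [
                "".join(rng.choice(alphabet, size=int(rng.integers(1, 61)), p=[0.23] * 4 + [0.08]))
                for _ in range(n_reads)
            ]
            k = int(rng.integers(1, 6))
            assert count_kmers(ReadSet("s", seqs), k).to_dict() == naive_kmer_counts(seqs, k)

    @given(
        seqs=st.lists(st.text(alphabet="ACGTN", min_size=1, max_size=40), min_size=1, max_size=3),
        k=st.integers(min_value=1, max_value=5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, seqs, k):
        assert count_kmers(ReadSet("s", seqs), k).to_dict() == naive_kmer_counts(seqs, k)

    def test_k_longer_than_reads_gives_empty_table(self):
        table = count_kmers(ReadSet("s", ["ACG"]), 5)
        assert table.total == 0

    def test_windows_do_not_span_reads(self):
        # "AC" + "GT" pooled must not create the junction "CG"
        table = count_kmers(ReadSet("s", ["AC", "GT"]), 2)
        assert table.to_dict() == {"AC": 1, "GT": 1}


class TestCompositionVector:
    def test_three_dimers(self):
        cv = composition_vector(count_kmers(ReadSet("s", ["ACGT"]), 2))
        d = dict(zip(cv.names, cv.values))
        assert d["C:AC"] == d["C:CG"] == d["C:GT"] == pytest.approx(1 / 3)
        assert sum(cv.values) == pytest.approx(1.0)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="no countable"):
            composition_vector(count_kmers(ReadSet("s", ["AC"]), 5))

    def test_uniform_sequence_monte_carlo(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=1_000_000))
        cv = composition_vector(count_kmers(ReadSet("s", [seq]), 4))
        assert np.all(np.abs(cv.values - 1 / 256) < 0.0005)


class TestIcoVector:
    def test_periodic_ac_worked_example(self):
        v = ico_vector(ReadSet("s", ["AC" * 10_000]), 2)
        d = dict(zip(v.names, v.values))
        assert d["F:1:A:C"] == pytest.approx(2.0, abs=1e-3)
        assert d["F:1:C:A"] == pytest.approx(2.0, abs=1e-3)
        for name, val in d.items():
            if name.startswith("F:") and name not in ("F:1:A:C", "F:1:C:A"):
                assert val == 0.0
        assert d["I:1:A"] == pytest.approx(1.0, abs=1e-3)
        assert d["I:1:C"] == pytest.approx(1.0, abs=1e-3)
        assert d["I:1:G"] == 0.0
        assert d["I:1:T"] == 0.0

    @pytest.mark.parametrize("k,expected", [(2, 20), (3, 148), (4, 852), (8, 480_596)])
    def test_dimension_closed_form(self, k, expected):
        assert ico_dimension(k) == expected
        assert len(ico_feature_names(k)) == expected

    def test_dimension_law_on_computed_vectors(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        reads = ReadSet("s", [seq])
        for k in range(2, 9):
            assert len(ico_vector(reads, k)) == ico_dimension(k)

    def test_independence_limit(self):
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), size=1_000_000))
        v = ico_vector(ReadSet("s", [seq]), 3)
        d = dict(zip(v.names, v.values))
        f_vals = np.array([val for nm, val in d.items() if nm.startswith("F:")])
        i_vals = np.array([val for nm, val in d.items() if nm.startswith("I:")])
        assert np.all(np.abs(f_vals - 1.0) < 0.05)
        assert np.all(np.abs(i_vals) < 0.01)

    def test_k1_rejected(self):
        with pytest.raises(ValueError, match="k >= 2"):
            ico_vector(ReadSet("s", ["ACGT"]), 1)

    def test_no_countable_kmers_errors(self):
        with pytest.raises(ValueError, match="no countable"):
            ico_vector(ReadSet("s", ["NNNN"]), 2)

    def test_read_order_permutation_invariance(self):
        rng = np.random.default_rng(9)
        seqs = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(20)]
        v1 = ico_vector(ReadSet("s", seqs), 3).values
        shuffled = list(seqs)
        rng.shuffle(shuffled)
        v2 = ico_vector(ReadSet("s", shuffled), 3).values
        np.testing.assert_array_equal(v1, v2)

    def test_pseudocount_smooths_zeros(self):
        v0 = ico_vector(ReadSet("s", ["AC" * 100]), 2).values
        v1 = ico_vector(ReadSet("s", ["AC" * 100]), 2, pseudocount=1.0).values
        assert np.sum(v0 == 0) > np.sum(v1 == 0)


class TestMinMaxNormalize:
    def test_hand_example(self):
        np.testing.assert_array_equal(minmax_normalize([1, 3, 5]), [0.0, 0.5, 1.0])

    def test_constant_vector_maps_to_zeros(self):
        np.testing.assert_array_equal(minmax_normalize([2, 2, 2]), [0.0, 0.0, 0.0])

    @given(
        st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=50)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_output_in_unit_interval(self, v):
        out = minmax_normalize(np.array(v))
        assert np.all(out >= 0.0) and np.all(out <= 1.0)
        if len(set(v)) > 1:
            assert out.min() == 0.0 and out.max() == 1.0

    def test_idempotent_on_unit_span(self):
        v = np.array([0.0, 0.25, 0.7, 1.0])
        np.testing.assert_array_equal(minmax_normalize(v), v)


class TestBuildFeatureMatrix:
    def test_shapes_names_labels(self, fasta_manifest):
        manifest = read_manifest(fasta_manifest)
        fm = build_feature_matrix(manifest, k=2, feature="ico")
        assert fm.values.shape == (4, 20)
        assert fm.feature_names == ico_feature_names(2)
        # 'disease' is lexicographically later than 'control' -> +1
        np.testing.assert_array_equal(fm.labels, [1, 1, -1, -1])

    def test_rows_are_minmax_normalized(self, fasta_manifest):
        fm = build_feature_matrix(read_manifest(fasta_manifest), k=3, feature="ico")
        assert np.allclose(fm.values.min(axis=1), 0.0)
        assert np.allclose(fm.values.max(axis=1), 1.0)

    def test_composition_feature(self, fasta_manifest):
        fm = build_feature_matrix(
            read_manifest(fasta_manifest), k=2, feature="composition", normalize=False
        )
        assert fm.values.shape == (4, 16)

    def test_identical_read_sets_give_identical_rows(self, tmp_path):
        (tmp_path / "x.fasta").write_text(">r\n" + "ACGT" * 30 + "\n")
        manifest = tmp_path / "m.tsv"
        manifest.write_text(
            "sample_id\tpaths\tlabel\na\tx.fasta\tu\nb\tx.fasta\tv\n"
        )
        fm = build_feature_matrix(read_manifest(manifest), k=3)
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_restrict_missing_column_names_it(self, planted_matrix):
        with pytest.raises(KeyError, match="absent"):
            planted_matrix.restrict(["absent"])
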