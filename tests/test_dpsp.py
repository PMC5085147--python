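"""Propensity estimation and DPSP encoding against hand counts and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline

from conftest import random_sequences
from oriforest.dpsp import (
    DINUCLEOTIDES,
    DPSPEncoder,
    build_propensity,
    dinucleotide_rank,
    encode,
    encode_all,
    frequency_profile,
    load_propensity,
    positional_frequencies,
    save_propensity,
)
from oriforest.errors import AlphabetError, EmptyInputError, LengthMismatchError
from oriforest.sequence_io import BenchmarkDataset, SequenceRecord
from oriforest.synthetic import BiasWindow, GeneratorSpec, generate


def naive_frequencies(seqs, length):
    """Independent double-loop oracle for per-position dinucleotide frequencies."""
    table = np.zeros((16, length - 1))
    for seq in seqs:
        for j in range(1, length):  # 1-based dinucleotide start positions
            table[DINUCLEOTIDES.index(seq[j - 1 : j + 1]), j - 1] += 1
    return table / len(seqs)


class TestDinucleotideRank:
    @pytest.mark.parametrize("code,rank", [("AA", 1), ("AC", 2), ("AG", 3),
                                           ("TG", 15), ("TT", 16)])
    def test_lexicographic_examples(self, code, rank):
        assert dinucleotide_rank(code) == rank

    def test_bijective_over_the_16_codes(self):
        assert sorted(dinucleotide_rank(c) for c in DINUCLEOTIDES) == list(range(1, 17))
        assert [DINUCLEOTIDES[dinucleotide_rank(c) - 1] for c in DINUCLEOTIDES] == list(
            DINUCLEOTIDES
        )

    @pytest.mark.parametrize("bad", ["AN", "A", "ACG", "XY"])
    def test_invalid_codes_rejected(self, bad):
        with pytest.raises(AlphabetError):
            dinucleotide_rank(bad)


class TestPositionalFrequencies:
    def test_two_identical_sequences(self):
        table = positional_frequencies(["AA", "AA"], 2)
        expected = np.zeros((16, 1))
        expected[0, 0] = 1.0
        np.testing.assert_array_equal(table.values, expected)

    def test_split_column(self):
        table = positional_frequencies(["AC", "AA"], 2)
        assert table.values[0, 0] == 0.5  # AA
        assert table.values[1, 0] == 0.5  # AC
        assert table.values.sum() == 1.0

    def test_position_indexes_the_leading_base(self):
        table = positional_frequencies(["ACG"], 3)
        assert table.values[1, 0] == 1.0  # AC at position 1
        assert table.values[6, 1] == 1.0  # CG at position 2
        assert table.values.sum() == 2.0

    def test_empty_input_is_an_error(self):
        with pytest.raises(EmptyInputError):
            positional_frequencies([], 5)

    def test_matches_naive_double_loop_on_random_micro_datasets(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 21))
            length = int(rng.integers(2, 11))
            seqs = random_sequences(rng, n, length)
            table = positional_frequencies(seqs, length)
            np.testing.assert_array_equal(table.values, naive_frequencies(seqs, length))

    @settings(derandomize=True, max_examples=30)
    @given(data=st.data())
    def test_columns_are_categorical_distributions(self, data):
        length = data.draw(st.integers(2, 12))
        seqs = data.draw(
            st.lists(st.text(alphabet="ACGT", min_size=length, max_size=length),
                     min_size=1, max_size=12)
        )
        table = positional_frequencies(seqs, length)
        np.testing.assert_allclose(table.values.sum(axis=0),
                                   np.ones(length - 1), atol=1e-9)
        # every entry is a multiple of 1/n
        np.testing.assert_allclose(
            table.values * len(seqs), np.round(table.values * len(seqs)), atol=1e-9
        )


class TestBuildPropensity:
    def test_identical_tables_give_zero_matrix(self):
        t = positional_frequencies(["ACGT", "TTAA"], 4)
        np.testing.assert_array_equal(build_propensity(t, t).values, 0.0)

    def test_hand_counted_example(self):
        pos = positional_frequencies(["AA", "AA"], 2)
        neg = positional_frequencies(["AC", "AA"], 2)
        matrix = build_propensity(pos, neg)
        assert matrix.values[0, 0] == 0.5   # P(AA, 1)
        assert matrix.values[1, 0] == -0.5  # P(AC, 1)
        assert np.count_nonzero(matrix.values) == 2
        assert matrix.length == 2

    def test_antisymmetry_and_column_sums(self, rng):
        pos = positional_frequencies(random_sequences(rng, 9, 8), 8)
        neg = positional_frequencies(random_sequences(rng, 7, 8), 8)
        forward = build_propensity(pos, neg)
        backward = build_propensity(neg, pos)
        np.testing.assert_array_equal(forward.values, -backward.values)
        np.testing.assert_allclose(forward.values.sum(axis=0), 0.0, atol=1e-9)
        assert forward.values.min() >= -1.0 and forward.values.max() <= 1.0

    def test_shape_mismatch_rejected(self):
        a = positional_frequencies(["ACGT"], 4)
        b = positional_frequencies(["ACG"], 3)
        with pytest.raises(LengthMismatchError):
            build_propensity(a, b)


class TestEncode:
    def test_zero_matrix_encodes_to_zeros(self):
        pos = positional_frequencies(["AAA"], 3)
        matrix = build_propensity(pos, pos)
        np.testing.assert_array_equal(encode("AAA", matrix), np.zeros(2))

    def test_lookup_against_hand_built_matrix(self):
        pos = positional_frequencies(["AA", "AA"], 2)
        neg = positional_frequencies(["AC", "AA"], 2)
        matrix = build_propensity(pos, neg)
        np.testing.assert_array_equal(encode("AC", matrix), [-0.5])
        np.testing.assert_array_equal(encode("AA", matrix), [0.5])

    def test_encoding_is_a_pure_positionwise_lookup(self, rng):
        seqs = random_sequences(rng, 10, 12)
        pos = positional_frequencies(seqs[:5], 12)
        neg = positional_frequencies(seqs[5:], 12)
        matrix = build_propensity(pos, neg)
        probe = random_sequences(rng, 1, 12)[0]
        vec = encode(probe, matrix)
        for u in range(1, 12):
            assert vec[u - 1] == matrix.lookup(probe[u - 1 : u + 1], u)

    def test_length_mismatch_rejected(self):
        pos = positional_frequencies(["AAA"], 3)
        matrix = build_propensity(pos, pos)
        with pytest.raises(LengthMismatchError):
            encode("AAAA", matrix)

    def test_encode_all_matches_scalar_and_is_order_equivariant(self, rng):
        seqs = random_sequences(rng, 8, 10)
        pos = positional_frequencies(seqs[:4], 10)
        neg = positional_frequencies(seqs[4:], 10)
        matrix = build_propensity(pos, neg)
        probes = random_sequences(rng, 6, 10)
        table = encode_all(probes, matrix)
        assert table.shape == (6, 9)
        for k, probe in enumerate(probes):
            np.testing.assert_array_equal(table[k], encode(probe, matrix))
        perm = rng.permutation(6)
        np.testing.assert_array_equal(
            encode_all([probes[i] for i in perm], matrix), table[perm]
        )


class TestFrequencyProfile:
    def test_all_a_positives_have_unit_aa_profile(self):
        ds = BenchmarkDataset(
            positives=[SequenceRecord(id="p", seq="A" * 20)],
            negatives=[SequenceRecord(id="n", seq="ACGT" * 5)],
        )
        pos_series, neg_series = frequency_profile(ds, "AA")
        np.testing.assert_array_equal(pos_series, np.ones(19))
        assert neg_series.max() == 0.0

    def test_null_dataset_profiles_differ_only_by_sampling_noise(self):
        ds = generate(GeneratorSpec(n_pos=800, n_neg=800, length=100, seed=5))
        pos_series, neg_series = frequency_profile(ds, "AA")
        assert np.abs(pos_series - neg_series).max() < 0.08

    def test_planted_enrichment_lifts_the_positive_profile(self):
        spec = GeneratorSpec(
            n_pos=150, n_neg=150, length=200,
            bias_windows=(BiasWindow(start=100, end=150, code="AA", delta=0.7),),
            seed=3,
        )
        pos_series, neg_series = frequency_profile(generate(spec), "AA")
        window = slice(99, 149)  # positions 100..149, 0-based
        assert (pos_series[window] > neg_series[window]).mean() > 0.95


class TestDPSPEncoder:
    def test_fitted_attributes_and_shapes(self, tiny_biased_dataset):
        ds = tiny_biased_dataset
        enc = DPSPEncoder().fit(ds.records(), ds.labels())
        assert enc.sequence_length_ == ds.length
        assert enc.n_features_out_ == ds.length - 1
        assert enc.propensity_.values.shape == (16, ds.length - 1)
        assert enc.transform(ds.records()).shape == (ds.n_pos + ds.n_neg,
                                                     ds.length - 1)
        assert list(enc.get_feature_names_out()[:2]) == ["phi_1", "phi_2"]

    def test_clone_and_get_params_follow_sklearn_conventions(self):
        enc = DPSPEncoder(k=2, pseudocount=0.5)
        params = enc.get_params()
        assert params["pseudocount"] == 0.5
        assert clone(enc).get_params() == params

    def test_single_class_labels_rejected(self, rng):
        seqs = random_sequences(rng, 4, 10)
        with pytest.raises(EmptyInputError):
            DPSPEncoder().fit(seqs, [1, 1, 1, 1])

    def test_composes_in_a_sklearn_pipeline(self, tiny_biased_dataset):
        ds = tiny_biased_dataset
        pipe = Pipeline([
            ("dpsp", DPSPEncoder()),
            ("forest", RandomForestClassifier(n_estimators=25, random_state=0)),
        ])
        pipe.fit(ds.records(), ds.labels())
        assert pipe.score(ds.records(), ds.labels()) == 1.0


class TestPropensityRoundTrip:
    def test_tsv_round_trip(self, tmp_path, rng):
        seqs = random_sequences(rng, 10, 15)
        pos = positional_frequencies(seqs[:5], 15)
        neg = positional_frequencies(seqs[5:], 15)
        matrix = build_propensity(pos, neg)
        save_propensity(matrix, tmp_path / "p.tsv")
        loaded = load_propensity(tmp_path / "p.tsv")
        np.testing.assert_allclose(loaded.values, matrix.values, atol=1e-9)
        assert loaded.length == matrix.length and loaded.k == 2
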