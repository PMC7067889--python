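"""The eight feature encodings against closed forms and brute-force oracles."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from mc4deep import (
    DnaSample,
    GeneratorConfig,
    Scheme,
    encode,
    encode_dataset,
    encode_knn,
    feature_length,
    generate,
    stratified_folds,
)
from mc4deep.encoders import (
    BASES,
    EIIP,
    EncoderParams,
    TRINUCS,
    encode_knn_batch,
    feature_names,
)

RNG = np.random.default_rng(77)


def random_seq(n=41):
    return "".join(RNG.choice(list(BASES), size=n))


@pytest.mark.parametrize("scheme,expected", [
    (Scheme.BKF, 500),       # 4*41 one-hot + 16+64+256 k-mer frequencies
    (Scheme.DBPF, 680),      # 40 positions x (16 one-hot + running freq)
    (Scheme.KNN, 10),        # ten neighbourhood fractions
    (Scheme.PCP, 240),       # 40 positions x 6 scales
    (Scheme.MMI, 30),        # 10 unordered pairs + 20 unordered triples
    (Scheme.PSEDNC, 19),     # 16 dinucleotides + lambda=3 tiers
    (Scheme.PSEEIIP, 64),    # 4^3 trinucleotides
    (Scheme.RFHCP, 164),     # 41 positions x 4 values
])
def test_feature_lengths_match_closed_forms(scheme, expected):
    assert feature_length(scheme, 41) == expected
    assert len(feature_names(scheme, 41)) == expected


def test_encoded_vectors_match_declared_length():
    seq = random_seq()
    for scheme in Scheme:
        if scheme is Scheme.KNN:
            continue
        vec = encode(seq, scheme)
        assert len(vec) == feature_length(scheme, 41)
        assert np.isfinite(vec).all()


def test_unknown_scheme_rejected():
    with pytest.raises(ValueError, match="unknown"):
        feature_length("bogus", 41)


class TestBkf:
    def test_onehot_block_sums_to_length(self):
        vec = encode(random_seq(), Scheme.BKF)
        assert vec[: 4 * 41].sum() == 41  # one hot bit per position

    def test_kmer_blocks_are_relative_frequencies(self):
        seq = random_seq()
        vec = encode(seq, Scheme.BKF)
        offset = 4 * 41
        for k in (2, 3, 4):
            block = vec[offset : offset + 4**k]
            assert block.sum() == pytest.approx(1.0)
            # brute-force count oracle
            counts = Counter(seq[i : i + k] for i in range(41 - k + 1))
            kmers = ["".join(p) for p in itertools.product(BASES, repeat=k)]
            expected = np.asarray([counts[m] for m in kmers]) / (41 - k + 1)
            np.testing.assert_allclose(block, expected)
            offset += 4**k


class TestDbpf:
    def test_against_positionwise_oracle(self):
        seq = random_seq()
        vec = encode(seq, Scheme.DBPF).reshape(40, 17)
        dinucs = ["".join(p) for p in itertools.product(BASES, repeat=2)]
        for j in range(40):
            d = seq[j : j + 2]
            onehot = np.zeros(16)
            onehot[dinucs.index(d)] = 1
            np.testing.assert_array_equal(vec[j, :16], onehot)
            # running frequency of this dinucleotide among positions 1..j+1
            occurrences = sum(seq[i : i + 2] == d for i in range(j + 1))
            assert vec[j, 16] == pytest.approx(occurrences / (j + 1))


class TestPcp:
    def test_scales_are_standardized(self):
        from mc4deep.encoders import STEP_PARAMS

        mat = np.stack(list(STEP_PARAMS.values()))
        np.testing.assert_allclose(mat.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(mat.std(axis=0), 1, atol=1e-12)

    def test_positionwise_lookup(self):
        from mc4deep.encoders import STEP_PARAMS

        seq = random_seq()
        vec = encode(seq, Scheme.PCP).reshape(40, 6)
        for j in (0, 17, 39):
            np.testing.assert_array_equal(vec[j], STEP_PARAMS[seq[j : j + 2]])


class TestMmi:
    def test_reversal_invariance(self):
        # unordered window content is invariant under sequence reversal
        seq = random_seq()
        np.testing.assert_allclose(
            encode(seq, Scheme.MMI), encode(seq[::-1], Scheme.MMI)
        )

    def test_pair_terms_against_hand_formula(self):
        seq = random_seq()
        vec = encode(seq, Scheme.MMI)
        f1 = {b: seq.count(b) / 41 for b in BASES}
        windows = ["".join(sorted(seq[i : i + 2])) for i in range(40)]
        pairs = ["".join(p) for p in
                 itertools.combinations_with_replacement(BASES, 2)]
        for idx, pair in enumerate(pairs):
            fxy = windows.count(pair) / 40
            expected = 0.0
            if fxy > 0 and f1[pair[0]] > 0 and f1[pair[1]] > 0:
                expected = fxy * math.log(fxy / (f1[pair[0]] * f1[pair[1]]))
            assert vec[idx] == pytest.approx(expected)


class TestPseDnc:
    def test_components_sum_to_one(self):
        vec = encode(random_seq(), Scheme.PSEDNC)
        assert vec.sum() == pytest.approx(1.0)
        assert (vec >= 0).all()

    def test_lambda_widens_vector(self):
        params = EncoderParams(pse_lambda=5)
        assert feature_length(Scheme.PSEDNC, 41, params) == 21
        assert len(encode(random_seq(), Scheme.PSEDNC, params)) == 21


class TestPseEiip:
    def test_homopolymer_hand_example(self):
        vec = encode("A" * 41, Scheme.PSEEIIP)
        aaa = TRINUCS.index("AAA")
        assert vec[aaa] == pytest.approx(3 * 0.1260)  # = 0.378, frequency 1
        assert np.count_nonzero(np.delete(vec, aaa)) == 0

    def test_matches_weighted_frequency_oracle(self):
        seq = random_seq()
        vec = encode(seq, Scheme.PSEEIIP)
        counts = Counter(seq[i : i + 3] for i in range(39))
        for idx, t in enumerate(TRINUCS):
            expected = sum(EIIP[b] for b in t) * counts[t] / 39
            assert vec[idx] == pytest.approx(expected)
        assert (vec >= 0).all()


class TestRfhcp:
    def test_chemical_bits_and_cumulative_frequency(self):
        seq = random_seq()
        vec = encode(seq, Scheme.RFHCP).reshape(41, 4)
        bits = {"A": (1, 0, 1), "C": (0, 1, 1), "G": (1, 1, 0), "T": (0, 0, 0)}
        for i in (0, 20, 40):
            assert tuple(vec[i, :3]) == bits[seq[i]]
            prefix = seq[: i + 1]
            assert vec[i, 3] == pytest.approx(prefix.count(seq[i]) / (i + 1))

    def test_homopolymer_cumulative_channel_constant_one(self):
        vec = encode("A" * 41, Scheme.RFHCP).reshape(41, 4)
        np.testing.assert_array_equal(vec[:, 3], 1.0)


class TestKnn:
    def refs(self, n=10, seed=3):
        rng = np.random.default_rng(seed)
        return [
            DnaSample(f"r{i}", "".join(rng.choice(list(BASES), size=41)),
                      int(rng.integers(0, 2)))
            for i in range(n)
        ]

    def test_identical_positive_reference_wins(self):
        refs = self.refs()
        refs[4] = DnaSample("twin", refs[4].sequence, 1)
        params = EncoderParams(knn_fractions=(0.1,))  # single nearest of 10
        vec = encode_knn(refs[4].sequence, refs, params)
        assert vec[0] == 1.0

    def test_all_negative_references_give_zero(self):
        refs = [DnaSample(r.id, r.sequence, 0) for r in self.refs()]
        vec = encode_knn(random_seq(), refs)
        np.testing.assert_array_equal(vec, 0.0)

    def test_against_exhaustive_sort_oracle(self):
        refs = self.refs(10)
        query = random_seq()
        params = EncoderParams(knn_fractions=(0.5,))
        vec = encode_knn(query, refs, params)
        # brute force: exhaustive distance sort, neighbourhood ceil(0.5*10)=5
        sims = [sum(a == b for a, b in zip(query, r.sequence)) / 41
                for r in refs]
        order = sorted(range(10), key=lambda i: (-sims[i], i))
        expected = np.mean([refs[i].label for i in order[:5]])
        assert vec[0] == pytest.approx(expected)

    def test_ties_broken_by_reference_order(self):
        seq = random_seq()
        refs = [DnaSample("first", seq, 1), DnaSample("second", seq, 0)]
        params = EncoderParams(knn_fractions=(0.5,))  # single nearest of 2
        assert encode_knn(seq, refs, params)[0] == 1.0

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            encode_knn(random_seq(), [])

    def test_batch_matches_single_queries(self):
        refs = self.refs(12)
        queries = [random_seq() for _ in range(5)]
        batch = encode_knn_batch(queries, refs)
        for i, q in enumerate(queries):
            np.testing.assert_allclose(batch[i], encode_knn(q, refs))


class TestEncodeDataset:
    def test_shape_and_row_order(self, tiny_samples):
        enc = encode_dataset(tiny_samples[:4], Scheme.BKF)
        assert enc.matrix.shape == (4, 500)
        np.testing.assert_array_equal(
            enc.matrix[2], encode(tiny_samples[2], Scheme.BKF)
        )

    def test_empty_dataset_keeps_width(self):
        enc = encode_dataset([], Scheme.BKF)
        assert enc.matrix.shape == (0, 500)

    def test_permuting_rows_permutes_matrix(self, tiny_samples):
        perm = np.random.default_rng(0).permutation(len(tiny_samples))
        enc = encode_dataset(tiny_samples, Scheme.RFHCP)
        enc_perm = encode_dataset([tiny_samples[i] for i in perm], Scheme.RFHCP)
        np.testing.assert_array_equal(enc_perm.matrix, enc.matrix[perm])

    def test_knn_requires_folds(self, tiny_samples):
        with pytest.raises(ValueError, match="fold"):
            encode_dataset(tiny_samples, Scheme.KNN)

    def test_knn_rows_never_see_own_fold(self):
        # poison trick: give fold f's rows label 1 and everyone else 0;
        # out-of-fold references are then all-negative, so fold f's KNN
        # features must be exactly 0 if no in-fold reference leaked in.
        base = generate(GeneratorConfig(n_pos=30, n_neg=30, effect=0.0, seed=8))
        folds = stratified_folds(base, k=3, seed=8)
        for fold in range(3):
            in_fold = set(folds.rows_in_fold(fold).tolist())
            poisoned = [
                DnaSample(s.id, s.sequence, 1 if i in in_fold else 0)
                for i, s in enumerate(base)
            ]
            enc = encode_dataset(poisoned, Scheme.KNN, folds=folds)
            np.testing.assert_array_equal(enc.matrix[sorted(in_fold)], 0.0)
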