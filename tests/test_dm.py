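"""DM coding: marker sets, Jaccard, MinHash signatures, LSH retrieval."""

import numpy as np
import pytest

from wfclust import (
    BinaryCodes,
    Dataset,
    choose_bands,
    dm_encode,
    jaccard_sim,
    lsh_pairs,
    make_planted_binary,
    minhash_signatures,
    PlantedBinarySpec,
)
from wfclust.dm import (
    choose_bands_guaranteed,
    jaccard_for_pairs,
    jaccard_pairs_bruteforce,
    marker_join_pairs,
)


class TestEncode:
    def test_nonzero_markers(self):
        X = Dataset.from_array([[0.0, 2.5, 0.0, 1.0]])
        assert dm_encode(X, "nonzero")[0].tolist() == [1, 3]

    def test_all_zero_row_rejected(self):
        X = Dataset.from_array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="rows \\[1\\]"):
            dm_encode(X, "nonzero")

    def test_top_m_largest_magnitude(self):
        X = Dataset.from_array([[0.1, -3.0, 0.2]])
        assert dm_encode(X, "top_m", m=1)[0].tolist() == [1]

    def test_binned_equal_width(self):
        # range [0,1] over one dimension, 2 bins: 0.75 lands in bin 1
        X = Dataset.from_array([[0.0], [1.0], [0.75]])
        codes = dm_encode(X, "binned", B=2)
        assert codes[2].tolist() == [1]
        assert codes[0].tolist() == [0]
        assert codes.D == 2


class TestJaccard:
    def test_identical_disjoint_partial(self):
        c1 = np.array([0, 2, 3])          # 10110
        c2 = np.array([0, 3, 4])          # 10011
        c3 = np.array([1, 3])             # 01010
        assert jaccard_sim(c1, c1) == 1.0
        assert jaccard_sim(np.array([0, 2]), c3) == 0.0
        assert jaccard_sim(c1, c2) == 0.5  # AND 10010 (2), OR 10111 (4)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(50):
            a = np.unique(rng.integers(0, 40, size=rng.integers(1, 15)))
            b = np.unique(rng.integers(0, 40, size=rng.integers(1, 15)))
            j = jaccard_sim(a, b)
            assert j == jaccard_sim(b, a)
            assert 0.0 <= j <= 1.0
            assert (j == 1.0) == (a.tolist() == b.tolist())

    def test_vectorized_pairs_match_scalar(self, small_planted):
        _, codes, _ = small_planted
        pairs = [(0, 1), (0, 250), (7, 499), (123, 124)]
        vec = jaccard_for_pairs(codes, pairs)
        for (i, j), v in zip(pairs, vec):
            assert v == pytest.approx(jaccard_sim(codes[i], codes[j]))


class TestMinHash:
    def test_deterministic_and_identical_codes_agree(self):
        codes = BinaryCodes([[0, 5, 9], [0, 5, 9], [1, 2]], D=10)
        a = minhash_signatures(codes, k=32, seed=5)
        b = minhash_signatures(codes, k=32, seed=5)
        assert np.array_equal(a.signatures, b.signatures)
        assert np.array_equal(a.signatures[0], a.signatures[1])

    def test_different_seed_differs(self):
        codes = BinaryCodes([[0, 5, 9], [1, 2]], D=10)
        a = minhash_signatures(codes, k=32, seed=5)
        b = minhash_signatures(codes, k=32, seed=6)
        assert not np.array_equal(a.signatures, b.signatures)

    def test_small_k_rejected(self):
        codes = BinaryCodes([[0]], D=1)
        with pytest.raises(ValueError):
            minhash_signatures(codes, k=8)

    def test_agreement_concentrates_on_jaccard(self, rng):
        # binomial concentration: agreement within 3*sqrt(J(1-J)/k) for >=95%
        k = 256
        hits = 0
        total = 200
        sets, J = [], []
        for _ in range(total):
            a = np.unique(rng.integers(0, 200, size=30))
            b = np.unique(rng.integers(0, 200, size=30))
            sets.append((a, b))
            J.append(jaccard_sim(a, b))
        flat = [s for ab in sets for s in ab]
        codes = BinaryCodes(flat, D=200)
        sig = minhash_signatures(codes, k=k, seed=0).signatures
        for idx, j in enumerate(J):
            agree = (sig[2 * idx] == sig[2 * idx + 1]).mean()
            tol = 3 * np.sqrt(max(j * (1 - j), 1e-4) / k)
            hits += abs(agree - j) <= tol
        assert hits / total >= 0.95

    def test_estimator_mean_unbiased_over_seeds(self):
        a = np.arange(0, 30)
        b = np.arange(15, 45)  # J = 15/45 = 1/3
        codes = BinaryCodes([a, b], D=64)
        agree = []
        for seed in range(50):
            sig = minhash_signatures(codes, k=256, seed=seed).signatures
            agree.append((sig[0] == sig[1]).mean())
        assert abs(np.mean(agree) - 1.0 / 3.0) <= 0.02


class TestBanding:
    def test_admissible_choice_by_enumeration(self):
        b, r = choose_bands(256, 0.5)
        assert b * r == 256
        assert (1.0 / b) ** (1.0 / r) <= 0.5
        # no admissible factorization has a midpoint closer to t
        mids = [
            (1.0 / bb) ** (1.0 / (256 // bb))
            for bb in range(1, 257)
            if 256 % bb == 0 and (1.0 / bb) ** (1.0 / (256 // bb)) <= 0.5
        ]
        assert (1.0 / b) ** (1.0 / r) == pytest.approx(max(mids))

    def test_t_equal_one_admits_single_band(self):
        b, r = choose_bands(16, 1.0)
        assert b * r == 16

    def test_tiny_threshold(self):
        # (1/b)^(1/r) is minimized at b=k, r=1 -> 1/k; below that, no banding
        assert choose_bands(4, 0.3) == (4, 1)
        with pytest.raises(ValueError):
            choose_bands(4, 0.01)

    def test_guaranteed_choice_meets_floor(self):
        for t in (0.2, 0.5, 0.8):
            sel = choose_bands_guaranteed(256, t, floor=0.99)
            assert sel is not None
            b, r = sel
            assert 1 - (1 - t**r) ** b >= 0.99
        assert choose_bands_guaranteed(256, 0.001, floor=0.99) is None


class TestLshPairs:
    def test_identical_pair_always_found(self):
        codes = BinaryCodes([[0, 1, 2], [0, 1, 2], [5, 6, 7], [3, 8, 9]], D=10)
        idx = minhash_signatures(codes, k=64, seed=0)
        assert lsh_pairs(idx, codes, 0.9) == [(0, 1)]

    def test_no_false_positives_and_high_recall(self, small_planted):
        _, codes, _ = small_planted
        idx = minhash_signatures(codes, k=256, seed=0)
        for t in (0.3, 0.5, 0.7):
            got = set(lsh_pairs(idx, codes, t))
            truth = set(jaccard_pairs_bruteforce(codes, t))
            assert got <= truth
            assert len(got) / len(truth) >= 0.99

    def test_exact_verify_off_may_include_below_threshold(self, small_planted):
        _, codes, _ = small_planted
        idx = minhash_signatures(codes, k=256, seed=0)
        raw = set(lsh_pairs(idx, codes, 0.5, exact_verify=False))
        verified = set(lsh_pairs(idx, codes, 0.5))
        assert verified <= raw

    def test_edge_nesting_with_shared_banding(self, small_planted):
        # candidates generated once at the grossest threshold: the edge set at
        # a higher threshold is then a subset of that at a lower one
        _, codes, _ = small_planted
        idx = minhash_signatures(codes, k=256, seed=0)
        prev = None
        for t in (0.2, 0.4, 0.6, 0.8):
            cur = set(lsh_pairs(idx, codes, t, band_threshold=0.2))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_brute_force_cutoff_path(self):
        codes = BinaryCodes([[0, 1], [0, 1], [2, 3]], D=4)
        idx = minhash_signatures(codes, k=16, seed=0)
        assert lsh_pairs(idx, codes, 0.9, brute_force_cutoff=10) == [(0, 1)]

    def test_marker_join_is_exact_nonzero_join(self, small_planted):
        _, codes, _ = small_planted
        got = marker_join_pairs(codes)
        truth = set(jaccard_pairs_bruteforce(codes, 1e-12))
        assert got == truth
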