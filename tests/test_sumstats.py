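"""Site classification, per-locus statistics and moment compression."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triadmix.simulate import LocusData
from triadmix.sumstats import (
    FULL_3POP,
    MEANS_ONLY,
    REDUCED_SINGLE_HAPLOID,
    SiteCategory,
    StatConfig,
    classify_site,
    compress_moments,
    locus_stats,
    locus_stats_from_counts,
)


def _naive_classify(ai, aj):
    """Independent brute-force classifier used as the oracle."""
    pi = len(set(ai)) > 1
    pj = len(set(aj)) > 1
    if pi and pj:
        return SiteCategory.SHARED_POLYMORPHISM
    if pi:
        return SiteCategory.PRIVATE_POP_I
    if pj:
        return SiteCategory.PRIVATE_POP_J
    return (
        SiteCategory.FIXED_DIFFERENCE
        if ai[0] != aj[0]
        else SiteCategory.UNINFORMATIVE
    )


class TestClassifySite:
    def test_examples(self):
        assert classify_site([0, 0, 0], [1, 1]) is SiteCategory.FIXED_DIFFERENCE
        assert classify_site([0, 1], [0, 1, 1]) is SiteCategory.SHARED_POLYMORPHISM
        assert classify_site([0, 1, 1], [0, 0]) is SiteCategory.PRIVATE_POP_I
        assert classify_site([0, 0], [0, 1]) is SiteCategory.PRIVATE_POP_J
        assert classify_site([1, 1], [1]) is SiteCategory.UNINFORMATIVE

    def test_exhaustive_against_bruteforce(self):
        """All 2^5 assignments for sample sizes (3, 2) agree with the
        brute-force oracle, and the categories are exhaustive."""
        for bits in itertools.product([0, 1], repeat=5):
            ai, aj = list(bits[:3]), list(bits[3:])
            assert classify_site(ai, aj) is _naive_classify(ai, aj)

    def test_relabeling_symmetry(self):
        for bits in itertools.product([0, 1], repeat=6):
            ai, aj = list(bits[:3]), list(bits[3:])
            flipped = classify_site([1 - a for a in ai], [1 - a for a in aj])
            assert classify_site(ai, aj) is flipped

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            classify_site([], [0, 1])


def _random_locus(rng, n_seq=(3, 2, 1), n_sites=8):
    G = rng.integers(0, 2, size=(n_sites, sum(n_seq))).astype(np.uint8)
    pops = np.repeat(np.arange(3), n_seq)
    return LocusData(genotypes=G, populations=pops, length=100)


def _naive_locus_stats(G, pops):
    """Per-site classification with the scalar oracle, then counting."""
    out = []
    seg_in = lambda v: len(set(v)) > 1
    for i, j in ((0, 1), (0, 2), (1, 2)):
        cats = []
        for site in G:
            ai, aj = site[pops == i], site[pops == j]
            if seg_in(list(ai) + list(aj)):
                cats.append(_naive_classify(list(ai), list(aj)))
        k = len(cats)
        if k == 0:
            out += [0.0, 0.0, 0.0]
        else:
            fixed = sum(c is SiteCategory.FIXED_DIFFERENCE for c in cats)
            shared = sum(c is SiteCategory.SHARED_POLYMORPHISM for c in cats)
            priv = sum(
                c in (SiteCategory.PRIVATE_POP_I, SiteCategory.PRIVATE_POP_J)
                for c in cats
            )
            out += [fixed / k, shared / k, priv / k]
    for p in range(3):
        out.append(sum(seg_in(site[pops == p]) for site in G))
    out.append(sum(seg_in(site) for site in G))
    return np.array(out, dtype=float)


class TestLocusStats:
    def test_agreement_with_bruteforce_on_random_loci(self, rng):
        """10^4 random 6-sequence, 8-site loci match an independent
        naive per-site classifier exactly."""
        cfg = StatConfig(FULL_3POP)
        for _ in range(10_000):
            locus = _random_locus(rng)
            got = locus_stats(locus, cfg)
            want = _naive_locus_stats(locus.genotypes, locus.populations)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_hand_built_example(self):
        """4-site locus, pops (4,4,2): site1 fixed in pair (1,2), site2
        shared in (1,2), sites 3-4 private to pop3; hand-enumerated."""
        pops = np.repeat([0, 1, 2], [4, 4, 2])
        G = np.array(
            [
                [0, 0, 0, 0, 1, 1, 1, 1, 0, 0],   # fixed difference pair12
                [0, 0, 0, 1, 0, 1, 1, 1, 0, 0],   # shared pair12
                [0, 0, 0, 0, 0, 0, 0, 0, 0, 1],   # private pop3
                [0, 0, 0, 0, 0, 0, 0, 0, 1, 0],   # private pop3
            ],
            dtype=np.uint8,
        )
        v = locus_stats(LocusData(G, pops, 100), StatConfig(FULL_3POP))
        names = StatConfig(FULL_3POP).per_locus_names
        got = dict(zip(names, v))
        assert got["pair12_fixed"] == pytest.approx(0.5)
        assert got["pair12_shared"] == pytest.approx(0.5)
        assert got["pair12_private"] == 0.0
        assert got["S_total"] == 4
        assert got["S_pop3"] == 2
        # pair13: site2 private to pop1, sites 3-4 private to pop3
        assert got["pair13_private"] == pytest.approx(1.0)
        # pair23: site1 is ALSO fixed (pop2 all 1, pop3 all 0), site2
        # private to pop2, sites 3-4 private to pop3
        assert got["pair23_fixed"] == pytest.approx(0.25)
        assert got["pair23_private"] == pytest.approx(0.75)

    def test_zero_site_locus_all_zero(self):
        locus = LocusData(
            np.zeros((0, 6), dtype=np.uint8), np.repeat(np.arange(3), 2), 100
        )
        v = locus_stats(locus, StatConfig(FULL_3POP))
        assert (v == 0).all() and len(v) == 13

    def test_pair_proportions_sum_to_one(self, rng):
        """fixed + shared + private = 1 whenever a pair has informative
        sites."""
        cfg = StatConfig(FULL_3POP)
        for _ in range(200):
            locus = _random_locus(rng, n_seq=(3, 3, 2), n_sites=12)
            v = locus_stats(locus, cfg)
            for block in range(3):
                s = v[3 * block : 3 * block + 3].sum()
                assert s == pytest.approx(1.0) or s == 0.0

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_polarity_and_permutation_invariance(self, data):
        """Statistics are invariant to 0<->1 relabeling at any site and
        to permuting sequences within a population."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        locus = _random_locus(rng, n_seq=(3, 3, 2), n_sites=6)
        cfg = StatConfig(FULL_3POP)
        base = locus_stats(locus, cfg)

        flip = rng.random(6) < 0.5
        G2 = locus.genotypes.copy()
        G2[flip] = 1 - G2[flip]
        np.testing.assert_array_equal(
            base, locus_stats(LocusData(G2, locus.populations, 100), cfg)
        )

        perm = np.concatenate(
            [rng.permutation(np.flatnonzero(locus.populations == p)) for p in range(3)]
        )
        G3 = locus.genotypes[:, perm]
        np.testing.assert_array_equal(
            base, locus_stats(LocusData(G3, locus.populations[perm], 100), cfg)
        )


class TestStatConfigs:
    def test_vector_lengths(self):
        assert len(StatConfig(FULL_3POP).per_locus_names) == 13
        assert StatConfig(FULL_3POP).length == 52
        assert len(StatConfig(REDUCED_SINGLE_HAPLOID).per_locus_names) == 10
        assert StatConfig(REDUCED_SINGLE_HAPLOID).length == 40
        assert StatConfig(MEANS_ONLY).length == 13

    def test_reduced_drops_singleton_information(self):
        names = StatConfig(REDUCED_SINGLE_HAPLOID, singleton_pop=2).per_locus_names
        assert "S_pop3" not in names
        assert "pair13_shared" not in names and "pair23_shared" not in names
        assert "pair13_fixed" in names and "pair23_private" in names

    def test_reduced_requires_single_sequence(self):
        cfg = StatConfig(REDUCED_SINGLE_HAPLOID)
        with pytest.raises(ValueError, match="exactly one sequence"):
            cfg.validate_sample_sizes((2, 2, 2))
        cfg.validate_sample_sizes((2, 2, 1))


class TestCompressMoments:
    def test_counts_per_configuration(self, rng):
        X13 = rng.random((30, 13))
        assert compress_moments(X13, StatConfig(FULL_3POP)).shape == (52,)
        X10 = rng.random((30, 10))
        assert compress_moments(X10, StatConfig(REDUCED_SINGLE_HAPLOID)).shape == (40,)
        assert compress_moments(X13, StatConfig(MEANS_ONLY)).shape == (13,)

    def test_constant_statistic_convention(self):
        """A statistic constant across loci: mean c, variance 0, and
        skewness/kurtosis reported as 0."""
        X = np.column_stack([np.full(20, 3.5)] * 13)
        v = compress_moments(X, StatConfig(FULL_3POP)).reshape(13, 4)
        np.testing.assert_allclose(v[:, 0], 3.5)
        np.testing.assert_allclose(v[:, 1:], 0.0)

    def test_moments_match_scipy_definitions(self, rng):
        from scipy import stats as sps

        X = rng.random((50, 13))
        v = compress_moments(X, StatConfig(FULL_3POP)).reshape(13, 4)
        np.testing.assert_allclose(v[:, 0], X.mean(0))
        np.testing.assert_allclose(v[:, 1], X.var(0, ddof=1))
        np.testing.assert_allclose(v[:, 2], sps.skew(X, axis=0))
        np.testing.assert_allclose(v[:, 3], sps.kurtosis(X, axis=0, fisher=False))

    def test_too_few_loci_rejected(self):
        with pytest.raises(ValueError):
            compress_moments(np.ones((1, 13)), StatConfig(FULL_3POP))

    def test_counts_path_matches_matrix_path(self, rng):
        """locus_stats_from_counts agrees with the genotype-matrix path."""
        locus = _random_locus(rng, n_seq=(2, 2, 2), n_sites=10)
        n_seq = np.array([2, 2, 2])
        derived = np.stack(
            [locus.genotypes[:, locus.populations == p].sum(1) for p in range(3)],
            axis=1,
        )
        cfg = StatConfig(FULL_3POP)
        np.testing.assert_array_equal(
            locus_stats(locus, cfg), locus_stats_from_counts(derived, n_seq, cfg)
        )
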