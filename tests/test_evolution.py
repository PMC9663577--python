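"""K2P distances, LTR dating, expansion profiling, TFBS pair search."""

import math

import numpy as np
import pytest

from polytereg.evolution import (
    K2PSaturationError,
    K2PUndefinedError,
    cross_lineage_te_distance,
    detect_modes,
    find_similar_tfbs_pairs,
    k2p_distance,
    k2p_distance_unaligned,
    shared_cross_lineage_mode,
    te_insertion_age,
    tfbs_expansion_profile,
)
from polytereg.simulate import mutate_k2p, simulate_ltr_pairs


def _pair_with_counts(sites, n_ts, n_tv):
    """Aligned pair with exact transition/transversion counts."""
    a = "A" * sites
    b = "G" * n_ts + "C" * n_tv + "A" * (sites - n_ts - n_tv)
    return a, b


class TestK2PDistance:
    def test_identical_sequences(self):
        r = k2p_distance("ACGTACGT", "ACGTACGT")
        assert (r.p, r.q, r.distance) == (0.0, 0.0, 0.0)

    def test_closed_form_example(self):
        a, b = _pair_with_counts(100, 10, 5)
        r = k2p_distance(a, b)
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.90)
        assert r.p == 0.10 and r.q == 0.05
        assert r.distance == pytest.approx(expected, abs=1e-12)

    def test_gapped_columns_ignored(self):
        # every mismatching column is gapped -> distance 0 on the rest
        r = k2p_distance("AC-G-T", "ACCGAT")
        assert r.distance == 0.0 and r.sites == 4

    def test_ambiguous_bases_excluded(self):
        r = k2p_distance("ACGN", "ACGT")
        assert r.sites == 3 and r.distance == 0.0

    def test_saturation_raises_distinct_error(self):
        a, b = _pair_with_counts(100, 45, 15)  # 1-2p-q = -0.05
        with pytest.raises(K2PSaturationError):
            k2p_distance(a, b)
        with pytest.raises(K2PUndefinedError):
            k2p_distance("---", "AAA")

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        for _ in range(20):
            a = "".join(rng.choice(list(bases), 200))
            b = "".join(rng.choice(list(bases), 200))
            try:
                d1 = k2p_distance(a, b).distance
            except K2PSaturationError:
                with pytest.raises(K2PSaturationError):
                    k2p_distance(b, a)
                continue
            assert k2p_distance(b, a).distance == pytest.approx(d1, abs=1e-15)

    def test_correction_expands_raw_mismatch_proportion(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            sites = 500
            n_ts = int(rng.integers(0, 120))
            n_tv = int(rng.integers(0, 120))
            a, b = _pair_with_counts(sites, n_ts, n_tv)
            try:
                r = k2p_distance(a, b)
            except K2PSaturationError:
                continue
            assert r.distance >= r.p + r.q - 1e-12


class TestTEInsertionAge:
    def test_identical_ltrs_age_zero(self):
        age = te_insertion_age("te1", "ACGT" * 100, "ACGT" * 100)
        assert age.age_years == 0.0

    def test_age_formula_with_default_rate(self):
        # construct LTR pair with known K2P distance ~ 0.026
        sites = 2000
        n_ts = 34
        n_tv = 17
        a, b = _pair_with_counts(sites, n_ts, n_tv)
        d = k2p_distance(a, b).distance
        age = te_insertion_age("te1", a, b)
        assert age.age_years == pytest.approx(d / (2 * 1.3e-8))

    def test_age_linear_in_inverse_rate(self):
        a, b = _pair_with_counts(1000, 20, 10)
        age1 = te_insertion_age("t", a, b, mutation_rate=1.3e-8).age_years
        age2 = te_insertion_age("t", a, b, mutation_rate=2.6e-8).age_years
        assert age1 == pytest.approx(2 * age2)

    def test_missing_ltr_rejected(self):
        with pytest.raises(ValueError):
            te_insertion_age("t", "", "ACGT")

    def test_parameter_recovery_on_simulated_copies(self):
        pairs = simulate_ltr_pairs(40, 1e6, ltr_length=1000, seed=3)
        ages = [te_insertion_age(t, l5, l3).age_years for t, l5, l3, _ in pairs]
        assert np.median(ages) == pytest.approx(1e6, rel=0.10)


class TestExpansionProfile:
    def _clones(self, n, branch_years, seed, length=300):
        rng = np.random.default_rng(seed)
        anc = rng.integers(0, 4, size=length).astype(np.uint8)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        return [
            bases[mutate_k2p(anc, branch_years, 1.3e-8, rng)].tobytes().decode()
            for _ in range(n)
        ]

    def test_single_expansion_is_unimodal_at_twice_branch_length(self):
        seqs = self._clones(25, 2e6, seed=4)
        prof = tfbs_expansion_profile(seqs, n_sample=25, seed=0)
        assert len(prof.modes) == 1
        expected = 2 * 1.3e-8 * 2e6  # 0.052
        assert prof.modes[0][0] == pytest.approx(expected, abs=0.02)

    def test_two_expansion_waves_give_two_modes(self):
        recent = self._clones(20, 4e5, seed=5)
        # ancient wave: clones of a diverged ancestor
        ancient = self._clones(20, 7e6, seed=6)
        dists_r = tfbs_expansion_profile(recent, n_sample=20, seed=0).distances
        dists_a = tfbs_expansion_profile(ancient, n_sample=20, seed=0).distances
        modes = detect_modes(np.concatenate([dists_r, dists_a]))
        assert len(modes) >= 2
        locs = sorted(m[0] for m in modes[:2])
        assert locs[0] == pytest.approx(2 * 1.3e-8 * 4e5, abs=0.02)
        assert locs[1] == pytest.approx(2 * 1.3e-8 * 7e6, abs=0.05)

    def test_sampling_reproducible_under_seed(self):
        seqs = self._clones(30, 1e6, seed=7)
        p1 = tfbs_expansion_profile(seqs, n_sample=10, seed=9)
        p2 = tfbs_expansion_profile(seqs, n_sample=10, seed=9)
        assert np.array_equal(p1.distances, p2.distances)

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            tfbs_expansion_profile(["ACGT"], n_sample=5, seed=0)


class TestFindSimilarPairs:
    def test_duplicate_sequence_full_identity(self):
        rng = np.random.default_rng(8)
        s = "".join(rng.choice(list("ACGT"), 120))
        pairs = find_similar_tfbs_pairs([s, s])
        assert len(pairs) == 1
        i, j, ident, cov = pairs[0]
        assert ident == pytest.approx(100.0) and cov == pytest.approx(100.0)

    def test_half_shared_segment_rejected_on_coverage(self):
        rng = np.random.default_rng(9)
        shared = "".join(rng.choice(list("ACGT"), 100))
        a = shared + "".join(rng.choice(list("ACGT"), 100))
        b = shared + "".join(rng.choice(list("ACGT"), 100))
        # shared prefix is 50% of each sequence: coverage <= 70 fails
        assert find_similar_tfbs_pairs([a, b]) == []

    def test_planted_family_recovered_without_decoy_pairs(self):
        rng = np.random.default_rng(10)
        anc = rng.integers(0, 4, size=150).astype(np.uint8)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        family = [
            bases[mutate_k2p(anc, 3e6, 1.3e-8, rng)].tobytes().decode()
            for _ in range(12)
        ]
        decoys = ["".join(rng.choice(list("ACGT"), 150)) for _ in range(30)]
        seqs = family + decoys
        pairs = find_similar_tfbs_pairs(seqs)
        fam_idx = set(range(12))
        fam_pairs = [p for p in pairs if p[0] in fam_idx and p[1] in fam_idx]
        assert not [p for p in pairs if p[0] not in fam_idx or p[1] not in fam_idx]
        assert len(fam_pairs) >= 0.9 * (12 * 11 / 2)


class TestCrossLineage:
    def test_small_lineage_skipped(self, caplog):
        rng = np.random.default_rng(11)
        big = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(30)]
        small = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(10)]
        profiles = cross_lineage_te_distance(
            {"A": big, "B": big, "rye": small}, n_sample=5, seed=0
        )
        assert all("rye" not in pair for pair in profiles)

    def test_shared_mode_requires_two_pairs(self):
        assert shared_cross_lineage_mode({}) is None

    def test_unaligned_distance_matches_aligned_for_equal_length(self):
        a, b = "ACGTACGTACGTACGTACGA", "ACGTACGTACGTACGTACGG"
        assert k2p_distance_unaligned(a, b).distance == pytest.approx(
            k2p_distance(a, b).distance
        )
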