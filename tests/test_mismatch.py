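import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psira import (
    build_index,
    encode_reference,
    exact_align,
    k_mismatch_align,
    longest_matching_prefix,
    rightmost_compare,
)
from psira.errors import ParameterError
from psira.fixtures import (
    LinearErrorProfile,
    generate_genome,
    oracle_hamming_scan,
    sample_reads,
)
from psira.mismatch import Candidate, MismatchMask, generate_level_candidates
from psira.reference import decode_codes, encode_query

from conftest import LMP_PATTERN, LMP_REF


class TestLongestMatchingPrefix:
    def test_worked_example(self, lmp_index):
        # reference contains AGGTCGATTC but not AGGTCGATTCG
        assert LMP_REF.find("AGGTCGATTC") >= 0
        assert LMP_REF.find("AGGTCGATTCG") == -1
        assert longest_matching_prefix(lmp_index, LMP_PATTERN) == 10

    def test_present_pattern_returns_length(self, lmp_index):
        assert longest_matching_prefix(lmp_index, "AGGTCGATTC") == 10
        assert longest_matching_prefix(lmp_index, LMP_REF) == len(LMP_REF)

    def test_matches_brute_force_lcp(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            g = generate_genome(int(rng.integers(30, 800)), int(rng.integers(1e6)))
            d = int(rng.choice([1, 2, 3]))
            idx = build_index(g, d, 2)
            q = decode_codes(rng.integers(0, 4, int(rng.integers(5, 25))).astype(np.uint8))
            s = g.decode()
            expected = max(
                len_common_prefix(s[p:], q) for p in range(0, g.n, d)
            )
            if any(s[p:].startswith(q) for p in range(0, g.n, d)):
                expected = len(q)
            assert longest_matching_prefix(idx, q) == expected


def len_common_prefix(a, b):
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


class TestRightmostCompare:
    def test_single_mismatch_later_wins(self):
        assert rightmost_compare(MismatchMask(8, (7,)), MismatchMask(8, (6,))) == -1

    def test_subset_example(self):
        a, b = MismatchMask(8, (5,)), MismatchMask(8, (5, 7))
        assert a.b_value() == 0b11111011 == 251
        assert b.b_value() == 0b11111010 == 250
        assert rightmost_compare(a, b) == -1

    def test_empty_mask_first(self):
        empty = MismatchMask(8, ())
        for positions in [(0,), (7,), (3, 5)]:
            assert rightmost_compare(empty, MismatchMask(8, positions)) == -1

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            rightmost_compare(MismatchMask(8, ()), MismatchMask(9, ()))

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.integers(0, 11), max_size=4, unique=True),
        st.lists(st.integers(0, 11), max_size=4, unique=True),
    )
    def test_consistent_with_b_integer(self, pa, pb):
        a = MismatchMask(12, tuple(sorted(pa)))
        b = MismatchMask(12, tuple(sorted(pb)))
        cmp = rightmost_compare(a, b)
        assert cmp == (-1 if a.b_value() > b.b_value() else (1 if a.b_value() < b.b_value() else 0))
        assert rightmost_compare(b, a) == -cmp


class TestCandidateGeneration:
    def _root(self, pattern, failure_prefix, offset=0):
        codes = encode_query(pattern)
        root = Candidate(codes.copy(), (), offset)
        root.failure_prefix = failure_prefix
        return root, codes

    def test_level1_prunes_right_of_l(self):
        root, codes = self._root(LMP_PATTERN, 10)
        out = generate_level_candidates([root], codes)
        positions = [c.altered_positions[0] for c in out]
        assert sorted(set(positions), reverse=True) == list(range(10, -1, -1))
        assert max(positions) == 10  # the last five bases are never altered
        assert positions == sorted(positions, reverse=True)

    def test_three_bases_per_position(self):
        root, codes = self._root("ACGTACGTACGTACGT", 3)
        out = generate_level_candidates([root], codes)
        assert len(out) == 3 * 4  # positions 3..0
        for cand in out:
            p = cand.altered_positions[0]
            assert cand.pattern[p] != codes[p]
            assert cand.level == 1

    def test_level2_strictly_right_of_parent(self):
        # new alterations go right of the previous one, up to the new prefix
        root, codes = self._root("ACGTACGTACGTACGT", 15)
        parent = next(
            c for c in generate_level_candidates([root], codes)
            if c.altered_positions == (6,)
        )
        parent.failure_prefix = 11
        children = generate_level_candidates([parent], codes)
        news = {c.altered_positions[1] for c in children}
        assert news == set(range(7, 12))
        assert all(c.altered_positions == tuple(sorted(c.altered_positions)) for c in children)

    def test_unsearched_parent_rejected(self):
        codes = encode_query("ACGTACGT")
        with pytest.raises(ParameterError):
            generate_level_candidates([Candidate(codes.copy(), (), 0)], codes)


class TestKMismatchAlign:
    def test_k0_equals_exact(self, genome_1k):
        idx = build_index(genome_1k, 2, 2)
        pat = genome_1k.decode(17, 41)
        exact = [(h.gstart, h.mismatch_positions) for h in exact_align(idx, pat)]
        kmm = [(a.gstart, mk.positions) for a, mk in k_mismatch_align(idx, pat, 0)]
        assert kmm == exact

    @pytest.mark.parametrize("engine", ["fast", "python"])
    def test_oracle_equivalence(self, engine):
        rng = np.random.default_rng(31)
        for _ in range(30):
            g = generate_genome(int(rng.integers(50, 1200)), int(rng.integers(1e6)))
            d = int(rng.choice([1, 2, 4]))
            k = int(rng.integers(1, 4))
            idx = build_index(g, d, int(rng.choice([1, 2, 4])))
            m = int(rng.integers(12, 30))
            pat = _draw_pattern(rng, g, m)
            got = [(a.gstart, mk.positions) for a, mk in k_mismatch_align(idx, pat, k, engine=engine)]
            assert len(got) == len(set(got))
            assert set(got) == oracle_hamming_scan(g, pat, k)

    def test_engines_identical(self):
        rng = np.random.default_rng(32)
        for _ in range(15):
            g = generate_genome(int(rng.integers(50, 600)), int(rng.integers(1e6)))
            idx = build_index(g, int(rng.choice([1, 2, 3])), 2)
            pat = _draw_pattern(rng, g, int(rng.integers(12, 24)))
            k = int(rng.integers(0, 4))
            fast = k_mismatch_align(idx, pat, k, engine="fast")
            python = k_mismatch_align(idx, pat, k, engine="python")
            assert fast == python

    def test_exact_mismatch_counts_per_level(self):
        g = generate_genome(400, seed=77)
        idx = build_index(g, 2, 2)
        pat_codes = g.codes[50:70].copy()
        pat_codes[15] = (pat_codes[15] + 1) % 4
        res = k_mismatch_align(idx, decode_codes(pat_codes), 2)
        for aln, mask in res:
            assert aln.mismatch_positions == mask.positions
            window = idx.genome.codes[aln.gstart : aln.gstart + 20]
            true_mask = tuple(
                int(p) for p in np.flatnonzero(window != encode_query(decode_codes(pat_codes)))
            )
            assert true_mask == mask.positions

    def test_rightmost_output_order(self):
        g = generate_genome(1500, seed=99)
        idx = build_index(g, 2, 2)
        pat = _draw_pattern(np.random.default_rng(99), g, 18)
        res = k_mismatch_align(idx, pat, 3)
        bs = [mk.b_value() for _, mk in res]
        assert bs == sorted(bs, reverse=True)
        starts_within = [
            (mk.b_value(), a.gstart) for a, mk in res
        ]
        assert starts_within == sorted(starts_within, key=lambda t: (-t[0], t[1]))

    def test_injected_errors_recovered(self):
        g = generate_genome(5000, seed=55)
        idx = build_index(g, 4, 4)
        reads = sample_reads(g, 50, 30, LinearErrorProfile(0.02, 0.25), seed=56)
        for read, start, mask in reads:
            e = len(mask)
            res = k_mismatch_align(idx, read.sequence, max(e, 1))
            assert any(a.gstart == start and mk.positions == mask for a, mk in res)

    def test_negative_k_rejected(self, fig1_index):
        with pytest.raises(ParameterError):
            k_mismatch_align(fig1_index, "GGTCGATTCGGGACC", -1)


def _draw_pattern(rng, g, m):
    if rng.random() < 0.5 and g.n > m:
        s = int(rng.integers(0, g.n - m))
        codes = g.codes[s : s + m].copy()
        for _ in range(int(rng.integers(0, 3))):
            p = int(rng.integers(0, m))
            codes[p] = (codes[p] + 1 + int(rng.integers(0, 3))) % 4
        return decode_codes(codes)
    return decode_codes(rng.integers(0, 4, m).astype(np.uint8))
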