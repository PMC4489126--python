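"""Pair counting, probabilities, log-odds scores, entropy, composition."""

import numpy as np
import pytest

import oracles
from conftest import random_blocks, to_alignment_blocks
from famsubmat import (
    AlignmentBlock,
    ProbabilityTables,
    SegmentDefinition,
    background_frequencies,
    build_matrix,
    column_conservation,
    composition,
    count_pairs,
    expected_probabilities,
    grouped_fraction,
    log_odds,
    observed_probabilities,
    relative_entropy,
)
from famsubmat.alphabet import AA_INDEX, AA_ORDER

A, C, L = AA_INDEX["A"], AA_INDEX["C"], AA_INDEX["L"]


def tables_for(block):
    t = count_pairs([block])
    O = observed_probabilities(t)
    p = background_frequencies(O)
    e = expected_probabilities(p)
    return t, ProbabilityTables(O, p, e)


class TestToyExample:
    """The 3-sequence, 2-column block worked by hand: columns AAC and LLL."""

    def test_pair_counts(self, toy_block):
        t = count_pairs([toy_block])
        assert t.counts[A, A] == 1
        assert t.counts[A, C] == t.counts[C, A] == 2
        assert t.counts[L, L] == 3
        assert t.total_pairs == 6

    def test_probabilities(self, toy_block):
        _, probs = tables_for(toy_block)
        assert probs.observed[A, A] == pytest.approx(1 / 6)
        assert probs.observed[A, C] == pytest.approx(1 / 3)
        assert probs.observed[L, L] == pytest.approx(1 / 2)
        assert probs.background[A] == pytest.approx(1 / 3)
        assert probs.background[C] == pytest.approx(1 / 6)
        assert probs.background[L] == pytest.approx(1 / 2)
        assert probs.expected[A, A] == pytest.approx(1 / 9)
        assert probs.expected[A, C] == pytest.approx(1 / 9)
        assert probs.expected[L, L] == pytest.approx(1 / 4)

    def test_scores(self, toy_block):
        _, probs = tables_for(toy_block)
        m = log_odds(probs)
        assert m.scores_real[A, A] == pytest.approx(2 * np.log2(1.5))
        assert m.scores_real[A, C] == pytest.approx(2 * np.log2(3))
        assert m.scores_real[L, L] == pytest.approx(2.0)
        assert m.scores_int[A, A] == 1
        assert m.scores_int[A, C] == 3
        assert m.scores_int[L, L] == 2

    def test_relative_entropy(self, toy_block):
        _, probs = tables_for(toy_block)
        h = relative_entropy(probs)
        expect = (1 / 6) * np.log2(1.5) + (1 / 3) * np.log2(3) + 0.5
        assert h == pytest.approx(expect)
        assert h == pytest.approx(1.1258, abs=5e-5)
        assert relative_entropy(probs, "paper_scaled") == pytest.approx(2 * h)

    def test_end_to_end_build(self, toy_alignment):
        m = build_matrix(toy_alignment, redundancy=None)
        assert m.scores_int[A, A] == 1
        assert m.scores_int[A, C] == 3
        assert m.scores_int[L, L] == 2
        # unobserved cells take the floor = most penalised observed exchange
        assert m.scores_real[C, C] == pytest.approx(min(
            2 * np.log2(1.5), 2 * np.log2(3), 2.0
        ))
        assert m.relative_entropy == pytest.approx(1.1258, abs=5e-5)


class TestCountPairsRules:
    def test_gap_column_contributes_partial(self):
        seg = SegmentDefinition("b", 0, 1)
        block = AlignmentBlock(seg, (("r1", "A"), ("r2", "-"), ("r3", "C")))
        t = count_pairs([block])
        assert t.counts[A, C] == 1
        assert t.total_pairs == 1

    def test_ambiguity_letters_excluded(self):
        seg = SegmentDefinition("b", 0, 1)
        block = AlignmentBlock(seg, (("r1", "A"), ("r2", "X"), ("r3", "A")))
        t = count_pairs([block])
        assert t.counts[A, A] == 1
        assert t.total_pairs == 1

    def test_two_identical_blocks_double_counts(self, toy_block):
        one = count_pairs([toy_block])
        two = count_pairs([toy_block, toy_block])
        assert np.array_equal(two.counts, 2 * one.counts)

    def test_empty_block_list_is_error(self):
        with pytest.raises(ValueError):
            count_pairs([])

    def test_single_column_pair(self):
        seg = SegmentDefinition("b", 0, 1)
        block = AlignmentBlock(seg, (("r1", "A"), ("r2", "A")))
        _, probs = tables_for(block)
        assert probs.observed[A, A] == 1.0
        assert probs.background[A] == 1.0
        m = log_odds(probs)
        assert m.scores_real[A, A] == 0.0  # O == e == 1


class TestOracleEquivalence:
    """Vectorised pipeline vs brute-force enumeration on random small blocks."""

    def test_counts_and_probabilities_match_brute_force(self):
        rng = np.random.default_rng(2024)
        raw = random_blocks(rng, 300)
        blocks = to_alignment_blocks(raw)
        # counts (exact integers)
        t = count_pairs(blocks)
        f = oracles.brute_pair_counts(raw)
        for i, x in enumerate(AA_ORDER):
            for j, y in enumerate(AA_ORDER):
                key = tuple(sorted((x, y)))
                assert t.counts[i, j] == f.get(key, 0), (x, y)
        # probabilities and scores to 1e-12
        O = observed_probabilities(t)
        p = background_frequencies(O)
        e = expected_probabilities(p)
        obs = oracles.brute_observed(f)
        bg = oracles.brute_background(obs)
        exp = oracles.brute_expected(bg)
        for i, x in enumerate(AA_ORDER):
            assert p[i] == pytest.approx(bg[x], abs=1e-12)
            for j, y in enumerate(AA_ORDER):
                key = tuple(sorted((x, y)))
                assert O[i, j] == pytest.approx(obs.get(key, 0.0), abs=1e-12)
                assert e[i, j] == pytest.approx(exp[key], abs=1e-12)
        probs = ProbabilityTables(O, p, e)
        m = log_odds(probs)
        sc = oracles.brute_scores(obs, exp)
        for (x, y), v in sc.items():
            assert m.scores_real[AA_INDEX[x], AA_INDEX[y]] == pytest.approx(
                v, abs=1e-12
            )
        assert relative_entropy(probs) == pytest.approx(
            oracles.brute_relative_entropy(obs, exp), abs=1e-12
        )


class TestMassAndSymmetry:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_probability_mass_conserved(self, seed):
        rng = np.random.default_rng(seed)
        blocks = to_alignment_blocks(random_blocks(rng, 30))
        t = count_pairs(blocks)
        O = observed_probabilities(t)
        p = background_frequencies(O)
        e = expected_probabilities(p)
        tri = np.tril_indices(20)
        assert O[tri].sum() == pytest.approx(1.0, abs=1e-9)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert e[tri].sum() == pytest.approx(1.0, abs=1e-9)
        for mtx in (t.counts, O, e):
            assert np.allclose(mtx, mtx.T)

    def test_entropy_nonnegative_and_scaling(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            blocks = to_alignment_blocks(random_blocks(rng, 10))
            t = count_pairs(blocks)
            O = observed_probabilities(t)
            p = background_frequencies(O)
            probs = ProbabilityTables(O, p, expected_probabilities(p))
            h = relative_entropy(probs)
            assert h >= 0
            assert relative_entropy(probs, "paper_scaled") == pytest.approx(2 * h)

    def test_scale_linearity(self, toy_block):
        _, probs = tables_for(toy_block)
        m2 = log_odds(probs, scale=2.0)
        m4 = log_odds(probs, scale=4.0)
        assert np.allclose(m4.scores_real, 2 * m2.scores_real)

    def test_uniform_observed_gives_uniform_background(self):
        O = np.full((20, 20), 0.0)
        tri = np.tril_indices(20)
        O[tri] = 1 / 210
        O = np.maximum(O, O.T)
        p = background_frequencies(O)
        assert np.allclose(p, 1 / 20)


class TestPermutationEquivariance:
    def test_row_and_block_order_irrelevant(self):
        rng = np.random.default_rng(7)
        raw = random_blocks(rng, 12)
        blocks = to_alignment_blocks(raw)
        base = count_pairs(blocks).counts
        shuffled_rows = to_alignment_blocks(
            [list(rng.permutation(rows)) for rows in raw]
        )
        assert np.array_equal(count_pairs(shuffled_rows).counts, base)
        order = rng.permutation(len(blocks))
        assert np.array_equal(
            count_pairs([blocks[i] for i in order]).counts, base
        )

    def test_residue_relabeling_permutes_matrix(self):
        rng = np.random.default_rng(8)
        raw = random_blocks(rng, 12, gap_prob=0.0, ambig_prob=0.0)
        perm = rng.permutation(20)
        mapping = {AA_ORDER[i]: AA_ORDER[perm[i]] for i in range(20)}
        relabeled = [
            ["".join(mapping[ch] for ch in row) for row in rows] for rows in raw
        ]
        f1 = count_pairs(to_alignment_blocks(raw)).counts
        f2 = count_pairs(to_alignment_blocks(relabeled)).counts
        assert np.array_equal(f2[np.ix_(perm, perm)], f1)


class TestComposition:
    def test_single_column(self):
        seg = SegmentDefinition("b", 0, 1)
        block = AlignmentBlock(seg, (("r1", "L"), ("r2", "L"), ("r3", "L"), ("r4", "V")))
        prof = composition([block])
        assert prof["L"] == pytest.approx(0.75)
        assert prof["V"] == pytest.approx(0.25)
        assert prof.fractions.sum() == pytest.approx(1.0)

    def test_gaps_do_not_dilute(self):
        seg = SegmentDefinition("b", 0, 1)
        block = AlignmentBlock(seg, (("r1", "L"), ("r2", "-"), ("r3", "L")))
        assert composition([block])["L"] == pytest.approx(1.0)

    def test_grouped_fraction(self):
        seg = SegmentDefinition("b", 0, 1)
        block = AlignmentBlock(seg, (("r1", "R"), ("r2", "K"), ("r3", "L"), ("r4", "L")))
        prof = composition([block])
        assert grouped_fraction(prof, "RKHDENQ") == pytest.approx(0.5)
        assert grouped_fraction(prof, AA_ORDER) == pytest.approx(1.0)
        assert grouped_fraction(prof, "") == 0.0
        with pytest.raises(KeyError):
            grouped_fraction(prof, "J")


class TestConservation:
    def test_monomorphic_column(self):
        seg = SegmentDefinition("b", 0, 1)
        block = AlignmentBlock(
            seg, (("r1", "N"), ("r2", "N"), ("r3", "N"), ("r4", "N"))
        )
        prof = column_conservation(block)
        assert prof.frequencies[0, AA_INDEX["N"]] == 1.0
        assert prof.max_frequency("N") == 1.0

    def test_gap_excluded_denominator(self):
        seg = SegmentDefinition("b", 0, 1)
        block = AlignmentBlock(seg, (("r1", "N"), ("r2", "N"), ("r3", "D"), ("r4", "-")))
        prof = column_conservation(block)
        assert prof.frequencies[0, AA_INDEX["N"]] == pytest.approx(2 / 3)
        assert prof.frequencies[0, AA_INDEX["D"]] == pytest.approx(1 / 3)

    def test_all_gap_column_flagged(self):
        seg = SegmentDefinition("b", 0, 2)
        block = AlignmentBlock(seg, (("r1", "N-"), ("r2", "N-")))
        prof = column_conservation(block)
        assert list(prof.empty_columns) == [False, True]
        assert prof.max_frequency("N") == 1.0  # empty column excluded from max
        assert prof.max_residue[1] is None
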