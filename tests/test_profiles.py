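"""Tests for frequency profiles, pseudo-counts and profile-derived sequences."""

import numpy as np
import pytest

from pcdt.alphabet import AAINDEX_ORDER
from pcdt.pdt import PDTParams, ProteinSequence, transform
from pcdt.profiles import (
    AlignmentColumn,
    EmptyColumnError,
    FrequencyProfile,
    PseudoCountModel,
    PseudoCountModelError,
    blosum62_matrices,
    column_frequencies,
    default_pseudo_count_model,
    filter_alignment,
    nth_sequence,
    profile_from_alignment,
    profile_pdt,
    pseudo_counts,
    psiblast_command,
    target_frequencies,
)
from pcdt.synthetic import make_degenerate_profile

from conftest import pseudo_count_oracle, random_sequences, target_frequency_oracle


def col(letters):
    return column_frequencies(list(letters))


def uniform_identity_model(beta_pc=10.0):
    """Uniform background with q = I/20: pseudo-counts reproduce f exactly."""
    p = np.full(20, 1 / 20)
    q = np.eye(20) / 20
    return PseudoCountModel(beta_pc=beta_pc, background=p, q=q, mode="frequency")


class TestColumnFrequencies:
    def test_single_residue_column(self):
        c = col("AAA")
        assert c.freqs[AAINDEX_ORDER.index("A")] == 1.0
        assert c.distinct_count == 1

    def test_counting_with_gaps(self):
        c = col("AC-C")
        assert c.freqs[AAINDEX_ORDER.index("A")] == pytest.approx(1 / 3)
        assert c.freqs[AAINDEX_ORDER.index("C")] == pytest.approx(2 / 3)
        assert c.distinct_count == 2

    def test_all_gap_column_raises(self):
        with pytest.raises(EmptyColumnError):
            col("--")

    def test_freqs_sum_to_one(self, rng):
        letters = [AAINDEX_ORDER[i] for i in rng.integers(0, 20, size=30)]
        c = column_frequencies(letters)
        assert c.freqs.sum() == pytest.approx(1.0)


class TestFilterAlignment:
    def test_exact_duplicate_of_query_removed(self):
        query = "ACDEFGHIKL"
        msa = [query, query, "ACDEFGHIKW"]
        kept = filter_alignment(msa, query)
        assert kept == [query, "ACDEFGHIKW"]

    def test_all_below_threshold_unchanged(self):
        query = "ACDEFGHIKL"
        msa = [query, "WWWWWWWWWW", "ACDEWWWWWW"]
        assert filter_alignment(msa, query) == msa

    def test_97_of_100_positions_retained(self):
        query = "A" * 100
        row = "C" * 3 + "A" * 97  # 97% identity -> below the 98% cutoff
        assert filter_alignment([query, row], query) == [query, row]

    def test_98_of_100_positions_removed(self):
        query = "A" * 100
        row = "C" * 2 + "A" * 98
        assert filter_alignment([query, row], query) == [query]

    def test_gap_positions_excluded_from_identity(self):
        query = "ACDEFGHIKL"
        # identical on every aligned (non-gap) position -> 100%, removed
        row = "ACDEF---KL"
        assert filter_alignment([query, row], query) == [query]


class TestPseudoCounts:
    def test_matches_loop_oracle_default_model(self, rng):
        model = default_pseudo_count_model()
        f = rng.dirichlet(np.ones(20))
        c = AlignmentColumn(freqs=f, distinct_count=int((f > 0).sum()))
        g = pseudo_counts(c, model)
        oracle = pseudo_count_oracle(
            f.tolist(), model.background.tolist(), model.q.tolist(), "frequency"
        )
        np.testing.assert_allclose(g, oracle, atol=1e-12)

    def test_matches_loop_oracle_score_mode(self, rng):
        model = default_pseudo_count_model(mode="score")
        f = rng.dirichlet(np.ones(20))
        c = AlignmentColumn(freqs=f, distinct_count=20)
        oracle = pseudo_count_oracle(
            f.tolist(), model.background.tolist(), model.q.tolist(), "score"
        )
        np.testing.assert_allclose(pseudo_counts(c, model), oracle, atol=1e-12)

    def test_concentrated_column_single_term_sum(self):
        model = default_pseudo_count_model()
        c = col("AAAA")
        g = pseudo_counts(c, model)
        a = AAINDEX_ORDER.index("A")
        expected = model.q[:, a] / model.background[a]
        np.testing.assert_allclose(g, expected, atol=1e-12)

    def test_zero_background_rejected(self):
        p = np.full(20, 1 / 20)
        p[0] = 0.0
        model = PseudoCountModel(background=p, q=np.eye(20) / 20)
        with pytest.raises(PseudoCountModelError):
            pseudo_counts(col("AC"), model)

    def test_identity_q_uniform_background_reproduces_f(self):
        model = uniform_identity_model()
        c = col("AACC")
        np.testing.assert_allclose(pseudo_counts(c, model), c.freqs, atol=1e-12)


class TestTargetFrequencies:
    def test_single_residue_column_is_fully_pseudo_count_driven(self):
        model = default_pseudo_count_model()
        c = col("AAAAA")  # alpha = 0
        t = target_frequencies(c, model)
        g = pseudo_counts(c, model)
        np.testing.assert_allclose(t, g / g.sum(), atol=1e-12)

    def test_rows_sum_to_one_random_columns(self, rng):
        model = default_pseudo_count_model()
        for _ in range(20):
            letters = [AAINDEX_ORDER[i] for i in rng.integers(0, 20, size=8)]
            t = target_frequencies(column_frequencies(letters), model)
            assert t.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(t >= 0)

    def test_two_residue_toy_column_hand_evaluated(self):
        # uniform background, identity-like q: g = f, so the blend returns f
        model = uniform_identity_model()
        c = col("AACC")
        t = target_frequencies(c, model)
        np.testing.assert_allclose(t, c.freqs, atol=1e-12)

    def test_matches_blend_oracle(self, rng):
        model = default_pseudo_count_model()
        letters = [AAINDEX_ORDER[i] for i in rng.integers(0, 20, size=12)]
        c = column_frequencies(letters)
        t = target_frequencies(c, model)
        oracle = target_frequency_oracle(
            c.freqs.tolist(), c.distinct_count,
            model.background.tolist(), model.q.tolist(), "frequency",
        )
        np.testing.assert_allclose(t, oracle, atol=1e-12)

    def test_modal_residue_maximal_as_column_approaches_certainty(self):
        model = default_pseudo_count_model()
        c = column_frequencies(list("A" * 50 + "C"))
        t = target_frequencies(c, model)
        assert np.argmax(t) == AAINDEX_ORDER.index("A")

    def test_score_mode_still_a_distribution(self):
        model = default_pseudo_count_model(mode="score")
        t = target_frequencies(col("AACW"), model)
        assert t.sum() == pytest.approx(1.0)
        assert np.all(t >= 0)


class TestBlosumModel:
    def test_q_symmetric_and_normalized(self):
        _, q = blosum62_matrices()
        np.testing.assert_allclose(q, q.T, atol=1e-15)
        assert q.sum() == pytest.approx(1.0)
        assert np.all(q > 0)

    def test_background_sums_to_one(self):
        model = default_pseudo_count_model()
        assert model.background.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_mode_rejected(self):
        with pytest.raises(PseudoCountModelError):
            PseudoCountModel(mode="blosum")


class TestProfileFromAlignment:
    def test_row_stochastic(self, rng):
        query = "ACDEFGHIKL"
        msa = [query] + [
            "".join(AAINDEX_ORDER[i] for i in rng.integers(0, 20, size=10))
            for _ in range(6)
        ]
        profile = profile_from_alignment(msa, query)
        assert len(profile) == 10
        np.testing.assert_allclose(profile.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_query_gap_columns_skipped(self):
        query = "AC-DE"
        msa = [query, "ACWDE"]
        profile = profile_from_alignment(msa, query)
        assert len(profile) == 4  # gap column in the query is not a position

    def test_tsv_round_trip(self, tmp_path, rng):
        query = "ACDEFGH"
        msa = [query, "ACDEFGW", "ACWEFGH"]
        profile = profile_from_alignment(msa, query, query_id="q1")
        path = tmp_path / "profile.tsv"
        profile.to_tsv(path)
        again = FrequencyProfile.from_tsv(path)
        assert again.id == "q1"
        np.testing.assert_array_equal(again.matrix, profile.matrix)


class TestNthSequence:
    def test_degenerate_profile_n1_returns_original(self):
        seq = ProteinSequence("s", "ACDEFGHIKLMNPQRSTVWY")
        profile = make_degenerate_profile(seq)
        assert nth_sequence(profile, 1).residues == seq.residues

    def test_toy_profile_second_ranked(self):
        rows = np.zeros((3, 20))
        for i, (first, second) in enumerate([("A", "C"), ("W", "Y"), ("K", "R")]):
            rows[i, AAINDEX_ORDER.index(first)] = 0.6
            rows[i, AAINDEX_ORDER.index(second)] = 0.3
            rows[i] += (1 - rows[i].sum()) / 20
        profile = FrequencyProfile(id="toy", matrix=rows)
        assert nth_sequence(profile, 1).residues == "AWK"
        assert nth_sequence(profile, 2).residues == "CYR"

    def test_ties_broken_alphabetically(self):
        row = np.full(20, 1 / 20)  # every residue tied
        profile = FrequencyProfile(id="tie", matrix=row[None, :])
        assert nth_sequence(profile, 1).residues == "A"
        assert nth_sequence(profile, 2).residues == "C"
        assert nth_sequence(profile, 20).residues == "Y"

    def test_rank_consistency_between_n_levels(self, rng):
        matrix = rng.dirichlet(np.ones(20), size=15)
        profile = FrequencyProfile(id="r", matrix=matrix)
        s1 = nth_sequence(profile, 1).residues
        s2 = nth_sequence(profile, 2).residues
        for i in range(15):
            f1 = matrix[i, AAINDEX_ORDER.index(s1[i])]
            f2 = matrix[i, AAINDEX_ORDER.index(s2[i])]
            assert f1 >= f2

    def test_n_out_of_range(self):
        profile = FrequencyProfile(id="x", matrix=np.full((2, 20), 1 / 20))
        with pytest.raises(ValueError):
            nth_sequence(profile, 0)
        with pytest.raises(ValueError):
            nth_sequence(profile, 21)


class TestProfilePDT:
    def test_degenerate_profile_reduces_to_sequence_transform(self, index_set, rng):
        seq = random_sequences(1, rng, min_len=30, max_len=60)[0]
        profile = make_degenerate_profile(seq)
        params = PDTParams(beta=3)
        vec = profile_pdt(profile, index_set, params, n_max=1)
        np.testing.assert_allclose(vec, transform(seq, index_set, params), atol=0)

    def test_length_formula_with_n(self, index_set, rng):
        matrix = rng.dirichlet(np.ones(20), size=25)
        profile = FrequencyProfile(id="p", matrix=matrix)
        for n_max in (1, 2):
            vec = profile_pdt(profile, index_set, PDTParams(beta=4), n_max=n_max)
            assert vec.shape == (index_set.n_indices * 4 * n_max,)
        # the printed large-scale formula: 531 indices, beta 8, n 2 -> 8496
        assert 531 * 8 * 2 == 8496

    def test_equals_manual_concatenation(self, index_set, rng):
        matrix = rng.dirichlet(np.ones(20), size=25)
        profile = FrequencyProfile(id="p", matrix=matrix)
        params = PDTParams(beta=3)
        vec = profile_pdt(profile, index_set, params, n_max=2)
        manual = np.concatenate([
            transform(nth_sequence(profile, 1), index_set, params),
            transform(nth_sequence(profile, 2), index_set, params),
        ])
        np.testing.assert_array_equal(vec, manual)


def test_psiblast_command_carries_published_parameters():
    cmd = psiblast_command("q.fasta")
    assert "-num_iterations" in cmd and cmd[cmd.index("-num_iterations") + 1] == "10"
    assert "-evalue" in cmd and cmd[cmd.index("-evalue") + 1] == "0.001"
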