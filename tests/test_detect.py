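import numpy as np
import pytest

import _oracles as orc
from conftest import random_alignment
from coevosim.alignment import ALPHABET, GAP_CODE, Alignment
from coevosim.binary import (
    BinaryAlignment,
    resort,
    to_differential_binary,
    to_global_differential_binary,
    to_normal_binary,
)
from coevosim.detect import (
    CoevolutionMatrix,
    InsufficientPositionsError,
    apc,
    binary_covariance,
    collapse_global_cov,
    db_zpx2,
    dgb_zpx2,
    merge_mi_cov,
    mi_matrix,
    nb_zpx2,
    omes,
    zpx2,
)


def random_symmetric(rng, n):
    m = rng.normal(size=(n, n))
    return (m + m.T) / 2


class TestMI:
    def test_identical_half_half_binary_columns_give_one_bit(self):
        col = np.array([0, 0, 1, 1])
        msa = np.stack([col, col], axis=1)
        assert mi_matrix(msa).scores[0, 1] == pytest.approx(1.0)

    def test_constant_column_gives_zero(self):
        msa = np.array([[0, 0], [0, 1], [0, 0], [0, 1]])
        assert mi_matrix(msa).scores[0, 1] == pytest.approx(0.0)

    def test_matches_joint_histogram_oracle(self, rng):
        msa = rng.integers(0, 4, size=(6, 3))
        got = mi_matrix(msa).scores
        np.testing.assert_allclose(got, orc.mi_oracle(msa), atol=1e-12)

    def test_gap_exclusion_drops_rows_pairwise(self):
        # without the gap rows, the two columns are perfectly coupled
        aln = Alignment.from_sequences(
            ["a", "b", "c", "d", "e"], ["AC", "AC", "DE", "DE", "A-"]
        )
        got = mi_matrix(aln.rows, exclude_gaps=True).scores[0, 1]
        sub = aln.rows[:4]
        assert got == pytest.approx(orc.mi_oracle(sub)[0, 1], abs=1e-12)

    def test_symmetric(self, rng):
        msa = rng.integers(0, 3, size=(8, 5))
        s = mi_matrix(msa).scores
        np.testing.assert_allclose(s, s.T)


class TestAPC:
    def test_constant_off_diagonal_becomes_zero(self):
        m = np.full((4, 4), 3.0)
        out = apc(CoevolutionMatrix(m, "x")).scores
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(out[off], 0.0, atol=1e-12)

    def test_hand_matrix_matches_arithmetic_oracle(self, rng):
        m = random_symmetric(rng, 3)
        out = apc(CoevolutionMatrix(m, "x")).scores
        np.testing.assert_allclose(out, orc.apc_oracle(m), atol=1e-12)

    def test_row_means_shrink_toward_zero(self, rng):
        m = np.abs(random_symmetric(rng, 40)) + 1.0
        out = apc(CoevolutionMatrix(m, "x")).scores
        off = ~np.eye(40, dtype=bool)
        before = np.abs(np.where(off, m, 0).sum(1) / 39 - m[off].mean())
        # corrected row means sit near zero relative to the original spread
        after = np.abs(np.where(off, out, 0).sum(1) / 39)
        assert after.max() < 0.2 * m[off].mean()

    def test_zero_mean_matrix_returned_unchanged(self):
        m = np.zeros((3, 3))
        with pytest.warns(UserWarning):
            out = apc(CoevolutionMatrix(m, "x")).scores
        np.testing.assert_array_equal(out, m)


class TestZPX2:
    def test_constant_matrix_gives_zero(self):
        m = np.full((4, 4), 2.0)
        out = zpx2(CoevolutionMatrix(m, "x")).scores
        np.testing.assert_allclose(out, 0.0)

    def test_matches_row_zscore_oracle(self, rng):
        m = random_symmetric(rng, 4)
        out = zpx2(CoevolutionMatrix(m, "x")).scores
        np.testing.assert_allclose(out, orc.zpx2_oracle(m), atol=1e-10)

    def test_nonnegative_everywhere(self, rng):
        m = random_symmetric(rng, 8)
        assert (zpx2(CoevolutionMatrix(m, "x")).scores >= 0).all()

    def test_signed_variant_keeps_sign_magnitude(self, rng):
        m = random_symmetric(rng, 6)
        plain = zpx2(CoevolutionMatrix(m, "x")).scores
        signed = zpx2(CoevolutionMatrix(m, "x"), signed=True).scores
        np.testing.assert_allclose(np.abs(signed), plain, atol=1e-12)

    def test_too_few_positions_raises(self):
        with pytest.raises(InsufficientPositionsError):
            zpx2(CoevolutionMatrix(np.zeros((2, 2)), "x"))

    def test_invariant_under_simultaneous_permutation(self, rng):
        m = random_symmetric(rng, 7)
        perm = rng.permutation(7)
        out = zpx2(CoevolutionMatrix(m, "x")).scores
        out_p = zpx2(CoevolutionMatrix(m[np.ix_(perm, perm)], "x")).scores
        np.testing.assert_allclose(out[np.ix_(perm, perm)], out_p, atol=1e-12)


class TestCovariance:
    def test_matches_textbook_oracle(self, rng):
        bits = rng.integers(0, 2, size=(10, 5)).astype(np.uint8)
        b = BinaryAlignment(bits=bits, order=np.arange(10))
        got = binary_covariance(b).scores
        np.testing.assert_allclose(got, orc.cov_oracle(bits), atol=1e-12)

    def test_identical_columns_covary_as_variance(self):
        col = np.array([0, 1, 1, 0, 1], dtype=np.uint8)
        b = BinaryAlignment(bits=np.stack([col, col], axis=1), order=np.arange(5))
        cov = binary_covariance(b).scores
        assert cov[0, 1] == pytest.approx(cov[0, 0])

    def test_constant_columns_give_zero(self):
        bits = np.zeros((6, 3), dtype=np.uint8)
        b = BinaryAlignment(bits=bits, order=np.arange(6))
        np.testing.assert_allclose(binary_covariance(b).scores, 0.0)


class TestCollapse:
    def test_collapsed_shape_from_210_column_expansion(self, rng):
        aln = random_alignment(rng, 10, 10)
        gb = to_global_differential_binary(aln, resort(aln))
        assert gb.bits.shape == (10, 210)
        out = collapse_global_cov(gb).scores
        assert out.shape == (10, 10)
        assert (out >= 0).all()
        np.testing.assert_allclose(out, out.T)

    def test_matches_blockwise_frobenius_oracle(self, rng):
        aln = random_alignment(rng, 8, 4)
        gb = to_global_differential_binary(aln, resort(aln))
        cov = np.cov(gb.bits.astype(float), rowvar=False, ddof=1)
        out = collapse_global_cov(gb).scores
        for i in range(4):
            for j in range(4):
                block = cov[i * 21 : (i + 1) * 21, j * 21 : (j + 1) * 21]
                assert out[i, j] == pytest.approx(np.linalg.norm(block, "fro"))

    def test_all_zero_input_collapses_to_zero(self):
        from coevosim.binary import GlobalBinaryAlignment

        gb = GlobalBinaryAlignment(
            bits=np.zeros((5, 42), dtype=np.uint8), order=np.arange(5)
        )
        np.testing.assert_allclose(collapse_global_cov(gb).scores, 0.0)


class TestMerge:
    def test_cov_equal_mi_returns_mi(self, rng):
        m = np.abs(random_symmetric(rng, 5))
        merged = merge_mi_cov(
            CoevolutionMatrix(m, "MI"), CoevolutionMatrix(m.copy(), "COV")
        ).scores
        np.testing.assert_allclose(merged, m, atol=1e-10)

    def test_scaled_cov_is_rescaled_back(self, rng):
        m = np.abs(random_symmetric(rng, 5))
        merged = merge_mi_cov(
            CoevolutionMatrix(m, "MI"), CoevolutionMatrix(2 * m, "COV")
        ).scores
        np.testing.assert_allclose(merged, m, atol=1e-10)

    def test_regression_matches_closed_form(self, rng):
        mi = random_symmetric(rng, 6)
        cov = random_symmetric(rng, 6)
        iu = np.triu_indices(6, 1)
        a, b = orc.lstsq_oracle(cov[iu], mi[iu])
        merged = merge_mi_cov(
            CoevolutionMatrix(mi, "MI"), CoevolutionMatrix(cov, "COV")
        ).scores
        np.testing.assert_allclose(merged, 0.5 * (mi + a * cov + b), atol=1e-10)

    def test_constant_cov_degenerates_to_mi(self, rng):
        mi = random_symmetric(rng, 4)
        with pytest.warns(UserWarning):
            merged = merge_mi_cov(
                CoevolutionMatrix(mi, "MI"),
                CoevolutionMatrix(np.ones((4, 4)), "COV"),
            ).scores
        np.testing.assert_array_equal(merged, mi)


class TestOMES:
    def test_perfectly_coupled_columns_match_hand_contingency(self):
        aln = Alignment.from_sequences(
            [f"s{i}" for i in range(8)],
            ["AD"] * 4 + ["CE"] * 4,
        )
        # N_valid=8; cells (A,D) and (C,E): N_obs=4, N_exp=4*4/8=2 each
        # score = 2 * (4-2)^2 / 8 = 1.0
        assert omes(aln).scores[0, 1] == pytest.approx(1.0)

    def test_invariant_columns_score_zero(self):
        aln = Alignment.from_sequences(["a", "b", "c"], ["AC"] * 3)
        assert omes(aln).scores[0, 1] == pytest.approx(0.0)

    def test_independent_columns_vanish_relative_to_coupled(self, rng):
        # independent columns: O(1) statistic; coupled columns grow with n,
        # so the independent score is negligible on the coupled scale
        n = 4000
        rows = rng.integers(0, 4, size=(n, 2)).astype(np.uint8)
        indep = Alignment([f"s{i}" for i in range(n)], rows)
        coupled_rows = np.stack([rows[:, 0], rows[:, 0]], axis=1)
        coupled = Alignment(indep.ids, coupled_rows)
        s_indep = omes(indep).scores[0, 1]
        s_coupled = omes(coupled).scores[0, 1]
        assert s_indep < 2.0
        assert s_indep < 0.01 * s_coupled

    def test_matches_contingency_oracle(self, rng):
        aln = random_alignment(rng, 12, 4, n_symbols=21)
        got = omes(aln).scores
        expected = orc.omes_oracle(aln.rows, GAP_CODE)
        iu = np.triu_indices(4, 1)
        np.testing.assert_allclose(got[iu], expected[iu], atol=1e-10)


class TestCompositePipelines:
    def test_identical_sequences_give_all_zero_matrix(self):
        aln = Alignment.from_sequences(["a", "b", "c"], ["ACDE"] * 3)
        with pytest.warns(UserWarning):  # degenerate covariance regression
            out = db_zpx2(aln)
        np.testing.assert_allclose(out.scores, 0.0)

    def test_db_equals_manual_composition(self, rng):
        aln = random_alignment(rng, 12, 8, n_symbols=6)
        got = db_zpx2(aln).scores
        order = resort(aln)
        b = to_differential_binary(aln, order)
        merged = merge_mi_cov(mi_matrix(b.bits), binary_covariance(b))
        expected = zpx2(merged).scores
        iu = np.triu_indices(8, 1)
        expected_diag = expected.copy()
        np.fill_diagonal(expected_diag, expected[iu].min())
        np.testing.assert_allclose(got, expected_diag, atol=1e-12)

    def test_dgb_equals_manual_composition(self, rng):
        aln = random_alignment(rng, 12, 8, n_symbols=6)
        got = dgb_zpx2(aln).scores
        order = resort(aln)
        b = to_differential_binary(aln, order)
        gb = to_global_differential_binary(aln, order)
        merged = merge_mi_cov(mi_matrix(b.bits), collapse_global_cov(gb))
        expected = zpx2(merged).scores
        iu = np.triu_indices(8, 1)
        np.fill_diagonal(expected, expected[iu].min())
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_nb_equals_manual_composition(self, rng):
        aln = random_alignment(rng, 12, 8, n_symbols=6)
        got = nb_zpx2(aln).scores
        order = resort(aln)
        nb = to_normal_binary(aln, order)
        expected = zpx2(mi_matrix(nb.codes)).scores
        iu = np.triu_indices(8, 1)
        np.fill_diagonal(expected, expected[iu].min())
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_pipelines_are_deterministic(self, rng):
        aln = random_alignment(rng, 10, 7, n_symbols=5)
        for fn in (db_zpx2, dgb_zpx2, nb_zpx2):
            np.testing.assert_array_equal(fn(aln).scores, fn(aln).scores)

    def test_strong_covarions_rank_in_top_scores(self):
        # 5 strongly coupled pairs in 100x60 simulated MSAs: each composite
        # detector should place all 5 inside its top 15 ranked pairs in at
        # least 16 of 20 seeded replicates
        from coevosim.evaluate import ranked_pairs
        from coevosim.simulate import (
            SimulationConfig,
            evolve,
            random_disjoint_pairs,
        )

        recovered = {fn: 0 for fn in (db_zpx2, dgb_zpx2, nb_zpx2)}
        n_rep = 20
        for seed in range(n_rep):
            pair_rng = np.random.default_rng(30_000 + seed)
            pairs = random_disjoint_pairs(60, 5, pair_rng)
            cfg = SimulationConfig(
                n_pos=60, branching=(3, 2, 4, 3), cycles_per_level=(8, 6, 3, 2),
                mutation_prob=0.02, covarion_pairs=pairs, covarion_mut_prob=0.3,
                crossover_points=(20, 40), recombination_prob=0.1, n_seq=100,
            )
            aln, _ = evolve(cfg, seed=seed)
            truth = {(min(i, j) - 1, max(i, j) - 1) for i, j in pairs}
            for fn in recovered:
                i_idx, j_idx = ranked_pairs(fn(aln).scores)
                top = set(zip(i_idx[:15].tolist(), j_idx[:15].tolist()))
                recovered[fn] += truth <= top
        for fn, hits in recovered.items():
            assert hits >= 0.8 * n_rep, f"{fn.__name__}: {hits}/{n_rep}"

    def test_outputs_symmetric_with_min_diagonal(self, rng):
        aln = random_alignment(rng, 10, 7, n_symbols=5)
        for fn in (db_zpx2, dgb_zpx2, nb_zpx2):
            s = fn(aln).scores
            np.testing.assert_allclose(s, s.T)
            iu = np.triu_indices(7, 1)
            assert (np.diag(s) <= s[iu].min() + 1e-15).all()
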