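"""Detection-call filtering and the exact rank-correlation screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ic50screen import (
    ExpressionMatrix,
    IC50Profile,
    exact_null_distribution,
    filter_by_detection,
    genome_screen,
    rank_lines_by_gene,
    read_expression_tsv,
    read_gene_set,
    signature_correlation,
    spearman_exact,
    write_expression_tsv,
)

LINES = ["CL1", "CL2", "CL3", "CL4", "CL5"]


def make_matrix(values, calls=None, ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, m = values.shape
    ids = ids or [f"T{i}" for i in range(n)]
    cols = LINES[:m]
    if calls is None:
        calls = np.full((n, m), "P")
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=ids, columns=cols),
        calls=pd.DataFrame(np.asarray(calls), index=ids, columns=cols),
    )


def brute_force_spearman_p(x, y):
    """Independent oracle: enumerate every permutation of y directly."""
    rx = stats.rankdata(x)
    obs = np.corrcoef(rx, stats.rankdata(y))[0, 1]
    count_pos = count_two = 0
    perms = list(itertools.permutations(stats.rankdata(y)))
    for p in perms:
        r = np.corrcoef(rx, p)[0, 1]
        count_pos += r >= obs - 1e-9
        count_two += abs(r) >= abs(obs) - 1e-9
    return obs, count_pos / len(perms), count_two / len(perms)


class TestDetectionFilter:
    def test_all_present_or_marginal_retained(self):
        m = make_matrix([[1, 2, 3, 4, 5]], [["P", "P", "M", "P", "P"]])
        assert filter_by_detection(m).transcript_ids == ["T0"]

    def test_single_absent_call_removes_transcript(self):
        m = make_matrix(
            [[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]],
            [["P", "P", "A", "P", "P"], ["M", "M", "M", "P", "P"]],
        )
        assert filter_by_detection(m).transcript_ids == ["T1"]

    def test_accepting_all_calls_is_identity(self):
        m = make_matrix([[1, 2, 3, 4, 5]], [["A", "A", "A", "A", "A"]])
        assert filter_by_detection(m, {"P", "M", "A"}).transcript_ids == ["T0"]

    def test_filter_shrinks_with_accepted_set(self, rng):
        calls = rng.choice(["P", "M", "A"], size=(50, 5))
        m = make_matrix(rng.normal(size=(50, 5)), calls)
        kept_pm = set(filter_by_detection(m, {"P", "M", "A"}).transcript_ids)
        kept_p = set(filter_by_detection(m, {"P", "M"}).transcript_ids)
        assert kept_p <= kept_pm

    def test_empty_result_errors(self):
        m = make_matrix([[1, 2, 3, 4, 5]], [["A", "P", "P", "P", "P"]])
        with pytest.raises(ValueError, match="relax"):
            filter_by_detection(m)


class TestExactSpearman:
    def test_perfect_concordance(self):
        gc = spearman_exact([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert gc.rho == pytest.approx(1.0)
        assert gc.p_one_sided_pos == pytest.approx(1 / 120)

    def test_perfect_anticoncordance(self):
        gc = spearman_exact([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert gc.rho == pytest.approx(-1.0)
        assert gc.p_one_sided_neg == pytest.approx(1 / 120)

    def test_rho_point_nine_p_value(self):
        # one adjacent swap: sum d^2 = 2, rho = 0.9; permutations at least
        # as concordant: four with rho = 0.9 plus the identity, 5/120
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 3, 4, 5]
        gc = spearman_exact(x, y)
        obs, p_pos, p_two = brute_force_spearman_p(x, y)
        assert gc.rho == pytest.approx(0.9) == pytest.approx(obs)
        assert gc.p_one_sided_pos == pytest.approx(5 / 120) == pytest.approx(p_pos)
        assert gc.p_two_sided == pytest.approx(p_two)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_brute_force_oracle_with_ties(self, n, rng):
        for _ in range(10):
            x = rng.integers(0, n, size=n).astype(float)
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            gc = spearman_exact(x, y)
            obs, p_pos, p_two = brute_force_spearman_p(x, y)
            assert gc.rho == pytest.approx(obs)
            assert gc.p_one_sided_pos == pytest.approx(p_pos)
            assert gc.p_two_sided == pytest.approx(p_two)

    def test_rho_agrees_with_scipy_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 8))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            gc = spearman_exact(x, y)
            assert gc.rho == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_constant_input_is_degenerate(self):
        gc = spearman_exact([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert gc.degenerate
        assert gc.rho == 0.0
        assert gc.p_one_sided_pos == 1.0

    def test_large_n_falls_back_to_t_approximation(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        gc = spearman_exact(x, y, exact_cap=8)
        ref = stats.spearmanr(x, y, alternative="greater")
        assert gc.rho == pytest.approx(ref.statistic)
        assert gc.p_one_sided_pos == pytest.approx(ref.pvalue, rel=1e-6)

    def test_p_two_sided_dominates_smaller_one_sided(self, rng):
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            gc = spearman_exact(x, y)
            assert gc.p_two_sided >= min(gc.p_one_sided_pos, gc.p_one_sided_neg) - 1e-12


class TestExactNull:
    def test_null_at_n5(self):
        support, probs = exact_null_distribution(5)
        assert probs.sum() == pytest.approx(1.0)
        assert probs[np.isclose(support, 1.0)].sum() == pytest.approx(1 / 120)
        assert probs[support >= 0.9 - 1e-9].sum() == pytest.approx(5 / 120)
        # symmetry about zero
        assert np.allclose(support, -support[::-1])
        assert np.allclose(probs, probs[::-1])


def planted_profile(cfg):
    return IC50Profile(
        cell_lines=[f"CL{i+1}" for i in range(cfg.n_cell_lines)],
        values=cfg.signature(),
    )


class TestGenomeScreen:
    def test_recovers_planted_sets_exactly(self, small_expression):
        matrix, truth, cfg = small_expression
        res = genome_screen(matrix, planted_profile(cfg), alpha=0.05)
        assert set(res.positive_set) == set(
            truth[truth["direction"] == 1]["transcript_id"]
        )
        assert set(res.negative_set) == set(
            truth[truth["direction"] == -1]["transcript_id"]
        )

    def test_row_permutation_invariance(self, small_expression, rng):
        matrix, _, cfg = small_expression
        perm = rng.permutation(len(matrix.values))
        shuffled = ExpressionMatrix(
            values=matrix.values.iloc[perm], calls=matrix.calls.iloc[perm]
        )
        res1 = genome_screen(matrix, planted_profile(cfg))
        res2 = genome_screen(shuffled, planted_profile(cfg))
        assert set(res1.positive_set) == set(res2.positive_set)
        assert set(res1.negative_set) == set(res2.negative_set)

    def test_alpha_below_exact_floor_selects_nothing(self, small_expression):
        matrix, _, cfg = small_expression
        res = genome_screen(matrix, planted_profile(cfg), alpha=1 / 240)
        assert res.positive_set == [] and res.negative_set == []

    def test_tied_profile_selects_nothing(self, small_expression):
        matrix, _, cfg = small_expression
        with pytest.warns(UserWarning):
            flat = IC50Profile(
                cell_lines=planted_profile(cfg).cell_lines,
                values=np.ones(cfg.n_cell_lines),
            )
        res = genome_screen(matrix, flat)
        assert res.positive_set == [] and res.negative_set == []

    def test_nested_selection_across_alpha(self, small_expression):
        matrix, _, cfg = small_expression
        loose = genome_screen(matrix, planted_profile(cfg), alpha=0.05)
        strict = genome_screen(matrix, planted_profile(cfg), alpha=0.01)
        assert set(strict.positive_set) <= set(loose.positive_set)

    def test_label_mismatch_errors(self, small_expression):
        matrix, _, cfg = small_expression
        bad = IC50Profile(
            cell_lines=["X1", "X2", "X3", "X4", "X5"], values=cfg.signature()
        )
        with pytest.raises(ValueError, match="do not align"):
            genome_screen(matrix, bad)

    def test_case_insensitive_alignment(self, small_expression):
        matrix, truth, cfg = small_expression
        prof = IC50Profile(
            cell_lines=[c.lower() for c in planted_profile(cfg).cell_lines],
            values=cfg.signature(),
        )
        res = genome_screen(matrix, prof)
        assert set(res.positive_set) == set(
            truth[truth["direction"] == 1]["transcript_id"]
        )

    def test_missing_values_dropped(self, small_expression):
        matrix, _, cfg = small_expression
        vals = matrix.values.copy()
        vals.iloc[0, 0] = np.nan
        res = genome_screen(
            ExpressionMatrix(values=vals, calls=matrix.calls),
            planted_profile(cfg),
        )
        assert res.n_filtered == len(vals) - 1


class TestSignatureCorrelation:
    def test_planted_gene_significant_for_its_profile(self, small_expression):
        matrix, truth, cfg = small_expression
        gene = truth[truth["direction"] == 1]["transcript_id"].iloc[0]
        prof = planted_profile(cfg)
        reversed_prof = IC50Profile(
            cell_lines=prof.cell_lines, values=cfg.signature()[::-1].copy()
        )
        table, summary = signature_correlation(
            [gene], matrix, {"fwd": prof, "rev": reversed_prof}
        )
        fwd = table[table["profile"] == "fwd"].iloc[0]
        rev = table[table["profile"] == "rev"].iloc[0]
        assert fwd["rho"] == pytest.approx(1.0)
        assert fwd["p_one_sided_pos"] <= 0.05
        assert rev["rho"] == pytest.approx(-1.0)
        assert rev["p_one_sided_neg"] <= 0.05
        assert ((summary["fraction_significant"] >= 0)
                & (summary["fraction_significant"] <= 1)).all()

    def test_absent_signature_errors(self, small_expression):
        matrix, _, cfg = small_expression
        with pytest.raises(ValueError, match="no signature gene"):
            signature_correlation(
                ["NOPE"], matrix, {"fwd": planted_profile(cfg)}
            )


class TestRankLinesByGene:
    def test_descending_order(self):
        m = make_matrix([[5, 3, 4, 2, 1]], ids=["CDH1"])
        assert rank_lines_by_gene(m, "CDH1") == ["CL1", "CL3", "CL2", "CL4", "CL5"]

    def test_ties_keep_input_order(self):
        m = make_matrix([[5, 5, 1, 5, 1]], ids=["G"])
        assert rank_lines_by_gene(m, "G") == ["CL1", "CL2", "CL4", "CL3", "CL5"]

    def test_absent_gene_errors(self):
        m = make_matrix([[1, 2, 3, 4, 5]])
        with pytest.raises(ValueError, match="not present"):
            rank_lines_by_gene(m, "MISSING")


class TestIO:
    def test_expression_tsv_round_trip(self, small_expression, tmp_path):
        matrix, _, _ = small_expression
        path = tmp_path / "expr.tsv"
        write_expression_tsv(matrix, path)
        back = read_expression_tsv(path)
        assert back.cell_lines == matrix.cell_lines
        assert np.allclose(back.values.to_numpy(), matrix.values.to_numpy())
        assert (back.calls.to_numpy() == matrix.calls.to_numpy()).all()

    def test_gene_set_file_with_comments(self, tmp_path):
        p = tmp_path / "sig.txt"
        p.write_text("# EMT markers\nCDH1\nZEB1  # mesenchymal\n\nVIM\n")
        assert read_gene_set(p) == ["CDH1", "ZEB1", "VIM"]
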