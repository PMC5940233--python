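"""Contingency tables, concordance, chi-square, and the gene screen."""

import random

import numpy as np
import pytest
from scipy import stats

from conftest import make_inventory, pearson_chi2, permutation_pvalue
from plastome.association import (
    ContingencyTable,
    chi_square_test,
    concordance_rate,
    contingency_table,
    screen_genes,
)
from plastome.matrix import build_matrix
from plastome.simulate import (
    GeneLossSpec,
    SimulationConfig,
    simulate_gene_loss,
    simulate_habitat,
    simulate_tree,
)


class TestContingencyTable:
    def test_hand_count(self):
        invs = [make_inventory(f"m{i}", ["pbsA"]) for i in range(3)] + [
            make_inventory(f"f{i}", ["psbA"]) for i in range(2)
        ]
        habitat = {f"m{i}": "marine" for i in range(3)}
        habitat.update({f"f{i}": "freshwater" for i in range(2)})
        m = build_matrix(invs, habitat)
        tab = contingency_table(m, "pbsA")
        assert (tab.a, tab.b, tab.c, tab.d) == (3, 0, 0, 2)

    def test_brackish_policies(self):
        invs = [
            make_inventory("m1", ["pbsA"]),
            make_inventory("f1", ["psbA"]),
            make_inventory("b1", ["pbsA"]),
        ]
        habitat = {"m1": "marine", "f1": "freshwater", "b1": "brackish"}
        m = build_matrix(invs, habitat)
        excl = contingency_table(m, "pbsA", "exclude")
        assert (excl.a, excl.n_excluded_brackish) == (1, 1)
        as_m = contingency_table(m, "pbsA", "as_marine")
        assert (as_m.a, as_m.n_excluded_brackish) == (2, 0)
        as_f = contingency_table(m, "pbsA", "as_freshwater")
        assert as_f.c == 1

    def test_all_brackish_excluded_is_error(self):
        invs = [make_inventory("b1", ["psbA"]), make_inventory("b2", ["psbA"])]
        m = build_matrix(invs, {"b1": "brackish", "b2": "brackish"})
        with pytest.raises(ValueError):
            contingency_table(m, "psbA", "exclude")

    def test_unknown_gene_is_error(self, three_genome_matrix):
        with pytest.raises(KeyError):
            contingency_table(three_genome_matrix, "nonexistent")


class TestConcordance:
    def test_perfect_concordance(self):
        rate, direction = concordance_rate(ContingencyTable(3, 0, 0, 2))
        assert rate == 1.0 and direction == "marine_retained"

    def test_printed_pbsa_counts(self):
        rate, direction = concordance_rate(ContingencyTable(100, 16, 4, 12))
        assert rate == pytest.approx(112 / 132)
        assert direction == "marine_retained"

    def test_direction_flip(self):
        rate, direction = concordance_rate(ContingencyTable(1, 9, 9, 1))
        assert rate == pytest.approx(0.9)
        assert direction == "freshwater_retained"

    def test_rate_never_below_half(self):
        rng = random.Random(0)
        for _ in range(200):
            cells = [rng.randint(0, 30) for _ in range(4)]
            if sum(cells) == 0:
                continue
            rate, _ = concordance_rate(ContingencyTable(*cells))
            assert rate >= 0.5


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        res = chi_square_test(ContingencyTable(5, 5, 50, 50))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_printed_pbsa_table_uncorrected_and_yates(self):
        tab = ContingencyTable(100, 16, 4, 12)
        plain = chi_square_test(tab, correction=False)
        yates = chi_square_test(tab, correction=True)
        # hand-evaluated Pearson / Yates formulas
        assert plain.chi2 == pytest.approx(31.518, abs=1e-3)
        assert plain.p_value == pytest.approx(1.976e-8, rel=1e-3)
        assert yates.chi2 == pytest.approx(27.962, abs=1e-3)
        assert plain.df == 1

    def test_matches_hand_formula(self):
        rng = random.Random(1)
        for _ in range(100):
            a, b, c, d = (rng.randint(1, 40) for _ in range(4))
            res = chi_square_test(ContingencyTable(a, b, c, d))
            assert res.chi2 == pytest.approx(pearson_chi2(a, b, c, d))

    def test_invariant_under_row_and_column_swaps(self):
        rng = random.Random(2)
        for _ in range(50):
            a, b, c, d = (rng.randint(1, 30) for _ in range(4))
            base = chi_square_test(ContingencyTable(a, b, c, d)).chi2
            assert chi_square_test(ContingencyTable(c, d, a, b)).chi2 == pytest.approx(base)
            assert chi_square_test(ContingencyTable(b, a, d, c)).chi2 == pytest.approx(base)

    def test_p_monotone_in_chi2(self):
        chis = np.linspace(0, 40, 100)
        ps = stats.chi2.sf(chis, 1)
        assert np.all(np.diff(ps) <= 0)

    def test_zero_margin_is_flagged_degenerate_not_exception(self):
        res = chi_square_test(ContingencyTable(3, 0, 2, 0))
        assert res.degenerate and res.p_value == 1.0

    def test_orders_tables_like_exact_permutation_oracle(self):
        # within every fixed-margin family (n <= 30), the asymptotic
        # p-value must rank tables exactly as the exact conditional
        # permutation distribution of the statistic does
        for n in (8, 14, 21, 30):
            for r1 in range(1, n):
                for c1 in range(1, n):
                    rows = []
                    for a in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
                        tab = ContingencyTable(
                            a, r1 - a, c1 - a, (n - r1) - (c1 - a)
                        )
                        if tab.degenerate:
                            continue
                        rows.append(
                            (
                                chi_square_test(tab).p_value,
                                permutation_pvalue(tab.a, tab.b, tab.c, tab.d),
                            )
                        )
                    rows.sort()
                    perm_ps = [p for _, p in rows]
                    assert all(
                        p2 >= p1 - 1e-12
                        for p1, p2 in zip(perm_ps, perm_ps[1:])
                    ), (n, r1, c1, rows)


class TestScreen:
    def _simulated_matrix(self, genes, seed, n_marine=20, n_freshwater=16):
        cfg = SimulationConfig(
            n_marine=n_marine,
            n_freshwater=n_freshwater,
            n_brackish=0,
            tree_model="star",
            genes=genes,
            seed=seed,
        )
        tree = simulate_tree(cfg)
        habitats = simulate_habitat(tree, cfg)
        m, _ = simulate_gene_loss(tree, habitats, cfg)
        return m

    def test_planted_habitat_genes_all_flagged(self):
        genes = [GeneLossSpec(f"hab{i}", 0.05, 0.9) for i in range(5)] + [
            GeneLossSpec(f"null{i}", 0.3, 0.3) for i in range(5)
        ]
        m = self._simulated_matrix(genes, seed=11)
        results = screen_genes(m, alpha=0.01)
        flagged = {r.gene for r in results if r.significant}
        assert {f"hab{i}" for i in range(5)} <= flagged

    def test_results_sorted_by_pvalue(self):
        genes = [GeneLossSpec(f"g{i}", 0.1 * (i % 5), 0.5) for i in range(8)]
        m = self._simulated_matrix(genes, seed=4)
        results = screen_genes(m)
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)

    def test_alpha_one_flags_everything(self):
        genes = [GeneLossSpec(f"g{i}", 0.3, 0.3) for i in range(6)]
        m = self._simulated_matrix(genes, seed=5)
        results = screen_genes(m, alpha=1.0)
        assert all(r.significant for r in results)

    def test_single_habitat_matrix_is_error(self):
        invs = [make_inventory(f"m{i}", ["psbA"]) for i in range(4)]
        m = build_matrix(invs, {f"m{i}": "marine" for i in range(4)})
        with pytest.raises(ValueError, match="marine and freshwater"):
            screen_genes(m)

    def test_bonferroni_is_more_conservative(self):
        genes = [GeneLossSpec(f"g{i}", 0.2, 0.6) for i in range(10)]
        m = self._simulated_matrix(genes, seed=6)
        raw = screen_genes(m, alpha=0.05)
        adj = screen_genes(m, alpha=0.05, adjust="bonferroni")
        assert sum(r.significant for r in adj) <= sum(
            r.significant for r in raw
        )
        assert all(
            r.p_adjusted >= r.p_value - 1e-15 for r in adj
        )
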