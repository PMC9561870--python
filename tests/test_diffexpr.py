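"""Rank test, weighted-mean differential expression, cross-tissue filter."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import osteotx as ox
from osteotx.diffexpr import CrossTissueFilterSpec, SignificanceRule


def exact_rank_p(a, b):
    """Brute-force permutation oracle for the two-sided rank-sum test.

    Enumerates every assignment of the pooled values into groups of
    the observed sizes and counts assignments with a U statistic at
    least as far from its null mean as the observed one.
    """
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    n1, n2 = len(a), len(b)
    ranks = {}
    for i, v in enumerate(pooled):
        ranks.setdefault(v, []).append(i + 1)
    assert all(len(r) == 1 for r in ranks.values()), "oracle needs untied data"
    rank_of = {v: r[0] for v, r in ranks.items()}
    u_obs = sum(rank_of[v] for v in a) - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = sum(comb) + n1 - n1 * (n1 + 1) / 2  # 0-based indices -> ranks
        u = sum(i + 1 for i in comb) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestRankTest:
    def test_identical_groups_p_one(self):
        assert ox.rank_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_all_tied_p_one(self):
        assert ox.rank_test([5, 5, 5], [5, 5, 5, 5]) == 1.0

    def test_separated_groups_match_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        p = ox.rank_test(a, b)
        assert p == pytest.approx(exact_rank_p(a, b), abs=1e-12)
        assert p == pytest.approx(2 / 20)  # 2 extreme of C(6,3) assignments

    def test_matches_enumeration_over_all_small_splits(self, rng):
        """Every two-group split of <= 8 untied values is exact."""
        for n_total in range(2, 9):
            vals = rng.normal(size=n_total)
            while len(set(vals)) < n_total:
                vals = rng.normal(size=n_total)
            for n1 in range(1, n_total):
                for comb in itertools.combinations(range(n_total), n1):
                    a = vals[list(comb)]
                    b = np.delete(vals, list(comb))
                    assert ox.rank_test(a, b) == pytest.approx(
                        exact_rank_p(a, b), abs=1e-12
                    )

    def test_symmetry(self, rng):
        a = rng.poisson(4, 15).astype(float)
        b = rng.poisson(6, 12).astype(float)
        assert ox.rank_test(a, b) == pytest.approx(ox.rank_test(b, a))

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            ox.rank_test([], [1.0])

    def test_axis_vectorization_matches_scalar(self, rng):
        a = rng.poisson(5, size=(8, 10)).astype(float)
        b = rng.poisson(5, size=(8, 10)).astype(float)
        vec = ox.rank_test(a, b, axis=1)
        for i in range(8):
            assert vec[i] == pytest.approx(ox.rank_test(a[i], b[i]))


def _two_group_matrix(count_a, count_b, total=10000, n_per_group=10):
    """Deterministic matrix: gene g at count_a in A cells, count_b in B."""
    n = 2 * n_per_group
    counts = np.zeros((2, n), dtype=int)
    counts[0, :n_per_group] = count_a
    counts[0, n_per_group:] = count_b
    counts[1] = total - counts[0]
    units = [f"A{i}" for i in range(n_per_group)] + [
        f"B{i}" for i in range(n_per_group)
    ]
    m = ox.CountMatrix(sp.csr_matrix(counts), ["g", "rest"], units)
    return m, units[:n_per_group], units[n_per_group:]


class TestDifferentialExpression:
    def test_small_change_never_significant(self):
        """15% change with a tiny p-value stays below the 20% floor."""
        m, a, b = _two_group_matrix(100, 115, n_per_group=200)
        table = ox.differential_expression(m, a, b, genes=["g"])
        row = table.iloc[0]
        assert row["p_adj"] < 1e-6
        assert row["pct_change"] == pytest.approx(15.0)
        assert not row["significant"]

    def test_two_fold_effect_recovered(self):
        """A simulated 2x effect at 500 cells/group is detected and the
        estimated fold lands within 20% of truth (several seeds)."""
        hits, folds = 0, []
        for seed in range(5):
            ct = ox.default_cell_types()
            ct["osteoblast"].mean_fraction["Hspa9"] *= 2.0
            a = ox.simulate_cells(
                ox.SimulationSpec(n_cells=500, seed=100 + seed, batch="a")
            )
            b = ox.simulate_cells(
                ox.SimulationSpec(
                    n_cells=500, seed=200 + seed, batch="b", cell_types=ct
                )
            )
            m = ox.merge([a, b])
            table = ox.differential_expression(
                m, a.unit_ids, b.unit_ids, genes=["Hspa9", "Hspa5"]
            )
            row = table.set_index("gene").loc["Hspa9"]
            hits += bool(row["significant"])
            folds.append(row["fold_change"])
        assert hits == 5
        assert all(abs(f - 2.0) / 2.0 < 0.2 for f in folds)

    def test_self_contrast_is_null(self, wt_cells):
        ids = wt_cells.unit_ids
        table = ox.differential_expression(
            wt_cells, ids, ids, genes=wt_cells.gene_names[:20]
        )
        clean = table[table["flag"] == ""]
        np.testing.assert_allclose(clean["fold_change"], 1.0)
        assert not table["significant"].any()

    def test_fold_inverts_under_group_swap(self, wt_cells, het_cells):
        m = ox.merge([wt_cells, het_cells])
        genes = ["Hspa9", "Actb", "Hspa5"]
        ab = ox.differential_expression(
            m, wt_cells.unit_ids, het_cells.unit_ids, genes=genes
        ).set_index("gene")
        ba = ox.differential_expression(
            m, het_cells.unit_ids, wt_cells.unit_ids, genes=genes
        ).set_index("gene")
        for g in genes:
            assert ab.loc[g, "fold_change"] == pytest.approx(
                1.0 / ba.loc[g, "fold_change"]
            )
            assert ab.loc[g, "p_raw"] == pytest.approx(ba.loc[g, "p_raw"])

    def test_zero_both_groups_flagged_not_dropped(self):
        counts = np.array([[0, 0, 0, 0, 0, 0], [10, 10, 10, 10, 10, 10]])
        m = ox.CountMatrix(
            sp.csr_matrix(counts), ["dead", "rest"],
            [f"u{i}" for i in range(6)],
        )
        table = ox.differential_expression(
            m, [f"u{i}" for i in range(3)], [f"u{i}" for i in range(3, 6)],
            genes=["dead"],
        )
        row = table.iloc[0]
        assert row["flag"] == "zero_both"
        assert row["p_raw"] == 1.0
        assert not row["significant"]

    def test_bonferroni_denominator_is_genes_tested(self):
        m, a, b = _two_group_matrix(50, 200, n_per_group=5)
        t1 = ox.differential_expression(m, a, b, genes=["g"])
        t2 = ox.differential_expression(m, a, b, genes=["g", "rest"])
        p = t1.iloc[0]["p_raw"]
        assert t1.iloc[0]["p_adj"] == pytest.approx(min(1.0, p * 1))
        assert t2.set_index("gene").loc["g", "p_adj"] == pytest.approx(
            min(1.0, p * 2)
        )

    def test_group_size_floor(self, tiny_matrix):
        with pytest.raises(ValueError, match=">="):
            ox.differential_expression(tiny_matrix, ["c1"], ["c2", "c3"])


def _de_row(gene, fold, significant):
    return {
        "gene": gene,
        "mean_A": 1.0,
        "mean_B": fold,
        "fold_change": fold,
        "pct_change": abs(fold - 1) * 100,
        "p_raw": 0.001,
        "p_adj": 0.01 if significant else 0.5,
        "significant": significant,
        "flag": "",
    }


class TestCrossTissueFilter:
    def _tables(self, fold_main=2.5, sig=True, rep_folds=(1.3, 1.2)):
        return {
            "Hom_E18.5": pd.DataFrame([_de_row("g1", fold_main, sig)]),
            "Het_P5": pd.DataFrame([_de_row("g1", 1.4, sig)]),
            "P5_exp1": pd.DataFrame([_de_row("g1", rep_folds[0], False)]),
            "P5_exp2": pd.DataFrame([_de_row("g1", rep_folds[1], False)]),
        }

    def _spec(self, annotation=None, min_categories=2):
        return CrossTissueFilterSpec(
            required_significant=["Hom_E18.5", "Het_P5"],
            min_fold_contrast="Hom_E18.5",
            min_fold=2.0,
            replication_contrasts=["P5_exp1", "P5_exp2"],
            annotation_table=annotation
            if annotation is not None
            else {"g1": {"stress", "mito"}},
            min_categories=min_categories,
        )

    def test_all_criteria_pass(self):
        genes, trace = ox.cross_tissue_filter(self._tables(), self._spec())
        assert genes == ["g1"]
        assert trace.iloc[0]["passes"]

    def test_fold_below_two_excluded(self):
        genes, trace = ox.cross_tissue_filter(
            self._tables(fold_main=1.8), self._spec()
        )
        assert genes == []
        assert not trace.iloc[0]["min_fold_met"]

    def test_downregulation_counts_as_fold_change(self):
        tables = self._tables(fold_main=0.4)
        tables["P5_exp1"].loc[0, "fold_change"] = 0.8
        tables["P5_exp2"].loc[0, "fold_change"] = 0.7
        genes, _ = ox.cross_tissue_filter(tables, self._spec())
        assert genes == ["g1"]

    def test_discordant_replication_excluded(self):
        genes, trace = ox.cross_tissue_filter(
            self._tables(rep_folds=(1.3, 0.8)), self._spec()
        )
        assert genes == []
        assert not trace.iloc[0]["replicated_direction"]

    def test_empty_annotation_empty_result(self):
        genes, trace = ox.cross_tissue_filter(
            self._tables(), self._spec(annotation={})
        )
        assert genes == []
        assert trace.iloc[0]["n_categories"] == 0

    def test_missing_contrast_errors(self):
        tables = self._tables()
        del tables["Het_P5"]
        with pytest.raises(ValueError, match="Het_P5"):
            ox.cross_tissue_filter(tables, self._spec())
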