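"""Probe collapsing, batch removal, Welch tests and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from ifxmps import (
    SimConfig,
    benjamini_hochberg,
    collapse_duplicates,
    differential_expression,
    filter_degs,
    remove_batch_effect,
    simulate_cohort,
)
from ifxmps.diffexp import DEGRecord

from .conftest import make_expression, make_phenotype


class TestCollapseDuplicates:
    def test_keeps_highest_mean_probe(self):
        frame = pd.DataFrame(
            [[5.0, 5.0], [7.0, 7.0]], index=["A", "A"], columns=["S1", "S2"]
        )
        out = collapse_duplicates(frame)
        assert out.gene_ids == ["A"]
        np.testing.assert_array_equal(out.values, [[7.0, 7.0]])

    def test_no_duplicates_is_identity(self, small_cohort):
        expr, _, _ = small_cohort
        out = collapse_duplicates(expr)
        assert out.gene_ids == expr.gene_ids
        np.testing.assert_array_equal(out.values, expr.values)

    def test_matches_brute_force_group_by_max_mean(self, rng):
        symbols = list(rng.choice([f"G{i}" for i in range(8)], size=25))
        values = rng.normal(8, 2, size=(25, 6))
        frame = pd.DataFrame(values, index=symbols,
                             columns=[f"S{j}" for j in range(6)])
        out = collapse_duplicates(frame)
        # brute-force oracle: per symbol, the row of maximal mean
        expected = {
            sym: values[[i for i, s in enumerate(symbols) if s == sym]][
                np.argmax(values[[i for i, s in enumerate(symbols) if s == sym]].mean(axis=1))
            ]
            for sym in dict.fromkeys(symbols)
        }
        assert set(out.gene_ids) == set(expected)
        for gene, row in expected.items():
            np.testing.assert_array_equal(out.to_frame().loc[gene].to_numpy(), row)


class TestRemoveBatchEffect:
    def test_single_batch_is_identity(self, small_cohort):
        expr, pheno, _ = small_cohort
        out = remove_batch_effect(expr, pheno)
        np.testing.assert_array_equal(out.values, expr.values)

    def test_between_batch_difference_removed_within_class(self):
        cfg = SimConfig(
            n_genes=300, n_sig_down_in_resp=10, n_sig_up_in_resp=0,
            n_resp=40, n_nonresp=40, delta=2.0, sigma=0.5,
            batch_offsets={"b1": 0.0, "b2": 1.0},
            batch_assignment=(["b1"] * 20 + ["b2"] * 20) * 2, seed=21,
        )
        expr, pheno, _ = simulate_cohort(cfg)
        out = remove_batch_effect(expr, pheno)
        resp_b1 = [i for i, (r, b) in enumerate(zip(pheno.response, pheno.batch))
                   if r == "responder" and b == "b1"]
        resp_b2 = [i for i, (r, b) in enumerate(zip(pheno.response, pheno.batch))
                   if r == "responder" and b == "b2"]
        diff = out.values[:, resp_b1].mean(axis=1) - out.values[:, resp_b2].mean(axis=1)
        se = cfg.sigma * np.sqrt(1 / len(resp_b1) + 1 / len(resp_b2))
        assert np.abs(diff.mean()) < 3 * se / np.sqrt(cfg.n_genes)
        assert np.abs(diff).max() < 4 * se

    def test_planted_class_effect_preserved(self):
        cfg = SimConfig(
            n_genes=200, n_sig_down_in_resp=20, n_sig_up_in_resp=0,
            n_resp=200, n_nonresp=200, delta=2.0, sigma=0.5,
            batch_offsets={"b1": 0.0, "b2": 1.5},
            batch_assignment=(["b1"] * 100 + ["b2"] * 100) * 2, seed=22,
        )
        expr, pheno, _ = simulate_cohort(cfg)
        is_resp = np.array([r == "responder" for r in pheno.response])

        def lfc(matrix):
            return matrix[:, is_resp].mean(axis=1) - matrix[:, ~is_resp].mean(axis=1)

        out = remove_batch_effect(expr, pheno)
        np.testing.assert_allclose(lfc(out.values), lfc(expr.values), atol=0.05)

    def test_grand_mean_preserved(self, rng):
        expr = make_expression(rng.normal(8, 1, size=(30, 12)))
        pheno = make_phenotype(6, 6)
        pheno.batch = ["b1"] * 3 + ["b2"] * 3 + ["b1"] * 3 + ["b2"] * 3
        out = remove_batch_effect(expr, pheno)
        np.testing.assert_allclose(
            out.values.mean(axis=1), expr.values.mean(axis=1), atol=1e-10
        )

    def test_confounded_batch_recorded_in_metadata(self, rng):
        expr = make_expression(rng.normal(8, 1, size=(10, 8)))
        pheno = make_phenotype(4, 4)
        pheno.batch = ["b1"] * 4 + ["b2"] * 4  # batch == class
        out = remove_batch_effect(expr, pheno)
        assert any("confounded" in w for w in out.metadata["warnings"])


class TestDifferentialExpression:
    def test_identical_values_give_zero_lfc_p_one(self):
        expr = make_expression(np.full((1, 6), 5.0))
        records = differential_expression(expr, make_phenotype(3, 3))
        assert records[0].log2fc == 0.0
        assert records[0].p_value == 1.0

    def test_exact_mean_difference(self):
        expr = make_expression([[5.0, 5.1, 4.9, 3.0, 3.1, 2.9]])
        records = differential_expression(expr, make_phenotype(3, 3))
        assert records[0].log2fc == pytest.approx(2.0, abs=1e-12)
        assert records[0].direction == "up"

    def test_zero_variance_unequal_means_p_zero(self):
        expr = make_expression([[5.0, 5.0, 5.0, 3.0, 3.0, 3.0]])
        records = differential_expression(expr, make_phenotype(3, 3))
        assert records[0].p_value == 0.0

    def test_p_values_match_textbook_welch_formula(self, rng):
        """Oracle: hand-coded t statistic and Welch-Satterthwaite df."""
        from scipy.stats import t as t_dist

        for _ in range(20):
            n1, n2 = rng.integers(3, 10), rng.integers(3, 10)
            a, b = rng.normal(0, 1, n1), rng.normal(0.5, 2, n2)
            expr = make_expression(np.concatenate([a, b])[None, :])
            rec = differential_expression(expr, make_phenotype(int(n1), int(n2)))[0]
            v1, v2 = a.var(ddof=1), b.var(ddof=1)
            t_stat = (a.mean() - b.mean()) / np.sqrt(v1 / n1 + v2 / n2)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
            expected = 2 * t_dist.sf(abs(t_stat), df)
            assert rec.p_value == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_sample_reordering(self, rng, small_cohort):
        expr, pheno, _ = small_cohort
        before = differential_expression(expr, pheno)
        perm = rng.permutation(expr.n_samples)
        shuffled = make_expression(expr.values[:, perm])
        shuffled.gene_ids = expr.gene_ids
        shuffled.sample_ids = [expr.sample_ids[i] for i in perm]
        after = differential_expression(shuffled, pheno)
        for r1, r2 in zip(before, after):
            assert r1.log2fc == pytest.approx(r2.log2fc, abs=1e-10)
            assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)

    def test_invariant_under_per_gene_constant_shift(self, small_cohort):
        expr, pheno, _ = small_cohort
        before = differential_expression(expr, pheno)[0]
        shifted = make_expression(expr.values.copy())
        shifted.gene_ids = expr.gene_ids
        shifted.sample_ids = expr.sample_ids
        shifted.values[0] += 7.5
        after = differential_expression(shifted, pheno)[0]
        assert after.log2fc == pytest.approx(before.log2fc, abs=1e-9)
        assert after.p_value == pytest.approx(before.p_value, rel=1e-9)

    def test_single_sample_class_rejected(self, rng):
        expr = make_expression(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_expression(expr, make_phenotype(1, 2))


def bh_brute_force(p):
    """Step-up definition applied literally: fdr_(i) = min_{j>=i} m p_(j)/j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    fdr = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
        fdr[idx] = min(1.0, min(candidates))
    return fdr


class TestBenjaminiHochberg:
    def test_singleton_identity(self):
        np.testing.assert_array_equal(benjamini_hochberg([0.05]), [0.05])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_worked_example_matches_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(benjamini_hochberg(p), bh_brute_force(p), atol=1e-15)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    def test_matches_brute_force_on_random_vectors(self, p):
        p = np.array(p)
        np.testing.assert_allclose(benjamini_hochberg(p), bh_brute_force(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        for _ in range(10):
            p = rng.uniform(size=rng.integers(1, 100))
            np.testing.assert_allclose(
                benjamini_hochberg(p),
                multipletests(p, method="fdr_bh")[1],
                atol=1e-12,
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestFilterDegs:
    @pytest.mark.parametrize(
        "fdr,lfc,kept",
        [
            (0.05, 2.0, False),   # fdr boundary is strict
            (0.01, 1.0, False),   # lfc boundary is strict
            (0.049, 1.01, True),
            (0.01, -1.5, True),   # magnitude counts, sign does not
        ],
    )
    def test_strict_thresholds(self, fdr, lfc, kept):
        rec = DEGRecord("G", lfc, fdr / 2, fdr)
        assert (rec in filter_degs([rec])) is kept

    def test_planted_genes_pass_nulls_fail(self):
        """delta=2, sigma=0.3, 23/23: planted genes pass, >=99% of nulls fail."""
        planted_pass, null_fail, null_total = 0, 0, 0
        for seed in range(20):
            cfg = SimConfig(n_genes=1000, n_sig_down_in_resp=28, n_sig_up_in_resp=2,
                            n_resp=23, n_nonresp=23, delta=2.0, sigma=0.3, seed=seed)
            expr, pheno, truth = simulate_cohort(cfg)
            kept = {r.gene_id for r in
                    filter_degs(differential_expression(expr, pheno))}
            planted_pass += len(kept & set(truth.gene_ids))
            nulls = set(expr.gene_ids) - set(truth.gene_ids)
            null_total += len(nulls)
            null_fail += len(nulls - kept)
        assert planted_pass == 20 * 30
        assert null_fail / null_total >= 0.99


def test_global_null_false_positive_fraction_controlled():
    """Under delta=0, the expected fraction of fdr<0.05 genes stays below 0.05."""
    fractions = []
    for seed in range(20):
        cfg = SimConfig(n_genes=2000, n_sig_down_in_resp=0, n_sig_up_in_resp=0,
                        n_resp=23, n_nonresp=23, delta=0.0, sigma=0.5, seed=seed)
        expr, pheno, _ = simulate_cohort(cfg)
        records = differential_expression(expr, pheno)
        fractions.append(np.mean([r.fdr < 0.05 for r in records]))
    assert np.mean(fractions) <= 0.05
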