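"""Per-platform candidate selectors and the shared BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import omicdriver as od
from omicdriver.multitest import bh_adjust


def bh_stepup_reference(p):
    """Independent BH oracle: q_i = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBH:
    def test_worked_example(self):
        # p = [.01,.02,.03,.04], m=4: all adjusted values collapse to 0.04
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    def test_agrees_with_stepup_enumeration(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals),
                                   bh_stepup_reference(pvals), atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestDifferentialExpression:
    def test_identical_groups_not_significant(self):
        # row 'a' is constant everywhere (degenerate, p forced to 1);
        # row 'b' has identical per-group distributions (t = 0, p = 1)
        expr = pd.DataFrame([[5.0] * 6, [0, 1, 2, 0, 1, 2.0]],
                            index=list("ab"),
                            columns=[f"s{i}" for i in range(6)])
        flags = pd.Series([True, True, True, False, False, False],
                          index=expr.columns)
        res = od.differential_expression(expr, flags)
        assert res.loc["a", "degenerate"]
        assert res.loc["a", "p"] == 1.0
        assert not res.loc["b", "degenerate"]
        assert res.loc["b", "t"] == 0.0
        assert res.loc["b", "p"] == 1.0
        assert not res["significant"].any()

    def test_two_sd_shift_power(self, rng):
        # a 2-SD mean shift at 30 vs 30 samples: nearly all shifted genes
        # flagged at FDR 0.05, none of the null genes beyond ~5%
        shifted = 2.0 + rng.standard_normal((100, 30))
        null = rng.standard_normal((100, 30))
        tum = np.vstack([shifted, null])
        nor = rng.standard_normal((200, 30))
        expr = pd.DataFrame(np.hstack([tum, nor]),
                            index=[f"g{i}" for i in range(200)],
                            columns=[f"s{i}" for i in range(60)])
        flags = pd.Series([True] * 30 + [False] * 30, index=expr.columns)
        res = od.differential_expression(expr, flags)
        assert res["significant"][:100].mean() >= 0.95
        assert res["significant"][100:].mean() <= 0.05

    def test_direction_from_fold_change(self, default_cohort):
        cohort, truth = default_cohort
        res = od.differential_expression(cohort.expression,
                                         cohort.tumor_flags)
        for reg in truth.planted_regulators:
            genes = truth.module_of_gene.index[
                truth.module_of_gene == reg.module]
            assert np.sign(res.loc[genes, "lfc"].mean()) == reg.sign


class TestDifferentialMethylation:
    def _toy(self, silencer=True, shuffle_expr=False, seed=0):
        rng = np.random.default_rng(seed)
        n_t, n_n = 40, 20
        samples = [f"T{i}" for i in range(n_t)] + [f"N{i}" for i in range(n_n)]
        flags = pd.Series([True] * n_t + [False] * n_n, index=samples)
        beta = 0.2 + 0.03 * rng.random((5, n_t + n_n))
        expr = 8.0 + 0.3 * rng.standard_normal((5, n_t + n_n))
        if silencer:
            hi = rng.choice(n_t, n_t // 2, replace=False)
            beta[0, hi] = 0.8 + 0.03 * rng.random(len(hi))
            expr[0, hi] -= 2.0
        b = pd.DataFrame(beta, index=list("abcde"), columns=samples)
        e = pd.DataFrame(expr, index=list("abcde"), columns=samples)
        if shuffle_expr:
            e.loc["a", samples[:n_t]] = rng.permutation(
                e.loc["a", samples[:n_t]].to_numpy())
        return b, e, flags

    def test_no_difference_no_candidates(self):
        b, e, flags = self._toy(silencer=False)
        res = od.differential_methylation(b, e, flags)
        assert len(res) == 0

    def test_planted_silencer_detected(self):
        b, e, flags = self._toy(silencer=True)
        res = od.differential_methylation(b, e, flags)
        assert "a" in res.index
        assert res.loc["a", "direction"] == "down"
        assert res.loc["a", "delta_beta"] > 0.4

    def test_predictivity_filter_rejects_shuffled_expression(self):
        hits = 0
        for seed in range(25):
            b, e, flags = self._toy(silencer=True, shuffle_expr=True,
                                    seed=seed)
            res = od.differential_methylation(b, e, flags)
            hits += "a" in res.index
        assert hits <= 2  # >= ~95% rejected by the predictivity filter


class TestMirnaCandidates:
    def test_perfect_anticorrelation(self):
        mir = pd.DataFrame([[1, 2, 3, 4.0]], index=["m1"],
                           columns=list("wxyz"))
        mrna = pd.DataFrame([[8, 6, 4, 2.0]], index=["g1"],
                            columns=list("wxyz"))
        inter = pd.DataFrame({"mirna": ["m1"], "target": ["g1"]})
        res = od.mirna_candidates(mir, mrna, inter)
        assert res.loc[0, "rho"] == pytest.approx(-1.0)

    def test_spearman_closed_form(self, rng):
        # tie-free: rho = 1 - 6*sum(d^2)/(n(n^2-1)), checked on random data
        x = rng.permutation(20).astype(float)
        y = rng.permutation(20).astype(float)
        mir = pd.DataFrame([x], index=["m1"],
                           columns=[f"s{i}" for i in range(20)])
        mrna = pd.DataFrame([y], index=["g1"], columns=mir.columns)
        inter = pd.DataFrame({"mirna": ["m1"], "target": ["g1"]})
        res = od.mirna_candidates(mir, mrna, inter)
        d = np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))
        expected = 1 - 6 * (d ** 2).sum() / (20 * (20 ** 2 - 1))
        assert res.loc[0, "rho"] == pytest.approx(expected)

    def test_positive_pairs_excluded_and_unknown_skipped(self):
        mir = pd.DataFrame([[1, 2, 3, 4.0]], index=["m1"],
                           columns=list("wxyz"))
        mrna = pd.DataFrame([[1, 2, 3, 4.0]], index=["g1"],
                            columns=list("wxyz"))
        inter = pd.DataFrame({"mirna": ["m1", "m9"],
                              "target": ["g1", "g9"]})
        res = od.mirna_candidates(mir, mrna, inter)
        assert len(res) == 1            # unknown pair skipped
        assert not res["kept"].any()    # positive rho filtered


class TestMutationCnvCandidates:
    def test_mutation_frequency_rule(self):
        m = pd.DataFrame(0, index=["g1", "g2"],
                         columns=[f"t{i}" for i in range(100)])
        m.iloc[0, :3] = 1       # 3% >= 2% kept
        m.iloc[1, :1] = 1       # 1% dropped
        assert od.mutation_candidates(m, min_frequency=0.02) == ["g1"]

    def test_external_list_intersection(self):
        m = pd.DataFrame(0, index=["TP53", "CTNNB1", "OTHER"],
                         columns=["t1"])
        got = od.mutation_candidates(m, external_list=["TP53", "CTNNB1",
                                                       "ABSENT"])
        assert got == ["TP53", "CTNNB1"]

    def test_all_zero_matrix_empty(self):
        m = pd.DataFrame(0, index=["g1"], columns=["t1", "t2"])
        assert od.mutation_candidates(m) == []

    def test_cnv_amp_del_independent(self):
        cnv = pd.DataFrame(0, index=["amp", "both", "zero"],
                           columns=[f"t{i}" for i in range(10)])
        cnv.loc["amp", cnv.columns[:2]] = 2
        cnv.loc["both", cnv.columns[:2]] = 2
        cnv.loc["both", cnv.columns[2:4]] = -1
        amp, dele = od.cnv_candidates(cnv, min_frequency=0.1)
        assert set(amp) == {"amp", "both"}
        assert dele == ["both"]


class TestAssembleAndMonotonicity:
    def test_multi_platform_gene_gets_two_entries(self, default_cohort):
        cohort, _ = default_cohort
        cs = od.assemble_candidates(
            samples=cohort.tumors, expr=cohort.expression,
            cnv_amp=["G0000"], cnv_matrix=cohort.cnv,
            methylation_table=pd.DataFrame(
                {"rho": [-0.5], "q": [0.01], "direction": ["down"]},
                index=["G0000"]),
            beta_matrix=cohort.methylation)
        assert len(cs) == 2
        assert set(cs.entries["platform"]) == {"cnv_amp", "methylation"}
        assert cs.entries["id"].nunique() == 1

    def test_empty_inputs_yield_empty_set(self, default_cohort):
        cohort, _ = default_cohort
        cs = od.assemble_candidates(samples=cohort.tumors,
                                    expr=cohort.expression)
        assert len(cs) == 0

    def test_planted_regulators_present_at_defaults(self, default_cohort):
        cohort, truth = default_cohort
        cs = od.candidates_from_cohort(cohort)
        assert set(truth.regulator_ids) <= set(cs.ids)

    def test_selection_monotone_in_thresholds(self, default_cohort):
        cohort, _ = default_cohort
        loose = od.mutation_candidates(cohort.mutation, cohort.tumor_flags,
                                       min_frequency=0.02)
        strict = od.mutation_candidates(cohort.mutation, cohort.tumor_flags,
                                        min_frequency=0.1)
        assert set(strict) <= set(loose)
        amp_l, del_l = od.cnv_candidates(cohort.cnv, cohort.tumor_flags,
                                         min_frequency=0.05)
        amp_s, del_s = od.cnv_candidates(cohort.cnv, cohort.tumor_flags,
                                         min_frequency=0.2)
        assert set(amp_s) <= set(amp_l) and set(del_s) <= set(del_l)

    def test_permuted_labels_control_false_positives(self):
        # permuting tumor/normal labels: DE candidate rate at FDR 0.05
        # stays near zero on average
        rates = []
        for seed in range(10):
            cohort, _ = od.generate_cohort(od.SimConfig(
                seed=seed, n_genes=100, n_modules=2, genes_per_module=20))
            rng = np.random.default_rng(seed)
            flags = pd.Series(rng.permutation(cohort.tumor_flags.to_numpy()),
                              index=cohort.tumor_flags.index)
            res = od.differential_expression(cohort.expression, flags)
            rates.append(res["significant"].mean())
        assert np.mean(rates) <= 0.05
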