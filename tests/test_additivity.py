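"""Expression ratios, the additive "Sum" null and exact Wilcoxon tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from communitylens import Condition
from communitylens.additivity import (additivity_tests, bonferroni_adjust,
                                      build_ratio_table, exact_wilcoxon_signed,
                                      expression_ratios, pairwise_sum)
from communitylens.count_data import CountMatrix, cpm_normalize


def brute_force_signed_rank(x, y):
    """Oracle: enumerate all sign assignments of the nonzero differences."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([np.sum(ranks[np.array(s)]) if any(s) else 0.0
                   for s in itertools.product([False, True], repeat=d.size)])
    n = ws.size
    cdf = np.sum(ws <= w_obs + 1e-12) / n
    sf = np.sum(ws >= w_obs - 1e-12) / n
    return min(1.0, 2.0 * min(cdf, sf))


class TestRatios:
    def _nm(self, col_by_cond):
        meta, cols = {}, {}
        for cond, values in col_by_cond.items():
            meta[f"{cond.name}_r1"] = (cond, 1)
            cols[f"{cond.name}_r1"] = values
        genes = [f"g{i}" for i in range(len(next(iter(col_by_cond.values()))))]
        cm = CountMatrix("F", pd.DataFrame(cols, index=genes), meta)
        return cpm_normalize(cm)

    def test_ratio_of_condition_means(self):
        alone, fp = Condition({"F"}), Condition({"F", "P"})
        nm = self._nm({alone: [100, 999900], fp: [200, 999800]})
        r = expression_ratios(nm, fp, alone)
        assert r.loc["g0"] == pytest.approx(2.0, rel=1e-2)

    def test_identical_condition_gives_unity(self):
        alone = Condition({"F"})
        nm = self._nm({alone: [5, 50, 500]})
        assert np.allclose(expression_ratios(nm, alone, alone), 1.0)

    def test_pseudo_count_rescues_zero_baseline(self):
        alone, fp = Condition({"F"}), Condition({"F", "P"})
        # alone mean 0 cpm, condition mean 10 cpm, pseudo 0.5 -> ratio 21
        meta = {"F_r1": (alone, 1), "FP_r1": (fp, 1)}
        counts = pd.DataFrame({"F_r1": [0, 1000000], "FP_r1": [10, 999990]},
                              index=["g0", "g1"])
        nm = cpm_normalize(CountMatrix("F", counts, meta))
        r = expression_ratios(nm, fp, alone, pseudo_cpm=0.5)
        assert r.loc["g0"] == pytest.approx(21.0, rel=1e-3)

    def test_wrong_alone_condition_rejected(self):
        alone, fp = Condition({"F"}), Condition({"F", "P"})
        nm = self._nm({alone: [1], fp: [1]})
        with pytest.raises(ValueError):
            expression_ratios(nm, fp, fp)


class TestPairwiseSum:
    def test_log_additivity(self):
        assert pairwise_sum(pd.Series([2.0]), pd.Series([4.0]))[0] == 8.0

    def test_neutral_partner_is_identity(self):
        r = pd.Series([0.3, 1.0, 7.2])
        assert np.allclose(pairwise_sum(r, pd.Series([1.0, 1.0, 1.0])), r)

    def test_opposite_regulation_cancels(self):
        assert pairwise_sum(pd.Series([4.0]), pd.Series([0.25]))[0] == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pairwise_sum(pd.Series([0.0]), pd.Series([1.0]))


class TestExactWilcoxon:
    def test_equal_vectors_give_one(self):
        assert exact_wilcoxon_signed([1, 2, 3], [1, 2, 3]) == 1.0

    def test_all_positive_n6(self):
        p = exact_wilcoxon_signed([2, 3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6])
        assert p == pytest.approx(2.0 / 64.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(14)
        for n in range(2, 11):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert exact_wilcoxon_signed(x, y) == pytest.approx(
                brute_force_signed_rank(x, y), abs=1e-12)

    def test_matches_oracle_with_ties_and_zeros(self):
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0, 6.0, 3.0])
        y = np.array([0.0, 1.0, 3.0, 4.0, 4.0, 5.0, 4.0])
        assert exact_wilcoxon_signed(x, y) == pytest.approx(
            brute_force_signed_rank(x, y), abs=1e-12)

    def test_agrees_with_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        ours = exact_wilcoxon_signed(x, y)
        ref = stats.wilcoxon(x, y, mode="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(16)
        x = rng.normal(0.3, 1, 60)
        y = rng.normal(0.0, 1, 60)
        ours = exact_wilcoxon_signed(x, y)
        ref = stats.wilcoxon(x, y, correction=True, mode="approx").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=9))
    def test_p_in_unit_interval_and_symmetric(self, diffs):
        x = np.array(diffs, dtype=float)
        y = np.zeros_like(x)
        p = exact_wilcoxon_signed(x, y)
        assert 0 <= p <= 1
        assert exact_wilcoxon_signed(y, x) == pytest.approx(p, abs=1e-12)


class TestBonferroni:
    def test_basic_and_capped(self):
        assert bonferroni_adjust([0.01], 3)[0] == pytest.approx(0.03)
        assert bonferroni_adjust([0.5], 3)[0] == 1.0

    def test_default_family_is_length(self):
        assert bonferroni_adjust([0.01, 0.02]) == pytest.approx([0.02, 0.04])

    def test_family_smaller_than_vector_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.1, 0.1], 2)

    def test_panel_family_matches_hand_count(self):
        # 3 contrasts x 2 gene sets analyzed as one panel: family = 6
        p = [0.004, 0.012, 0.2, 0.03, 0.5, 0.001]
        adj = bonferroni_adjust(p, family_size=6)
        assert adj == pytest.approx([0.024, 0.072, 1.0, 0.18, 1.0, 0.006])


class TestAdditivityReport:
    def _flat_ratio_table(self):
        conds = [Condition({"F"}), Condition({"B", "F"}), Condition({"F", "P"}),
                 Condition({"B", "F", "P"})]
        meta, cols = {}, {}
        rng = np.random.default_rng(17)
        base = rng.integers(100, 1000, 40)
        for cond in conds:
            for r in (1, 2):
                sid = f"{cond.name}_r{r}"
                meta[sid] = (cond, r)
                cols[sid] = base
        cm = CountMatrix("F", pd.DataFrame(cols, index=[f"g{i}" for i in range(40)]),
                         meta)
        nm = cpm_normalize(cm)
        return build_ratio_table(nm, *conds)

    def test_all_unity_ratios_give_p_one(self):
        rt = self._flat_ratio_table()
        report = additivity_tests(rt, rt.table.index)
        assert (report["p"] == 1.0).all()
        assert (report["p_adjusted"] == 1.0).all()
        assert set(report["contrast"]) == {"BFP_vs_BF", "BFP_vs_FP", "BFP_vs_Sum"}

    def test_sum_identity_on_log_scale(self):
        rt = self._flat_ratio_table()
        t = rt.table
        assert np.allclose(np.log10(t["sum_predicted"]),
                           np.log10(t["ratio_pairwise1"]) + np.log10(t["ratio_pairwise2"]))

    def test_gene_order_invariance(self):
        rt = self._flat_ratio_table()
        genes = list(rt.table.index)
        fwd = additivity_tests(rt, genes)
        rev = additivity_tests(rt, genes[::-1])
        assert np.allclose(fwd["p"], rev["p"])

    def test_small_set_warns_but_runs(self):
        rt = self._flat_ratio_table()
        with pytest.warns(UserWarning, match="only 3 genes"):
            report = additivity_tests(rt, list(rt.table.index[:3]))
        assert len(report) == 3

    def test_empty_set_rejected(self):
        rt = self._flat_ratio_table()
        with pytest.raises(ValueError):
            additivity_tests(rt, [])
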