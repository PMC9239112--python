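"""Conditions, count I/O, low-expression filter and cpm normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from communitylens import Condition
from communitylens.conditions import core_conditions
from communitylens.count_data import (CountMatrix, condition_means, cpm_normalize,
                                      filter_low_expression, median_of_ratios_factors,
                                      read_counts, read_sample_sheet, write_counts,
                                      write_sample_sheet)
from communitylens.simulate import simulate_community

from conftest import small_config, toy_count_matrix


class TestCondition:
    def test_canonical_name_sorts_members(self):
        assert Condition({"P", "F"}).name == "FP"
        assert Condition({"B", "F", "P"}).name == "BFP"
        assert Condition({"F", "P"}, genotype="dkec").name == "FP_dkec"
        assert Condition({"F", "P"}, inoculum="low").name == "FP_PLI"

    def test_equality_is_member_order_free(self):
        assert Condition("PF") == Condition("FP")
        assert Condition("FP") != Condition("FP", genotype="dkec")
        assert hash(Condition("PF")) == hash(Condition("FP"))

    def test_from_name_round_trip(self):
        for name in ["B", "BF", "BFP", "BP_dkec", "FP_PLI"]:
            assert Condition.from_name(name).name == name

    def test_mutant_requires_producer(self):
        with pytest.raises(ValueError):
            Condition({"B", "F"}, genotype="dkec")
        with pytest.raises(ValueError):
            Condition({"B"}, inoculum="low")

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            Condition(set())

    def test_core_conditions(self):
        names = [c.name for c in core_conditions("F", ("B", "F", "P"))]
        assert names == ["F", "BF", "FP", "BFP"]


class TestCountIO:
    def test_round_trip_is_byte_identical(self, tmp_path):
        cm = toy_count_matrix(n_genes=3, replicates=2)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_counts(cm, p1)
        back = read_counts(p1, "F", cm.sample_meta)
        assert back.counts.shape == (3, 2)
        assert (back.counts.values == cm.counts.values).all()
        write_counts(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    @pytest.mark.parametrize("bad,msg", [("-1", "negative"), ("1.5", "non-integer"),
                                         ("x", "non-numeric")])
    def test_bad_cell_identified(self, tmp_path, bad, msg):
        path = tmp_path / "c.tsv"
        path.write_text(f"gene_id\ts1\ts2\ng1\t5\t3\ng2\t{bad}\t7\n")
        with pytest.raises(ValueError, match=f"{msg}.*g2.*s1"):
            read_counts(path, "F")

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("gene_id\ts1\ng1\t5\ng1\t3\n")
        with pytest.raises(ValueError, match="duplicate gene"):
            read_counts(path, "F")

    def test_species_must_be_in_sample_condition(self):
        meta = {"s1": (Condition({"B"}), 1)}
        with pytest.raises(ValueError, match="does not contain species"):
            CountMatrix("F", pd.DataFrame({"s1": [1]}, index=["g1"]), meta)

    def test_simulator_output_readable(self, tmp_path):
        from communitylens.simulate import write_simulation
        sim = simulate_community(small_config(60), seed=5)
        write_simulation(sim, tmp_path)
        meta = read_sample_sheet(tmp_path / "sample_sheet.tsv")
        cm = read_counts(tmp_path / "counts_F.tsv", "F", meta)
        assert set(cm.samples) == set(sim.counts["F"].samples)
        assert all(s in meta for s in cm.samples)
        conds = {c.name for c in cm.conditions()}
        assert {"F", "BF", "FP", "BFP"} <= conds


class TestSampleSheet:
    def _sheet(self, tmp_path, rows):
        path = tmp_path / "sheet.tsv"
        head = "sample_id\tspecies_present\tgenotype\tinoculum\treplicate\n"
        path.write_text(head + "".join("\t".join(map(str, r)) + "\n" for r in rows))
        return path

    def test_membership_canonicalized(self, tmp_path):
        path = self._sheet(tmp_path, [("s1", "FP", "WT", "standard", 1),
                                      ("s2", "PF", "WT", "standard", 2)])
        meta = read_sample_sheet(path)
        assert meta["s1"][0] == meta["s2"][0] == Condition({"F", "P"})
        assert meta["s2"][1] == 2

    def test_duplicate_sample_rejected(self, tmp_path):
        path = self._sheet(tmp_path, [("s1", "F", "WT", "standard", 1),
                                      ("s1", "F", "WT", "standard", 2)])
        with pytest.raises(ValueError, match="listed twice"):
            read_sample_sheet(path)

    def test_mutant_without_producer_rejected(self, tmp_path):
        path = self._sheet(tmp_path, [("s1", "BF", "dkec", "standard", 1)])
        with pytest.raises(ValueError):
            read_sample_sheet(path)

    def test_unknown_enum_rejected(self, tmp_path):
        path = self._sheet(tmp_path, [("s1", "F", "mut", "standard", 1)])
        with pytest.raises(ValueError, match="genotype"):
            read_sample_sheet(path)

    def test_write_round_trip(self, tmp_path):
        meta = {"s1": (Condition({"F", "P"}), 1), "s2": (Condition({"F"}), 2)}
        path = tmp_path / "out.tsv"
        write_sample_sheet(meta, path)
        assert read_sample_sheet(path) == meta


class TestFilter:
    def _matrix_with_totals(self, totals):
        conds = core_conditions("F")
        meta, cols = {}, {}
        for cond in conds:
            meta[f"{cond.name}_r1"] = (cond, 1)
        n = len(totals)
        per = np.array(totals) // 4
        rem = np.array(totals) - 3 * per
        for i, cond in enumerate(conds):
            cols[f"{cond.name}_r1"] = per if i < 3 else rem
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
        return CountMatrix("F", counts, meta), conds

    def test_sum_threshold_boundary(self):
        cm, conds = self._matrix_with_totals([9, 10, 11])
        kept = filter_low_expression(cm, conds, 10)
        assert list(kept.genes) == ["g1", "g2"]

    def test_idempotent_and_order_preserving(self):
        cm, conds = self._matrix_with_totals([50, 9, 30, 10])
        once = filter_low_expression(cm, conds, 10)
        twice = filter_low_expression(once, conds, 10)
        assert list(once.genes) == ["g0", "g2", "g3"]
        assert list(twice.genes) == list(once.genes)

    def test_each_mode_is_stricter(self):
        cm, conds = self._matrix_with_totals([40, 43])
        # g0: 10 in each condition; g1: 10,10,10,13
        each = filter_low_expression(cm, conds, 10, mode="each")
        assert list(each.genes) == ["g0", "g1"]
        cm2, _ = self._matrix_with_totals([39])  # 9,9,9,12: fails 'each', passes 'sum'
        assert len(filter_low_expression(cm2, conds, 10, mode="each").genes) == 0
        assert len(filter_low_expression(cm2, conds, 10, mode="sum").genes) == 1

    def test_missing_condition_is_error(self):
        cm, conds = self._matrix_with_totals([50])
        absent = Condition({"F", "P"}, inoculum="low")
        with pytest.raises(ValueError, match="no samples"):
            filter_low_expression(cm, conds + [absent], 10)

    def test_simulated_retained_fraction_matches_expressed_fraction(self, small_sim):
        cfg = small_sim.config
        cm = small_sim.counts["F"]
        kept = filter_low_expression(cm, core_conditions("F"), 10)
        frac = len(kept.genes) / len(cm.genes)
        assert abs(frac - cfg.expressed_fraction) < 0.03


class TestCpm:
    def test_single_gene_example(self):
        meta = {"s1": (Condition({"F"}), 1)}
        counts = pd.DataFrame({"s1": [500, 999500]}, index=["g1", "g2"])
        nm = cpm_normalize(CountMatrix("F", counts, meta))
        assert nm.values.loc["g1", "s1"] == pytest.approx(500.0)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=30).filter(lambda v: sum(v) > 0),
           st.integers(2, 7))
    def test_columns_sum_to_million(self, column, mult):
        counts = pd.DataFrame({"s1": column, "s2": [c * mult for c in column]},
                              index=[f"g{i}" for i in range(len(column))])
        nm = cpm_normalize(CountMatrix("F", counts,
                                       {"s1": (Condition({"F"}), 1),
                                        "s2": (Condition({"F"}), 2)}))
        assert nm.values["s1"].sum() == pytest.approx(1e6, rel=1e-9)
        # cpm is invariant to uniform per-column scaling
        assert np.allclose(nm.values["s1"], nm.values["s2"])

    def test_zero_column_names_sample(self):
        counts = pd.DataFrame({"s1": [1], "s2": [0]}, index=["g1"])
        cm = CountMatrix("F", counts, {"s1": (Condition({"F"}), 1),
                                       "s2": (Condition({"F"}), 2)})
        with pytest.raises(ValueError, match="s2"):
            cpm_normalize(cm)

    def test_condition_means(self):
        cond = Condition({"F"})
        meta = {"s1": (cond, 1), "s2": (cond, 2)}
        counts = pd.DataFrame({"s1": [10, 999990], "s2": [30, 999970]}, index=["g1", "g2"])
        nm = cpm_normalize(CountMatrix("F", counts, meta))
        assert condition_means(nm, cond).loc["g1"] == pytest.approx(20.0)
        with pytest.raises(ValueError, match="no samples"):
            condition_means(nm, Condition({"B", "F"}))

    def test_nb_condition_mean_recovery(self):
        # 4 replicates of NB data: sample mean within 4 SE of the true mean
        mu, phi, n = 200.0, 0.1, 4
        cm = toy_count_matrix(replicates=n, n_genes=300, mean=mu, phi=phi, seed=3)
        nm = cpm_normalize(cm)
        means = condition_means(nm, Condition({"F"}))
        cpm_mu = mu / (300 * mu) * 1e6
        se = cpm_mu * np.sqrt((1 / mu + phi) / n)
        assert (np.abs(means - cpm_mu) < 4 * se).mean() > 0.95

    def test_median_of_ratios_absorbs_composition_shift(self):
        # 40% of genes 4x up in sample 2: factors should rescale so that
        # unchanged genes keep equal effective cpm
        rng = np.random.default_rng(0)
        base = rng.integers(200, 2000, 200)
        up = np.concatenate([base[:80] * 4, base[80:]])
        counts = pd.DataFrame({"s1": base, "s2": up},
                              index=[f"g{i}" for i in range(200)])
        cm = CountMatrix("F", counts, {"s1": (Condition({"F"}), 1),
                                       "s2": (Condition({"F"}), 2)})
        nm = cpm_normalize(cm, norm_factors=median_of_ratios_factors(cm))
        stable = nm.values.iloc[80:]
        ratio = (stable["s2"] / stable["s1"]).median()
        assert ratio == pytest.approx(1.0, rel=1e-6)
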