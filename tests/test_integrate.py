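"""GSRC definition, coverage classes, correlation, contrasts, enrichment."""
import math

import numpy as np
import pandas as pd
import pytest

from phasiclust.integrate import (
    correlate,
    coverage_class,
    define_gsrcs,
    enrichment,
    intersections,
    mutant_contrast,
    size_factors,
)
from phasiclust.records import GeneModel, GeneSRCLink, SRC
from phasiclust.synthetic import simulate_contrast_counts


def link(gene, src, action="retain"):
    return GeneSRCLink(gene_id=gene, src_id=src, overlap_bp=100, gene_frac=0.5,
                       src_frac=1.0, action=action)


class TestDefineGsrcs:
    def test_gene_in_all_serotypes_is_gsrc(self):
        links = {st: [link("g1", f"s_{st}")] for st in "ABDH"}
        gsrcs, present = define_gsrcs(links)
        assert gsrcs == ["g1"]
        assert present["g1"] == set("ABDH")

    def test_gene_in_three_of_four_is_not_gsrc_but_counted(self):
        links = {st: [link("g1", "s1")] for st in "ABD"}
        links["H"] = []
        gsrcs, present = define_gsrcs(links)
        assert gsrcs == []
        assert present["g1"] == set("ABD")

    def test_discard_links_ignored(self):
        links = {"A": [link("g1", "s1")], "B": [link("g1", "s1", action="discard")]}
        gsrcs, _ = define_gsrcs(links)
        assert gsrcs == []

    def test_fewer_than_two_serotypes_rejected(self):
        with pytest.raises(ValueError, match="2 serotypes"):
            define_gsrcs({"A": []})

    def test_planted_universal_vs_private_design(self):
        links = {}
        for st in "ABDH":
            ls = [link("g_all", f"u_{st}")]
            if st == "D":
                ls.append(link("g_private", "p1"))
            links[st] = ls
        gsrcs, present = define_gsrcs(links)
        assert gsrcs == ["g_all"]
        assert present["g_private"] == {"D"}


class TestCoverageClass:
    def _gene(self, length=1000):
        return GeneModel("g1", "chr1", "+", ((0, length),))

    def _src(self, s, e):
        return SRC("s1", "chr1", s, e, 30)

    def test_full_coverage_is_class_three(self):
        pct, cls = coverage_class(self._gene(), [self._src(0, 1000)])
        assert pct == 100.0 and cls == "III"

    def test_partial_coverage_class_one(self):
        pct, cls = coverage_class(self._gene(), [self._src(100, 400)])
        assert pct == pytest.approx(30.0) and cls == "I"

    def test_union_of_overlapping_srcs(self):
        pct, cls = coverage_class(self._gene(), [self._src(0, 400), self._src(300, 700)])
        assert pct == pytest.approx(70.0) and cls == "II"

    @pytest.mark.parametrize(
        "pct, cls", [(0.0, "I"), (46.0, "I"), (46.001, "II"), (88.0, "II"), (88.001, "III")]
    )
    def test_cut_boundaries_exact(self, pct, cls):
        gene = self._gene(100_000)
        cov = int(round(pct / 100 * gene.length))
        srcs = [self._src(0, cov)] if cov else []
        got_pct, got_cls = coverage_class(gene, srcs)
        assert got_pct == pytest.approx(pct)
        assert got_cls == cls

    def test_src_clipped_to_gene_body(self):
        pct, _ = coverage_class(self._gene(), [self._src(900, 5000)])
        assert pct == pytest.approx(10.0)


class TestCorrelate:
    def _mats(self, srna, mrna):
        cols = [f"c{i}" for i in range(len(srna))]
        return (
            pd.DataFrame([srna], index=["g1"], columns=cols),
            pd.DataFrame([mrna], index=["g1"], columns=cols),
        )

    def test_exact_linear_gives_r_one(self):
        x = np.arange(12.0) + 1
        s, m = self._mats(x, 2 * x)
        res = correlate(s, m)
        assert res.loc[0, "r"] == pytest.approx(1.0)
        assert res.loc[0, "sign"] == "positive"

    def test_anti_linear_gives_r_minus_one(self):
        x = np.arange(12.0) + 1
        s, m = self._mats(x, x.max() - x)
        res = correlate(s, m)
        assert res.loc[0, "r"] == pytest.approx(-1.0)
        assert res.loc[0, "sign"] == "negative"

    def test_bh_step_up_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_q_never_below_p_and_alpha_one_all_significant(self):
        rng = np.random.default_rng(4)
        cols = [f"c{i}" for i in range(12)]
        srna = pd.DataFrame(rng.uniform(1, 100, (20, 12)), columns=cols,
                            index=[f"g{i}" for i in range(20)])
        mrna = pd.DataFrame(rng.uniform(1, 100, (20, 12)), columns=cols,
                            index=[f"g{i}" for i in range(20)])
        res = correlate(srna, mrna, alpha=1.0)
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()
        assert (res.loc[~res["zero_variance"], "sign"] != "ns").all()

    def test_zero_variance_flagged_ns(self):
        s, m = self._mats(np.ones(12), np.arange(12.0))
        res = correlate(s, m)
        assert bool(res.loc[0, "zero_variance"]) is True
        assert res.loc[0, "sign"] == "ns"

    def test_sign_recovery_on_planted_coupling(self):
        """Strongly coupled genes (empirical |r| >= 0.9) recover their sign."""
        rng = np.random.default_rng(77)
        n_genes, n_samples = 40, 12
        cols = [f"c{i}" for i in range(n_samples)]
        recovered = total = 0
        for _ in range(20):
            srna = rng.uniform(10, 100, (n_genes, n_samples))
            beta = np.where(np.arange(n_genes) % 2 == 0, 2.0, -2.0)
            noise = rng.normal(0, 5, (n_genes, n_samples))
            mrna = 500 + beta[:, None] * srna + noise
            sdf = pd.DataFrame(srna, columns=cols, index=[f"g{i}" for i in range(n_genes)])
            mdf = pd.DataFrame(mrna, columns=cols, index=[f"g{i}" for i in range(n_genes)])
            res = correlate(sdf, mdf).set_index("gene_id")
            strong = res[res["r"].abs() >= 0.9]
            total += len(strong)
            want = np.where(
                [int(g[1:]) % 2 == 0 for g in strong.index], "positive", "negative"
            )
            recovered += (strong["sign"].to_numpy() == want).sum()
        assert total > 100
        assert recovered / total >= 0.95


class TestMutantContrast:
    def test_planted_depletion_recovered(self):
        """75% depletion confined to a minority of loci -> log2FC about -2."""
        rng = np.random.default_rng(9)
        n, n_dep = 220, 20
        base = rng.uniform(150, 400, n)
        mut_mean = base.copy()
        mut_mean[:n_dep] *= 0.25
        cols_wt, cols_mut = ["w1", "w2", "w3"], ["m1", "m2", "m3"]
        data = {c: rng.poisson(base) for c in cols_wt}
        data.update({c: rng.poisson(mut_mean) for c in cols_mut})
        counts = pd.DataFrame(data, index=[f"L{i}" for i in range(n)])
        flags = pd.Series([i < n_dep for i in range(n)], index=counts.index)
        table, test = mutant_contrast(counts, cols_wt, cols_mut, flags)
        assert table.loc[flags, "log2fc"].mean() == pytest.approx(-2.0, abs=0.35)
        assert test["p_value"] < 1e-6

    def test_null_identical_conditions_centres_at_zero(self):
        rng = np.random.default_rng(10)
        base = rng.uniform(100, 300, 100)
        data = {c: rng.poisson(base) for c in ["w1", "w2", "m1", "m2"]}
        counts = pd.DataFrame(data, index=[f"L{i}" for i in range(100)])
        flags = pd.Series(rng.random(100) < 0.5, index=counts.index)
        table, test = mutant_contrast(counts, ["w1", "w2"], ["m1", "m2"], flags)
        assert abs(table["log2fc"].median()) < 0.15
        assert test["p_value"] > 0.001

    def test_all_zero_locus_excluded_and_flagged(self):
        counts = pd.DataFrame(
            {"w1": [100, 0], "w2": [110, 0], "m1": [90, 0], "m2": [105, 0]},
            index=["a", "b"],
        )
        flags = pd.Series([True, False], index=counts.index)
        table, test = mutant_contrast(counts, ["w1", "w2"], ["m1", "m2"], flags)
        assert bool(table.loc["b", "all_zero"]) is True
        assert test["n_unphased"] == 0

    def test_replicate_floor(self):
        counts = pd.DataFrame({"w1": [1], "m1": [1]}, index=["a"])
        with pytest.raises(ValueError, match="replicates"):
            mutant_contrast(counts, ["w1"], ["m1"], pd.Series([True], index=["a"]))

    def test_size_factors_absorb_depth_differences(self):
        rng = np.random.default_rng(11)
        base = rng.uniform(100, 300, 50)
        counts = pd.DataFrame(
            {"a": rng.poisson(base), "b": rng.poisson(3 * base)},
            index=[f"L{i}" for i in range(50)],
        )
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(3.0, rel=0.1)

    def test_contrast_generator_plants_both_effects(self):
        sim = simulate_contrast_counts(seed=5)
        table, test = mutant_contrast(
            sim["srna_counts"], sim["wt_samples"], sim["mutant_samples"], sim["phased"]
        )
        assert test["median_phased"] < test["median_unphased"]
        mtab, mtest = mutant_contrast(
            sim["mrna_tpm"],
            sim["wt_samples"],
            sim["mutant_samples"],
            sim["phased"].set_axis(sim["mrna_tpm"].index),
        )
        assert mtest["median_phased"] > mtest["median_unphased"]


class TestIntersections:
    def test_exact_enumeration(self):
        counts = intersections({"a": {"A", "B"}, "b": {"A", "B"}, "c": {"A"}})
        assert counts == {frozenset({"A", "B"}): 2, frozenset({"A"}): 1}

    def test_all_items_in_all_conditions(self):
        counts = intersections({f"i{k}": set("ABDH") for k in range(5)})
        assert counts == {frozenset("ABDH"): 5}

    def test_counts_sum_to_item_count(self):
        rng = np.random.default_rng(13)
        conds = "ABDH"
        members = {
            f"i{k}": {c for c in conds if rng.random() < 0.5} for k in range(200)
        }
        assert sum(intersections(members).values()) == 200


class TestTagDeGroups:
    def test_membership_naming_across_two_mutants(self):
        from phasiclust.integrate import tag_de_groups

        t1 = pd.DataFrame(
            {"log2FC": [-2.0, -1.5, 1.2, 0.1], "padj": [0.01, 0.02, 0.01, 0.9]},
            index=["a", "b", "c", "d"],
        )
        t2 = pd.DataFrame(
            {"log2FC": [-1.8, 2.0, 1.1, -0.2], "padj": [0.03, 0.01, 0.2, 0.8]},
            index=["a", "b", "c", "d"],
        )
        groups = tag_de_groups({"1": t1, "2": t2})
        assert groups["a"] == "D1D2"
        assert groups["b"] == "D1U2"
        assert groups["c"] == "U1"
        assert groups["d"] == ""


class TestEnrichment:
    def test_uniform_distribution_not_enriched(self):
        # 30 phased spread evenly over three classes of 100
        p = enrichment(n_total=300, n_group=100, n_marked=30, n_marked_in_group=10)
        assert 0.3 <= p <= 1.0

    def test_total_concentration_matches_exact_pmf(self):
        p = enrichment(n_total=60, n_group=20, n_marked=20, n_marked_in_group=20)
        assert p == pytest.approx(1 / math.comb(60, 20), rel=1e-9)

    def test_empty_marked_set_gives_one(self):
        assert enrichment(100, 30, 0, 0) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment(10, 5, 3, 4)
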