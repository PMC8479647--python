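"""Sensitivity and contrast analyses."""

import numpy as np
import pandas as pd
import pytest

from ursaburden import (
    GeneSet,
    ValidationError,
    exclude_chromosome,
    group_contrast,
    leave_genes_out,
    permutation_subsample,
)
from ursaburden.secondary import gene_chromosome_map


@pytest.fixture(scope="module")
def halves(small_cohort):
    ctrl = small_cohort.samples.loc[
        small_cohort.samples["phenotype"] == "control", "sample"
    ].tolist()
    return ctrl[: len(ctrl) // 2], ctrl[len(ctrl) // 2:]


class TestExcludeChromosome:
    def test_chrx_genes_removed_everywhere(self, small_cohort):
        v, c, sets = exclude_chromosome(
            small_cohort.variants, small_cohort.carriers,
            small_cohort.gene_sets, "X",
        )
        assert not (v["chrom"] == "X").any()
        assert not (c["chrom"] == "X").any()
        gmap = gene_chromosome_map(small_cohort.variants)
        x_genes = set(gmap.index[gmap == "X"])
        n_before = small_cohort.variants["gene"].nunique()
        assert v["gene"].nunique() == n_before - len(x_genes)
        # roughly the configured chrX fraction disappears from the universe
        frac = 1 - v["gene"].nunique() / n_before
        assert abs(frac - small_cohort.config.chrx_gene_frac) < 0.06
        for gs in sets:
            assert not set(gs.genes) & x_genes

    def test_absent_chromosome_is_identity(self, small_cohort):
        v, c, sets = exclude_chromosome(
            small_cohort.variants, small_cohort.carriers,
            small_cohort.gene_sets, "7_does_not_exist",
        )
        pd.testing.assert_frame_equal(v, small_cohort.variants)
        pd.testing.assert_frame_equal(c, small_cohort.carriers)
        assert [gs.name for gs in sets] == [gs.name for gs in small_cohort.gene_sets]

    def test_conflicting_gene_chromosome_mapping_rejected(self, small_cohort):
        v = small_cohort.variants.copy()
        v.loc[v.index[0], "gene"] = v.loc[v.index[-1], "gene"]
        if v.loc[v.index[0], "chrom"] != v.loc[v.index[-1], "chrom"]:
            with pytest.raises(ValidationError, match="multiple chromosomes"):
                gene_chromosome_map(v)


class TestGroupContrast:
    def test_label_swap_negates_log_odds(self, small_cohort, halves):
        a, b = halves
        sets = [gs for gs in small_cohort.gene_sets if gs.name == "setA"]
        ab = group_contrast(small_cohort.samples, small_cohort.variants,
                            small_cohort.carriers, a, b, sets)
        ba = group_contrast(small_cohort.samples, small_cohort.variants,
                            small_cohort.carriers, b, a, sets)
        fa = ab.frame.set_index("class")
        fb = ba.frame.set_index("class")
        for cls in fa.index:
            la, lb = fa.loc[cls, "log_odds"], fb.loc[cls, "log_odds"]
            if fa.loc[cls, "degenerate"]:
                assert la == lb == 0.0
            else:
                assert la == pytest.approx(-lb, abs=1e-6)

    def test_empty_group_rejected(self, small_cohort, halves):
        with pytest.raises(ValidationError, match="non-empty"):
            group_contrast(small_cohort.samples, small_cohort.variants,
                           small_cohort.carriers, halves[0], [], [])

    def test_overlapping_groups_rejected(self, small_cohort, halves):
        with pytest.raises(ValidationError, match="disjoint"):
            group_contrast(small_cohort.samples, small_cohort.variants,
                           small_cohort.carriers, halves[0], halves[0], [])


class TestPermutationSubsample:
    def _run(self, cohort, n_perm, seed):
        gs = next(g for g in cohort.gene_sets if g.name == "setA")
        return permutation_subsample(
            cohort.samples, cohort.variants, cohort.carriers, gs,
            "All functional", n_case_sub=150, n_ctrl_sub=150,
            n_perm=n_perm, seed=seed, phenotype="GGE",
        )

    def test_single_permutation_equals_its_run(self, small_cohort):
        s = self._run(small_cohort, 1, 3)
        assert s.n_perm == 1
        assert s.mean_log_odds == s.records["log_odds"].iloc[0]
        assert s.centile_2_5 == s.centile_97_5 == s.mean_log_odds
        assert s.mean_p == s.records["p"].iloc[0]

    def test_seed_reproducibility(self, small_cohort):
        s1 = self._run(small_cohort, 5, 11)
        s2 = self._run(small_cohort, 5, 11)
        pd.testing.assert_frame_equal(s1.records, s2.records)
        assert self._run(small_cohort, 5, 12).mean_log_odds != s1.mean_log_odds

    def test_null_cohort_centres_near_zero(self, small_cohort):
        s = self._run(small_cohort, 20, 21)
        lo = s.records["log_odds"].to_numpy()
        se = lo.std(ddof=1) / np.sqrt(len(lo))
        # subsampled replicates of an unspiked cell scatter around 0
        assert abs(s.mean_log_odds) < max(3 * se, 0.5)
        assert s.centile_2_5 <= s.mean_log_odds <= s.centile_97_5

    def test_oversized_subsample_rejected(self, small_cohort):
        gs = small_cohort.gene_sets[0]
        with pytest.raises(ValidationError, match="exceeds"):
            permutation_subsample(
                small_cohort.samples, small_cohort.variants,
                small_cohort.carriers, gs, "PTV",
                n_case_sub=10_000, n_ctrl_sub=10, n_perm=1, seed=0,
                phenotype="GGE",
            )


class TestLeaveGenesOut:
    def test_dropping_qv_free_genes_changes_nothing(self, small_cohort):
        from ursaburden import UrvFilterConfig, build_qv_table, default_class_rules

        gs = next(g for g in small_cohort.gene_sets if g.name == "setA")
        # find set genes without any 'All functional' QV in the GGE analysis
        rules = tuple(r for r in default_class_rules() if r.name == "All functional")
        qvt = build_qv_table(small_cohort.variants, small_cohort.carriers,
                             small_cohort.samples, UrvFilterConfig(), rules, "GGE")
        t = qvt["All functional"]
        col_hits = np.asarray(t.matrix.sum(axis=0)).ravel()
        empty_genes = set(t.gene_index[col_hits == 0])
        spare = [g for g in gs.genes if g in empty_genes]
        assert spare, "fixture should contain a QV-free gene"
        before, after = leave_genes_out(
            small_cohort.samples, small_cohort.variants, small_cohort.carriers,
            gs, spare[:1], "All functional", "GGE",
        )
        assert after.log_odds == pytest.approx(before.log_odds, abs=1e-9)
        assert after.pvalue == pytest.approx(before.pvalue, abs=1e-9)

    def test_dropping_all_genes_degenerates(self, small_cohort):
        gs = next(g for g in small_cohort.gene_sets if g.name == "setA")
        before, after = leave_genes_out(
            small_cohort.samples, small_cohort.variants, small_cohort.carriers,
            gs, list(gs.genes), "All functional", "GGE",
        )
        assert after.degenerate
        assert after.pvalue == 1.0

    def test_unknown_gene_rejected(self, small_cohort):
        gs = next(g for g in small_cohort.gene_sets if g.name == "setA")
        with pytest.raises(ValidationError, match="not in gene set"):
            leave_genes_out(
                small_cohort.samples, small_cohort.variants,
                small_cohort.carriers, gs, ["NOT_A_MEMBER"],
                "All functional", "GGE",
            )

    def test_dropping_spiked_driver_genes_shrinks_effect(self):
        # setB (the spiked drivers) sits entirely inside setA; removing the
        # drivers from setA should collapse setA's enrichment toward 0
        from ursaburden import SimConfig, generate_cohort

        cfg = SimConfig(
            n_cases={"GGE": 800}, n_controls=800, n_genes=300,
            genes_per_set={"setA": 80, "setB": 20, "ctrl": 40},
            control_sets=("ctrl",),
            set_overlap={("setA", "setB"): 1.0},
            spiked_or={("setB", "All functional"): 3.0}, seed=77,
        )
        cohort = generate_cohort(cfg)
        sets = {g.name: g for g in cohort.gene_sets}
        assert set(sets["setB"].genes) <= set(sets["setA"].genes)
        before, after = leave_genes_out(
            cohort.samples, cohort.variants, cohort.carriers,
            sets["setA"], list(sets["setB"].genes), "All functional", "GGE",
        )
        assert before.pvalue < 0.05
        assert after.log_odds < before.log_odds / 2
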