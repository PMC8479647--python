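"""URV qualification and class assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ursaburden import (
    AnalysisError,
    UrvFilterConfig,
    ValidationError,
    VariantAnnotation,
    assign_classes,
    build_qv_table,
    compute_internal_mac,
    filter_urv,
)
from ursaburden.qv import class_membership, urv_mask, variant_key_frame


def _variant(**kw):
    base = dict(chrom="1", pos=100, ref="A", alt="T", gene="G1",
                consequence="missense")
    base.update(kw)
    return VariantAnnotation(**base)


def _carriers(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample",
                                       "allele_count"])


class TestInternalMac:
    def test_three_het_carriers_in_cohort(self):
        c = _carriers([("1", 100, "A", "T", s, 1) for s in ("s1", "s2", "s3")])
        mac = compute_internal_mac(c, {"s1", "s2", "s3"})
        assert mac["1:100:A:T"] == 3

    def test_hom_plus_het_counts_alleles_not_carriers(self):
        c = _carriers([
            ("1", 100, "A", "T", "s1", 2),
            ("1", 100, "A", "T", "s2", 1),
            ("1", 100, "A", "T", "outside", 1),
        ])
        mac = compute_internal_mac(c, {"s1", "s2"})
        assert mac["1:100:A:T"] == 3

    def test_variant_outside_analysis_gets_zero(self):
        c = _carriers([("1", 100, "A", "T", "dee_case", 1)])
        mac = compute_internal_mac(c, {"s1"}, variant_keys=["1:100:A:T"])
        assert mac["1:100:A:T"] == 0

    def test_unknown_sample_rejected(self):
        c = _carriers([("1", 100, "A", "T", "ghost", 1)])
        with pytest.raises(ValidationError, match="ghost"):
            compute_internal_mac(c, {"s1"}, known_samples={"s1"})


class TestUrvFilter:
    cfg = UrvFilterConfig()

    @pytest.mark.parametrize(
        "mac, gaf, daf, expected",
        [
            (3, 0.0, 0.0, True),      # at the MAC boundary
            (4, 0.0, 0.0, False),     # exceeds MAC <= 3
            (1, 3e-5, 0.0, False),    # too common in gnomAD
            (1, 2e-5, 0.0, True),     # gnomAD boundary is inclusive
            (1, 0.0, 1e-4, False),    # present in DiscovEHR
        ],
    )
    def test_thresholds(self, mac, gaf, daf, expected):
        v = _variant(gnomad_af=gaf, discovehr_af=daf)
        assert filter_urv(v, mac, self.cfg) is expected

    def test_monotone_in_gnomad_threshold(self):
        rng = np.random.default_rng(0)
        n = 200
        variants = pd.DataFrame({
            "chrom": "1", "pos": np.arange(1, n + 1), "ref": "A", "alt": "T",
            "gnomad_af": rng.choice([0.0, 1e-5, 2e-5, 1e-4, 1e-3], n),
            "discovehr_af": 0.0,
        })
        mac = pd.Series(1, index=variant_key_frame(variants))
        thresholds = sorted([0.0, 1e-5, 2e-5, 1e-4, 1e-2])
        counts = [
            urv_mask(variants, mac, UrvFilterConfig(gnomad_af_max=t)).sum()
            for t in thresholds
        ]
        assert counts == sorted(counts)


class TestAssignClasses:
    def test_stop_gained_is_ptv_and_all_functional(self, rules):
        v = _variant(consequence="stop_gained")
        assert assign_classes(v, rules) == {"PTV", "All functional"}

    def test_fully_damaging_constrained_missense(self, rules):
        v = _variant(pph2="probably_damaging", sift="deleterious",
                     mpc=2.5, mtr=0.5, ccr=85.0, para_z=1.2)
        assert assign_classes(v, rules) == {
            "Damaging missense", "All functional", "MPC 1", "MPC 2",
            "MTR ClinVar", "MTR De Novo", "CCR 80",
            "Paralog conserved", "Paralog highly conserved",
        }

    def test_ccr80_requires_mpc_condition(self, rules):
        v = _variant(ccr=85.0, mpc=0.5, mtr=0.5)
        classes = assign_classes(v, rules)
        assert "CCR 80" not in classes
        assert {"MTR ClinVar", "MTR De Novo"} <= classes

    def test_synonymous_only_synonymous(self, rules):
        assert assign_classes(_variant(consequence="synonymous"), rules) == {
            "Synonymous"
        }

    def test_inframe_only_all_functional(self, rules):
        v = _variant(consequence="inframe_indel", ref="AC", alt="A")
        assert assign_classes(v, rules) == {"All functional"}

    def test_missing_scores_fail_predicates(self, rules):
        assert assign_classes(_variant(), rules) == set()

    def test_discordant_predictions_neither_benign_nor_damaging(self, rules):
        v = _variant(pph2="probably_damaging", sift="tolerated")
        classes = assign_classes(v, rules)
        assert "Damaging missense" not in classes
        assert "Benign missense" not in classes

    def test_unknown_consequence_no_class(self, rules):
        assert assign_classes(_variant(consequence="intergenic"), rules) == set()


class TestClassInvariantsOnCohort:
    def test_nesting_and_partition(self, small_cohort, rules):
        v = small_cohort.variants
        m = class_membership(v, rules)

        def subset(a, b):
            assert not (m[a] & ~m[b]).any(), f"{a} not within {b}"

        subset("MPC 2", "MPC 1")
        subset("MTR De Novo", "MTR ClinVar")
        subset("CCR 80", "MPC 1")
        subset("CCR 80", "MTR ClinVar")
        subset("Paralog highly conserved", "Paralog conserved")
        # synonymous never co-occurs with a non-synonymous class
        nonsyn = m.drop(columns=["Synonymous"]).any(axis=1)
        assert not (m["Synonymous"] & nonsyn).any()
        # paralog classes partition missense with observed para-Z
        has_pz = (v["consequence"] == "missense") & v["para_z"].notna()
        both = m["Paralog conserved"] & m["Paralog non-conserved"]
        neither = ~m["Paralog conserved"] & ~m["Paralog non-conserved"]
        assert not (has_pz & both).any()
        assert not (has_pz & neither).any()


@st.composite
def _mini_cohort(draw):
    """Hand-sized variant/carrier/sample triple for property checks."""
    n_var = draw(st.integers(2, 6))
    rows, carr = [], []
    for i in range(n_var):
        rows.append(("1", 100 + i, "A", "T", f"G{draw(st.integers(1, 3))}",
                     "missense", "probably_damaging", "deleterious",
                     2.0, 0.5, 85.0, 1.0, 0.0, 0.0))
        for s in draw(st.sets(st.sampled_from(["c1", "c2", "k1", "k2"]), min_size=1)):
            carr.append(("1", 100 + i, "A", "T", s, draw(st.sampled_from([1, 2]))))
    variants = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "gene", "consequence", "pph2", "sift",
        "mpc", "mtr", "ccr", "para_z", "gnomad_af", "discovehr_af"])
    carriers = pd.DataFrame(carr, columns=[
        "chrom", "pos", "ref", "alt", "sample", "allele_count"])
    samples = pd.DataFrame({
        "sample": ["c1", "c2", "k1", "k2"],
        "phenotype": ["GGE", "GGE", "control", "control"],
        "sex": ["F", "M", "M", "M"], "batch": "b",
        **{f"PC{i}": 0.0 for i in range(1, 11)},
    })
    return variants, carriers, samples


class TestBuildQvTable:
    def _samples(self):
        return pd.DataFrame({
            "sample": ["case1", "case2", "ctrl1", "ctrl2"],
            "phenotype": ["GGE", "NAFE", "control", "control"],
            "sex": ["F", "M", "M", "F"], "batch": "b",
            **{f"PC{i}": 0.0 for i in range(1, 11)},
        })

    def test_two_qvs_in_one_gene_give_single_indicator(self, rules):
        variants = pd.DataFrame([
            ("1", 100, "A", "T", "G1", "missense", "probably_damaging",
             "deleterious", np.nan, np.nan, np.nan, np.nan, 0.0, 0.0),
            ("1", 101, "A", "T", "G1", "missense", "probably_damaging",
             "deleterious", np.nan, np.nan, np.nan, np.nan, 0.0, 0.0),
        ], columns=["chrom", "pos", "ref", "alt", "gene", "consequence",
                    "pph2", "sift", "mpc", "mtr", "ccr", "para_z",
                    "gnomad_af", "discovehr_af"])
        carriers = _carriers([
            ("1", 100, "A", "T", "case1", 1),
            ("1", 101, "A", "T", "case1", 1),
        ])
        qvt = build_qv_table(variants, carriers, self._samples(),
                             UrvFilterConfig(), rules, "GGE")
        t = qvt["Damaging missense"]
        assert t.indicator("case1", "G1") == 1
        assert t.matrix.sum() == 1
        assert qvt.covariate_counts.loc["case1", "urv_count"] == 2
        assert qvt.covariate_counts.loc["case1", "singleton_count"] == 2

    def test_macs_differ_between_analyses(self, rules):
        # carried by the GGE case and one control: MAC 2 in the GGE analysis,
        # MAC 1 in the NAFE analysis (where the GGE carrier is absent)
        variants = pd.DataFrame([
            ("1", 100, "A", "T", "G1", "synonymous", np.nan, np.nan,
             np.nan, np.nan, np.nan, np.nan, 0.0, 0.0),
        ], columns=["chrom", "pos", "ref", "alt", "gene", "consequence",
                    "pph2", "sift", "mpc", "mtr", "ccr", "para_z",
                    "gnomad_af", "discovehr_af"])
        carriers = _carriers([
            ("1", 100, "A", "T", "case1", 1),
            ("1", 100, "A", "T", "ctrl1", 1),
        ])
        gge = compute_internal_mac(carriers, {"case1", "ctrl1", "ctrl2"})
        nafe = compute_internal_mac(carriers, {"case2", "ctrl1", "ctrl2"})
        assert gge["1:100:A:T"] == 2
        assert nafe["1:100:A:T"] == 1
        # and the per-analysis QV tables reflect the analysis cohort
        qvt = build_qv_table(variants, carriers, self._samples(),
                             UrvFilterConfig(), rules, "NAFE")
        assert "case1" not in qvt.sample_index

    def test_no_carriers_all_zero(self, rules):
        variants = pd.DataFrame([
            ("1", 100, "A", "T", "G1", "missense", np.nan, np.nan,
             np.nan, np.nan, np.nan, np.nan, 0.0, 0.0),
        ], columns=["chrom", "pos", "ref", "alt", "gene", "consequence",
                    "pph2", "sift", "mpc", "mtr", "ccr", "para_z",
                    "gnomad_af", "discovehr_af"])
        carriers = _carriers([])
        qvt = build_qv_table(variants, carriers, self._samples(),
                             UrvFilterConfig(), rules, "GGE")
        assert all(t.matrix.nnz == 0 for t in qvt.tables.values())
        assert (qvt.covariate_counts == 0).all().all()

    def test_empty_stratum_is_analysis_error(self, rules):
        variants = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "gene",
                                         "consequence", "pph2", "sift", "mpc",
                                         "mtr", "ccr", "para_z", "gnomad_af",
                                         "discovehr_af"])
        with pytest.raises(AnalysisError, match="case stratum"):
            build_qv_table(variants, _carriers([]), self._samples(),
                           UrvFilterConfig(), rules, "DEE")

    @settings(max_examples=25, deadline=None)
    @given(data=_mini_cohort())
    def test_idempotent(self, data, rules):
        variants, carriers, samples = data
        a = build_qv_table(variants, carriers, samples, UrvFilterConfig(),
                           rules, "GGE")
        b = build_qv_table(variants, carriers, samples, UrvFilterConfig(),
                           rules, "GGE")
        for cls in a.tables:
            assert (a[cls].matrix != b[cls].matrix).nnz == 0
        pd.testing.assert_frame_equal(a.covariate_counts, b.covariate_counts)
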