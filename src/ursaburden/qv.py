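"""Qualifying-variant engine.

Qualifies ultra-rare variants (URVs) for one case-control analysis and assigns
them to the 13 partially overlapping functional classes used throughout the
burden grid.  A variant qualifies when its minor allele count (MAC), computed
*within the samples of the current analysis*, does not exceed ``mac_max``
(default 3), it is absent from DiscovEHR, and its gnomAD allele frequency is at
most 2e-5.  Because each phenotype is contrasted against the controls
separately, MACs — and hence URV membership — are recomputed per analysis.

Classes are defined on the functional consequence plus in-silico deleteriousness
(PolyPhen-2/SIFT), regional constraint (MPC, MTR, CCR) and paralog conservation
(para-Z).  A missing score always fails the predicate that needs it; scores are
never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import AnalysisError, ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "pph2", "sift",
    "mpc", "mtr", "ccr", "para_z", "gnomad_af", "discovehr_af",
]
CARRIER_COLUMNS = ["chrom", "pos", "ref", "alt", "sample", "allele_count"]

PTV_CONSEQUENCES = frozenset(
    {"stop_gained", "start_lost", "frameshift", "splice_donor", "splice_acceptor"}
)
KNOWN_CONSEQUENCES = PTV_CONSEQUENCES | {
    "synonymous", "missense", "inframe_indel", "other"
}

#: canonical class names, in grid order
CLASS_NAMES = (
    "Benign missense",
    "Damaging missense",
    "PTV",
    "All functional",
    "MPC 1",
    "MPC 2",
    "MTR ClinVar",
    "MTR De Novo",
    "CCR 80",
    "Paralog non-conserved",
    "Paralog conserved",
    "Paralog highly conserved",
    "Synonymous",
)
SYNONYMOUS_CLASS = "Synonymous"
NONSYNONYMOUS_CLASSES = tuple(c for c in CLASS_NAMES if c != SYNONYMOUS_CLASS)


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix so 'chrX' and 'X' compare equal."""
    s = str(chrom)
    return s[3:] if s.lower().startswith("chr") else s


def variant_key_frame(df: pd.DataFrame) -> pd.Series:
    """Canonical ``chrom:pos:ref:alt`` key for each row of a variant-shaped frame."""
    return (
        df["chrom"].astype(str).map(normalize_chrom)
        + ":" + df["pos"].astype(int).astype(str)
        + ":" + df["ref"].astype(str)
        + ":" + df["alt"].astype(str)
    )


@dataclass(frozen=True)
class VariantAnnotation:
    """One annotated alternate allele.

    ``None`` marks a missing score/prediction.  Population frequencies default
    to 0.0, i.e. absence from the reference database.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    pph2: str | None = None
    sift: str | None = None
    mpc: float | None = None
    mtr: float | None = None
    ccr: float | None = None
    para_z: float | None = None
    gnomad_af: float = 0.0
    discovehr_af: float = 0.0

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt alleles must be non-empty")
        for name in ("gnomad_af", "discovehr_af"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")

    @property
    def key(self) -> str:
        return f"{normalize_chrom(self.chrom)}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class CarrierRecord:
    """Link between a variant and a sample carrying 1 or 2 alternate alleles."""

    variant_key: str
    sample_id: str
    allele_count: int

    def __post_init__(self):
        if self.allele_count not in (1, 2):
            raise ValidationError(
                f"allele_count must be 1 or 2, got {self.allele_count}"
            )


@dataclass(frozen=True)
class UrvFilterConfig:
    """Ultra-rare variant thresholds: internal MAC and external reference MAFs."""

    mac_max: int = 3
    gnomad_af_max: float = 2e-5
    discovehr_af_max: float = 0.0

    def __post_init__(self):
        if self.mac_max < 1:
            raise ConfigurationError(f"mac_max must be >= 1, got {self.mac_max}")
        for name in ("gnomad_af_max", "discovehr_af_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")


# --------------------------------------------------------------------------
# class rules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassRule:
    """Predicate over a single variant annotation.

    Numeric bounds are inclusive (``mpc_min`` means MPC >= mpc_min) except
    ``para_z_gt`` which is strict.  A rule only matches consequences in its
    roster; any score needed by a set bound must be present, otherwise the
    predicate fails.
    """

    name: str
    consequences: frozenset[str]
    pph2: frozenset[str] | None = None
    sift: frozenset[str] | None = None
    mpc_min: float | None = None
    mtr_max: float | None = None
    ccr_min: float | None = None
    para_z_min: float | None = None
    para_z_gt: float | None = None
    para_z_max: float | None = None

    def matches(self, v: VariantAnnotation) -> bool:
        if v.consequence not in self.consequences:
            return False
        if self.pph2 is not None and v.pph2 not in self.pph2:
            return False
        if self.sift is not None and v.sift not in self.sift:
            return False
        if self.mpc_min is not None and not (v.mpc is not None and v.mpc >= self.mpc_min):
            return False
        if self.mtr_max is not None and not (v.mtr is not None and v.mtr <= self.mtr_max):
            return False
        if self.ccr_min is not None and not (v.ccr is not None and v.ccr >= self.ccr_min):
            return False
        if self.para_z_min is not None and not (
            v.para_z is not None and v.para_z >= self.para_z_min
        ):
            return False
        if self.para_z_gt is not None and not (
            v.para_z is not None and v.para_z > self.para_z_gt
        ):
            return False
        if self.para_z_max is not None and not (
            v.para_z is not None and v.para_z <= self.para_z_max
        ):
            return False
        return True

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        """Vectorised predicate over a variant table (NaN comparisons fail)."""
        m = df["consequence"].isin(self.consequences).to_numpy()
        if self.pph2 is not None:
            m &= df["pph2"].isin(self.pph2).to_numpy()
        if self.sift is not None:
            m &= df["sift"].isin(self.sift).to_numpy()
        if self.mpc_min is not None:
            m &= (df["mpc"].to_numpy(dtype=float) >= self.mpc_min)
        if self.mtr_max is not None:
            m &= (df["mtr"].to_numpy(dtype=float) <= self.mtr_max)
        if self.ccr_min is not None:
            m &= (df["ccr"].to_numpy(dtype=float) >= self.ccr_min)
        pz = None
        if self.para_z_min is not None or self.para_z_gt is not None or self.para_z_max is not None:
            pz = df["para_z"].to_numpy(dtype=float)
        if self.para_z_min is not None:
            m &= (pz >= self.para_z_min)
        if self.para_z_gt is not None:
            m &= (pz > self.para_z_gt)
        if self.para_z_max is not None:
            m &= (pz <= self.para_z_max)
        return m


@dataclass(frozen=True)
class UnionRule:
    """Class defined as the union of component rules ('All functional')."""

    name: str
    parts: tuple[ClassRule, ...]

    def matches(self, v: VariantAnnotation) -> bool:
        return any(p.matches(v) for p in self.parts)

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        m = np.zeros(len(df), dtype=bool)
        for p in self.parts:
            m |= p.mask(df)
        return m


def default_class_rules(damaging_requires_both: bool = True) -> tuple:
    """The 13 shipped class rules.

    ``damaging_requires_both`` controls whether the damaging/benign missense
    calls require concordant PolyPhen-2 and SIFT predictions (the default) or
    accept either predictor alone.
    """
    missense = frozenset({"missense"})
    if damaging_requires_both:
        benign = ClassRule(
            "Benign missense", missense,
            pph2=frozenset({"benign"}), sift=frozenset({"tolerated"}),
        )
        damaging = ClassRule(
            "Damaging missense", missense,
            pph2=frozenset({"possibly_damaging", "probably_damaging"}),
            sift=frozenset({"deleterious"}),
        )
    else:
        benign = ClassRule(
            "Benign missense", missense,
            pph2=frozenset({"benign", ""}), sift=frozenset({"tolerated", ""}),
        )
        damaging = ClassRule(
            "Damaging missense", missense,
            pph2=frozenset({"possibly_damaging", "probably_damaging", ""}),
            sift=frozenset({"deleterious", ""}),
        )
    ptv = ClassRule("PTV", PTV_CONSEQUENCES)
    inframe = ClassRule("_inframe", frozenset({"inframe_indel"}))
    all_functional = UnionRule("All functional", (ptv, inframe, damaging))
    rules = (
        benign,
        damaging,
        ptv,
        all_functional,
        ClassRule("MPC 1", missense, mpc_min=1.0),
        ClassRule("MPC 2", missense, mpc_min=2.0),
        ClassRule("MTR ClinVar", missense, mtr_max=0.825),
        ClassRule("MTR De Novo", missense, mtr_max=0.565),
        ClassRule("CCR 80", missense, ccr_min=80.0, mpc_min=1.0, mtr_max=0.825),
        ClassRule("Paralog non-conserved", missense, para_z_max=0.0),
        ClassRule("Paralog conserved", missense, para_z_gt=0.0),
        ClassRule("Paralog highly conserved", missense, para_z_min=1.0),
        ClassRule("Synonymous", frozenset({"synonymous"})),
    )
    assert tuple(r.name for r in rules) == CLASS_NAMES
    return rules


def assign_classes(variant: VariantAnnotation, rules: Sequence) -> set[str]:
    """Every class whose predicate holds for this variant (classes overlap)."""
    if variant.consequence not in KNOWN_CONSEQUENCES:
        logger.warning(
            "unknown consequence %r for %s: variant classified into no class",
            variant.consequence, variant.key,
        )
        return set()
    return {r.name for r in rules if r.matches(variant)}


def class_membership(variants: pd.DataFrame, rules: Sequence) -> pd.DataFrame:
    """Boolean membership matrix (variants x classes) for a variant table."""
    unknown = ~variants["consequence"].isin(KNOWN_CONSEQUENCES)
    if unknown.any():
        logger.warning(
            "%d variants with unknown consequence classified into no class",
            int(unknown.sum()),
        )
    out = {}
    for rule in rules:
        m = rule.mask(variants)
        m[unknown.to_numpy()] = False
        out[rule.name] = m
    return pd.DataFrame(out, index=variants.index)


# --------------------------------------------------------------------------
# URV qualification
# --------------------------------------------------------------------------

def compute_internal_mac(
    carriers: pd.DataFrame,
    analysis_samples: Iterable[str],
    variant_keys: Iterable[str] | None = None,
    known_samples: Iterable[str] | None = None,
) -> pd.Series:
    """Minor allele count per variant within one analysis cohort.

    MAC sums ``allele_count`` over carriers whose sample belongs to
    ``analysis_samples``.  When ``variant_keys`` is given, variants without
    in-cohort carriers are reported with MAC 0.
    """
    sample_set = set(analysis_samples)
    if known_samples is not None:
        bad = set(carriers["sample"]) - set(known_samples)
        if bad:
            raise ValidationError(
                f"carriers reference unknown samples: {sorted(bad)[:5]}"
            )
    keys = variant_key_frame(carriers)
    in_cohort = carriers["sample"].isin(sample_set).to_numpy()
    mac = (
        pd.Series(carriers["allele_count"].to_numpy()[in_cohort], index=keys[in_cohort])
        .groupby(level=0)
        .sum()
    )
    if variant_keys is not None:
        mac = mac.reindex(pd.Index(variant_keys), fill_value=0)
    return mac.astype(int)


def filter_urv(variant: VariantAnnotation, mac: int, cfg: UrvFilterConfig) -> bool:
    """True iff the variant is ultra-rare under the analysis's internal MAC."""
    return (
        mac <= cfg.mac_max
        and variant.discovehr_af <= cfg.discovehr_af_max
        and variant.gnomad_af <= cfg.gnomad_af_max
    )


def urv_mask(variants: pd.DataFrame, mac: pd.Series, cfg: UrvFilterConfig) -> np.ndarray:
    """Vectorised URV filter; missing reference AFs count as 0 (absent)."""
    keys = variant_key_frame(variants)
    mac_v = mac.reindex(keys, fill_value=0).to_numpy()
    gaf = variants["gnomad_af"].fillna(0.0).to_numpy(dtype=float)
    daf = variants["discovehr_af"].fillna(0.0).to_numpy(dtype=float)
    return (mac_v <= cfg.mac_max) & (gaf <= cfg.gnomad_af_max) & (daf <= cfg.discovehr_af_max)


# --------------------------------------------------------------------------
# QV tables
# --------------------------------------------------------------------------

@dataclass
class QVTable:
    """Sparse binary (sample x gene) qualifying-variant indicators for one class."""

    analysis: str
    class_name: str
    matrix: sp.csr_matrix
    sample_index: pd.Index
    gene_index: pd.Index

    def indicator(self, sample: str, gene: str) -> int:
        i = self.sample_index.get_loc(sample)
        j = self.gene_index.get_loc(gene)
        return int(self.matrix[i, j] > 0)


@dataclass
class QVTables:
    """All class tables for one analysis plus per-sample covariate counts.

    ``covariate_counts`` carries the exome-wide URV count and exome-wide
    singleton (MAC = 1) count per analysis sample, computed from the variants
    passing the URV filters of *this* analysis.
    """

    analysis: str
    tables: dict[str, QVTable]
    covariate_counts: pd.DataFrame
    sample_index: pd.Index
    gene_index: pd.Index
    is_case: pd.Series
    funnel: dict = field(default_factory=dict)

    def __getitem__(self, class_name: str) -> QVTable:
        return self.tables[class_name]


def build_qv_table(
    variants: pd.DataFrame,
    carriers: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: UrvFilterConfig,
    rules: Sequence,
    phenotype: str,
    control_label: str = "control",
    case_ids: Iterable[str] | None = None,
    control_ids: Iterable[str] | None = None,
) -> QVTables:
    """Qualify URVs for one phenotype-vs-controls analysis and collapse by gene.

    The analysis cohort is the phenotype's cases plus all controls (or the
    explicit ``case_ids``/``control_ids`` for a custom contrast, e.g. a
    controls-only capture-kit comparison).  Internal MACs are computed within
    this cohort only, so URV membership is analysis specific.
    """
    if case_ids is None:
        case_ids = samples.loc[samples["phenotype"] == phenotype, "sample"]
    if control_ids is None:
        control_ids = samples.loc[samples["phenotype"] == control_label, "sample"]
    case_ids = pd.Index(case_ids)
    control_ids = pd.Index(control_ids)
    if len(case_ids) == 0:
        raise AnalysisError(f"analysis {phenotype!r}: empty case stratum")
    if len(control_ids) == 0:
        raise AnalysisError(f"analysis {phenotype!r}: empty control stratum")

    sample_index = case_ids.append(control_ids)
    is_case = pd.Series(
        np.r_[np.ones(len(case_ids), dtype=bool), np.zeros(len(control_ids), dtype=bool)],
        index=sample_index,
    )
    gene_index = pd.Index(sorted(variants["gene"].astype(str).unique()))

    vkeys = variant_key_frame(variants)
    mac = compute_internal_mac(
        carriers, sample_index, variant_keys=vkeys,
        known_samples=samples["sample"],
    )
    passing = urv_mask(variants, mac, cfg)
    funnel = {
        "n_variants_input": int(len(variants)),
        "n_urv_pass": int(passing.sum()),
    }
    logger.info(
        "analysis %s: %d/%d variants pass URV filters",
        phenotype, funnel["n_urv_pass"], funnel["n_variants_input"],
    )

    pass_variants = variants.loc[passing].copy()
    pass_variants["_key"] = vkeys[passing].to_numpy()
    pass_mac = mac.to_numpy()[passing]

    # carriers restricted to analysis samples and passing variants
    ckeys = variant_key_frame(carriers)
    in_analysis = carriers["sample"].isin(set(sample_index)).to_numpy()
    cc = carriers.loc[in_analysis, ["sample"]].copy()
    cc["_key"] = ckeys[in_analysis].to_numpy()
    key_info = pd.DataFrame(
        {"_key": pass_variants["_key"].to_numpy(),
         "gene": pass_variants["gene"].astype(str).to_numpy(),
         "_mac": pass_mac},
    )
    cc = cc.merge(key_info[["_key", "_mac"]].drop_duplicates("_key"), on="_key", how="inner")

    # exome-wide covariates: distinct passing URVs carried, and singletons
    urv_count = cc.groupby("sample")["_key"].nunique()
    singleton_count = cc.loc[cc["_mac"] == 1].groupby("sample")["_key"].nunique()
    cov = pd.DataFrame(index=sample_index)
    cov["urv_count"] = urv_count.reindex(sample_index).fillna(0).astype(int)
    cov["singleton_count"] = singleton_count.reindex(sample_index).fillna(0).astype(int)

    membership = class_membership(pass_variants, rules)
    spos = pd.Series(np.arange(len(sample_index)), index=sample_index)
    gpos = pd.Series(np.arange(len(gene_index)), index=gene_index)
    key_to_gene = key_info.drop_duplicates("_key").set_index("_key")["gene"]
    cc["_gene"] = key_to_gene.reindex(cc["_key"]).to_numpy()
    cc["_si"] = spos.reindex(cc["sample"]).to_numpy()
    cc["_gi"] = gpos.reindex(cc["_gene"]).to_numpy()

    tables: dict[str, QVTable] = {}
    key_index = pd.Index(pass_variants["_key"])
    for rule in rules:
        cls = rule.name
        class_keys = set(key_index[membership[cls].to_numpy()])
        sub = cc.loc[cc["_key"].isin(class_keys), ["_si", "_gi"]].drop_duplicates()
        mat = sp.coo_matrix(
            (np.ones(len(sub), dtype=np.int8), (sub["_si"].to_numpy(), sub["_gi"].to_numpy())),
            shape=(len(sample_index), len(gene_index)),
        ).tocsr()
        mat.data[:] = 1  # collapse duplicates to a binary indicator
        tables[cls] = QVTable(phenotype, cls, mat, sample_index, gene_index)
        funnel[f"n_qv_{cls}"] = int(mat.nnz)

    return QVTables(
        analysis=phenotype,
        tables=tables,
        covariate_counts=cov,
        sample_index=sample_index,
        gene_index=gene_index,
        is_case=is_case,
        funnel=funnel,
    )
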