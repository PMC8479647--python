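"""Bias-control and contrast analyses around the primary burden grid.

These mirror the sensitivity checks a careful case-control burden study runs:
excluding chromosome X to probe sex-imbalance bias, contrasting two control
strata to probe capture-kit bias, repeated random subsampling of one grid cell
to characterise its sampling distribution, and removing candidate driver genes
from a set to see whether an enrichment is carried by a handful of genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .collapse import GeneSet, burden_score
from .errors import ValidationError
from .qv import UrvFilterConfig, build_qv_table, default_class_rules, normalize_chrom
from .stats import BurdenLogitResults, GridResults, build_covariate_matrix, \
    lrt_burden_test, run_grid

logger = logging.getLogger(__name__)


def gene_chromosome_map(variants: pd.DataFrame) -> pd.Series:
    """Gene -> chromosome, taken from the variant table; conflicts are fatal."""
    m = variants.assign(_c=variants["chrom"].astype(str).map(normalize_chrom))
    per_gene = m.groupby("gene")["_c"].nunique()
    conflicts = per_gene[per_gene > 1]
    if len(conflicts):
        raise ValidationError(
            f"genes mapped to multiple chromosomes: {list(conflicts.index[:5])}"
        )
    return m.groupby("gene")["_c"].first()


def exclude_chromosome(
    variants: pd.DataFrame,
    carriers: pd.DataFrame,
    gene_sets: list[GeneSet],
    chrom: str,
) -> tuple[pd.DataFrame, pd.DataFrame, list[GeneSet]]:
    """Remove every gene on ``chrom`` from variants, carriers and gene sets."""
    target = normalize_chrom(chrom)
    gmap = gene_chromosome_map(variants)
    dropped_genes = set(gmap.index[gmap == target])
    keep_v = ~variants["gene"].isin(dropped_genes)
    variants_f = variants.loc[keep_v].reset_index(drop=True)
    ckey = carriers["chrom"].astype(str).map(normalize_chrom) != target
    carriers_f = carriers.loc[ckey].reset_index(drop=True)
    sets_f = [
        GeneSet(gs.name, tuple(g for g in gs.genes if g not in dropped_genes),
                category=gs.category, description=gs.description)
        for gs in gene_sets
    ]
    sets_f = [gs for gs in sets_f if len(gs.genes) > 0]
    logger.info("excluded chromosome %s: %d genes removed", chrom, len(dropped_genes))
    return variants_f, carriers_f, sets_f


def group_contrast(
    samples: pd.DataFrame,
    variants: pd.DataFrame,
    carriers: pd.DataFrame,
    group_a,
    group_b,
    gene_sets: list[GeneSet],
    rules=None,
    urv_cfg: UrvFilterConfig | None = None,
    n_pcs: int = 10,
    label: str = "group_a_vs_group_b",
) -> GridResults:
    """Burden grid with ``group_a`` as pseudo-cases and ``group_b`` as controls.

    Internal MACs are computed within the union of the two groups, exactly as
    in a primary analysis.  Used for the controls-only capture-kit contrast
    and the direct case-vs-case (e.g. GGE vs NAFE) comparison.
    """
    a = pd.Index(group_a)
    b = pd.Index(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("group_a and group_b must be non-empty")
    if len(a.intersection(b)):
        raise ValidationError("group_a and group_b must be disjoint")
    known = set(samples["sample"])
    unknown = (set(a) | set(b)) - known
    if unknown:
        raise ValidationError(f"unknown samples in contrast groups: {sorted(unknown)[:5]}")
    rules = default_class_rules() if rules is None else rules
    urv_cfg = UrvFilterConfig() if urv_cfg is None else urv_cfg
    qvt = build_qv_table(
        variants, carriers, samples, urv_cfg, rules, label,
        case_ids=a, control_ids=b,
    )
    return run_grid(
        samples, variants, carriers, gene_sets, phenotypes=[label],
        rules=rules, urv_cfg=urv_cfg, n_pcs=n_pcs, qv_tables={label: qvt},
    )


@dataclass
class PermutationSummary:
    """Summary of repeated subsampled burden tests of one grid cell."""

    n_perm: int
    mean_log_odds: float
    mean_odds: float           # mean of per-permutation odds ratios
    exp_mean_log_odds: float   # geometric-mean odds ratio
    centile_2_5: float
    centile_97_5: float
    mean_p: float
    records: pd.DataFrame      # per-permutation log_odds and p

    def summary(self) -> str:
        return (
            f"{self.n_perm} permutations: mean log-odds "
            f"{self.mean_log_odds:.4f} "
            f"[{self.centile_2_5:.4f}, {self.centile_97_5:.4f}] "
            f"(2.5th/97.5th centiles), mean p {self.mean_p:.4g}"
        )


def permutation_subsample(
    samples: pd.DataFrame,
    variants: pd.DataFrame,
    carriers: pd.DataFrame,
    gene_set: GeneSet,
    class_name: str,
    n_case_sub: int,
    n_ctrl_sub: int,
    n_perm: int,
    seed: int,
    phenotype: str | None = None,
    rules=None,
    urv_cfg: UrvFilterConfig | None = None,
    n_pcs: int = 10,
    control_label: str = "control",
) -> PermutationSummary:
    """Repeatedly subsample cases/controls and rerun one burden cell.

    Each permutation draws ``n_case_sub`` cases and ``n_ctrl_sub`` controls
    without replacement, requalifies URVs within the subsample (internal MACs
    are cohort specific), and records the cell's log-odds and LRT p.  Centiles
    use linear interpolation between order statistics.
    """
    rules = default_class_rules() if rules is None else rules
    urv_cfg = UrvFilterConfig() if urv_cfg is None else urv_cfg
    if phenotype is None:
        non_ctrl = [p for p in dict.fromkeys(samples["phenotype"]) if p != control_label]
        phenotype = non_ctrl[0]
    case_pool = samples.loc[samples["phenotype"] == phenotype, "sample"].to_numpy()
    ctrl_pool = samples.loc[samples["phenotype"] == control_label, "sample"].to_numpy()
    if n_case_sub > len(case_pool):
        raise ValidationError(
            f"n_case_sub {n_case_sub} exceeds available {phenotype} cases "
            f"({len(case_pool)})"
        )
    if n_ctrl_sub > len(ctrl_pool):
        raise ValidationError(
            f"n_ctrl_sub {n_ctrl_sub} exceeds available controls ({len(ctrl_pool)})"
        )
    rng = np.random.default_rng(seed)
    rule_map = {r.name: r for r in rules}
    if class_name not in rule_map:
        raise ValidationError(f"unknown class {class_name!r}")
    cell_rules = (rule_map[class_name],)

    recs = []
    for i in range(n_perm):
        sub_cases = rng.choice(case_pool, size=n_case_sub, replace=False)
        sub_ctrls = rng.choice(ctrl_pool, size=n_ctrl_sub, replace=False)
        qvt = build_qv_table(
            variants, carriers, samples, urv_cfg, cell_rules, phenotype,
            case_ids=pd.Index(sub_cases), control_ids=pd.Index(sub_ctrls),
        )
        cov = build_covariate_matrix(samples, qvt, n_pcs=n_pcs)
        kept = cov.index
        y = qvt.is_case.reindex(kept).to_numpy(dtype=float)
        score = burden_score(qvt[class_name], gene_set).reindex(kept)
        res = lrt_burden_test(y, score.to_numpy(), cov.reset_index(drop=True))
        recs.append({"perm": i, "log_odds": res.log_odds, "p": res.pvalue,
                     "converged": res.converged, "degenerate": res.degenerate})
    records = pd.DataFrame(recs)
    lo = records["log_odds"].to_numpy(dtype=float)
    return PermutationSummary(
        n_perm=n_perm,
        mean_log_odds=float(np.mean(lo)),
        mean_odds=float(np.mean(np.exp(lo))),
        exp_mean_log_odds=float(np.exp(np.mean(lo))),
        centile_2_5=float(np.percentile(lo, 2.5)),   # linear interpolation
        centile_97_5=float(np.percentile(lo, 97.5)),
        mean_p=float(records["p"].mean()),
        records=records,
    )


def leave_genes_out(
    samples: pd.DataFrame,
    variants: pd.DataFrame,
    carriers: pd.DataFrame,
    gene_set: GeneSet,
    genes_to_drop,
    class_name: str,
    phenotype: str,
    rules=None,
    urv_cfg: UrvFilterConfig | None = None,
    n_pcs: int = 10,
) -> tuple[BurdenLogitResults, BurdenLogitResults]:
    """One cell's result before and after removing genes from the set.

    Driver-gene sensitivity: if the enrichment of a set is carried by a few
    genes, dropping them should shrink the log-odds toward 0.
    """
    drop = set(genes_to_drop)
    bad = drop - set(gene_set.genes)
    if bad:
        raise ValidationError(f"genes_to_drop not in gene set: {sorted(bad)[:5]}")
    rules = default_class_rules() if rules is None else rules
    urv_cfg = UrvFilterConfig() if urv_cfg is None else urv_cfg
    rule_map = {r.name: r for r in rules}
    cell_rules = (rule_map[class_name],)
    qvt = build_qv_table(variants, carriers, samples, urv_cfg, cell_rules, phenotype)
    cov = build_covariate_matrix(samples, qvt, n_pcs=n_pcs)
    kept = cov.index
    y = qvt.is_case.reindex(kept).to_numpy(dtype=float)
    covr = cov.reset_index(drop=True)

    reduced = GeneSet(
        gene_set.name + "_reduced",
        tuple(g for g in gene_set.genes if g not in drop),
        category=gene_set.category,
    )
    before = lrt_burden_test(
        y, burden_score(qvt[class_name], gene_set).reindex(kept).to_numpy(), covr
    )
    after = lrt_burden_test(
        y, burden_score(qvt[class_name], reduced).reindex(kept).to_numpy(), covr
    )
    return before, after
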