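"""Covariate-adjusted logistic burden model, LRT, and BH-FDR over the grid.

The central quantity is the coefficient of the per-sample gene-set burden score
in a logistic regression of case-control status on burden plus covariates
(sex, ten principal components, exome-wide URV count, exome-wide singleton
count).  Significance comes from a 1-df likelihood-ratio test of the full model
against the covariates-only null; the reported effect is the burden log-odds
with a Wald 95% confidence interval.  p values from the full grid of
(phenotype x gene set x non-synonymous class) cells are adjusted jointly with
the Benjamini-Hochberg step-up procedure; the synonymous class is computed as a
calibration track and deliberately excluded from adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .collapse import GeneSet, burden_score, carrier_summary
from .errors import ModelError, ValidationError
from .qv import (
    CLASS_NAMES,
    NONSYNONYMOUS_CLASSES,
    SYNONYMOUS_CLASS,
    QVTables,
    UrvFilterConfig,
    build_qv_table,
    default_class_rules,
)

logger = logging.getLogger(__name__)

Z_95 = 1.959964  # two-sided 95% normal quantile
COEF_GUARD = 15.0  # |coefficient| beyond this flags quasi-separation

STAR_THRESHOLDS = ((5e-5, "****"), (5e-4, "***"), (5e-3, "**"), (5e-2, "*"))


# --------------------------------------------------------------------------
# maximum-likelihood logistic fit
# --------------------------------------------------------------------------

@dataclass
class LogisticFit:
    params: pd.Series
    cov: pd.DataFrame
    llf: float
    converged: bool
    dropped: tuple[str, ...] = ()


def _prune_design(X: pd.DataFrame) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Drop constant non-intercept columns; keep a single intercept column."""
    dropped = []
    keep = []
    intercept_kept = False
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if np.all(v == v[0]):
            if v[0] != 0 and not intercept_kept:
                intercept_kept = True
                keep.append(col)
            else:
                dropped.append(col)
        else:
            keep.append(col)
    if dropped:
        logger.warning("dropping constant design columns: %s", dropped)
    return X[keep], tuple(dropped)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Name columns implicated in rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    A = X.to_numpy(dtype=float)
    _, r, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    bad += [X.columns[j] for j in piv[len(diag):]]
    return [str(c) for c in bad]


def fit_logistic(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Newton maximum-likelihood fit of a binomial GLM with logit link.

    The covariance is the inverse observed information at the optimum.
    ``converged`` is False when the iteration cap is hit or any coefficient
    exceeds the quasi-separation guard.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ModelError(f"outcome length {len(y)} != design rows {len(X)}")
    if np.all(y == y[0]):
        raise ModelError("no variation in outcome: all samples share one label")
    X, dropped = _prune_design(X)
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        raise ModelError(
            "design matrix is rank deficient; collinear columns: "
            f"{_collinear_columns(X)}"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X.astype(float)).fit(
                method="newton", maxiter=maxiter, tol=tol, disp=0,
                warn_convergence=False,
            )
    except (np.linalg.LinAlgError, ValueError, Exception) as exc:  # separation etc.
        logger.warning("logistic fit failed (%s); flagging non-convergence", exc)
        nan = pd.Series(np.nan, index=X.columns)
        return LogisticFit(nan, pd.DataFrame(np.nan, index=X.columns, columns=X.columns),
                           np.nan, False, dropped)
    converged = bool(res.mle_retvals.get("converged", False))
    params = pd.Series(res.params, index=X.columns)
    if np.nanmax(np.abs(params.to_numpy())) > COEF_GUARD:
        converged = False
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns)
    return LogisticFit(params, cov, float(res.llf), converged, dropped)


# --------------------------------------------------------------------------
# burden model / results objects
# --------------------------------------------------------------------------

@dataclass
class BurdenLogitResults:
    """Result of one burden LRT cell."""

    log_odds: float
    se: float
    ci_lo: float
    ci_hi: float
    lrt_stat: float
    pvalue: float
    converged: bool
    degenerate: bool
    n_cases: int
    n_controls: int
    full_fit: LogisticFit | None = None
    null_fit: LogisticFit | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.log_odds))

    def summary(self) -> str:
        lines = [
            "Gene-set burden logistic regression (likelihood-ratio test)",
            f"  cases / controls : {self.n_cases} / {self.n_controls}",
            f"  log-odds (burden): {self.log_odds: .4f}  (SE {self.se:.4f})",
            f"  95% CI           : [{self.ci_lo: .4f}, {self.ci_hi: .4f}]",
            f"  odds ratio       : {self.odds_ratio:.4f}",
            f"  LRT chi2(1)      : {self.lrt_stat:.4f}",
            f"  p (LRT)          : {self.pvalue:.4g}",
            f"  converged        : {self.converged}   degenerate: {self.degenerate}",
        ]
        return "\n".join(lines)


class BurdenLogit:
    """Logistic burden model for one (gene set, class, analysis) cell.

    Parameters
    ----------
    endog : binary case/control labels (1 = case), aligned with ``score``.
    score : per-sample gene-set burden score (the predictor of interest).
    covariates : DataFrame of adjustment covariates, same row order; an
        intercept is added automatically.
    """

    def __init__(self, endog, score, covariates: pd.DataFrame | None = None):
        self.endog = np.asarray(endog, dtype=float)
        self.score = np.asarray(score, dtype=float)
        if covariates is None:
            covariates = pd.DataFrame(index=range(len(self.endog)))
        if len(self.endog) != len(self.score) or len(self.endog) != len(covariates):
            raise ModelError("endog, score and covariates must have equal length")
        self.covariates = covariates.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, score_col: str = "burden",
                       label_col: str = "is_case",
                       covariate_cols: list[str] | None = None) -> "BurdenLogit":
        covs = df[covariate_cols] if covariate_cols else None
        return cls(df[label_col], df[score_col], covs)

    def _designs(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        X_null = self.covariates.copy()
        X_null.insert(0, "const", 1.0)
        X_full = X_null.copy()
        X_full.insert(1, "burden", self.score)
        return X_full, X_null

    def fit(self, null_fit: LogisticFit | None = None) -> BurdenLogitResults:
        n_cases = int(self.endog.sum())
        n_controls = int(len(self.endog) - n_cases)
        if np.all(self.score == self.score[0]):
            # constant burden across samples: no information, calibrated null
            return BurdenLogitResults(
                0.0, np.nan, np.nan, np.nan, 0.0, 1.0, True, True,
                n_cases, n_controls,
            )
        X_full, X_null = self._designs()
        full = fit_logistic(self.endog, X_full)
        if null_fit is None:
            null_fit = fit_logistic(self.endog, X_null)
        if not np.isfinite(full.llf) or not np.isfinite(null_fit.llf):
            return BurdenLogitResults(
                np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False, False,
                n_cases, n_controls, full, null_fit,
            )
        lrt = max(0.0, 2.0 * (full.llf - null_fit.llf))
        p = float(sps.chi2.sf(lrt, df=1))
        b = float(full.params["burden"])
        se = float(np.sqrt(full.cov.loc["burden", "burden"]))
        return BurdenLogitResults(
            b, se, b - Z_95 * se, b + Z_95 * se, lrt, p,
            full.converged and null_fit.converged, False,
            n_cases, n_controls, full, null_fit,
        )


def lrt_burden_test(
    phenotype_labels,
    scores,
    covariates: pd.DataFrame | None = None,
    null_fit: LogisticFit | None = None,
) -> BurdenLogitResults:
    """One burden LRT: labels (1 = case) vs. burden score, covariate adjusted."""
    return BurdenLogit(phenotype_labels, scores, covariates).fit(null_fit=null_fit)


# --------------------------------------------------------------------------
# multiplicity
# --------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def star_annotation(p_adj: float) -> str:
    """Significance stars with strict thresholds; boundary values get fewer stars."""
    if not np.isfinite(p_adj):
        return ""
    for thr, stars in STAR_THRESHOLDS:
        if p_adj < thr:
            return stars
    return ""


@dataclass
class SignificanceSummary:
    n_significant: int
    n_tests: int

    @property
    def percent(self) -> float:
        """Percentage significant, rounded to one decimal place."""
        return round(100.0 * self.n_significant / self.n_tests, 1) if self.n_tests else 0.0


def significant_fraction(pvalues, alpha: float = 0.05) -> SignificanceSummary:
    """Count and one-decimal percentage of tests below ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    return SignificanceSummary(int((p < alpha).sum()), int(p.size))


# --------------------------------------------------------------------------
# covariates and the full grid
# --------------------------------------------------------------------------

_SEX_CODES = {"F": 1, "M": 0, "female": 1, "male": 0, "1": 1, "0": 0, 1: 1, 0: 0}


def build_covariate_matrix(
    samples: pd.DataFrame,
    qvt: QVTables,
    n_pcs: int = 10,
) -> pd.DataFrame:
    """Sex (female = 1), PC1..PCn, exome-wide URV and singleton counts.

    Rows follow the analysis sample order; samples with missing covariate
    values are dropped with a logged count.
    """
    meta = samples.set_index("sample").reindex(qvt.sample_index)
    cov = pd.DataFrame(index=qvt.sample_index)
    cov["sex"] = meta["sex"].map(_SEX_CODES)
    pc_cols = [f"PC{i}" for i in range(1, n_pcs + 1) if f"PC{i}" in meta.columns]
    for c in pc_cols:
        cov[c] = pd.to_numeric(meta[c], errors="coerce")
    cov["urv_count"] = qvt.covariate_counts["urv_count"]
    cov["singleton_count"] = qvt.covariate_counts["singleton_count"]
    n_missing = int(cov.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d samples with missing covariates", n_missing)
        cov = cov.dropna()
    return cov.astype(float)


RESULT_COLUMNS = [
    "phenotype", "gene_set", "class", "log_odds", "se", "ci_lo", "ci_hi",
    "lrt_stat", "p", "p_fdr", "stars", "converged", "degenerate",
    "n_genes_with_qv", "n_case_carriers", "n_control_carriers",
    "case_hits", "control_hits", "frac_case_carriers", "frac_control_carriers",
]


class GridResults:
    """Burden results for the full phenotype x gene-set x class grid.

    ``frame`` holds one row per grid cell.  Non-synonymous cells carry jointly
    BH-adjusted p values (``p_fdr``); the synonymous calibration track keeps
    ``p_fdr`` empty and its stars are derived from the unadjusted p.
    """

    def __init__(self, frame: pd.DataFrame, alpha: float = 0.05, meta: dict | None = None):
        self.frame = frame.reset_index(drop=True)
        self.alpha = alpha
        self.meta = meta or {}

    @property
    def n_adjusted_tests(self) -> int:
        return int((self.frame["class"] != SYNONYMOUS_CLASS).sum())

    @property
    def n_synonymous_tests(self) -> int:
        return int((self.frame["class"] == SYNONYMOUS_CLASS).sum())

    def subset(self, **kw) -> pd.DataFrame:
        df = self.frame
        for col, val in kw.items():
            vals = val if isinstance(val, (list, tuple, set)) else [val]
            df = df[df[col].isin(vals)]
        return df

    def forest_frame(self) -> pd.DataFrame:
        cols = ["gene_set", "class", "phenotype", "log_odds", "ci_lo", "ci_hi", "stars"]
        return self.frame[cols].copy()

    def summary(self, top: int = 10) -> str:
        df = self.frame[self.frame["class"] != SYNONYMOUS_CLASS]
        df = df.sort_values("p", kind="mergesort").head(top)
        lines = [
            f"Gene-set burden grid: {self.n_adjusted_tests} FDR-adjusted tests, "
            f"{self.n_synonymous_tests} synonymous control tests",
            f"(alpha = {self.alpha}; BH-FDR over non-synonymous cells)",
            "",
            f"{'phenotype':<10}{'gene_set':<24}{'class':<24}"
            f"{'log_odds':>9}{'p':>11}{'p_fdr':>11}  stars",
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{r['phenotype']:<10}{r['gene_set']:<24}{r['class']:<24}"
                f"{r['log_odds']:>9.3f}{r['p']:>11.3g}{r['p_fdr']:>11.3g}  {r['stars']}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        from .io import write_results_tsv

        write_results_tsv(self.frame, path)

    def plot_forest(self, phenotype: str, class_name: str, ax=None):
        """Forest plot of one (phenotype, class) slice across gene sets."""
        import matplotlib.pyplot as plt

        df = self.subset(phenotype=phenotype, **{"class": class_name})
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * len(df) + 1))
        ypos = np.arange(len(df))[::-1]
        ax.errorbar(
            df["log_odds"], ypos,
            xerr=[df["log_odds"] - df["ci_lo"], df["ci_hi"] - df["log_odds"]],
            fmt="o", capsize=2,
        )
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_yticks(ypos)
        ax.set_yticklabels(df["gene_set"])
        ax.set_xlabel("log odds (LRT)")
        ax.set_title(f"{phenotype} — {class_name}")
        return ax


def run_grid(
    samples: pd.DataFrame,
    variants: pd.DataFrame,
    carriers: pd.DataFrame,
    gene_sets: list[GeneSet],
    phenotypes: list[str] | None = None,
    rules=None,
    urv_cfg: UrvFilterConfig | None = None,
    alpha: float = 0.05,
    n_pcs: int = 10,
    control_label: str = "control",
    qv_tables: dict[str, QVTables] | None = None,
) -> GridResults:
    """Run the burden LRT over every (phenotype, gene set, class) cell.

    One null (covariates-only) model is fitted per phenotype analysis and
    shared across that analysis's cells.  All non-synonymous cells — including
    degenerate ones — enter the joint BH adjustment, so the adjusted test count
    depends only on the grid dimensions.
    """
    rules = default_class_rules() if rules is None else rules
    urv_cfg = UrvFilterConfig() if urv_cfg is None else urv_cfg
    if phenotypes is None:
        phenotypes = [
            p for p in dict.fromkeys(samples["phenotype"]) if p != control_label
        ]

    rows = []
    funnels: dict[str, dict] = {}
    for phenotype in phenotypes:
        if qv_tables is not None and phenotype in qv_tables:
            qvt = qv_tables[phenotype]
        else:
            qvt = build_qv_table(
                variants, carriers, samples, urv_cfg, rules, phenotype,
                control_label=control_label,
            )
        funnels[phenotype] = dict(qvt.funnel)
        cov = build_covariate_matrix(samples, qvt, n_pcs=n_pcs)
        kept = cov.index
        y = qvt.is_case.reindex(kept).to_numpy(dtype=float)
        X_null = cov.reset_index(drop=True).copy()
        X_null.insert(0, "const", 1.0)
        null_fit = fit_logistic(y, X_null)
        for rule in rules:
            cls = rule.name
            table = qvt[cls]
            for gs in gene_sets:
                score = burden_score(table, gs).reindex(kept)
                summ = carrier_summary(table, gs, qvt.is_case)
                res = lrt_burden_test(y, score.to_numpy(), cov.reset_index(drop=True),
                                      null_fit=null_fit)
                rows.append({
                    "phenotype": phenotype, "gene_set": gs.name, "class": cls,
                    "log_odds": res.log_odds, "se": res.se,
                    "ci_lo": res.ci_lo, "ci_hi": res.ci_hi,
                    "lrt_stat": res.lrt_stat, "p": res.pvalue,
                    "converged": res.converged, "degenerate": res.degenerate,
                    **summ.as_dict(),
                })
    frame = pd.DataFrame(rows)
    nonsyn = frame["class"] != SYNONYMOUS_CLASS
    frame["p_fdr"] = np.nan
    p_raw = frame.loc[nonsyn, "p"].to_numpy(dtype=float)
    # failed fits (NaN p) keep NaN adjusted values but still occupy grid cells
    finite = np.isfinite(p_raw)
    adj = np.full(p_raw.shape, np.nan)
    if finite.any():
        # BH uses m = all non-synonymous cells, degenerate (p = 1) included
        adj[finite] = bh_adjust(p_raw[finite])
    frame.loc[nonsyn, "p_fdr"] = adj
    frame["stars"] = [
        star_annotation(r["p"] if r["class"] == SYNONYMOUS_CLASS else r["p_fdr"])
        for _, r in frame.iterrows()
    ]
    frame = frame[RESULT_COLUMNS]
    meta = {
        "phenotypes": list(phenotypes),
        "classes": [r.name for r in rules],
        "gene_sets": [gs.name for gs in gene_sets],
        "alpha": alpha,
        "urv_filter": {
            "mac_max": urv_cfg.mac_max,
            "gnomad_af_max": urv_cfg.gnomad_af_max,
            "discovehr_af_max": urv_cfg.discovehr_af_max,
        },
        "funnel": funnels,
    }
    return GridResults(frame, alpha=alpha, meta=meta)
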