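"""Gene-set collapsing: per-sample burden scores and carrier summaries.

The burden score of a sample for a gene set is the number of genes in the set
in which the sample carries at least one qualifying variant of the class under
test (equal weights, one direction).  Set members absent from the data
contribute nothing; unmatched symbols are counted and logged, not fatal, since
catalogues routinely contain symbols missing from any given call set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .qv import QVTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named gene list with a catalogue category."""

    name: str
    genes: tuple[str, ...]
    category: str = "functional"
    description: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        deduped = tuple(dict.fromkeys(self.genes))
        if len(deduped) != len(self.genes):
            object.__setattr__(self, "genes", deduped)

    def __len__(self) -> int:
        return len(self.genes)


def _set_columns(qv: QVTable, gene_set: GeneSet) -> np.ndarray:
    """Column indices of the set's genes in the QV matrix (case-normalised)."""
    lut = {g.upper(): i for i, g in enumerate(qv.gene_index)}
    cols, missing = [], 0
    for g in gene_set.genes:
        i = lut.get(str(g).upper())
        if i is None:
            missing += 1
        else:
            cols.append(i)
    if missing:
        logger.debug(
            "gene set %s: %d/%d members absent from data",
            gene_set.name, missing, len(gene_set.genes),
        )
    return np.asarray(cols, dtype=int)


def burden_score(qv: QVTable, gene_set: GeneSet) -> pd.Series:
    """Per-sample count of set genes harbouring >= 1 qualifying variant."""
    cols = _set_columns(qv, gene_set)
    if len(cols) == 0:
        return pd.Series(np.zeros(len(qv.sample_index), dtype=int), index=qv.sample_index)
    score = np.asarray(qv.matrix[:, cols].sum(axis=1)).ravel().astype(int)
    return pd.Series(score, index=qv.sample_index)


@dataclass
class CarrierSummary:
    """Descriptive counts for one (gene set, class, analysis) cell."""

    n_genes_with_qv: int = 0
    n_case_carriers: int = 0
    n_control_carriers: int = 0
    case_hits: int = 0
    control_hits: int = 0
    frac_case_carriers: float = 0.0
    frac_control_carriers: float = 0.0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def carrier_summary(qv: QVTable, gene_set: GeneSet, is_case: pd.Series) -> CarrierSummary:
    """Counts of QV-bearing genes, carriers, and per-gene hits in cases/controls."""
    cols = _set_columns(qv, gene_set)
    case = is_case.reindex(qv.sample_index).fillna(False).to_numpy(dtype=bool)
    n_cases = int(case.sum())
    n_controls = int((~case).sum())
    if len(cols) == 0:
        return CarrierSummary()
    sub = qv.matrix[:, cols]
    score = np.asarray(sub.sum(axis=1)).ravel()
    genes_hit = int((np.asarray(sub.sum(axis=0)).ravel() > 0).sum())
    case_score, ctrl_score = score[case], score[~case]
    return CarrierSummary(
        n_genes_with_qv=genes_hit,
        n_case_carriers=int((case_score >= 1).sum()),
        n_control_carriers=int((ctrl_score >= 1).sum()),
        case_hits=int(case_score.sum()),
        control_hits=int(ctrl_score.sum()),
        frac_case_carriers=float((case_score >= 1).mean()) if n_cases else 0.0,
        frac_control_carriers=float((ctrl_score >= 1).mean()) if n_controls else 0.0,
    )
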