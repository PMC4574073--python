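"""Association of repeat instability with expression and methylation.

Per-gene scheme: among the genes whose promoter (or exon) shows repeat
instability in at least one tumor, compare the mean expression of each gene
in tumors where it is instability-flagged against its mean in the remaining
tumors, then test the paired (log2) means across genes with the Wilcoxon
signed-rank test.  Methylation beta values follow the identical scheme
without the log transform.  Genes flagged in all or in no tumors have no
comparison group and are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DIRECTION_DOWN = "down_in_instability"
DIRECTION_UP = "up_in_instability"
DIRECTION_NONE = "none"


@dataclass(frozen=True)
class GeneAssociation:
    """Group means of one gene across instability / other tumors."""

    gene_id: str
    n_instability_tumors: int
    n_other_tumors: int
    mean_instability: float
    mean_other: float
    log2_mean_instability: float
    log2_mean_other: float


@dataclass(frozen=True)
class AssociationResult:
    """Signed-rank comparison of per-gene group means."""

    scope: str
    omics: str  # "expression" | "methylation"
    n_genes: int
    statistic: float
    p_raw: float
    p_adjusted: float
    direction: str
    correction: str


def gene_group_means(matrix: pd.DataFrame, table: pd.DataFrame,
                     epsilon: float = 1e-6) -> list[GeneAssociation]:
    """Per-gene means over instability-flagged vs remaining tumors.

    ``matrix`` is the boolean gene x tumor instability matrix (genes with
    instability in >= 1 tumor); ``table`` holds one omics value per gene
    and tumor.  Genes absent from the table, or flagged in all or no
    shared tumors, are excluded (and logged).
    """
    tumors = [t for t in matrix.columns if t in table.columns]
    if not tumors:
        raise ValueError("no overlapping tumors between matrix and table")
    out: list[GeneAssociation] = []
    n_excluded = 0
    for gene in matrix.index:
        if gene not in table.index:
            n_excluded += 1
            continue
        flags = matrix.loc[gene, tumors].to_numpy(dtype=bool)
        k = int(flags.sum())
        if k == 0 or k == len(tumors):
            n_excluded += 1
            continue
        values = table.loc[gene, tumors].to_numpy(dtype=float)
        mean_i = float(values[flags].mean())
        mean_o = float(values[~flags].mean())
        out.append(GeneAssociation(
            gene_id=gene, n_instability_tumors=k,
            n_other_tumors=len(tumors) - k,
            mean_instability=mean_i, mean_other=mean_o,
            log2_mean_instability=float(np.log2(mean_i + epsilon)),
            log2_mean_other=float(np.log2(mean_o + epsilon))))
    if n_excluded:
        log.info("gene_group_means: excluded %d genes without a comparison "
                 "group", n_excluded)
    return out


def signed_rank_test(x, y):
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (Wilcoxon convention); the exact null
    distribution is used for <= 25 tie-free nonzero pairs, the normal
    approximation with correction otherwise.  Returns
    (statistic, p, direction, n_nonzero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) == 0:
        raise ValueError("paired samples of equal nonzero length required")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 1.0, DIRECTION_NONE, 0
    ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    med = float(np.median(d))
    if med < 0:
        direction = DIRECTION_DOWN
    elif med > 0:
        direction = DIRECTION_UP
    else:
        direction = DIRECTION_NONE
    return float(res.statistic), float(res.pvalue), direction, len(d)


def _associate(matrix: pd.DataFrame, table: pd.DataFrame, omics: str,
               scope: str, gene_set=None, log_transform: bool = True,
               family_size: int = 1, epsilon: float = 1e-6) -> AssociationResult:
    if gene_set is not None:
        matrix = matrix.loc[matrix.index.intersection(sorted(gene_set))]
    assoc = gene_group_means(matrix, table, epsilon=epsilon)
    if not assoc:
        return AssociationResult(scope, omics, 0, 0.0, 1.0, 1.0,
                                 DIRECTION_NONE,
                                 "bonferroni" if family_size > 1 else "none")
    if log_transform:
        x = [a.log2_mean_instability for a in assoc]
        y = [a.log2_mean_other for a in assoc]
    else:
        x = [a.mean_instability for a in assoc]
        y = [a.mean_other for a in assoc]
    stat, p, direction, _ = signed_rank_test(x, y)
    p_adj = min(1.0, p * family_size)
    return AssociationResult(scope, omics, len(assoc), stat, p, p_adj,
                             direction,
                             "bonferroni" if family_size > 1 else "none")


def expression_association(matrix: pd.DataFrame, expression: pd.DataFrame,
                           scope: str = "genome_wide", gene_set=None,
                           family_size: int = 1,
                           epsilon: float = 1e-6) -> AssociationResult:
    """Signed-rank comparison of per-gene log2 mean expression (rpkm)
    between instability-flagged and other tumors."""
    if (expression.to_numpy(dtype=float) < 0).any():
        raise ValueError("expression values must be nonnegative rpkm")
    return _associate(matrix, expression, "expression", scope, gene_set,
                      log_transform=True, family_size=family_size,
                      epsilon=epsilon)


def methylation_association(matrix: pd.DataFrame, methylation: pd.DataFrame,
                            scope: str = "genome_wide", gene_set=None,
                            family_size: int = 1) -> AssociationResult:
    """Same scheme on promoter methylation beta values (no log transform)."""
    values = methylation.to_numpy(dtype=float)
    if (values < 0).any() or (values > 1).any():
        raise ValueError("methylation beta values must lie in [0, 1]")
    return _associate(matrix, methylation, "methylation", scope, gene_set,
                      log_transform=False, family_size=family_size)


def associations_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "scope": r.scope, "omics": r.omics, "n_genes": r.n_genes,
        "statistic": r.statistic, "p_raw": r.p_raw,
        "p_adjusted": r.p_adjusted, "direction": r.direction,
        "correction": r.correction,
    } for r in results])
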