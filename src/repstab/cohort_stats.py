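"""Cohort-level comparisons of repeat instability.

The central contrast is tumor-vs-matched-normal pairs (one per patient)
against the all-pairs normal-normal null (all C(n, 2) unordered pairs of
normal genomes, pooled).  Per-pair gene counts -- genes with orphan
repeats, with unstable repeats, or with either -- are compared with the
Wilcoxon rank-sum test; MSI-vs-MSS and per-pathway proportions follow the
same scheme, Bonferroni-corrected over the family of metrics tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

EVENT_TYPES = ("orphan", "unstable", "instability")


@dataclass(frozen=True)
class PairProfile:
    """Per-genome-pair instability counts and per-pathway proportions.

    ``counts`` is keyed "<region>_<event>" with optional "_mono" suffix,
    e.g. "promoter_orphan", "exon_instability_mono".  ``pathway_props`` is
    keyed (pathway, region, event) and holds the proportion of the
    pathway's analysed genes flagged in this pair.
    """

    pair_id: str
    pair_class: str  # "tumor_normal" | "normal_normal"
    msi: bool | None
    counts: dict[str, int]
    pathway_props: dict[tuple[str, str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortTestResult:
    """One group comparison: statistic, raw and adjusted p-value."""

    name: str
    test: str  # "WRS" | "WSR"
    statistic: float
    n_a: int
    n_b: int
    p_raw: float
    p_adjusted: float
    correction: str  # "none" | "bonferroni"


def enumerate_normal_pairs(genomes: list) -> list[tuple]:
    """All C(n, 2) unordered pairs of normal genomes, in deterministic order."""
    if len(genomes) < 2:
        raise ValueError("need at least two genomes to form pairs")
    return list(combinations(genomes, 2))


def _flag(flags, key, attr):
    f = flags.get(key)
    return bool(getattr(f, attr)) if f is not None else False


def profile_pair(flags: dict, pair_id: str, pair_class: str,
                 msi: bool | None = None,
                 analyzed_genes: list[str] | None = None,
                 pathways: dict[str, set] | None = None,
                 region_kinds=("promoter", "exon")) -> PairProfile:
    """Summarise one genome pair's per-gene flags into a PairProfile.

    ``flags`` maps (gene_id, region_kind) -> GeneInstabilityFlags (from
    ``instability.call_pair``).  Pathway proportions use as denominator all
    pathway genes present in ``analyzed_genes`` (the analysed gene set),
    regardless of whether they carry repeats.
    """
    counts: dict[str, int] = {}
    attr_of = {"orphan": "has_orphan", "unstable": "has_unstable",
               "instability": "has_instability"}
    for kind in region_kinds:
        keys = [k for k in flags if k[1] == kind]
        for event, attr in attr_of.items():
            counts[f"{kind}_{event}"] = sum(
                1 for k in keys if getattr(flags[k], attr))
            counts[f"{kind}_{event}_mono"] = sum(
                1 for k in keys if getattr(flags[k], "mono_" + attr))
    props: dict[tuple[str, str, str], float] = {}
    if pathways:
        if analyzed_genes is None:
            raise ValueError("pathway proportions need the analysed gene set")
        universe = set(analyzed_genes)
        for name, genes in pathways.items():
            members = sorted(genes & universe)
            denom = len(members)
            for kind in region_kinds:
                for event, attr in attr_of.items():
                    if denom == 0:
                        props[(name, kind, event)] = 0.0
                        continue
                    hit = sum(1 for g in members
                              if _flag(flags, (g, kind), attr))
                    props[(name, kind, event)] = hit / denom
    return PairProfile(pair_id=pair_id, pair_class=pair_class, msi=msi,
                       counts=counts, pathway_props=props)


def rank_sum_test(values_a, values_b, name: str = "WRS") -> CohortTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact permutation distribution when the smaller group has <= 8
    observations and the pooled values are tie-free; otherwise the normal
    approximation with tie and continuity correction.  Two identical
    constant groups give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return CohortTestResult(name, "WRS", len(a) * len(b) / 2.0,
                                len(a), len(b), 1.0, 1.0, "none")
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return CohortTestResult(name, "WRS", float(res.statistic),
                            len(a), len(b), p, p, "none")


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, p * m)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("family size m smaller than number of p-values")
    return [min(1.0, p * m) for p in p_values]


def _adjusted(result: CohortTestResult, m: int) -> CohortTestResult:
    return CohortTestResult(result.name, result.test, result.statistic,
                            result.n_a, result.n_b, result.p_raw,
                            bonferroni([result.p_raw], m)[0], "bonferroni")


def compare_cohorts(tumor_profiles: list[PairProfile],
                    normal_profiles: list[PairProfile],
                    metric: str) -> CohortTestResult:
    """WRS of a per-pair count between tumor-normal and normal-normal pairs."""
    a = [p.counts[metric] for p in tumor_profiles]
    b = [p.counts[metric] for p in normal_profiles]
    return rank_sum_test(a, b, name=f"tumor_vs_normal:{metric}")


def compare_msi(tumor_profiles: list[PairProfile], metric: str,
                family_size: int = 4) -> CohortTestResult:
    """WRS of a per-pair count between MSI and MSS tumor pairs.

    ``family_size`` is the Bonferroni family (four panels by default:
    {promoter, exon} x {all repeats, mononucleotide}).
    """
    msi = [p.counts[metric] for p in tumor_profiles if p.msi]
    mss = [p.counts[metric] for p in tumor_profiles if not p.msi]
    if not msi or not mss:
        raise ValueError("both MSI and MSS subgroups must be non-empty")
    res = rank_sum_test(msi, mss, name=f"msi_vs_mss:{metric}")
    return _adjusted(res, family_size)


def pathway_enrichment(tumor_profiles: list[PairProfile],
                       normal_profiles: list[PairProfile],
                       pathway_names: list[str],
                       region_kind: str = "promoter",
                       events=("unstable", "orphan")) -> list[CohortTestResult]:
    """Per-pathway WRS of per-pair proportions, tumor-normal vs
    normal-normal, Bonferroni-corrected over pathways x event types."""
    m = len(pathway_names) * len(events)
    out = []
    for name in pathway_names:
        for event in events:
            key = (name, region_kind, event)
            a = [p.pathway_props[key] for p in tumor_profiles]
            b = [p.pathway_props[key] for p in normal_profiles]
            res = rank_sum_test(
                a, b, name=f"pathway:{name}:{region_kind}:{event}")
            out.append(_adjusted(res, m))
    return out


def results_to_frame(results: list[CohortTestResult]):
    import pandas as pd

    return pd.DataFrame([{
        "name": r.name, "test": r.test, "statistic": r.statistic,
        "n_a": r.n_a, "n_b": r.n_b, "p_raw": r.p_raw,
        "p_adjusted": r.p_adjusted, "correction": r.correction,
    } for r in results])
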