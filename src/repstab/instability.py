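"""Pairing of tandem repeats between two genomes and instability calling.

Repeats detected in the same gene region of two genomes are matched when
they share a canonical repeat unit and their starts lie within a positional
window (50 nt by default, tolerating indel-driven shifts).  A matched pair
whose unit copy numbers differ by at least one full unit is *unstable*;
repeats with no counterpart are *orphans*, i.e. de-novo gains or losses.
Gene-level flags and the gene x patient instability matrix aggregate these
calls for cohort statistics and omics association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .repeat_finder import TandemRepeat, canonical_unit

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STATUS_STABLE = "stable"
STATUS_UNSTABLE = "unstable"
STATUS_ORPHAN_A = "orphan_a"
STATUS_ORPHAN_B = "orphan_b"


@dataclass(frozen=True)
class RepeatMatch:
    """Pairing of repeats from genomes A and B in one gene region."""

    gene_id: str
    region_kind: str
    repeat_a: TandemRepeat | None
    repeat_b: TandemRepeat | None
    status: str
    copy_delta: float | None

    @property
    def unit(self) -> str:
        rep = self.repeat_a or self.repeat_b
        return rep.unit

    @property
    def is_mono(self) -> bool:
        return len(self.unit) == 1


@dataclass(frozen=True)
class GeneInstabilityFlags:
    """Per gene-region OR of match statuses, with mononucleotide subset."""

    gene_id: str
    region_kind: str
    has_orphan: bool
    has_unstable: bool
    mono_has_orphan: bool
    mono_has_unstable: bool

    @property
    def has_instability(self) -> bool:
        return self.has_orphan or self.has_unstable

    @property
    def mono_has_instability(self) -> bool:
        return self.mono_has_orphan or self.mono_has_unstable


def _unit_key(unit: str, identify_revcomp: bool) -> str:
    if not identify_revcomp:
        return unit
    rc = canonical_unit(unit.translate(_COMPLEMENT)[::-1])
    return min(unit, rc)


def classify_match(repeat_a: TandemRepeat | None, repeat_b: TandemRepeat | None,
                   unstable_min_delta: float = 1.0) -> str:
    """Status of a (possibly one-sided) repeat pairing.

    One-sided pairings are orphans; two-sided ones are unstable when the
    copy numbers differ by at least ``unstable_min_delta`` units.
    """
    if repeat_a is None and repeat_b is None:
        raise ValueError("at least one repeat required")
    if repeat_b is None:
        return STATUS_ORPHAN_A
    if repeat_a is None:
        return STATUS_ORPHAN_B
    # 1e-9 guards against float error in length/period copy numbers
    if abs(repeat_a.copy_number - repeat_b.copy_number) >= unstable_min_delta - 1e-9:
        return STATUS_UNSTABLE
    return STATUS_STABLE


def match_repeats(repeats_a: list[TandemRepeat], repeats_b: list[TandemRepeat],
                  max_shift: int = 50, unstable_min_delta: float = 1.0,
                  gene_id: str = "", region_kind: str = "",
                  identify_revcomp: bool = False) -> list[RepeatMatch]:
    """One-to-one matching of repeats from two genomes of one gene region.

    Candidate pairs share a canonical unit and have starts within
    ``max_shift``; pairs are accepted greedily by increasing positional
    distance (ties: higher summed score, then lower start in A).  Unmatched
    repeats become orphans.  Every input repeat appears in exactly one
    returned RepeatMatch.
    """
    cand = []
    for i, ra in enumerate(repeats_a):
        ka = _unit_key(ra.unit, identify_revcomp)
        for j, rb in enumerate(repeats_b):
            if ka != _unit_key(rb.unit, identify_revcomp):
                continue
            dist = abs(ra.start - rb.start)
            if dist <= max_shift:
                cand.append((dist, -(ra.score + rb.score), ra.start, rb.start, i, j))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[RepeatMatch] = []
    for dist, _, _, _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        ra, rb = repeats_a[i], repeats_b[j]
        status = classify_match(ra, rb, unstable_min_delta)
        matches.append(RepeatMatch(gene_id or ra.gene_id,
                                   region_kind or ra.region_kind,
                                   ra, rb, status,
                                   ra.copy_number - rb.copy_number))
    for i, ra in enumerate(repeats_a):
        if i not in used_a:
            matches.append(RepeatMatch(gene_id or ra.gene_id,
                                       region_kind or ra.region_kind,
                                       ra, None, STATUS_ORPHAN_A, None))
    for j, rb in enumerate(repeats_b):
        if j not in used_b:
            matches.append(RepeatMatch(gene_id or rb.gene_id,
                                       region_kind or rb.region_kind,
                                       None, rb, STATUS_ORPHAN_B, None))
    matches.sort(key=lambda m: ((m.repeat_a or m.repeat_b).start,
                                m.status))
    return matches


def gene_flags(matches: list[RepeatMatch]) -> GeneInstabilityFlags:
    """OR-aggregate one gene region's matches into instability flags."""
    if not matches:
        raise ValueError("no matches for gene region")
    gene_id = matches[0].gene_id
    region_kind = matches[0].region_kind
    has_orphan = has_unstable = mono_orphan = mono_unstable = False
    for m in matches:
        orphan = m.status in (STATUS_ORPHAN_A, STATUS_ORPHAN_B)
        unstable = m.status == STATUS_UNSTABLE
        has_orphan |= orphan
        has_unstable |= unstable
        if m.is_mono:
            mono_orphan |= orphan
            mono_unstable |= unstable
    return GeneInstabilityFlags(gene_id, region_kind, has_orphan, has_unstable,
                                mono_orphan, mono_unstable)


def call_pair(repeats_a: dict, repeats_b: dict, max_shift: int = 50,
              unstable_min_delta: float = 1.0, identify_revcomp: bool = False):
    """Match and classify all gene regions of one genome pair.

    ``repeats_a``/``repeats_b`` map (gene_id, region_kind) to repeat lists.
    Returns (matches, flags) where flags maps (gene_id, region_kind) to
    GeneInstabilityFlags; regions with no repeat on either side are absent.
    """
    matches: list[RepeatMatch] = []
    flags: dict[tuple[str, str], GeneInstabilityFlags] = {}
    for key in sorted(set(repeats_a) | set(repeats_b)):
        ra = repeats_a.get(key, [])
        rb = repeats_b.get(key, [])
        if not ra and not rb:
            continue
        gene_id, region_kind = key
        region_matches = match_repeats(ra, rb, max_shift, unstable_min_delta,
                                       gene_id, region_kind, identify_revcomp)
        matches.extend(region_matches)
        flags[key] = gene_flags(region_matches)
    return matches, flags


def build_matrix(flags_by_patient: dict[str, dict], region_kind: str = "promoter",
                 flag: str = "has_instability",
                 drop_empty: bool = True) -> pd.DataFrame:
    """Gene x patient boolean instability matrix from per-pair flags.

    ``flags_by_patient`` maps patient id to the flags dict returned by
    ``call_pair`` for that patient's tumor vs matched normal.  Genes with no
    instability in any patient are dropped (they carry no contrast for the
    downstream association analyses).
    """
    patients = sorted(flags_by_patient)
    genes = sorted({g for fl in flags_by_patient.values()
                    for (g, kind) in fl if kind == region_kind})
    data = {}
    for patient in patients:
        fl = flags_by_patient[patient]
        data[patient] = [bool(getattr(fl[(g, region_kind)], flag))
                        if (g, region_kind) in fl else False
                        for g in genes]
    matrix = pd.DataFrame(data, index=genes, dtype=bool)
    matrix.index.name = "gene_id"
    if drop_empty:
        kept = matrix.any(axis=1)
        n_drop = int((~kept).sum())
        if n_drop:
            log.info("build_matrix: dropping %d genes with no instability",
                     n_drop)
        matrix = matrix.loc[kept]
    return matrix


def matches_to_frame(matches: list[RepeatMatch],
                     pair_id: str = "") -> pd.DataFrame:
    """Tidy pair-call table (one row per RepeatMatch)."""
    rows = []
    for m in matches:
        ra, rb = m.repeat_a, m.repeat_b
        rows.append({
            "pair_id": pair_id,
            "gene_id": m.gene_id,
            "region_kind": m.region_kind,
            "status": m.status,
            "unit": m.unit,
            "period": len(m.unit),
            "copies_a": ra.copy_number if ra else float("nan"),
            "copies_b": rb.copy_number if rb else float("nan"),
            "start_a": ra.start if ra else -1,
            "start_b": rb.start if rb else -1,
            "score_a": ra.score if ra else -1,
            "score_b": rb.score if rb else -1,
        })
    return pd.DataFrame(rows, columns=["pair_id", "gene_id", "region_kind",
                                       "status", "unit", "period", "copies_a",
                                       "copies_b", "start_a", "start_b",
                                       "score_a", "score_b"])
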