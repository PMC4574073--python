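"""Promoter and exon super-transcript extraction, plus genome-level QC.

The promoter of a gene is the 5,000 bp (configurable) immediately upstream
of its 5'-most transcription start site across all transcripts,
strand-oriented; the exon "super-transcript" is the union of all
transcripts' exon intervals merged into non-overlapping blocks and
concatenated 5'->3'.  Genes annotated on more than one chromosome (e.g.
transposon-like multi-copy annotations) are excluded.  Genomes whose
regions contain unaligned bases (N) in more than 10 % of positions fail QC
and are removed from every downstream analysis.

Coordinates are 0-based half-open throughout; GFF3 input (1-based,
inclusive) is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRegion:
    """One promoter or exon super-transcript region of a gene."""

    gene_id: str
    region_kind: str  # "promoter" | "exon"
    chromosome: str
    strand: str  # "+" | "-"
    intervals: tuple[tuple[int, int], ...]  # 0-based half-open, sorted
    sequence: str  # strand-oriented (reverse-complemented on "-")
    truncated: bool = False

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass(frozen=True)
class GenomeQC:
    genome_id: str
    fraction_unaligned_promoters: float
    fraction_unaligned_exons: float
    passed: bool


def merge_intervals(intervals) -> tuple[tuple[int, int], ...]:
    """Union of half-open intervals, merged and sorted (idempotent)."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    if not ivs:
        return ()
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def _parse_gff3(path: str) -> pd.DataFrame:
    """Exon records from a GFF3 file as a tidy frame (0-based half-open).

    Transcript parentage is resolved through mRNA/transcript features; exon
    rows carrying a direct gene Parent are accepted too.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    rows = []
    for exon in db.features_of_type("exon"):
        gene_ids = set()
        for parent_id in exon.attributes.get("Parent", []):
            try:
                parent = db[parent_id]
            except Exception:
                continue
            if parent.featuretype == "gene":
                gene_ids.add(parent.id)
            else:
                for gene in db.parents(parent, featuretype="gene"):
                    gene_ids.add(gene.id)
        for gid in gene_ids or {exon.attributes.get("gene_id", [""])[0]}:
            if not gid:
                continue
            rows.append({"gene_id": gid, "chrom": exon.seqid,
                         "start": exon.start - 1, "end": exon.end,
                         "strand": exon.strand})
    return pd.DataFrame(rows)


def _parse_bed(path: str) -> pd.DataFrame:
    """Exon records from a BED6 file (name column = gene id)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     usecols=range(6),
                     names=["chrom", "start", "end", "gene_id", "score",
                            "strand"])
    return df[["gene_id", "chrom", "start", "end", "strand"]]


def build_regions(reference_fasta: str, annotation: str,
                  promoter_length: int = 5000) -> list[GeneRegion]:
    """Per-gene promoter and exon super-transcript regions.

    ``annotation`` may be GFF3 (*.gff/*.gff3) or BED6 with exon intervals.
    Genes on multiple chromosomes are excluded; promoters running past the
    chromosome start are truncated and flagged.
    """
    ann = str(annotation)
    exons = _parse_gff3(ann) if ann.endswith((".gff", ".gff3")) else _parse_bed(ann)
    if exons.empty:
        raise ValueError(f"no exon records parsed from {annotation}")
    chroms = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(reference_fasta), "fasta")}
    regions: list[GeneRegion] = []
    for gene_id, sub in exons.groupby("gene_id", sort=True):
        if sub.chrom.nunique() > 1:
            log.warning("gene %s annotated on multiple chromosomes; excluded",
                        gene_id)
            continue
        chrom = sub.chrom.iloc[0]
        if chrom not in chroms:
            log.warning("gene %s on unknown chromosome %s; skipped",
                        gene_id, chrom)
            continue
        strand = sub.strand.iloc[0]
        seq = chroms[chrom]
        merged = merge_intervals(zip(sub.start, sub.end))
        if not merged:
            log.warning("gene %s has no exon intervals; skipped", gene_id)
            continue
        # exon super-transcript, concatenated 5'->3'
        exon_seq = "".join(seq[s:e] for s, e in merged)
        if strand == "-":
            exon_seq = str(Seq(exon_seq).reverse_complement())
        regions.append(GeneRegion(gene_id, "exon", chrom, strand, merged,
                                  exon_seq))
        # promoter upstream of the 5'-most TSS
        truncated = False
        if strand == "-":
            tss = merged[-1][1]
            lo, hi = tss, min(tss + promoter_length, len(seq))
            truncated = hi - lo < promoter_length
            prom = str(Seq(seq[lo:hi]).reverse_complement())
        else:
            tss = merged[0][0]
            lo, hi = max(tss - promoter_length, 0), tss
            truncated = hi - lo < promoter_length
            prom = seq[lo:hi]
        if truncated:
            log.warning("gene %s promoter truncated at chromosome edge",
                        gene_id)
        regions.append(GeneRegion(gene_id, "promoter", chrom, strand,
                                  ((lo, hi),), prom, truncated=truncated))
    regions.sort(key=lambda r: (r.gene_id, r.region_kind))
    return regions


def _n_fraction(seqs: list[str]) -> float:
    total = sum(len(s) for s in seqs)
    if total == 0:
        return 1.0
    return sum(s.count("N") for s in seqs) / total


def qc_genomes(genomes: dict[str, dict], max_unaligned: float = 0.10):
    """Filter genomes by unaligned (N) content.

    ``genomes`` maps genome_id to {(gene_id, region_kind): sequence}.  A
    genome fails when its N fraction over all promoter positions, or over
    all exon positions, exceeds ``max_unaligned`` (strictly); a genome with
    no regions fails.  Returns (passing_ids, qc_table).
    """
    passing = []
    rows = []
    for genome_id in sorted(genomes):
        regions = genomes[genome_id]
        proms = [s for (g, kind), s in regions.items() if kind == "promoter"]
        exons = [s for (g, kind), s in regions.items() if kind == "exon"]
        fp = _n_fraction(proms)
        fe = _n_fraction(exons)
        ok = bool(regions) and fp <= max_unaligned and fe <= max_unaligned
        if ok:
            passing.append(genome_id)
        else:
            log.info("genome %s failed QC (promoter N %.3f, exon N %.3f)",
                     genome_id, fp, fe)
        rows.append(GenomeQC(genome_id, fp, fe, ok))
    table = pd.DataFrame([{
        "genome_id": r.genome_id,
        "fraction_unaligned_promoters": r.fraction_unaligned_promoters,
        "fraction_unaligned_exons": r.fraction_unaligned_exons,
        "pass": r.passed,
    } for r in rows])
    return passing, table
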