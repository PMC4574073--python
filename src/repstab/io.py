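"""File I/O: FASTA genomes, TSV tables, pathway sets, YAML configs.

Per-genome FASTA files carry one record per gene region with IDs of the
form ``geneID|region_kind``.  All tables are tab-separated with a header
line; writers prepend ``#`` comment lines recording the tool version and a
configuration hash so outputs are traceable to the run that made them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None,
              index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# repstab {__version__}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_genome_fasta(regions: dict, path) -> None:
    """Write one genome's regions; keys are (gene_id, region_kind)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(seq), id=f"{gene}|{kind}", description="")
               for (gene, kind), seq in sorted(regions.items())]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path) -> dict:
    """Read a per-genome FASTA back into a {(gene_id, kind): seq} dict."""
    regions = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"record id {rec.id!r} is not geneID|region_kind")
        gene, kind = rec.id.rsplit("|", 1)
        regions[(gene, kind)] = str(rec.seq).upper()
    return regions


def write_cohort_fastas(genomes: dict, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for genome_id, regions in sorted(genomes.items()):
        write_genome_fasta(regions, directory / f"{genome_id}.fasta")


def read_cohort_fastas(directory, genome_ids=None) -> dict:
    directory = Path(directory)
    paths = sorted(directory.glob("*.fasta"))
    if genome_ids is not None:
        wanted = set(genome_ids)
        paths = [p for p in paths if p.stem in wanted]
        missing = wanted - {p.stem for p in paths}
        if missing:
            raise FileNotFoundError(
                f"genome FASTA missing for: {sorted(missing)}")
    return {p.stem: read_genome_fasta(p) for p in paths}


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = read_tsv(path)
    required = ["genome_id", "patient_id", "tissue", "msi"]
    if list(sheet.columns[:4]) != required:
        raise ValueError(f"sample sheet must start with columns {required}")
    sheet["msi"] = sheet["msi"].astype(bool)
    return sheet


def read_pathways(path) -> dict[str, set]:
    """Pathway gene sets from two-column TSV (pathway, gene) or GMT."""
    path = Path(path)
    pathways: dict[str, set] = {}
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    pathways[parts[0]] = set(p for p in parts[2:] if p)
        return pathways
    df = read_tsv(path, header=None, names=["pathway", "gene"])
    if df.iloc[0, 0] == "pathway":  # header present
        df = df.iloc[1:]
    for name, sub in df.groupby("pathway"):
        pathways[str(name)] = set(sub.gene)
    return pathways


def write_pathways(pathways: dict[str, set], path) -> None:
    rows = [{"pathway": name, "gene": gene}
            for name in sorted(pathways) for gene in sorted(pathways[name])]
    write_tsv(pd.DataFrame(rows), path)


def read_omics_table(path) -> pd.DataFrame:
    table = read_tsv(path, index_col=0)
    table.index.name = "gene_id"
    return table


def read_matrix(path) -> pd.DataFrame:
    matrix = read_tsv(path, index_col=0)
    return matrix.astype(bool)
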