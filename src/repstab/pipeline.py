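"""Pipeline stages tying simulation, detection, calling and statistics together.

Each ``run_*`` stage reads its inputs from, and writes its outputs to, the
configured output directory, so stages can be run separately or end-to-end
via ``run_all``.  All outputs are deterministic given (config, seed); every
table carries the tool version and a config hash in its header comments.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import instability, io
from .cohort_stats import (
    compare_cohorts,
    compare_msi,
    enumerate_normal_pairs,
    pathway_enrichment,
    profile_pair,
    results_to_frame,
)
from .omics_assoc import (
    associations_to_frame,
    expression_association,
    methylation_association,
)
from .regions import qc_genomes
from .repeat_finder import DetectionParams, find_tandem_repeats
from .synthetic_data import (
    SimulationConfig,
    generate_cohort,
    generate_expression,
    generate_methylation,
    generate_reference,
)

log = logging.getLogger(__name__)

EVENT_METRICS = ("orphan", "unstable", "instability")


@dataclass
class PipelineConfig:
    """Run-wide configuration; serialises to/from a flat YAML file."""

    outdir: str = "repstab_out"
    seed: int = 0
    genomes_dir: str | None = None          # defaults to <outdir>/genomes
    sample_sheet: str | None = None
    expression: str | None = None
    methylation: str | None = None
    pathways: str | None = None
    detection: dict = field(default_factory=dict)   # DetectionParams overrides
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    max_shift: int = 50
    unstable_min_delta: float = 1.0
    identify_revcomp: bool = False
    qc_max_unaligned: float = 0.10
    msi_family_size: int = 4
    pathway_region: str = "promoter"
    n_synthetic_pathways: int = 5
    log_level: str = "INFO"

    def detection_params(self) -> DetectionParams:
        return DetectionParams(**self.detection)

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        return SimulationConfig(**sim)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return io.config_hash(self.to_dict())

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    # resolved paths -----------------------------------------------------
    def path(self, name: str) -> Path:
        return Path(self.outdir) / name

    def resolved_genomes_dir(self) -> Path:
        return Path(self.genomes_dir) if self.genomes_dir else self.path("genomes")

    def _resolve(self, explicit: str | None, default_name: str,
                 what: str) -> Path:
        p = Path(explicit) if explicit else self.path(default_name)
        if not p.exists():
            raise FileNotFoundError(
                f"{what} not found at {p}; run the upstream stage or point "
                f"the config at an existing file")
        return p

    def _meta(self) -> dict:
        return {"config_hash": self.hash, "seed": self.seed}


def run_simulate(config: PipelineConfig) -> dict:
    """Generate the synthetic cohort: genomes, sample sheet, truth, omics."""
    sim = config.simulation_config()
    detection = config.detection_params()
    log.info("simulating cohort: %d genes x %d patients (seed %d)",
             sim.n_genes, sim.n_patients, sim.seed)
    reference = generate_reference(sim, detection)
    cohort = generate_cohort(reference, detection=detection)
    expression = generate_expression(cohort.truth, sim)
    methylation = generate_methylation(cohort.truth, sim)

    io.write_cohort_fastas(cohort.genomes, config.resolved_genomes_dir())
    io.write_genome_fasta(reference.regions, config.path("reference.fasta"))
    meta = config._meta()
    io.write_tsv(cohort.sample_sheet, config.path("sample_sheet.tsv"), meta)
    io.write_tsv(cohort.truth, config.path("truth.tsv"), meta)
    io.write_tsv(reference.annotation, config.path("reference_annotation.tsv"),
                 meta)
    io.write_tsv(expression.reset_index(), config.path("expression.tsv"), meta)
    io.write_tsv(methylation.reset_index(), config.path("methylation.tsv"), meta)

    # synthetic pathway gene sets: disjoint slices of the gene universe
    genes = reference.events.gene_ids
    k = max(config.n_synthetic_pathways, 1)
    size = max(len(genes) // (2 * k), 1)
    pathways = {f"pathway_{i + 1:02d}": set(genes[i * size:(i + 1) * size])
                for i in range(k)}
    io.write_pathways(pathways, config.path("pathways.tsv"))
    return {"cohort": cohort, "expression": expression,
            "methylation": methylation}


def detect_cohort_repeats(genomes: dict, params: DetectionParams) -> pd.DataFrame:
    """Detect repeats in every genome region, caching by sequence content.

    Matched normal and tumor regions are identical for most genes, so
    detection runs once per distinct sequence.
    """
    cache: dict = {}
    rows = []
    for genome_id in sorted(genomes):
        for (gene, kind), seq in sorted(genomes[genome_id].items()):
            key = hash(seq)
            found = cache.get(key)
            if found is None:
                found = find_tandem_repeats(seq, params)
                cache[key] = found
            for rep in found:
                rows.append({
                    "genome_id": genome_id, "gene_id": gene,
                    "region_kind": kind, "start": rep.start,
                    "length": rep.length, "unit": rep.unit,
                    "period": rep.period, "copy_number": rep.copy_number,
                    "score": rep.score, "identity": rep.identity,
                    "indel_fraction": rep.indel_fraction,
                })
    columns = ["genome_id", "gene_id", "region_kind", "start", "length",
               "unit", "period", "copy_number", "score", "identity",
               "indel_fraction"]
    return pd.DataFrame(rows, columns=columns)


def run_find_repeats(config: PipelineConfig) -> pd.DataFrame:
    """QC the genomes and detect tandem repeats in every region."""
    genomes_dir = config.resolved_genomes_dir()
    if not genomes_dir.exists():
        raise FileNotFoundError(f"genomes directory not found: {genomes_dir}")
    sheet = io.read_sample_sheet(
        config._resolve(config.sample_sheet, "sample_sheet.tsv", "sample sheet"))
    genomes = io.read_cohort_fastas(genomes_dir, sheet.genome_id)
    passing, qc = qc_genomes(genomes, config.qc_max_unaligned)
    if not passing:
        raise RuntimeError("no genome passed QC; nothing to analyse")
    meta = config._meta()
    io.write_tsv(qc, config.path("genome_qc.tsv"), meta)
    genes = sorted({g for regions in genomes.values() for (g, _k) in regions})
    io.write_tsv(pd.DataFrame({"gene_id": genes}), config.path("genes.tsv"),
                 meta)
    repeats = detect_cohort_repeats({g: genomes[g] for g in passing},
                                    config.detection_params())
    io.write_tsv(repeats, config.path("repeats.tsv"), meta)
    log.info("detected %d repeats across %d genomes", len(repeats),
             len(passing))
    return repeats


def _repeats_by_genome(repeats: pd.DataFrame) -> dict:
    """{genome_id: {(gene, kind): [TandemRepeat, ...]}} from the table."""
    from .repeat_finder import TandemRepeat

    out: dict = {}
    for row in repeats.itertuples(index=False):
        rep = TandemRepeat(start=int(row.start), length=int(row.length),
                           unit=row.unit, period=int(row.period),
                           copy_number=float(row.copy_number),
                           score=int(row.score), identity=float(row.identity),
                           indel_fraction=float(row.indel_fraction),
                           gene_id=row.gene_id, region_kind=row.region_kind)
        out.setdefault(row.genome_id, {}).setdefault(
            (row.gene_id, row.region_kind), []).append(rep)
    return out


def run_call_instability(config: PipelineConfig) -> pd.DataFrame:
    """Call per-pair repeat instability for tumor-normal and normal-normal
    pairs; write pair calls and the gene x patient instability matrices."""
    repeats = io.read_tsv(
        config._resolve(None, "repeats.tsv", "repeat calls"))
    sheet = io.read_sample_sheet(
        config._resolve(config.sample_sheet, "sample_sheet.tsv", "sample sheet"))
    qc = io.read_tsv(config._resolve(None, "genome_qc.tsv", "genome QC table"))
    passing = set(qc[qc["pass"]].genome_id)
    by_genome = _repeats_by_genome(repeats)
    for gid in passing:
        by_genome.setdefault(gid, {})

    normals = sorted(g for g in sheet[sheet.tissue == "normal"].genome_id
                     if g in passing)
    tumors = sheet[sheet.tissue == "tumor"].set_index("genome_id")
    patient_of = sheet.set_index("genome_id").patient_id.to_dict()

    kwargs = dict(max_shift=config.max_shift,
                  unstable_min_delta=config.unstable_min_delta,
                  identify_revcomp=config.identify_revcomp)
    frames = []
    flags_by_patient: dict[str, dict] = {}
    for tumor_id in sorted(t for t in tumors.index if t in passing):
        patient = patient_of[tumor_id]
        normal_id = sheet[(sheet.patient_id == patient)
                          & (sheet.tissue == "normal")].genome_id.iloc[0]
        if normal_id not in passing:
            log.info("patient %s skipped: normal genome failed QC", patient)
            continue
        matches, flags = instability.call_pair(
            by_genome[tumor_id], by_genome[normal_id], **kwargs)
        flags_by_patient[patient] = flags
        frames.append(instability.matches_to_frame(
            matches, pair_id=f"TN:{patient}"))
    if not flags_by_patient:
        raise RuntimeError("no QC-passing tumor-normal pair available")

    for ga, gb in enumerate_normal_pairs(normals):
        matches, _flags = instability.call_pair(by_genome[ga], by_genome[gb],
                                                **kwargs)
        frames.append(instability.matches_to_frame(
            matches, pair_id=f"NN:{ga}|{gb}"))

    pair_calls = pd.concat(frames, ignore_index=True) if frames else \
        instability.matches_to_frame([])
    meta = config._meta()
    io.write_tsv(pair_calls, config.path("pair_calls.tsv"), meta)
    for kind in ("promoter", "exon"):
        matrix = instability.build_matrix(flags_by_patient, region_kind=kind)
        io.write_tsv(matrix.reset_index(), config.path(f"matrix_{kind}.tsv"),
                     meta)
    return pair_calls


def _flags_from_calls(calls: pd.DataFrame) -> dict:
    """Rebuild {(gene, kind): GeneInstabilityFlags} from a pair-call table."""
    flags = {}
    for (gene, kind), sub in calls.groupby(["gene_id", "region_kind"],
                                           sort=False):
        orphan = sub.status.str.startswith("orphan")
        unstable = sub.status == "unstable"
        mono = sub.period == 1
        flags[(gene, kind)] = instability.GeneInstabilityFlags(
            gene, kind,
            bool(orphan.any()), bool(unstable.any()),
            bool((orphan & mono).any()), bool((unstable & mono).any()))
    return flags


def _build_profiles(pair_calls, sheet, analyzed_genes, pathways):
    msi_of = sheet.set_index("patient_id").msi.to_dict()
    tumor_profiles, normal_profiles = [], []
    for pair_id, sub in pair_calls.groupby("pair_id", sort=True):
        flags = _flags_from_calls(sub)
        if pair_id.startswith("TN:"):
            patient = pair_id[3:]
            tumor_profiles.append(profile_pair(
                flags, pair_id, "tumor_normal", msi=bool(msi_of[patient]),
                analyzed_genes=analyzed_genes, pathways=pathways))
        else:
            normal_profiles.append(profile_pair(
                flags, pair_id, "normal_normal", msi=None,
                analyzed_genes=analyzed_genes, pathways=pathways))
    return tumor_profiles, normal_profiles


def run_cohort_stats(config: PipelineConfig):
    """Pair profiles plus the cohort-level rank-sum comparisons."""
    pair_calls = io.read_tsv(config._resolve(None, "pair_calls.tsv",
                                             "pair calls"))
    sheet = io.read_sample_sheet(
        config._resolve(config.sample_sheet, "sample_sheet.tsv", "sample sheet"))
    genes = io.read_tsv(config._resolve(None, "genes.tsv",
                                        "gene list")).gene_id.tolist()
    pathways = None
    if config.pathways or config.path("pathways.tsv").exists():
        pathways = io.read_pathways(
            config._resolve(config.pathways, "pathways.tsv", "pathway sets"))

    tumor_profiles, normal_profiles = _build_profiles(pair_calls, sheet,
                                                      genes, pathways)
    if not tumor_profiles or not normal_profiles:
        raise RuntimeError("need both tumor-normal and normal-normal pairs")

    prof_rows = []
    for prof in tumor_profiles + normal_profiles:
        row = {"pair_id": prof.pair_id, "pair_class": prof.pair_class,
               "msi": prof.msi}
        row.update(prof.counts)
        prof_rows.append(row)
    meta = config._meta()
    io.write_tsv(pd.DataFrame(prof_rows), config.path("pair_profiles.tsv"),
                 meta)

    results = []
    for kind in ("promoter", "exon"):
        for event in EVENT_METRICS:
            results.append(compare_cohorts(tumor_profiles, normal_profiles,
                                           f"{kind}_{event}"))
    msi_metrics = ["promoter_instability", "promoter_instability_mono",
                   "exon_instability", "exon_instability_mono"]
    if any(p.msi for p in tumor_profiles) and \
            any(not p.msi for p in tumor_profiles):
        for metric in msi_metrics:
            results.append(compare_msi(tumor_profiles, metric,
                                       family_size=config.msi_family_size))
    else:
        log.warning("MSI comparison skipped: only one MSI class present")
    if pathways:
        results.extend(pathway_enrichment(tumor_profiles, normal_profiles,
                                          sorted(pathways),
                                          region_kind=config.pathway_region))
    table = results_to_frame(results)
    io.write_tsv(table, config.path("cohort_tests.tsv"), meta)
    log.info("wrote %d cohort test results", len(table))
    return table


def run_assoc(config: PipelineConfig):
    """Expression and methylation association with promoter instability."""
    matrix = io.read_matrix(config._resolve(None, "matrix_promoter.tsv",
                                            "instability matrix"))
    # matrix columns are patient ids; omics tables use tumor genome ids
    sheet = io.read_sample_sheet(
        config._resolve(config.sample_sheet, "sample_sheet.tsv", "sample sheet"))
    tumor_of = (sheet[sheet.tissue == "tumor"]
                .set_index("patient_id").genome_id.to_dict())
    matrix = matrix.rename(columns=tumor_of)
    expression = io.read_omics_table(
        config._resolve(config.expression, "expression.tsv",
                        "expression table"))
    methylation_path = (Path(config.methylation) if config.methylation
                        else config.path("methylation.tsv"))
    pathways = None
    if config.pathways or config.path("pathways.tsv").exists():
        pathways = io.read_pathways(
            config._resolve(config.pathways, "pathways.tsv", "pathway sets"))

    results = [expression_association(matrix, expression)]
    if pathways:
        m = len(pathways)
        for name in sorted(pathways):
            results.append(expression_association(
                matrix, expression, scope=f"pathway:{name}",
                gene_set=pathways[name], family_size=m))
    if methylation_path.exists():
        methylation = io.read_omics_table(methylation_path)
        results.append(methylation_association(matrix, methylation))
    table = associations_to_frame(results)
    io.write_tsv(table, config.path("assoc.tsv"), config._meta())
    return table


def run_all(config: PipelineConfig):
    """Full pipeline: simulate -> detect -> call -> cohort stats -> assoc."""
    run_simulate(config)
    run_find_repeats(config)
    run_call_instability(config)
    stats = run_cohort_stats(config)
    assoc = run_assoc(config)
    summary = {"cohort_tests": len(stats), "associations": len(assoc)}
    log.info("pipeline complete: %s", summary)
    return summary
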