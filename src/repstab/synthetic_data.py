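"""Synthetic paired tumor/normal cohorts with planted tandem repeats.

The generator emulates the study design this package analyses: each of
``n_genes`` genes has a promoter and an exon "super-transcript" region; a
configurable fraction of regions carries one perfect planted tandem repeat.
Every patient receives a germline (patient-private) genome derived from the
reference by replication-slippage copy-number changes at half the
normal-normal rate, and a tumor genome derived from that germline genome by
somatic copy-number changes (rate multiplied for MSI-flagged patients),
de-novo repeat gains, and repeat losses.  Gene expression (rpkm) and
promoter methylation (beta) tables are coupled to promoter instability.

Event draws are separated from sequence realisation: ``simulate_event_cohort``
returns the event-level truth only (fast path for power/calibration
studies), while ``generate_reference`` / ``generate_cohort`` additionally
render sequences.  Both consume the same event draw, and background
rejection sampling redraws only background nucleotides, never events, so
event rates are exactly the configured ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .repeat_finder import DetectionParams, canonical_unit, find_tandem_repeats

REGION_KINDS = ("promoter", "exon")

_EVENT_NONE, _EVENT_CC, _EVENT_GAIN, _EVENT_LOSS = 0, 1, 2, 3
_EVENT_NAMES = np.array(["none", "copy_change", "gain", "loss"])


def _default_unit_weights() -> dict[int, float]:
    # microsatellite-like unit spectrum, 30 % mononucleotide
    return {1: 0.30, 2: 0.25, 3: 0.20, 4: 0.10, 5: 0.10, 6: 0.05}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Probabilities are per locus (planted repeat) or per region (gains);
    ``p_slippage_normal`` is the rate at which two unrelated germline
    genomes differ at a repeat locus, so each genome receives private
    slippage at half that rate.  ``msi_rate_multiplier`` scales the somatic
    slippage rate for MSI-flagged patients.  ``expr_effect_log2`` shifts
    log2 expression for (gene, tumor) combinations whose promoter shows
    repeat instability; ``meth_effect_delta`` shifts the methylation beta
    the same way.
    """

    n_genes: int = 200
    n_patients: int = 35
    promoter_length: int = 5000
    exon_length_range: tuple[int, int] = (500, 2000)
    frac_genes_with_promoter_repeat: float = 0.5
    frac_genes_with_exon_repeat: float = 0.3
    unit_length_weights: dict[int, float] = field(default_factory=_default_unit_weights)
    copy_number_range: tuple[int, int] = (3, 15)
    p_slippage_normal: float = 0.016
    p_slippage_tumor: float = 0.08
    msi_rate_multiplier: float = 10.0
    p_gain: float = 0.05
    p_loss: float = 0.05
    expr_base_log2_mean: float = 5.0
    expr_base_log2_sd: float = 0.8
    expr_effect_log2: float = -1.0
    meth_base_beta: float = 0.3
    meth_noise_sd: float = 0.05
    meth_effect_delta: float = 0.1
    n_msi_patients: int = 4
    min_detectable_length: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_patients < 1:
            raise ValueError("n_genes and n_patients must be positive")
        if self.n_msi_patients > self.n_patients:
            raise ValueError("n_msi_patients exceeds n_patients")
        if self.promoter_length <= 0:
            raise ValueError("promoter_length must be positive")
        for name in ("frac_genes_with_promoter_repeat", "frac_genes_with_exon_repeat",
                     "p_slippage_normal", "p_slippage_tumor", "p_gain", "p_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.msi_rate_multiplier < 1.0:
            raise ValueError("msi_rate_multiplier must be >= 1")
        if not 0.0 <= self.meth_base_beta <= 1.0:
            raise ValueError("meth_base_beta must be in [0, 1]")
        if not all(1 <= u <= 100 for u in self.unit_length_weights):
            raise ValueError("unit lengths must be in 1..100")
        if min(self.copy_number_range) < 1:
            raise ValueError("copy numbers must be >= 1")
        p_cc_msi = min(1.0, self.p_slippage_tumor * self.msi_rate_multiplier)
        if p_cc_msi + self.p_gain + self.p_loss > 1.0 + 1e-12:
            raise ValueError("somatic event probabilities exceed 1 for MSI patients")

    def somatic_cc_rate(self, msi: bool) -> float:
        rate = self.p_slippage_tumor * (self.msi_rate_multiplier if msi else 1.0)
        return min(1.0, rate)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, n)].tobytes().decode()


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def _draw_unit(rng: np.random.Generator, length: int, forbid: set[str]) -> str:
    """Random primitive unit whose canonical rotation is not in ``forbid``."""
    for _ in range(200):
        u = _rand_seq(rng, length)
        if _is_primitive(u) and canonical_unit(u) not in forbid:
            return u
    raise RuntimeError("could not draw a distinct primitive unit")


def _min_copies(unit_len: int, min_len: int) -> int:
    """Copies needed to stay detectable with one unit of headroom."""
    return max(2, -(-min_len // unit_len) + 1)


def _clamped_delta(rng: np.random.Generator, copies: int, unit_len: int,
                   min_len: int) -> int:
    """+-k whole units, k geometric (p=0.5); sign flipped to + when a loss
    of k units would make the array shrink below detectability."""
    k = int(rng.geometric(0.5))
    sign = -1 if rng.random() < 0.5 else 1
    if sign < 0 and (copies - k) < _min_copies(unit_len, min_len):
        sign = 1
    return sign * k


@dataclass
class EventTable:
    """Event-level ground truth for one simulated cohort.

    Arrays are indexed per region kind: planted units/copies per gene,
    germline copy-number deltas and somatic event codes per (gene, patient).
    """

    config: SimulationConfig
    patients: list[str]
    msi: np.ndarray  # bool [P]
    unit: dict[str, list[str]]             # "" when no planted repeat
    copies: dict[str, np.ndarray]          # int [G]
    germline_delta: dict[str, np.ndarray]  # int [G, P]
    somatic_code: dict[str, np.ndarray]    # int8 [G, P]
    somatic_delta: dict[str, np.ndarray]   # int [G, P]
    gain_unit: dict[str, dict[tuple[int, int], str]]
    gain_copies: dict[str, dict[tuple[int, int], int]]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.config.n_genes)]

    def unit_lengths(self, kind: str) -> np.ndarray:
        return np.array([len(u) for u in self.unit[kind]])

    # ------------------------------------------------------------------
    # gene-level instability flags, straight from the truth
    def tumor_gene_flags(self, kind: str):
        """Boolean [G, P] arrays (orphan, unstable, mono_orphan, mono_unstable)
        for tumor vs matched-normal comparisons."""
        code = self.somatic_code[kind]
        orphan = (code == _EVENT_GAIN) | (code == _EVENT_LOSS)
        unstable = code == _EVENT_CC
        ulen = self.unit_lengths(kind)[:, None]
        mono_unstable = unstable & (ulen == 1)
        gain_mono = np.zeros_like(orphan)
        for (g, p), u in self.gain_unit[kind].items():
            if len(u) == 1:
                gain_mono[g, p] = True
        mono_orphan = ((code == _EVENT_LOSS) & (ulen == 1)) | gain_mono
        return orphan, unstable, mono_orphan, mono_unstable

    def normal_gene_flags(self, kind: str):
        """Boolean [G, n_pairs] unstable flags for all unordered normal
        pairs (germline deltas differ); plus the pair index list."""
        delta = self.germline_delta[kind]
        pairs = list(combinations(range(self.config.n_patients), 2))
        i = np.array([a for a, _ in pairs])
        j = np.array([b for _, b in pairs])
        unstable = delta[:, i] != delta[:, j]
        has_repeat = np.array([bool(u) for u in self.unit[kind]])[:, None]
        return unstable & has_repeat, pairs

    def mono_normal_gene_flags(self, kind: str):
        flags, pairs = self.normal_gene_flags(kind)
        mono = (self.unit_lengths(kind) == 1)[:, None]
        return flags & mono, pairs

    def promoter_instability_matrix(self) -> pd.DataFrame:
        """Gene x tumor boolean matrix of promoter instability (the input
        to expression/methylation association)."""
        code = self.somatic_code["promoter"]
        cols = [f"{p}_T" for p in self.patients]
        return pd.DataFrame(code != _EVENT_NONE, index=self.gene_ids, columns=cols)

    def to_frame(self) -> pd.DataFrame:
        """Tidy truth table: one row per (gene, patient, region_kind)."""
        rows = []
        for kind in REGION_KINDS:
            code = self.somatic_code[kind]
            gdelta = self.germline_delta[kind]
            sdelta = self.somatic_delta[kind]
            promoter_inst = self.somatic_code["promoter"] != _EVENT_NONE
            for g, gene in enumerate(self.gene_ids):
                for p, patient in enumerate(self.patients):
                    gu = self.gain_unit[kind].get((g, p), "")
                    rows.append({
                        "gene_id": gene,
                        "patient_id": patient,
                        "region_kind": kind,
                        "planted_unit": self.unit[kind][g],
                        "ref_copies": int(self.copies[kind][g]),
                        "germline_delta": int(gdelta[g, p]),
                        "event": _EVENT_NAMES[code[g, p]],
                        "somatic_delta": int(sdelta[g, p]),
                        "gain_unit": gu,
                        "gain_copies": int(self.gain_copies[kind].get((g, p), 0)),
                        "expr_effect_applied": bool(
                            promoter_inst[g, p]
                            and self.config.expr_effect_log2 != 0.0),
                    })
        return pd.DataFrame(rows)


def _draw_events(config: SimulationConfig) -> EventTable:
    rng = np.random.default_rng([config.seed, 101])
    G, P = config.n_genes, config.n_patients
    patients = [f"P{i:03d}" for i in range(P)]
    msi = np.zeros(P, dtype=bool)
    msi[rng.choice(P, config.n_msi_patients, replace=False)] = True

    u_lens = np.array(sorted(config.unit_length_weights))
    u_w = np.array([config.unit_length_weights[k] for k in u_lens], dtype=float)
    u_w = u_w / u_w.sum()
    lo, hi = config.copy_number_range
    min_len = config.min_detectable_length

    unit: dict[str, list[str]] = {}
    copies: dict[str, np.ndarray] = {}
    germ: dict[str, np.ndarray] = {}
    code: dict[str, np.ndarray] = {}
    sdelta: dict[str, np.ndarray] = {}
    gunit: dict[str, dict] = {}
    gcopies: dict[str, dict] = {}

    fracs = {"promoter": config.frac_genes_with_promoter_repeat,
             "exon": config.frac_genes_with_exon_repeat}
    for kind in REGION_KINDS:
        units_k: list[str] = []
        copies_k = np.zeros(G, dtype=np.int64)
        for g in range(G):
            if rng.random() < fracs[kind]:
                ul = int(rng.choice(u_lens, p=u_w))
                u = _draw_unit(rng, ul, forbid=set())
                c = int(rng.integers(lo, hi + 1))
                c = max(c, _min_copies(ul, min_len) + 1)
                units_k.append(u)
                copies_k[g] = c
            else:
                units_k.append("")
        unit[kind] = units_k
        copies[kind] = copies_k

        # patient-private germline slippage at half the normal-normal rate
        germ_k = np.zeros((G, P), dtype=np.int64)
        for g in range(G):
            if not units_k[g]:
                continue
            ul = len(units_k[g])
            hits = rng.random(P) < config.p_slippage_normal / 2.0
            for p in np.flatnonzero(hits):
                germ_k[g, p] = _clamped_delta(rng, int(copies_k[g]), ul, min_len)
        germ[kind] = germ_k

        # somatic events: mutually exclusive categorical draw per locus
        code_k = np.zeros((G, P), dtype=np.int8)
        sdelta_k = np.zeros((G, P), dtype=np.int64)
        gunit_k: dict = {}
        gcopies_k: dict = {}
        for g in range(G):
            planted = bool(units_k[g])
            ul = len(units_k[g]) if planted else 0
            forbid = {canonical_unit(units_k[g])} if planted else set()
            draws = rng.random(P)
            for p in range(P):
                p_cc = config.somatic_cc_rate(bool(msi[p])) if planted else 0.0
                p_loss = config.p_loss if planted else 0.0
                x = draws[p]
                if planted and x < p_cc:
                    code_k[g, p] = _EVENT_CC
                    base = int(copies_k[g] + germ_k[g, p])
                    sdelta_k[g, p] = _clamped_delta(rng, base, ul, min_len)
                elif planted and x < p_cc + p_loss:
                    code_k[g, p] = _EVENT_LOSS
                elif x < p_cc + p_loss + config.p_gain:
                    code_k[g, p] = _EVENT_GAIN
                    ngl = int(rng.choice(u_lens, p=u_w))
                    gu = _draw_unit(rng, ngl, forbid=forbid)
                    gc = max(int(rng.integers(lo, hi + 1)),
                             _min_copies(ngl, min_len) + 1)
                    gunit_k[(g, p)] = gu
                    gcopies_k[(g, p)] = gc
        code[kind] = code_k
        sdelta[kind] = sdelta_k
        gunit[kind] = gunit_k
        gcopies[kind] = gcopies_k

    return EventTable(config=config, patients=patients, msi=msi, unit=unit,
                      copies=copies, germline_delta=germ, somatic_code=code,
                      somatic_delta=sdelta, gain_unit=gunit, gain_copies=gcopies)


def simulate_event_cohort(config: SimulationConfig) -> EventTable:
    """Draw the event-level cohort truth without rendering sequences."""
    return _draw_events(config)


# ----------------------------------------------------------------------
# sequence rendering


@dataclass
class ReferenceSet:
    """Reference region sequences plus the planted-repeat annotation."""

    config: SimulationConfig
    events: EventTable
    regions: dict[tuple[str, str], str]           # (gene_id, kind) -> sequence
    repeat_start: dict[tuple[str, str], int]      # planted repeat offset

    @property
    def annotation(self) -> pd.DataFrame:
        rows = []
        for (gene, kind), seq in self.regions.items():
            rows.append({"gene_id": gene, "region_kind": kind,
                         "length": len(seq),
                         "planted_unit": dict(zip(self.events.gene_ids,
                                                  self.events.unit[kind]))[gene],
                         "planted_start": self.repeat_start.get((gene, kind), -1)})
        return pd.DataFrame(rows)


_EDGE_MARGIN = 20


def _validated_region(rng, length, inserts, detect, max_tries=80):
    """Random background with ``inserts`` = [(start, array), ...] spliced in,
    redrawn until detection reports exactly the planted arrays.

    ``inserts`` starts are positions in the final sequence; arrays must be
    non-overlapping and sorted.  Returns the sequence.
    """
    exp_units = [canonical_unit(ins[1]) for ins in inserts]
    for _ in range(max_tries):
        parts = []
        cursor = 0
        for start, unit, ulen, total in inserts:
            parts.append(_rand_seq(rng, start - cursor))
            parts.append((unit * (total // ulen + 1))[:total])
            cursor = start + total
        parts.append(_rand_seq(rng, length - cursor))
        seq = "".join(parts)
        found = find_tandem_repeats(seq, detect)
        if len(found) != len(inserts):
            continue
        ok = True
        for rep, (start, unit, ulen, total), cu in zip(
                found, inserts, exp_units):
            if rep.unit != cu or rep.start > start or rep.end < start + total:
                ok = False
                break
        if ok:
            return seq
    raise RuntimeError("background rejection sampling failed to converge")


def generate_reference(config: SimulationConfig,
                       detection: DetectionParams | None = None) -> ReferenceSet:
    """Render reference promoter/exon regions with planted repeats.

    Each planted repeat is embedded at a random offset in i.i.d. uniform
    background; backgrounds are rejection-sampled so the only detectable
    repeat in each region is the planted one.
    """
    detection = detection or DetectionParams()
    events = _draw_events(config)
    rng = np.random.default_rng([config.seed, 202])
    regions: dict[tuple[str, str], str] = {}
    repeat_start: dict[tuple[str, str], int] = {}
    exon_lo, exon_hi = config.exon_length_range
    for kind in REGION_KINDS:
        for g, gene in enumerate(events.gene_ids):
            length = (config.promoter_length if kind == "promoter"
                      else int(rng.integers(exon_lo, exon_hi + 1)))
            u = events.unit[kind][g]
            inserts = []
            if u:
                total = len(u) * int(events.copies[kind][g])
                if total > length - 2 * _EDGE_MARGIN:
                    raise ValueError(
                        f"planted repeat ({total} bp) cannot fit in {kind} "
                        f"region of {length} bp")
                start = int(rng.integers(_EDGE_MARGIN,
                                         length - total - _EDGE_MARGIN + 1))
                inserts = [(start, u, len(u), total)]
                repeat_start[(gene, kind)] = start
            regions[(gene, kind)] = _validated_region(rng, length, inserts,
                                                      detection)
    return ReferenceSet(config=config, events=events, regions=regions,
                        repeat_start=repeat_start)


@dataclass
class Cohort:
    """Rendered genomes of a simulated cohort plus sample sheet and truth."""

    reference: ReferenceSet
    genomes: dict[str, dict[tuple[str, str], str]]
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame

    @property
    def config(self) -> SimulationConfig:
        return self.reference.config


def _with_copies(seq: str, start: int, unit: str, old_total: int,
                 new_copies: int) -> str:
    """Replace the planted array with ``new_copies`` perfect units."""
    arr = unit * new_copies
    return seq[:start] + arr + seq[start + old_total:]


def _place_gain(rng, seq, avoid, unit, total, detect, expected, max_tries=80):
    """Insert a de-novo array at a random offset outside ``avoid``; the
    result must carry exactly the expected detections."""
    n = len(seq)
    for _ in range(max_tries):
        start = int(rng.integers(_EDGE_MARGIN, n - total - _EDGE_MARGIN + 1))
        if avoid is not None:
            a_lo, a_hi = avoid
            if start < a_hi + 10 and start + total > a_lo - 10:
                continue
        out = seq[:start] + unit * (total // len(unit)) + seq[start + total:]
        found = find_tandem_repeats(out, detect)
        if sorted(r.unit for r in found) == sorted(expected):
            return out
    raise RuntimeError("could not place de-novo repeat gain")


def generate_cohort(reference: ReferenceSet,
                    config: SimulationConfig | None = None,
                    detection: DetectionParams | None = None) -> Cohort:
    """Render per-patient normal and tumor genomes from the reference.

    Normal genomes carry the patient-private germline slippage; tumor
    genomes additionally carry somatic copy-number changes, losses
    (planted array replaced by validated background) and gains (validated
    de-novo arrays).  Genome IDs are ``<patient>_N`` / ``<patient>_T``.
    """
    detection = detection or DetectionParams()
    if config is not None and config != reference.config:
        raise ValueError("config does not match the one the reference was built with")
    config = reference.config
    events = reference.events
    rng = np.random.default_rng([config.seed, 303])
    genomes: dict[str, dict[tuple[str, str], str]] = {}
    sheet_rows = []
    for p, patient in enumerate(events.patients):
        normal: dict[tuple[str, str], str] = {}
        tumor: dict[tuple[str, str], str] = {}
        for kind in REGION_KINDS:
            for g, gene in enumerate(events.gene_ids):
                ref_seq = reference.regions[(gene, kind)]
                u = events.unit[kind][g]
                start = reference.repeat_start.get((gene, kind))
                ref_copies = int(events.copies[kind][g])
                gdelta = int(events.germline_delta[kind][g, p])
                n_seq = ref_seq
                germ_copies = ref_copies
                if u and gdelta:
                    germ_copies = ref_copies + gdelta
                    n_seq = _with_copies(ref_seq, start, u,
                                         len(u) * ref_copies, germ_copies)
                normal[(gene, kind)] = n_seq

                ev = int(events.somatic_code[kind][g, p])
                t_seq = n_seq
                if ev == _EVENT_CC:
                    sdelta = int(events.somatic_delta[kind][g, p])
                    t_seq = _with_copies(n_seq, start, u,
                                         len(u) * germ_copies,
                                         germ_copies + sdelta)
                elif ev == _EVENT_LOSS:
                    total = len(u) * germ_copies
                    head, tail = n_seq[:start], n_seq[start + total:]
                    for _ in range(80):
                        cand = head + _rand_seq(rng, total) + tail
                        if not find_tandem_repeats(cand, detection):
                            t_seq = cand
                            break
                    else:
                        raise RuntimeError("loss replacement failed to converge")
                elif ev == _EVENT_GAIN:
                    gu = events.gain_unit[kind][(g, p)]
                    gtotal = len(gu) * events.gain_copies[kind][(g, p)]
                    avoid = None
                    expected = [canonical_unit(gu)]
                    if u:
                        avoid = (start, start + len(u) * germ_copies)
                        expected.append(canonical_unit(u))
                    t_seq = _place_gain(rng, n_seq, avoid, gu, gtotal,
                                        detection, expected)
                tumor[(gene, kind)] = t_seq
        genomes[f"{patient}_N"] = normal
        genomes[f"{patient}_T"] = tumor
        msi_flag = bool(events.msi[p])
        sheet_rows.append({"genome_id": f"{patient}_N", "patient_id": patient,
                           "tissue": "normal", "msi": msi_flag})
        sheet_rows.append({"genome_id": f"{patient}_T", "patient_id": patient,
                           "tissue": "tumor", "msi": msi_flag})
    sheet = pd.DataFrame(sheet_rows, columns=["genome_id", "patient_id",
                                              "tissue", "msi"])
    return Cohort(reference=reference, genomes=genomes, sample_sheet=sheet,
                  truth=events.to_frame())


# ----------------------------------------------------------------------
# coupled omics tables


def _instability_flags(truth) -> pd.DataFrame:
    """Gene x patient boolean promoter-instability flags from a truth table
    (tidy DataFrame) or an EventTable."""
    if isinstance(truth, EventTable):
        return pd.DataFrame(truth.somatic_code["promoter"] != _EVENT_NONE,
                            index=truth.gene_ids, columns=truth.patients)
    prom = truth[truth.region_kind == "promoter"]
    flags = (prom.assign(flag=prom.event != "none")
             .pivot_table(index="gene_id", columns="patient_id", values="flag",
                          aggfunc="any"))
    return flags.astype(bool)


def generate_expression(truth, config: SimulationConfig) -> pd.DataFrame:
    """Expression table (genes x tumor genomes, rpkm).

    Baseline log2 levels are N(expr_base_log2_mean, expr_base_log2_sd) per
    (gene, tumor); promoter-instability combinations are shifted by
    ``expr_effect_log2`` before exponentiation, so values are positive.
    """
    rng = np.random.default_rng([config.seed, 404])
    flags = _instability_flags(truth)
    log2 = rng.normal(config.expr_base_log2_mean, config.expr_base_log2_sd,
                      size=flags.shape)
    log2 = log2 + config.expr_effect_log2 * flags.to_numpy()
    table = pd.DataFrame(np.exp2(log2), index=flags.index,
                         columns=[f"{p}_T" for p in flags.columns])
    table.index.name = "gene_id"
    return table


def generate_methylation(truth, config: SimulationConfig) -> pd.DataFrame:
    """Promoter methylation table (genes x tumor genomes, beta in [0, 1])."""
    rng = np.random.default_rng([config.seed, 505])
    flags = _instability_flags(truth)
    beta = rng.normal(config.meth_base_beta, config.meth_noise_sd,
                      size=flags.shape)
    beta = beta + config.meth_effect_delta * flags.to_numpy()
    table = pd.DataFrame(np.clip(beta, 0.0, 1.0), index=flags.index,
                         columns=[f"{p}_T" for p in flags.columns])
    table.index.name = "gene_id"
    return table
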