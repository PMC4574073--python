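"""Validation studies: oracle equivalence, truth recovery, power, calibration.

These routines exercise the package end-to-end on its own synthetic data
and are shared by the test suite and the acceptance script.  All randomness
is controlled by explicit seeds.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .bruteforce import brute_force_repeats
from .cohort_stats import rank_sum_test
from .instability import call_pair
from .omics_assoc import (
    expression_association,
    gene_group_means,
    methylation_association,
)
from .pipeline import detect_cohort_repeats
from .repeat_finder import DetectionParams, find_tandem_repeats
from .synthetic_data import (
    Cohort,
    SimulationConfig,
    generate_cohort,
    generate_expression,
    generate_methylation,
    generate_reference,
    simulate_event_cohort,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_test_sequences(n_sequences: int, seed: int,
                          min_len: int = 60, max_len: int = 500,
                          planted_fraction: float = 0.65) -> list[str]:
    """Random DNA sequences, a fraction carrying one planted repeat array
    (unit 1-7 bp, 40+ bp, with 0-2 substitutions and 0-1 indels)."""
    rng = np.random.default_rng(seed)

    def rand_seq(k):
        return _BASES[rng.integers(0, 4, k)].tobytes().decode()

    out = []
    for i in range(n_sequences):
        n = int(rng.integers(min_len, max_len + 1))
        seq = rand_seq(n)
        if rng.random() < planted_fraction:
            p = int(rng.integers(1, 8))
            copies = max(2, -(-44 // p)) + int(rng.integers(0, 4))
            arr = list(rand_seq(p) * copies)
            for _ in range(int(rng.integers(0, 3))):  # substitutions
                arr[int(rng.integers(len(arr)))] = rand_seq(1)
            if rng.random() < 0.5 and len(arr) > 42:  # one indel
                j = int(rng.integers(len(arr)))
                if rng.random() < 0.5:
                    del arr[j]
                else:
                    arr.insert(j, rand_seq(1))
            pos = int(rng.integers(0, n - 10))
            seq = seq[:pos] + "".join(arr) + seq[pos:]
        out.append(seq)
    return out


def detector_oracle_agreement(n_sequences: int = 1000, seed: int = 0,
                              max_period: int = 10,
                              params: DetectionParams | None = None) -> dict:
    """Fraction of random sequences where the seeded detector equals the
    exhaustive brute-force search under identical thresholds."""
    params = params or DetectionParams(max_unit_length=max_period)
    agree = 0
    for seq in random_test_sequences(n_sequences, seed):
        det = find_tandem_repeats(seq, params, max_period=max_period)
        orc = brute_force_repeats(seq, params, max_period=max_period)
        agree += det == orc
    return {"n": n_sequences, "agree": agree,
            "agreement": agree / n_sequences}


_EVENT_OF_STATUS = {"unstable": "copy_change", "orphan_a": "gain",
                    "orphan_b": "loss"}


def truth_recovery(config: SimulationConfig,
                   detection: DetectionParams | None = None,
                   max_shift: int = 50, unstable_min_delta: float = 1.0,
                   cohort: Cohort | None = None) -> dict:
    """Precision/recall of gain/loss/copy-change calls against the truth.

    Renders the cohort, detects repeats in every genome, calls each
    tumor-vs-matched-normal pair and compares the called events with the
    generator's ground truth at (gene, patient, region, event) granularity.
    """
    detection = detection or DetectionParams()
    if cohort is None:
        reference = generate_reference(config, detection)
        cohort = generate_cohort(reference, detection=detection)
    repeats = detect_cohort_repeats(cohort.genomes, detection)
    by_genome: dict = {g: {} for g in cohort.genomes}
    for row in repeats.itertuples(index=False):
        from .repeat_finder import TandemRepeat

        rep = TandemRepeat(start=int(row.start), length=int(row.length),
                           unit=row.unit, period=int(row.period),
                           copy_number=float(row.copy_number),
                           score=int(row.score), identity=float(row.identity),
                           indel_fraction=float(row.indel_fraction),
                           gene_id=row.gene_id, region_kind=row.region_kind)
        by_genome[row.genome_id].setdefault(
            (row.gene_id, row.region_kind), []).append(rep)

    truth = cohort.truth
    tp = fp = fn = 0
    for patient, sub in truth.groupby("patient_id"):
        matches, _ = call_pair(by_genome[f"{patient}_T"],
                               by_genome[f"{patient}_N"],
                               max_shift=max_shift,
                               unstable_min_delta=unstable_min_delta)
        predicted: dict[tuple, set] = {}
        for m in matches:
            event = _EVENT_OF_STATUS.get(m.status)
            if event:
                predicted.setdefault((m.gene_id, m.region_kind),
                                     set()).add(event)
        for row in sub.itertuples(index=False):
            key = (row.gene_id, row.region_kind)
            pred = predicted.pop(key, set())
            if row.event == "none":
                fp += len(pred)
            elif row.event in pred:
                tp += 1
                fp += len(pred) - 1
            else:
                fn += 1
                fp += len(pred)
        fp += sum(len(v) for v in predicted.values())
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return {"tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall,
            "n_events": tp + fn}


def _promoter_matrix(events):
    matrix = events.promoter_instability_matrix()
    return matrix.loc[matrix.any(axis=1)]


def power_study(config: SimulationConfig, n_replicates: int = 200,
                base_seed: int = 0, alpha: float = 0.05) -> dict:
    """Detection power of the three headline contrasts on event-level
    cohorts: tumor > normal instability (WRS), MSI > MSS (WRS), and
    expression downregulation with instability (WSR, direction + p)."""
    wins_tn = wins_msi = wins_expr = 0
    for rep in range(n_replicates):
        cfg = dataclasses.replace(config, seed=base_seed + rep)
        ev = simulate_event_cohort(cfg)
        orphan, unstable, _, _ = ev.tumor_gene_flags("promoter")
        tumor_counts = (orphan | unstable).sum(axis=0)
        normal_flags, _pairs = ev.normal_gene_flags("promoter")
        normal_counts = normal_flags.sum(axis=0)
        res = rank_sum_test(tumor_counts, normal_counts)
        wins_tn += (res.p_raw < alpha
                    and np.median(tumor_counts) > np.median(normal_counts))
        res = rank_sum_test(tumor_counts[ev.msi], tumor_counts[~ev.msi])
        wins_msi += (res.p_raw < alpha
                     and np.median(tumor_counts[ev.msi])
                     > np.median(tumor_counts[~ev.msi]))
        expr = generate_expression(ev, cfg)
        assoc = expression_association(_promoter_matrix(ev), expr)
        wins_expr += (assoc.direction == "down_in_instability"
                      and assoc.p_raw < alpha)
    return {"n": n_replicates,
            "tumor_gt_normal": wins_tn / n_replicates,
            "msi_gt_mss": wins_msi / n_replicates,
            "expression_down": wins_expr / n_replicates}


def calibration_study(config: SimulationConfig, n_replicates: int = 200,
                      base_seed: int = 0, alpha: float = 0.05) -> dict:
    """Rejection rates of each test under an all-effects-zero generator.

    ``config`` should carry equal tumor/normal slippage, no gains/losses,
    multiplier 1 and zero omics effects.  Besides the study's literal
    contrasts (all-pairs WRS, expression WSR) the rates for statistically
    exchangeable variants (disjoint normal pairs) are reported, because the
    pooled all-pairs design violates the WRS independence assumption and
    the mean-then-log expression scheme is group-size biased; see the
    methods note.
    """
    rej = {"wrs_all_pairs": 0, "wrs_disjoint_pairs": 0, "wrs_msi": 0,
           "wsr_expression": 0, "wsr_methylation": 0}
    for rep in range(n_replicates):
        cfg = dataclasses.replace(config, seed=base_seed + rep)
        ev = simulate_event_cohort(cfg)
        orphan, unstable, _, _ = ev.tumor_gene_flags("promoter")
        tumor_counts = (orphan | unstable).sum(axis=0)
        normal_flags, pairs = ev.normal_gene_flags("promoter")
        all_counts = normal_flags.sum(axis=0)
        rej["wrs_all_pairs"] += rank_sum_test(
            tumor_counts, all_counts).p_raw < alpha
        disjoint = [i for i, (a, b) in enumerate(pairs)
                    if a % 2 == 0 and b == a + 1]
        rej["wrs_disjoint_pairs"] += rank_sum_test(
            tumor_counts, normal_flags[:, disjoint].sum(axis=0)).p_raw < alpha
        rej["wrs_msi"] += rank_sum_test(
            tumor_counts[ev.msi], tumor_counts[~ev.msi]).p_raw < alpha
        matrix = _promoter_matrix(ev)
        expr = generate_expression(ev, cfg)
        rej["wsr_expression"] += expression_association(
            matrix, expr).p_raw < alpha
        meth = generate_methylation(ev, cfg)
        rej["wsr_methylation"] += methylation_association(
            matrix, meth).p_raw < alpha
    return {"n": n_replicates,
            **{k: v / n_replicates for k, v in rej.items()}}


def null_config(config: SimulationConfig) -> SimulationConfig:
    """All-effects-zero version of a simulation configuration."""
    return dataclasses.replace(
        config, p_slippage_tumor=config.p_slippage_normal,
        msi_rate_multiplier=1.0, p_gain=0.0, p_loss=0.0,
        expr_effect_log2=0.0, meth_effect_delta=0.0)


def effect_recovery(config: SimulationConfig, seed: int = 0) -> dict:
    """Recover the planted expression/methylation effects as mean per-gene
    group differences on one event-level cohort."""
    cfg = dataclasses.replace(config, seed=seed)
    ev = simulate_event_cohort(cfg)
    matrix = _promoter_matrix(ev)
    expr = generate_expression(ev, cfg)
    meth = generate_methylation(ev, cfg)
    ge = gene_group_means(matrix, expr)
    gm = gene_group_means(matrix, meth)
    expr_hat = float(np.mean([g.log2_mean_instability - g.log2_mean_other
                              for g in ge]))
    meth_hat = float(np.mean([g.mean_instability - g.mean_other
                              for g in gm]))
    return {"expr_effect_log2_hat": expr_hat,
            "meth_effect_delta_hat": meth_hat,
            "n_genes_expr": len(ge), "n_genes_meth": len(gm)}
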