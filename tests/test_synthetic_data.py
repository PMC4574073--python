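"""Tests of the synthetic cohort generator and its ground truth."""

import numpy as np
import pytest
from scipy import stats

from repstab.repeat_finder import find_tandem_repeats
from repstab.synthetic_data import (
    SimulationConfig,
    generate_cohort,
    generate_expression,
    generate_methylation,
    generate_reference,
    simulate_event_cohort,
)


def _tiny(**kw):
    base = dict(n_genes=8, n_patients=3, promoter_length=300,
                exon_length_range=(200, 260), n_msi_patients=1, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_msi_exceeds_patients(self):
        with pytest.raises(ValueError):
            _tiny(n_msi_patients=5)

    def test_beta_out_of_range(self):
        with pytest.raises(ValueError):
            _tiny(meth_base_beta=1.4)

    def test_repeat_cannot_fit(self, detect20):
        cfg = _tiny(promoter_length=60, frac_genes_with_promoter_repeat=1.0)
        with pytest.raises(ValueError, match="cannot fit"):
            generate_reference(cfg, detect20)

    def test_msi_multiplier_below_one(self):
        with pytest.raises(ValueError):
            _tiny(msi_rate_multiplier=0.5)


class TestReference:
    def test_fraction_one_plants_all(self, detect20):
        cfg = _tiny(frac_genes_with_promoter_repeat=1.0,
                    frac_genes_with_exon_repeat=0.0, n_genes=10)
        ref = generate_reference(cfg, detect20)
        planted = [u for u in ref.events.unit["promoter"] if u]
        assert len(planted) == 10
        assert all(u == "" for u in ref.events.unit["exon"])
        # every promoter contains exactly the planted repeat, detectably
        for g, gene in enumerate(ref.events.gene_ids):
            found = find_tandem_repeats(ref.regions[(gene, "promoter")],
                                        detect20)
            assert len(found) == 1

    def test_fraction_zero_plants_none(self, detect20):
        cfg = _tiny(frac_genes_with_promoter_repeat=0.0,
                    frac_genes_with_exon_repeat=0.0)
        ref = generate_reference(cfg, detect20)
        assert all(u == "" for kind in ("promoter", "exon")
                   for u in ref.events.unit[kind])

    def test_determinism_byte_identical(self, detect20):
        cfg = _tiny()
        ref1 = generate_reference(cfg, detect20)
        ref2 = generate_reference(cfg, detect20)
        assert ref1.regions == ref2.regions
        coh1 = generate_cohort(ref1, detection=detect20)
        coh2 = generate_cohort(ref2, detection=detect20)
        assert coh1.genomes == coh2.genomes
        assert coh1.truth.equals(coh2.truth)


class TestCohort:
    def test_zero_rates_tumors_identical(self, detect20):
        cfg = _tiny(p_slippage_tumor=0.0, p_gain=0.0, p_loss=0.0,
                    msi_rate_multiplier=1.0)
        coh = generate_cohort(generate_reference(cfg, detect20),
                              detection=detect20)
        for patient in coh.reference.events.patients:
            assert coh.genomes[f"{patient}_T"] == coh.genomes[f"{patient}_N"]
        assert (coh.truth.event == "none").all()

    def test_loss_rate_one_removes_all_planted(self, detect20):
        cfg = _tiny(frac_genes_with_promoter_repeat=1.0,
                    frac_genes_with_exon_repeat=0.0,
                    p_slippage_tumor=0.0, p_gain=0.0, p_loss=1.0,
                    msi_rate_multiplier=1.0, p_slippage_normal=0.0)
        coh = generate_cohort(generate_reference(cfg, detect20),
                              detection=detect20)
        prom = coh.truth[coh.truth.region_kind == "promoter"]
        assert (prom.event == "loss").all()
        for patient in coh.reference.events.patients:
            for gene in coh.reference.events.gene_ids:
                seq = coh.genomes[f"{patient}_T"][(gene, "promoter")]
                assert find_tandem_repeats(seq, detect20) == []

    def test_truth_consistency(self, small_cohort):
        """Every recorded somatic event corresponds to a tumor-vs-normal
        sequence difference, and vice versa."""
        for row in small_cohort.truth.itertuples(index=False):
            key = (row.gene_id, row.region_kind)
            normal = small_cohort.genomes[f"{row.patient_id}_N"][key]
            tumor = small_cohort.genomes[f"{row.patient_id}_T"][key]
            assert (row.event != "none") == (normal != tumor), row

    def test_sample_sheet_schema(self, small_cohort):
        sheet = small_cohort.sample_sheet
        assert list(sheet.columns) == ["genome_id", "patient_id", "tissue",
                                       "msi"]
        assert set(sheet.tissue) == {"tumor", "normal"}
        assert sheet.msi.sum() == 2  # both genomes of the MSI patient


class TestEventRates:
    def test_copy_change_rate_binomial(self):
        """~200 loci at p_slippage_tumor=0.2: event count within the exact
        binomial 99 % interval."""
        cfg = SimulationConfig(n_genes=200, n_patients=1,
                               frac_genes_with_promoter_repeat=1.0,
                               frac_genes_with_exon_repeat=0.0,
                               p_slippage_tumor=0.2, p_gain=0.0, p_loss=0.0,
                               msi_rate_multiplier=1.0, n_msi_patients=0,
                               seed=7)
        ev = simulate_event_cohort(cfg)
        n_cc = int((ev.somatic_code["promoter"] == 1).sum())
        lo = stats.binom.ppf(0.005, 200, 0.2)
        hi = stats.binom.ppf(0.995, 200, 0.2)
        assert lo <= n_cc <= hi

    def test_msi_ordering(self):
        cfg = SimulationConfig(n_genes=300, n_patients=10, n_msi_patients=5,
                               frac_genes_with_promoter_repeat=1.0,
                               p_slippage_tumor=0.05, msi_rate_multiplier=10,
                               p_gain=0.0, p_loss=0.0, seed=3)
        ev = simulate_event_cohort(cfg)
        cc = (ev.somatic_code["promoter"] == 1).sum(axis=0)
        assert cc[ev.msi].mean() > cc[~ev.msi].mean()

    def test_normal_pair_divergence_rate(self):
        """Two normals differ at ~p_slippage_normal per planted locus."""
        cfg = SimulationConfig(n_genes=400, n_patients=2, n_msi_patients=0,
                               frac_genes_with_promoter_repeat=1.0,
                               p_slippage_normal=0.1, seed=9)
        ev = simulate_event_cohort(cfg)
        flags, pairs = ev.normal_gene_flags("promoter")
        n_diff = int(flags[:, 0].sum())
        lo = stats.binom.ppf(0.001, 400, 0.1 * (1 - 0.05))
        hi = stats.binom.ppf(0.999, 400, 0.1)
        assert lo <= n_diff <= hi


class TestOmicsTables:
    def test_expression_nonnegative_and_effect_direction(self):
        cfg = SimulationConfig(n_genes=150, n_patients=20, seed=11)
        ev = simulate_event_cohort(cfg)
        expr = generate_expression(ev, cfg)
        assert (expr.to_numpy() > 0).all()
        flags = ev.somatic_code["promoter"] != 0
        vals = expr.to_numpy()
        flagged = np.log2(vals[flags])
        unflagged = np.log2(vals[~flags])
        assert flagged.mean() < unflagged.mean()

    def test_expression_null_no_group_difference(self):
        cfg = SimulationConfig(n_genes=200, n_patients=20,
                               expr_effect_log2=0.0, seed=12)
        ev = simulate_event_cohort(cfg)
        expr = generate_expression(ev, cfg)
        flags = ev.somatic_code["promoter"] != 0
        vals = np.log2(expr.to_numpy())
        t, p = stats.ttest_ind(vals[flags], vals[~flags])
        assert p > 0.01

    def test_methylation_bounds_and_delta(self):
        cfg = SimulationConfig(n_genes=300, n_patients=20,
                               meth_base_beta=0.3, meth_effect_delta=0.2,
                               seed=13)
        ev = simulate_event_cohort(cfg)
        meth = generate_methylation(ev, cfg)
        vals = meth.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()
        flags = ev.somatic_code["promoter"] != 0
        assert vals[flags].mean() == pytest.approx(0.5, abs=0.02)
        assert vals[~flags].mean() == pytest.approx(0.3, abs=0.02)
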