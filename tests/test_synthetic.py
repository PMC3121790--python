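"""Synthetic-data generator: planted truths are recoverable by the pipeline."""

import numpy as np
import pytest

from sdscan.expression import correlate
from sdscan.folding import mfe_energy, unpaired_probability
from sdscan.hybridization import SDClass, call_genes, sd_prevalence
from sdscan.simulate import (
    SyntheticParams,
    generate_construct_panel,
    generate_gene_set,
    simulate_activities,
)


class TestGeneSet:
    def test_full_sd_prevalence_relaxed(self):
        regs, truth = generate_gene_set(
            SyntheticParams(genes_per_genome=40, p_sd=1.0, seed=1)
        )
        assert sd_prevalence(call_genes(regs, scheme="relaxed")) == 1.0
        assert all(t.sd_planted for t in truth.genes.values())
        assert all(4 <= t.sd_spacing <= 9 for t in truth.genes.values())

    def test_scrubbed_genes_are_sd_minus(self):
        regs, _ = generate_gene_set(
            SyntheticParams(genes_per_genome=40, p_sd=0.0, seed=2)
        )
        assert sd_prevalence(call_genes(regs, scheme="relaxed")) == 0.0

    def test_prevalence_tracks_p_sd(self):
        p = 0.6
        regs, _ = generate_gene_set(
            SyntheticParams(genes_per_genome=200, p_sd=p, seed=3)
        )
        got = sd_prevalence(call_genes(regs, scheme="relaxed"))
        assert abs(got - p) <= 3 * np.sqrt(p * (1 - p) / 200)

    def test_unstructured_starts_accessible(self):
        regs, _ = generate_gene_set(
            SyntheticParams(genes_per_genome=25, p_sd=0.0,
                            start_window_mode="unstructured", seed=4)
        )
        acc = [
            unpaired_probability(g.seq, (g.start_codon_pos, g.start_codon_pos + 3)).p_unpaired
            for g in regs
        ]
        assert np.mean(acc) > 0.9

    def test_structured_starts_buried(self):
        regs, truth = generate_gene_set(
            SyntheticParams(genes_per_genome=15, p_sd=1.0,
                            sd_motifs=(("AGGAGG", 1.0),),
                            start_window_mode="structured", seed=5)
        )
        acc = [
            unpaired_probability(g.seq, (g.start_codon_pos, g.start_codon_pos + 3)).p_unpaired
            for g in regs
        ]
        assert np.mean(acc) < 0.1
        assert all(t.planted_hairpin_mfe < -10 for t in truth.genes.values())
        # AGGAGG passes the strict presence threshold
        calls = call_genes(regs, scheme="strict")
        assert all(c.call is SDClass.SD_PLUS for c in calls)

    def test_same_seed_bit_identical(self):
        p = SyntheticParams(genes_per_genome=15, p_sd=0.4,
                            start_window_mode="unstructured", n_internal_augs=1, seed=9)
        a, ta = generate_gene_set(p)
        b, tb = generate_gene_set(p)
        assert a == b and ta == tb

    def test_internal_augs_planted_in_hairpins(self):
        regs, truth = generate_gene_set(
            SyntheticParams(genes_per_genome=10, p_sd=0.0, n_internal_augs=2,
                            internal_aug_frame="in_frame", seed=6)
        )
        for g in regs:
            t = truth.genes[g.gene_id]
            assert len(t.internal_aug_bios) == 2
            for b in t.internal_aug_bios:
                assert b % 3 == 0  # in-frame
                idx = g.start_codon_pos + b
                assert g.seq[idx : idx + 3] == "ATG"
                assert mfe_energy(g.seq[idx - 24 : idx + 26]) < -10

    def test_out_of_frame_planting(self):
        regs, truth = generate_gene_set(
            SyntheticParams(genes_per_genome=5, n_internal_augs=1,
                            internal_aug_frame="out_of_frame", seed=7)
        )
        for g in regs:
            for b in truth.genes[g.gene_id].internal_aug_bios:
                assert b % 3 != 0
                assert g.seq[g.start_codon_pos + b :][:3] == "ATG"

    def test_orfs_are_valid(self):
        regs, _ = generate_gene_set(
            SyntheticParams(genes_per_genome=30, n_internal_augs=1,
                            start_window_mode="structured", seed=8)
        )
        stops = {"TAA", "TAG", "TGA"}
        for g in regs:
            cds = g.cds_seq
            assert cds[:3] == "ATG" and cds[-3:] in stops
            assert not any(cds[i : i + 3] in stops for i in range(3, len(cds) - 3, 3))

    def test_contradictory_params_error(self):
        with pytest.raises(ValueError):
            SyntheticParams(utr_len=20, start_window_width=50)
        with pytest.raises(ValueError):
            SyntheticParams(sd_spacing=(2, 9))


class TestConstructPanel:
    def test_noise_free_panel_perfect_correlation(self):
        p = generate_construct_panel(n_constructs=8, sd_status=False,
                                     sigma=0.0, seed=1, design_iters=1500)
        r = correlate(p.accessibility, p.activities)
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(p.truth.beta)

    def test_sd_panel_flat_within_2se(self, panel_plus):
        r = correlate(panel_plus.accessibility, panel_plus.activities)
        assert abs(r.slope) <= 2 * r.stderr

    def test_accessibility_ladder_spans_half_unit(self, panel_minus):
        acc = panel_minus.accessibility
        assert acc.max() - acc.min() >= 0.5

    def test_draw_activities_reproducible(self, panel_minus):
        a = panel_minus.draw_activities(3)
        b = panel_minus.draw_activities(3)
        assert np.array_equal(a, b)

    def test_activity_model(self):
        rng = np.random.default_rng(0)
        acc = np.array([0.1, 0.5, 0.9])
        flat = simulate_activities(acc, True, 2.0, 0.0, 1.5, rng)
        assert np.allclose(flat, 1.5)
        lin = simulate_activities(acc, False, 2.0, 0.0, 1.5, rng)
        assert np.allclose(lin, 2.0 * acc)

    def test_too_few_constructs_error(self):
        with pytest.raises(ValueError):
            generate_construct_panel(n_constructs=2)
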