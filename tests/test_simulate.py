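"""Generator construction checks: GC/repeat targets, het-site placement,
parthenogenetic inheritance, subclone arithmetic and pileup statistics."""

import numpy as np
import pytest

from regenmut.io import mask_from_intervals
from regenmut.simulate import (PLOIDY, PositionSampler, SimConfig, TruthTable,
                               derive_offspring, derive_regenerant,
                               found_parent, generate_reference,
                               simulate_pileup, stage_rng)


def small_config(**kw):
    defaults = dict(genome_length=200_000, n_scaffolds=2, seed=11,
                    n_invariant_sites=100)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGenerateReference:
    def test_gc_and_repeat_targets(self):
        cfg = SimConfig(genome_length=1_000_000, gc_fraction=0.32,
                        repeat_fraction=0.2, n_scaffolds=2, seed=3)
        genome, mask = generate_reference(cfg)
        gc = sum(s.count("G") + s.count("C")
                 for s in genome.sequences.values()) / genome.total_length
        assert abs(gc - 0.32) < 0.01
        assert abs(mask.total_length / genome.total_length - 0.2) < 0.02

    def test_zero_repeat_fraction_gives_empty_mask(self):
        _, mask = generate_reference(small_config(repeat_fraction=0.0))
        assert mask.total_length == 0

    def test_same_seed_is_deterministic(self):
        g1, m1 = generate_reference(small_config())
        g2, m2 = generate_reference(small_config())
        assert g1.sequences == g2.sequences
        assert m1.intervals == m2.intervals

    def test_dominating_repeat_fraction_rejected(self):
        with pytest.raises(ValueError, match="repeat_fraction"):
            generate_reference(small_config(repeat_fraction=0.95))

    def test_tiny_genome_rejected(self):
        with pytest.raises(ValueError, match="10 kb"):
            generate_reference(SimConfig(genome_length=5000, n_scaffolds=1))


class TestFoundParent:
    def test_site_count_matches_density(self):
        cfg = SimConfig(genome_length=1_000_000, n_scaffolds=2,
                        het_site_density=1 / 5000, seed=5)
        genome, _ = generate_reference(cfg)
        truth = TruthTable()
        parent = found_parent(genome, cfg, truth=truth)
        assert len(truth) == 200
        assert len(parent.occupied_positions()) == 200

    def test_single_haplotype_setting_gives_one_third_fractions(self):
        cfg = small_config(two_hap_fraction=0.0)
        genome, _ = generate_reference(cfg)
        parent = found_parent(genome, cfg)
        for h_idx, hap in enumerate(parent.haplotypes):
            for (scaf, pos0), var in hap.items():
                assert parent.site_fraction(scaf, pos0, var.alt) \
                    == pytest.approx(1 / 3)

    def test_haplotype_index_recorded_in_truth(self):
        cfg = small_config()
        genome, _ = generate_reference(cfg)
        truth = TruthTable()
        found_parent(genome, cfg, truth=truth)
        assert all(r.detail.startswith("hap") for r in truth.records)


class TestDeriveOffspring:
    @pytest.fixture
    def setting(self):
        cfg = small_config()
        genome, _ = generate_reference(cfg)
        parent = found_parent(genome, cfg)
        mask = mask_from_intervals({"scaffold_1": [(10_000, 60_000)]})
        sampler = PositionSampler(genome, mask)
        rng = stage_rng(cfg.seed, "test-offspring")
        return genome, parent, mask, sampler, rng

    def test_planted_snvs_land_inside_mask(self, setting):
        genome, parent, mask, sampler, rng = setting
        truth = TruthTable()
        derive_offspring(parent, "F1", 4, 0, (1 / 6,) * 6, sampler, rng,
                         truth=truth)
        de_novo = truth.with_label("de-novo-clonal")
        assert len(de_novo) == 4
        for rec in de_novo:
            assert mask.contains(rec.variant.scaffold, rec.variant.pos0)
            assert rec.carriers == ("F1",)

    def test_zero_counts_give_identical_genotype(self, setting):
        genome, parent, mask, sampler, rng = setting
        child = derive_offspring(parent, "F1", 0, 0, (1 / 6,) * 6, sampler, rng)
        assert child.haplotypes == parent.haplotypes

    def test_concentrated_spectrum_respected(self, setting):
        genome, parent, mask, sampler, rng = setting
        truth = TruthTable()
        weights = (0, 0, 1.0, 0, 0, 0)  # all C>T
        derive_offspring(parent, "F1", 20, 0, weights, sampler, rng, truth=truth)
        for rec in truth.with_label("de-novo-clonal"):
            v = rec.variant
            assert (v.ref, v.alt) in {("C", "T"), ("G", "A")}

    def test_negative_count_rejected(self, setting):
        genome, parent, mask, sampler, rng = setting
        with pytest.raises(ValueError):
            derive_offspring(parent, "F1", -1, 0, (1 / 6,) * 6, sampler, rng)


class TestDeriveRegenerant:
    @pytest.fixture
    def setting(self):
        cfg = small_config()
        genome, _ = generate_reference(cfg)
        parent = found_parent(genome, cfg)
        return parent, PositionSampler(genome), stage_rng(7, "test-regen")

    def test_subclone_fraction_arithmetic(self, setting):
        parent, sampler, rng = setting
        truth = TruthTable()
        regen = derive_regenerant(parent, "R1", [(0.18, 5)], sampler, rng,
                                  truth=truth)
        recs = truth.with_label("subclonal")
        assert len(recs) == 5
        for rec in recs:
            v = rec.variant
            assert regen.site_fraction(v.scaffold, v.pos0, v.alt) \
                == pytest.approx(0.18 / PLOIDY)

    def test_empty_design_is_identity(self, setting):
        parent, sampler, rng = setting
        regen = derive_regenerant(parent, "R1", [], sampler, rng)
        assert regen.haplotypes == parent.haplotypes
        assert regen.subclones == []

    def test_two_subclones(self, setting):
        parent, sampler, rng = setting
        regen = derive_regenerant(parent, "R1", [(0.09, 3), (0.03, 3)],
                                  sampler, rng)
        fractions = sorted(
            regen.site_fraction(v.scaffold, v.pos0, v.alt)
            for sc in regen.subclones for v in sc.variants
        )
        assert fractions[:3] == pytest.approx([0.01] * 3)
        assert fractions[3:] == pytest.approx([0.03] * 3)

    def test_overfull_design_rejected(self, setting):
        parent, sampler, rng = setting
        with pytest.raises(ValueError, match="sum to > 1"):
            derive_regenerant(parent, "R1", [(0.7, 1), (0.5, 1)], sampler, rng)


class TestSimulatePileup:
    def test_depth_equals_count_sum_everywhere(self):
        cfg = small_config()
        genome, repeat_mask = generate_reference(cfg)
        parent = found_parent(genome, cfg)
        t = simulate_pileup([parent], genome, cfg, repeat_mask=repeat_mask)
        for site in t.sites:
            for cell in site.cells.values():
                cell.validate()  # raises if depth != sum(counts)

    def test_same_seed_identical_tables(self):
        cfg = small_config()
        genome, _ = generate_reference(cfg)
        parent = found_parent(genome, cfg)
        t1 = simulate_pileup([parent], genome, cfg,
                             rng=stage_rng(1, "pile"))
        t2 = simulate_pileup([parent], genome, cfg,
                             rng=stage_rng(1, "pile"))
        for a, b in zip(t1.sites, t2.sites):
            assert a.pos0 == b.pos0
            for s in t1.samples:
                assert a.cells[s].counts == b.cells[s].counts

    def test_clonal_het_mean_af_converges_to_one_third(self):
        """Law of large numbers: >= 1000 single-haplotype het sites at 50x
        average to allele fraction 1/3 within 0.01."""
        cfg = SimConfig(genome_length=6_000_000, n_scaffolds=2,
                        het_site_density=1 / 5000, two_hap_fraction=0.0,
                        n_invariant_sites=0, seed=2)
        genome, _ = generate_reference(cfg)
        truth = TruthTable()
        parent = found_parent(genome, cfg, truth=truth)
        assert len(truth) >= 1000
        t = simulate_pileup([parent], genome, cfg)
        afs = []
        by_pos = {(r.variant.scaffold, r.variant.pos0): r.variant
                  for r in truth.records}
        for site in t.sites:
            var = by_pos[(site.scaffold, site.pos0)]
            cell = site.cells[parent.name]
            if cell.depth:
                afs.append(cell.allele_fraction(var.alt))
        assert abs(np.mean(afs) - 1 / 3) < 0.01

    def test_truth_and_pileup_consistent(self):
        """Every truth variant shows alt reads in carriers far above the
        error baseline of non-carriers."""
        cfg = small_config(n_invariant_sites=0)
        genome, _ = generate_reference(cfg)
        truth = TruthTable()
        parent = found_parent(genome, cfg, truth=truth)
        bystander = parent.clone("B", "parent", "control")
        stranger_vars = TruthTable()
        child = derive_offspring(parent, "F", 10, 0, (1 / 6,) * 6,
                                 PositionSampler(genome),
                                 stage_rng(3, "x"), truth=stranger_vars,
                                 occupied=parent.occupied_positions())
        t = simulate_pileup([parent, bystander, child], genome, cfg)
        for rec in stranger_vars.with_label("de-novo-clonal"):
            site = t.site_at(rec.variant.scaffold, rec.variant.pos0)
            carrier_frac = site.cells["F"].allele_fraction(rec.variant.alt)
            other_frac = site.cells[parent.name].allele_fraction(rec.variant.alt)
            assert carrier_frac > 0.1
            assert other_frac < 0.1

    def test_nonpositive_coverage_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            small_config(coverage_mean=0).validate()

    def test_repeat_sites_get_low_mapping_quality(self):
        cfg = small_config(repeat_fraction=0.3, n_invariant_sites=400)
        genome, repeat_mask = generate_reference(cfg)
        parent = found_parent(genome, cfg)
        t = simulate_pileup([parent], genome, cfg, repeat_mask=repeat_mask)
        inside = [s.cells[parent.name].mean_mq for s in t.sites
                  if repeat_mask.contains(s.scaffold, s.pos0)]
        outside = [s.cells[parent.name].mean_mq for s in t.sites
                   if not repeat_mask.contains(s.scaffold, s.pos0)]
        assert inside and all(10 <= mq <= 35 for mq in inside)
        assert outside and all(mq == 60.0 for mq in outside)
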