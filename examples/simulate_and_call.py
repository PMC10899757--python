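"""Simulate a small parthenogenetic cohort and call unique de novo SNVs.

Builds a 1 Mb triploid reference, founds an isogenic family (one parent,
two offspring with 4 and 7 planted clonal SNVs), samples a ~50x read-count
pileup and runs the threshold caller. The printed per-offspring counts
should match the planted ones: every clonal variant sits near allele
fraction 1/3 with ~16 supporting reads, far above the >= 7-read filter.
"""

from regenmut.burden import kmer_mappability_mask
from regenmut.calling import call_unique
from regenmut.simulate import (PositionSampler, SimConfig, TruthTable,
                               derive_offspring, found_parent,
                               generate_reference, simulate_pileup, stage_rng)

cfg = SimConfig(genome_length=1_000_000, n_scaffolds=2, seed=0,
                n_invariant_sites=500)
genome, repeat_mask = generate_reference(cfg)
mappable = kmer_mappability_mask(genome, k=50)
print(f"reference: {genome.total_length} bp, "
      f"{mappable.total_length} bp uniquely mappable")

truth = TruthTable()
parent = found_parent(genome, cfg, truth=truth)
sampler = PositionSampler(genome, mappable)
rng = stage_rng(cfg.seed, "offspring")
occupied = parent.occupied_positions()
f1 = derive_offspring(parent, "F1", 4, 0, cfg.spectrum_weights_control,
                      sampler, rng, truth=truth, occupied=occupied)
f2 = derive_offspring(parent, "F2", 7, 0, cfg.spectrum_weights_control,
                      sampler, rng, truth=truth, occupied=occupied)

pileup = simulate_pileup([parent, f1, f2], genome, cfg,
                         repeat_mask=repeat_mask)
calls = call_unique(pileup)
for name, planted in (("F1", 4), ("F2", 7)):
    found = [c for c in calls if c.carriers == [name]]
    afs = ", ".join(f"{c.allele_fractions[name]:.2f}" for c in found)
    print(f"{name}: planted {planted}, called {len(found)} (AFs: {afs})")
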