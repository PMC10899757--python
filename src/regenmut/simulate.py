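"""Synthetic triploid genomes, parthenogenetic pedigrees and read-count pileups.

The generator emulates the statistical structure of a triploid parthenogen
sequenced at ~50x: germline heterozygous sites at true allele fractions 1/3
and 2/3, family-private (lineage-specific) variants, per-offspring clonal de
novo SNVs/indels with a controllable 6-channel substitution spectrum,
regenerant subclones at specified cell fractions, and Poisson/binomial
read-count sampling with a per-base sequencing-error rate. Reads themselves
are never simulated: every downstream filter acts on counts, coverage and
mapping quality, all of which live at the pileup level.

Ground truth for every planted variant is recorded in a TruthTable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .calling import (DE_NOVO_CLONAL, GERMLINE_SHARED, LINEAGE_SPECIFIC,
                      SUBCLONAL, SUBSTITUTION_CHANNELS, revcomp)
from .io import Genome, IntervalMask, PileupCell, PileupSite, PileupTable, \
    mask_from_intervals

PLOIDY = 3  # stable triploidy; no tetraploid offspring are simulated

ROLE_PARENT = "parent"
ROLE_REGENERANT = "regenerant"
ROLE_OFFSPRING = "offspring"
GROUP_CONTROL = "control"
GROUP_REGENERATED = "regenerated"


class Variant(NamedTuple):
    scaffold: str
    pos0: int
    ref: str
    alt: str  # base or indel key


@dataclass
class Subclone:
    sid: str
    cell_fraction: float
    variants: List[Variant]


@dataclass
class Individual:
    """A triploid animal: three haplotype variant sets plus optional subclones."""

    name: str
    role: str
    group: str
    haplotypes: List[Dict[Tuple[str, int], Variant]]
    subclones: List[Subclone] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.haplotypes) != PLOIDY:
            raise ValueError("individuals are triploid: exactly 3 haplotypes")
        if sum(s.cell_fraction for s in self.subclones) > 1 + 1e-9:
            raise ValueError("subclone cell fractions exceed 1")

    def clone(self, name: str, role: str, group: str) -> "Individual":
        """Parthenogenetic copy: all three haplotypes, no recombination;
        subclones are not inherited (the germline is the clonal trunk)."""
        return Individual(name=name, role=role, group=group,
                          haplotypes=[dict(h) for h in self.haplotypes])

    def occupied_positions(self) -> set:
        pos = {k for h in self.haplotypes for k in h}
        for sc in self.subclones:
            pos.update((v.scaffold, v.pos0) for v in sc.variants)
        return pos

    def clonal_fraction(self, scaffold: str, pos0: int, alt: str) -> float:
        k = sum(
            1 for h in self.haplotypes
            if h.get((scaffold, pos0)) is not None
            and h[(scaffold, pos0)].alt == alt
        )
        return k / PLOIDY

    def site_fraction(self, scaffold: str, pos0: int, alt: str) -> float:
        """True allele fraction of alt at a site in this individual."""
        f = self.clonal_fraction(scaffold, pos0, alt)
        for sc in self.subclones:
            if any(v.scaffold == scaffold and v.pos0 == pos0 and v.alt == alt
                   for v in sc.variants):
                f += sc.cell_fraction / PLOIDY
        return f


class TruthRecord(NamedTuple):
    variant: Variant
    label: str            # one of the four VariantCall classes
    carriers: Tuple[str, ...]
    detail: str           # "hap<i>" or subclone id


@dataclass
class TruthTable:
    records: List[TruthRecord] = field(default_factory=list)

    def add(self, variant: Variant, label: str, carriers: Sequence[str],
            detail: str) -> None:
        self.records.append(TruthRecord(variant, label, tuple(carriers), detail))

    def with_label(self, label: str) -> List[TruthRecord]:
        return [r for r in self.records if r.label == label]

    def positions(self) -> set:
        return {(r.variant.scaffold, r.variant.pos0) for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SimConfig:
    """Study conditions for the synthetic replica.

    Defaults mirror the sequencing design: ~50x coverage, 0.2% per-base error,
    triploid heterozygosity at 1 het site / 5 kb, four parents per arm with
    offspring counts (1, 1, 0, 2), per-offspring planted clonal SNV counts
    (2, 4, 5, 9) in the control arm and (11, 13, 13, 17) in the regenerated
    arm, indel counts (0, 0, 2, 3) and (1, 1, 2, 2), and a C>T/T>C-enriched
    substitution spectrum for regeneration-associated mutations.
    """

    genome_length: int = 5_000_000
    gc_fraction: float = 0.32
    repeat_fraction: float = 0.10
    n_scaffolds: int = 5
    repeat_unit_length: int = 500
    het_site_density: float = 1 / 5000.0
    two_hap_fraction: float = 0.5
    coverage_mean: float = 50.0
    error_rate: float = 0.002
    seed: int = 0
    n_invariant_sites: int = 3000
    # per-offspring planted counts, offspring named F1, F2, F4A, F4B
    control_snv_counts: Tuple[int, ...] = (2, 4, 5, 9)
    control_indel_counts: Tuple[int, ...] = (0, 0, 2, 3)
    regen_snv_counts: Tuple[int, ...] = (11, 13, 13, 17)
    regen_indel_counts: Tuple[int, ...] = (1, 1, 2, 2)
    offspring_per_parent: Tuple[int, ...] = (1, 1, 0, 2)
    n_lineage_parent: int = 30
    n_lineage_regenerant: int = 15
    # per-regenerant subclone design: (cell_fraction, n_mutations) entries
    subclone_design: Tuple[Tuple[float, int], ...] = ((0.18, 5),)
    # optional germ-lineage linkage: fraction of each offspring's clonal SNVs
    # also planted subclonally in its regenerant, at subclone_cell_fraction.
    # Off by default: linked subclonal reads in the regenerant trip the
    # strict <=1-alt-read-in-any-other-sample postfilter and censor the very
    # calls they support.
    subclone_shared_fraction: float = 0.0
    subclone_cell_fraction: float = 0.04
    # broad, mildly structured spectrum for germline and control de novo
    # mutations; strongly C>T/T>C-enriched for regeneration-associated ones
    spectrum_weights_control: Tuple[float, ...] = (0.20, 0.10, 0.25, 0.10, 0.20, 0.15)
    spectrum_weights_regen: Tuple[float, ...] = (0.05, 0.04, 0.38, 0.04, 0.44, 0.05)
    spectrum_weights_germline: Tuple[float, ...] = (0.20, 0.10, 0.25, 0.10, 0.20, 0.15)

    def validate(self) -> None:
        if sum(cf for cf, _ in self.subclone_design) > 1:
            raise ValueError("subclone cell fractions sum to > 1")
        for name in ("gc_fraction", "repeat_fraction", "two_hap_fraction",
                     "subclone_shared_fraction", "subclone_cell_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.repeat_fraction >= 0.9:
            raise ValueError("repeat_fraction >= 0.9: mask would dominate")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        for weights in (self.spectrum_weights_control, self.spectrum_weights_regen,
                        self.spectrum_weights_germline):
            if len(weights) != 6 or abs(sum(weights) - 1) > 1e-9:
                raise ValueError("spectrum weights must be 6 probabilities summing to 1")


def stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    """Named substream: one root seed, per-stage derived generators."""
    return np.random.default_rng(
        np.random.SeedSequence([root_seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def generate_reference(config: SimConfig,
                       rng: Optional[np.random.Generator] = None
                       ) -> Tuple[Genome, IntervalMask]:
    """Build an i.i.d. genome at the requested GC fraction with repeats.

    Repeat regions are built by copying one master repeat unit to multiple
    loci, guaranteeing non-unique k-mers there; the returned mask marks the
    copied loci. Deterministic under the config seed.
    """
    config.validate()
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    rng = rng if rng is not None else stage_rng(config.seed, "reference")
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    per_scaf = config.genome_length // config.n_scaffolds
    unit_len = config.repeat_unit_length
    master = bases[rng.choice(4, size=unit_len, p=probs)].tobytes().decode()

    sequences: Dict[str, str] = {}
    repeat_iv: Dict[str, List[Tuple[int, int]]] = {}
    n_units_total = int(config.repeat_fraction * config.genome_length / unit_len)
    units_per_scaf = [n_units_total // config.n_scaffolds] * config.n_scaffolds
    for i in range(n_units_total % config.n_scaffolds):
        units_per_scaf[i] += 1

    for i in range(config.n_scaffolds):
        name = f"scaffold_{i + 1}"
        arr = bases[rng.choice(4, size=per_scaf, p=probs)]
        seq = bytearray(arr.tobytes())
        placed: List[Tuple[int, int]] = []
        n_units = units_per_scaf[i]
        attempts = 0
        while len(placed) < n_units and attempts < 50 * max(1, n_units):
            attempts += 1
            start = int(rng.integers(0, per_scaf - unit_len))
            if any(start < e and start + unit_len > s for s, e in placed):
                continue
            seq[start:start + unit_len] = master.encode()
            placed.append((start, start + unit_len))
        sequences[name] = seq.decode()
        if placed:
            repeat_iv[name] = sorted(placed)
    return Genome(sequences), mask_from_intervals(repeat_iv)


class PositionSampler:
    """Samples genomic positions, optionally restricted to a mask, with a
    requested reference-base class; avoids scaffold edges (context needs
    one flanking base) and a caller-maintained set of occupied positions."""

    def __init__(self, genome: Genome, mask: Optional[IntervalMask] = None):
        self.genome = genome
        self._positions: List[Tuple[str, np.ndarray]] = []
        for scaf, seq in genome.sequences.items():
            if mask is None:
                pos = np.arange(1, len(seq) - 1)
            else:
                ivs = mask.intervals.get(scaf, [])
                if not ivs:
                    continue
                pos = np.concatenate([
                    np.arange(max(s, 1), min(e, len(seq) - 1)) for s, e in ivs
                ]) if ivs else np.array([], dtype=int)
            if len(pos):
                self._positions.append((scaf, pos))
        self._weights = np.array([len(p) for _, p in self._positions], dtype=float)
        if self._weights.sum() == 0:
            raise ValueError("no positions available to sample")
        self._weights /= self._weights.sum()

    def draw(self, rng: np.random.Generator, occupied: set,
             ref_in: Optional[str] = None, max_tries: int = 10_000
             ) -> Tuple[str, int, str]:
        for _ in range(max_tries):
            i = rng.choice(len(self._positions), p=self._weights)
            scaf, pos_arr = self._positions[i]
            pos0 = int(pos_arr[rng.integers(0, len(pos_arr))])
            if (scaf, pos0) in occupied:
                continue
            ref = self.genome[scaf][pos0]
            if ref == "N":
                continue
            if ref_in is not None and ref not in ref_in:
                continue
            return scaf, pos0, ref
        raise RuntimeError("could not place a variant (genome too occupied)")


def _draw_snv(rng: np.random.Generator, sampler: PositionSampler,
              occupied: set, spectrum_weights: Sequence[float]) -> Variant:
    """Plant one SNV drawn from a 6-channel pyrimidine spectrum.

    A pyrimidine channel like C>T is realized on the reference strand either
    as C>T (ref C) or as its complement G>A (ref G), each with probability
    determined by which reference base the sampled position carries.
    """
    channel = SUBSTITUTION_CHANNELS[rng.choice(6, p=np.asarray(spectrum_weights))]
    pyr_ref, pyr_alt = channel[0], channel[2]
    scaf, pos0, ref = sampler.draw(rng, occupied, ref_in=pyr_ref + revcomp(pyr_ref))
    alt = pyr_alt if ref == pyr_ref else revcomp(pyr_alt)
    return Variant(scaf, pos0, ref, alt)


def _draw_indel(rng: np.random.Generator, sampler: PositionSampler,
                occupied: set) -> Variant:
    scaf, pos0, ref = sampler.draw(rng, occupied)
    length = int(rng.integers(1, 4))  # 1-3 bp
    if rng.random() < 0.5:
        ins = "".join(rng.choice(list("ACGT"), size=length))
        return Variant(scaf, pos0, ref, f"I:{ins}")
    return Variant(scaf, pos0, ref, f"D:{length}")


# ---------------------------------------------------------------------------
# Pedigree construction
# ---------------------------------------------------------------------------

def found_parent(genome: Genome, config: SimConfig,
                 rng: Optional[np.random.Generator] = None,
                 truth: Optional[TruthTable] = None,
                 name: str = "founder", group: str = GROUP_CONTROL,
                 sampler: Optional[PositionSampler] = None,
                 occupied: Optional[set] = None) -> Individual:
    """Found a parent with germline heterozygous sites at het_site_density.

    Each site is mutated on one haplotype (true allele fraction 1/3) or on two
    (2/3), in the configured proportion. Collisions are resampled.
    """
    config.validate()
    rng = rng if rng is not None else stage_rng(config.seed, "founder")
    sampler = sampler or PositionSampler(genome)
    ind = Individual(name=name, role=ROLE_PARENT, group=group,
                     haplotypes=[{}, {}, {}])
    n_sites = int(round(genome.total_length * config.het_site_density))
    occupied = occupied if occupied is not None else set()
    for _ in range(n_sites):
        var = _draw_snv(rng, sampler, occupied, config.spectrum_weights_germline)
        occupied.add((var.scaffold, var.pos0))
        n_hap = 2 if rng.random() < config.two_hap_fraction else 1
        haps = rng.choice(PLOIDY, size=n_hap, replace=False)
        for h in haps:
            ind.haplotypes[int(h)][(var.scaffold, var.pos0)] = var
        if truth is not None:
            truth.add(var, GERMLINE_SHARED, [name],
                      "hap" + ",".join(str(int(h)) for h in sorted(haps)))
    return ind


def add_clonal_variants(ind: Individual, n_snv: int, n_indel: int,
                        spectrum_weights: Sequence[float],
                        sampler: PositionSampler, rng: np.random.Generator,
                        occupied: set) -> List[Variant]:
    """Add clonal single-haplotype variants to an individual in place."""
    if n_snv < 0 or n_indel < 0:
        raise ValueError("variant counts must be >= 0")
    added: List[Variant] = []
    for _ in range(n_snv):
        var = _draw_snv(rng, sampler, occupied, spectrum_weights)
        occupied.add((var.scaffold, var.pos0))
        ind.haplotypes[int(rng.integers(0, PLOIDY))][(var.scaffold, var.pos0)] = var
        added.append(var)
    for _ in range(n_indel):
        var = _draw_indel(rng, sampler, occupied)
        occupied.add((var.scaffold, var.pos0))
        ind.haplotypes[int(rng.integers(0, PLOIDY))][(var.scaffold, var.pos0)] = var
        added.append(var)
    return added


def derive_offspring(parent: Individual, name: str, n_snv: int, n_indel: int,
                     spectrum_weights: Sequence[float],
                     sampler: PositionSampler, rng: np.random.Generator,
                     truth: Optional[TruthTable] = None,
                     occupied: Optional[set] = None,
                     inherited_clonal: Sequence[Variant] = ()) -> Individual:
    """Parthenogenetic offspring: all three parental haplotypes inherited,
    plus n_snv clonal de novo SNVs and n_indel 1-3 bp indels on one random
    haplotype each. ``inherited_clonal`` variants (e.g. a regenerant
    germ-lineage subclone fixed in the offspring) are added as clonal first
    and count toward the offspring's de novo total."""
    child = parent.clone(name=name, role=ROLE_OFFSPRING, group=parent.group)
    occupied = occupied if occupied is not None else child.occupied_positions()
    for var in inherited_clonal:
        child.haplotypes[int(rng.integers(0, PLOIDY))][(var.scaffold, var.pos0)] = var
    n_new_snv = n_snv - sum(1 for v in inherited_clonal if len(v.alt) == 1)
    n_new_indel = n_indel - sum(1 for v in inherited_clonal if len(v.alt) > 1)
    if n_new_snv < 0 or n_new_indel < 0:
        raise ValueError("inherited clonal variants exceed requested counts")
    added = add_clonal_variants(child, n_new_snv, n_new_indel, spectrum_weights,
                                sampler, rng, occupied)
    if truth is not None:
        for var in list(inherited_clonal) + added:
            truth.add(var, DE_NOVO_CLONAL, [name], "hap?")
    return child


def derive_regenerant(parent: Individual, name: str,
                      subclone_design: Sequence[Tuple[float, int]],
                      sampler: PositionSampler, rng: np.random.Generator,
                      truth: Optional[TruthTable] = None,
                      occupied: Optional[set] = None) -> Individual:
    """A regenerant: the parental trunk plus, per (cell_fraction, n) design
    entry, n single-haplotype SNVs confined to that cell fraction. The true
    site allele fraction of a subclonal variant is cell_fraction / 3."""
    if sum(cf for cf, _ in subclone_design) > 1 + 1e-9:
        raise ValueError("subclone cell fractions sum to > 1")
    regen = parent.clone(name=name, role=ROLE_REGENERANT, group=parent.group)
    occupied = occupied if occupied is not None else regen.occupied_positions()
    for i, (cf, n_mut) in enumerate(subclone_design):
        variants: List[Variant] = []
        for _ in range(n_mut):
            var = _draw_snv(rng, sampler, occupied, (1 / 6,) * 6)
            occupied.add((var.scaffold, var.pos0))
            variants.append(var)
        sid = f"{name}.sc{i}"
        regen.subclones.append(Subclone(sid=sid, cell_fraction=cf,
                                        variants=variants))
        if truth is not None:
            for var in variants:
                truth.add(var, SUBCLONAL, [name], sid)
    return regen


def attach_subclone(regenerant: Individual, variants: Sequence[Variant],
                    cell_fraction: float, sid: str,
                    truth: Optional[TruthTable] = None) -> None:
    """Attach a subclone with explicit variants (e.g. the germ lineage that
    founded an offspring, so the offspring's clonal mutations have subclonal
    support in the regenerant)."""
    regenerant.subclones.append(
        Subclone(sid=sid, cell_fraction=cell_fraction, variants=list(variants)))
    if truth is not None:
        for var in variants:
            truth.add(var, SUBCLONAL, [regenerant.name], sid)


def sample_germline_afs(rng: np.random.Generator, n_sites: int,
                        ploidy: int = PLOIDY, two_hap_fraction: float = 0.5,
                        depth_mean: float = 50.0,
                        error_rate: float = 0.002) -> List[float]:
    """Directly sample observed allele fractions of germline het sites.

    Heterozygous sites carry the variant on 1..ploidy-1 copies: for the
    triploid case on one haplotype or (with probability two_hap_fraction)
    on two; for other ploidies the copy number is uniform over 1..ploidy-1.
    The readout is binomial at Poisson depth with the sequencing-error
    model of simulate_pileup.
    """
    if ploidy < 2:
        raise ValueError("heterozygous sites need ploidy >= 2")
    e = error_rate
    afs: List[float] = []
    for _ in range(n_sites):
        if ploidy == 3:
            k = 2 if rng.random() < two_hap_fraction else 1
        else:
            k = int(rng.integers(1, ploidy))
        f = k / ploidy
        depth = max(1, int(rng.poisson(depth_mean)))
        p = f * (1 - e) + (1 - f) * e / 3
        afs.append(int(rng.binomial(depth, p)) / depth)
    return afs


# ---------------------------------------------------------------------------
# Pileup simulation
# ---------------------------------------------------------------------------

def simulate_pileup(individuals: Sequence[Individual], genome: Genome,
                    config: SimConfig, rng: Optional[np.random.Generator] = None,
                    repeat_mask: Optional[IntervalMask] = None,
                    n_invariant_sites: Optional[int] = None) -> PileupTable:
    """Sample a read-count pileup at every variant site plus invariant sites.

    Per sample and site: depth ~ Poisson(coverage_mean); for the (single)
    variant allele, alt reads ~ Binomial(depth, f(1-e) + (1-f)e/3) with f the
    individual's true site allele fraction and e the error rate; error reads
    for the remaining non-reference alleles are split evenly; the rest are
    reference. Mean mapping quality is 60 outside the repeat mask and drawn
    uniformly from [10, 35] inside it.
    """
    config.validate()
    rng = rng if rng is not None else stage_rng(config.seed, "pileup")
    e = config.error_rate

    # union of variant positions across individuals
    site_alleles: Dict[Tuple[str, int], Tuple[str, str]] = {}
    for ind in individuals:
        for h in ind.haplotypes:
            for (scaf, pos0), var in h.items():
                site_alleles[(scaf, pos0)] = (var.ref, var.alt)
        for sc in ind.subclones:
            for var in sc.variants:
                site_alleles[(var.scaffold, var.pos0)] = (var.ref, var.alt)

    n_inv = config.n_invariant_sites if n_invariant_sites is None \
        else n_invariant_sites
    sampler = PositionSampler(genome)
    occupied = set(site_alleles)
    inv_sites: List[Tuple[str, int, str]] = []
    for _ in range(n_inv):
        scaf, pos0, ref = sampler.draw(rng, occupied)
        occupied.add((scaf, pos0))
        inv_sites.append((scaf, pos0, ref))

    order = {name: i for i, name in enumerate(genome.scaffold_names)}
    all_sites: List[Tuple[str, int, str, Optional[str]]] = (
        [(scaf, pos0, ref, alt) for (scaf, pos0), (ref, alt)
         in site_alleles.items()]
        + [(scaf, pos0, ref, None) for scaf, pos0, ref in inv_sites]
    )
    all_sites.sort(key=lambda s: (order[s[0]], s[1]))

    samples = [ind.name for ind in individuals]
    sites: List[PileupSite] = []
    for scaf, pos0, ref, alt in all_sites:
        in_repeat = repeat_mask.contains(scaf, pos0) if repeat_mask else False
        cells: Dict[str, PileupCell] = {}
        for ind in individuals:
            depth = int(rng.poisson(config.coverage_mean))
            counts: Dict[str, int] = {}
            if depth > 0:
                non_ref_bases = [b for b in "ACGT" if b != ref]
                f = ind.site_fraction(scaf, pos0, alt) if alt else 0.0
                if alt is not None and f > 0:
                    p_alt = f * (1 - e) + (1 - f) * e / 3
                    n_alt = int(rng.binomial(depth, min(1.0, p_alt)))
                    if n_alt:
                        counts[alt] = n_alt
                    rest = depth - n_alt
                    err_targets = [b for b in non_ref_bases if b != alt]
                    n_err = int(rng.binomial(rest, e * len(err_targets) / 3)) \
                        if rest else 0
                else:
                    n_alt = 0
                    rest = depth
                    err_targets = non_ref_bases
                    n_err = int(rng.binomial(rest, e)) if rest else 0
                if n_err and err_targets:
                    split = rng.multinomial(n_err,
                                            [1 / len(err_targets)] * len(err_targets))
                    for b, c in zip(err_targets, split):
                        if c:
                            counts[b] = counts.get(b, 0) + int(c)
                n_ref = depth - sum(counts.values())
                if n_ref:
                    counts[ref] = n_ref
            mq = float(rng.uniform(10, 35)) if in_repeat else 60.0
            cells[ind.name] = PileupCell(depth=depth, counts=counts, mean_mq=mq)
        sites.append(PileupSite(scaf, pos0, ref, cells))
    return PileupTable(samples=samples, sites=sites)
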