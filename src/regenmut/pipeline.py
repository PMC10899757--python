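"""End-to-end orchestration of the study replica on synthetic data.

``run_study_replica`` generates a triploid reference, founds one isogenic
population, builds the control arm (4 parents, offspring counts 1, 1, 0, 2)
and the regenerated arm (4 parents, 4 regenerants, offspring counts
1, 1, 0, 2), simulates ~50x read-count pileups for the two cohorts, and runs
the whole analysis: unique and shared calling, pedigree inference, mappable
de novo counts and rates, control-vs-regenerated burden comparison, spectra
and their correlations, ploidy inference and subclonal mosaicism. Every
stage draws from a named substream of one root seed, so reruns with the same
seed produce identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .burden import (compare_burden, estimate_rate, kmer_mappability_mask,
                     restrict_calls)
from .calling import (DE_NOVO_CLONAL, GERMLINE_SHARED, CallerParams,
                      VariantCall, annotate_context, call_shared, call_unique)
from .io import Genome, IntervalMask, PileupTable
from .lineage import Pedigree, assign_pedigree, sharing_matrix, \
    sibling_shared_denovo
from .simulate import (GROUP_CONTROL, GROUP_REGENERATED, Individual,
                       PositionSampler, SimConfig, TruthTable,
                       add_clonal_variants, attach_subclone, derive_offspring,
                       derive_regenerant, found_parent, generate_reference,
                       simulate_pileup, stage_rng)
from .spectra import Spectrum, build_spectrum, spectrum_correlation
from .subclonal import (AFObservation, infer_ploidy, mosaicism_summary,
                        subclonal_support)

# offspring naming per parent index, mirroring counts (1, 1, 0, 2)
_OFFSPRING_SUFFIX = {0: ["1"], 1: ["2"], 2: [], 3: ["4A", "4B"]}


@dataclass
class StudyArm:
    group: str
    individuals: List[Individual]
    pileup: PileupTable
    truth: TruthTable
    offspring: List[str]
    parent_of: Dict[str, str]          # planted offspring/regenerant -> parent
    regenerant_of: Dict[str, str]      # planted offspring -> regenerant


@dataclass
class StudyData:
    genome: Genome
    repeat_mask: IntervalMask
    mappable_mask: IntervalMask
    control: StudyArm
    regenerated: StudyArm
    config: SimConfig
    seed: int


def _offspring_names(prefix: str) -> List[Tuple[int, str]]:
    out = []
    for parent_idx, suffixes in _OFFSPRING_SUFFIX.items():
        for sfx in suffixes:
            out.append((parent_idx, f"{prefix}{sfx}"))
    return out


def _build_arm(group: str, genome: Genome, mappable: IntervalMask,
               repeat_mask: IntervalMask, founder_variants, config: SimConfig,
               seed: int, occupied: set) -> StudyArm:
    """Construct one arm's individuals, truth table and pileup."""
    regenerated = group == GROUP_REGENERATED
    p_prefix, f_prefix = ("Pr", "Fr") if regenerated else ("Pc", "Fc")
    rng = stage_rng(seed, f"arm-{group}")
    truth = TruthTable()
    genome_sampler = PositionSampler(genome)
    mappable_sampler = PositionSampler(genome, mappable)
    snv_counts = config.regen_snv_counts if regenerated \
        else config.control_snv_counts
    indel_counts = config.regen_indel_counts if regenerated \
        else config.control_indel_counts
    weights = config.spectrum_weights_regen if regenerated \
        else config.spectrum_weights_control

    parents: List[Individual] = []
    lineage_added: List[List] = []
    for i in range(4):
        parent = founder_variants.clone(f"{p_prefix}{i + 1}", "parent", group)
        added = add_clonal_variants(
            parent, config.n_lineage_parent, 0,
            config.spectrum_weights_germline, genome_sampler, rng, occupied)
        parents.append(parent)
        lineage_added.append(added)

    regenerants: List[Individual] = []
    regen_added: List[List] = []
    parent_of: Dict[str, str] = {}
    if regenerated:
        for i, parent in enumerate(parents):
            regen = derive_regenerant(
                parent, f"R{i + 1}", list(config.subclone_design),
                genome_sampler, rng, truth=truth, occupied=occupied)
            regen.role = "regenerant"
            added = add_clonal_variants(
                regen, config.n_lineage_regenerant, 0,
                config.spectrum_weights_germline, genome_sampler, rng, occupied)
            regenerants.append(regen)
            regen_added.append(added)
            parent_of[regen.name] = parent.name

    offspring: List[Individual] = []
    regenerant_of: Dict[str, str] = {}
    for k, (parent_idx, name) in enumerate(_offspring_names(f_prefix)):
        source = regenerants[parent_idx] if regenerated else parents[parent_idx]
        child = derive_offspring(
            source, name, snv_counts[k], indel_counts[k], weights,
            mappable_sampler, rng, truth=truth, occupied=occupied)
        if config.subclone_shared_fraction > 0 and regenerated:
            de_novo = [r.variant for r in truth.records
                       if r.label == DE_NOVO_CLONAL and r.carriers == (name,)
                       and len(r.variant.alt) == 1]
            n_share = int(round(config.subclone_shared_fraction * len(de_novo)))
            attach_subclone(regenerants[parent_idx], de_novo[:n_share],
                            config.subclone_cell_fraction,
                            f"R{parent_idx + 1}.germ-{name}", truth=truth)
        offspring.append(child)
        parent_of[name] = parents[parent_idx].name
        if regenerated:
            regenerant_of[name] = regenerants[parent_idx].name

    individuals = parents + regenerants + offspring
    names = [ind.name for ind in individuals]
    germline_seen = set()
    for h in founder_variants.haplotypes:
        for key, var in h.items():
            if key not in germline_seen:
                germline_seen.add(key)
                truth.add(var, GERMLINE_SHARED, names, "founder")
    for parent, added in zip(parents, lineage_added):
        family = [parent.name] + [o for o, p in parent_of.items()
                                  if p == parent.name]
        for name in list(regenerant_of):
            if parent_of.get(regenerant_of[name]) == parent.name \
                    and name not in family:
                family.append(name)
        for var in added:
            truth.add(var, "lineage-specific", family, "parent-line")
    for regen, added in zip(regenerants, regen_added):
        family = [regen.name] + [o for o, r in regenerant_of.items()
                                 if r == regen.name]
        for var in added:
            truth.add(var, "lineage-specific", family, "regenerant-line")

    pileup = simulate_pileup(individuals, genome, config,
                             rng=stage_rng(seed, f"pileup-{group}"),
                             repeat_mask=repeat_mask)
    return StudyArm(group=group, individuals=individuals, pileup=pileup,
                    truth=truth, offspring=[o.name for o in offspring],
                    parent_of=parent_of, regenerant_of=regenerant_of)


def simulate_study(config: Optional[SimConfig] = None,
                   seed: Optional[int] = None,
                   arms: Sequence[str] = (GROUP_CONTROL, GROUP_REGENERATED),
                   ) -> StudyData:
    """Generate the full two-arm study replica with ground truth."""
    config = config or SimConfig()
    seed = config.seed if seed is None else seed
    config.validate()
    genome, repeat_mask = generate_reference(config,
                                             rng=stage_rng(seed, "reference"))
    mappable = kmer_mappability_mask(genome, k=50)
    occupied: set = set()
    founder = found_parent(genome, config, rng=stage_rng(seed, "founder"),
                           occupied=occupied)
    control = regen = None
    if GROUP_CONTROL in arms:
        control = _build_arm(GROUP_CONTROL, genome, mappable, repeat_mask,
                             founder, config, seed, occupied)
    if GROUP_REGENERATED in arms:
        regen = _build_arm(GROUP_REGENERATED, genome, mappable, repeat_mask,
                           founder, config, seed, occupied)
    return StudyData(genome=genome, repeat_mask=repeat_mask,
                     mappable_mask=mappable, control=control,
                     regenerated=regen, config=config, seed=seed)


# ---------------------------------------------------------------------------
# Analysis over one arm
# ---------------------------------------------------------------------------

@dataclass
class ArmResult:
    de_novo_calls: List[VariantCall]
    per_offspring_snv: Dict[str, int]
    per_offspring_indel: Dict[str, int]
    pedigree: Pedigree
    germline_calls: List[VariantCall]
    lineage_calls: List[VariantCall]


def analyze_arm(arm: StudyArm, mappable: IntervalMask, genome: Genome,
                params: Optional[CallerParams] = None) -> ArmResult:
    """Unique + shared calling, pedigree inference and per-offspring counts."""
    params = params or CallerParams()
    unique = call_unique(arm.pileup, params)
    shared = call_shared(arm.pileup, params)
    germline = [c for c in shared if c.label == GERMLINE_SHARED]
    lineage = [c for c in shared if c.label == "lineage-specific"]

    samples = arm.pileup.samples
    roles = {ind.name: ind.role for ind in arm.individuals}
    groups = {ind.name: ind.group for ind in arm.individuals}
    matrix = sharing_matrix(lineage, samples)
    pedigree = assign_pedigree(matrix, samples, roles, groups)

    offspring = set(arm.offspring)
    de_novo = [c for c in unique if c.carriers[0] in offspring]
    mappable_calls = restrict_calls(de_novo, mappable)
    for c in mappable_calls:
        c.label = DE_NOVO_CLONAL
        if c.variant_type == "SNV":
            annotate_context(genome, c)
    per_snv = {o: 0 for o in arm.offspring}
    per_indel = {o: 0 for o in arm.offspring}
    for c in mappable_calls:
        if c.variant_type == "SNV":
            per_snv[c.carriers[0]] += 1
        else:
            per_indel[c.carriers[0]] += 1
    return ArmResult(de_novo_calls=mappable_calls, per_offspring_snv=per_snv,
                     per_offspring_indel=per_indel, pedigree=pedigree,
                     germline_calls=germline, lineage_calls=lineage)


# ---------------------------------------------------------------------------
# Full replica
# ---------------------------------------------------------------------------

def run_study_replica(config: Optional[SimConfig] = None,
                      seed: int = 0,
                      params: Optional[CallerParams] = None) -> Dict:
    """Execute the full control + regenerated design and analysis.

    Returns a JSON-serializable bundle: inferred pedigrees, per-offspring
    recovered vs planted de novo counts, rates, the burden comparison,
    spectra with correlations, ploidy inference and the subclonal table,
    with provenance (seed, parameters, version).
    """
    config = config or SimConfig()
    params = params or CallerParams()
    study = simulate_study(config, seed=seed)
    genome, mappable = study.genome, study.mappable_mask

    ctrl = analyze_arm(study.control, mappable, genome, params)
    regen = analyze_arm(study.regenerated, mappable, genome, params)

    L = mappable.total_length
    rate = estimate_rate(ctrl.de_novo_calls,
                         n_offspring=len(study.control.offspring),
                         L_mappable=L)
    snv_ctrl = [ctrl.per_offspring_snv[o] for o in study.control.offspring]
    snv_regen = [regen.per_offspring_snv[o] for o in study.regenerated.offspring]
    burden_cmp = compare_burden(snv_ctrl, snv_regen)

    spec_ctrl = build_spectrum(ctrl.de_novo_calls, genome)
    spec_regen = build_spectrum(regen.de_novo_calls, genome)
    germ_calls = ctrl.germline_calls + regen.germline_calls
    for c in germ_calls:
        if c.variant_type == "SNV" and c.channel is None:
            annotate_context(genome, c)
    spec_germ = build_spectrum(germ_calls, genome)
    correlations = {}
    try:
        correlations = {
            "germline_vs_control": spectrum_correlation(spec_germ, spec_ctrl),
            "germline_vs_regenerated": spectrum_correlation(spec_germ, spec_regen),
        }
    except ValueError:
        correlations = {"germline_vs_control": None,
                        "germline_vs_regenerated": None}

    germ_afs = [af for c in germ_calls for af in c.allele_fractions.values()]
    ploidy_call = infer_ploidy(germ_afs) if len(germ_afs) >= 100 else None
    ploidy = ploidy_call.ploidy if ploidy_call and ploidy_call.ploidy else 3

    # subclonal mosaicism: planted subclonal truth sites read out in each
    # regenerant, plus support of filial clonal calls in their regenerant
    subclonal_rows = []
    truth_sub = study.regenerated.truth.with_label("subclonal")
    by_regen: Dict[str, List[VariantCall]] = {}
    for rec in truth_sub:
        target = rec.carriers[0]
        by_regen.setdefault(target, []).append(VariantCall(
            scaffold=rec.variant.scaffold, pos0=rec.variant.pos0,
            ref=rec.variant.ref, alt=rec.variant.alt, carriers=[target]))
    supported_obs: List[AFObservation] = []
    for target, calls in by_regen.items():
        obs = subclonal_support(calls, study.regenerated.pileup, target,
                                error_rate=config.error_rate)
        supported_obs.extend(obs)
        for o in obs:
            subclonal_rows.append({
                "regenerant": target,
                "variant": f"{o.variant[0]}:{o.variant[1] + 1}"
                           f"{o.variant[2]}>{o.variant[3]}",
                "alt_reads": o.alt_reads, "depth": o.depth,
                "allele_fraction": round(o.allele_fraction, 4),
                "supported": bool(o.supported),
                "cell_fraction": round(min(1.0, ploidy * o.allele_fraction), 4),
            })
    mosaic = mosaicism_summary(supported_obs, ploidy) if supported_obs else None

    planted_ctrl = dict(zip(study.control.offspring, config.control_snv_counts))
    planted_regen = dict(zip(study.regenerated.offspring,
                             config.regen_snv_counts))

    def pedigree_dict(p: Pedigree) -> Dict:
        return {
            "edges": {o: {"parent": e[0], "regenerant": e[1]}
                      for o, e in p.edges.items()},
            "sibling_groups": [sorted(g) for g in p.sibling_groups],
            "ambiguous": p.ambiguous,
        }

    bundle = {
        "provenance": {
            "seed": seed,
            "version": __version__,
            "genome_length": genome.total_length,
            "mappable_bp": L,
            "caller_params": vars(params) | {"cov_range": list(params.cov_range)},
        },
        "pedigree": {
            "control": pedigree_dict(ctrl.pedigree),
            "regenerated": pedigree_dict(regen.pedigree),
        },
        "counts": {
            "control": {
                "per_offspring_snv": ctrl.per_offspring_snv,
                "per_offspring_indel": ctrl.per_offspring_indel,
                "planted_snv": planted_ctrl,
                "mean_snv": float(np.mean(snv_ctrl)),
            },
            "regenerated": {
                "per_offspring_snv": regen.per_offspring_snv,
                "per_offspring_indel": regen.per_offspring_indel,
                "planted_snv": planted_regen,
                "mean_snv": float(np.mean(snv_regen)),
            },
        },
        "rates": {
            "L_mappable": L,
            "SNV": rate.rates["SNV"],
            "indel": rate.rates["indel"],
            "overall": rate.rates["overall"],
            "SNV_display": rate.display("SNV"),
            "overall_display": rate.display("overall"),
        },
        "burden": {
            "mean_control": burden_cmp.mean_control,
            "mean_regenerated": burden_cmp.mean_regenerated,
            "sd_control": burden_cmp.sd_control,
            "sd_regenerated": burden_cmp.sd_regenerated,
            "fold_change": burden_cmp.fold_change,
            "t_statistic": burden_cmp.t_statistic,
            "p_value": burden_cmp.p_value,
        },
        "spectra": {
            "control": spec_ctrl.as_dict(),
            "regenerated": spec_regen.as_dict(),
            "germline": spec_germ.as_dict(),
            "correlations": correlations,
        },
        "ploidy": {
            "inferred": ploidy_call.ploidy if ploidy_call else None,
            "peaks": ploidy_call.peaks if ploidy_call else [],
        },
        "subclonal": {
            "table": subclonal_rows,
            "median_af": mosaic.median_af if mosaic else None,
            "af_range": list(mosaic.af_range) if mosaic else None,
            "median_cell_fraction": mosaic.median_cell_fraction if mosaic else None,
            "max_cell_fraction": mosaic.max_cell_fraction if mosaic else None,
        },
    }
    return bundle


def bundle_to_json(bundle: Dict) -> str:
    return json.dumps(bundle, indent=2, sort_keys=True)


def render_report(bundle: Dict) -> str:
    """Human-readable summary mirroring the study's reporting structure."""
    lines: List[str] = []
    prov = bundle.get("provenance", {})
    lines.append(f"Study replica (seed {prov.get('seed')}, "
                 f"genome {prov.get('genome_length', '?')} bp, "
                 f"mappable {prov.get('mappable_bp', '?')} bp)")
    counts = bundle.get("counts")
    if counts:
        for group in ("control", "regenerated"):
            c = counts[group]
            per = c["per_offspring_snv"]
            lines.append(
                f"{group}: de novo SNVs per offspring "
                + ", ".join(f"{k}={v}" for k, v in per.items())
                + f" (mean {c['mean_snv']:.2f})")
    else:
        lines.append("counts: section missing")
    rates = bundle.get("rates")
    if rates:
        lines.append(f"SNV rate {rates['SNV_display']} /bp/generation; "
                     f"overall {rates['overall_display']} /bp/generation "
                     f"(L = {rates['L_mappable']} bp)")
    else:
        lines.append("rates: section missing")
    burden = bundle.get("burden")
    if burden:
        fold = burden["fold_change"]
        p = burden["p_value"]
        lines.append(
            f"burden: {burden['mean_control']:.2f} +/- "
            f"{burden['sd_control']:.2f} vs {burden['mean_regenerated']:.2f} "
            f"+/- {burden['sd_regenerated']:.2f}"
            + (f", fold {fold:.2f}" if fold else "")
            + (f", P = {p:.3g} (unpaired two-sided t-test)" if p is not None
               else ""))
    spectra = bundle.get("spectra", {})
    corr = spectra.get("correlations", {})
    if corr.get("germline_vs_control") is not None:
        lines.append(
            f"spectrum correlation with germline: control "
            f"r = {corr['germline_vs_control']:.3f}, regenerated "
            f"r = {corr['germline_vs_regenerated']:.3f}")
    ploidy = bundle.get("ploidy")
    if ploidy and ploidy.get("inferred"):
        peaks = ", ".join(f"{p:.1%}" for p in ploidy["peaks"])
        lines.append(f"ploidy {ploidy['inferred']} (AF peaks at {peaks})")
    sub = bundle.get("subclonal")
    if sub:
        supported = [r for r in sub.get("table", []) if r["supported"]]
        if supported:
            lines.append(
                f"subclonal: {len(supported)} supported variants, median AF "
                f"{sub['median_af']:.2%}, max cell fraction "
                f"{sub['max_cell_fraction']:.1%}")
        else:
            lines.append("subclonal: no supported subclonal variants")
    return "\n".join(lines)
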