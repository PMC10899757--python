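"""Assembly-curation computations: haplotig purging from self-alignments,
assembly statistics, and transcript-anchored synteny-link classification.

Haplotig purging retains a self-alignment as duplication evidence only when
it is a reciprocal-best mapping between two scaffolds, its secondary/primary
chain-score ratio is at most 0.5, its divergence at most 60%, its mapping
quality at least 60, and no single repeat interval covers more than 40% of
the aligned length; the aligned region on the shorter scaffold is then
excised. Synteny links classify scaffolds by how many partner scaffolds
their filtered gene anchors map to, and break sites between anchor runs by
orientation consistency.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .io import Genome, IntervalMask, SelfAlignment, merge_intervals

SINGLE_LINK = "single-link"
MULTI_LINK = "multi-link"
BREAK_REARRANGEMENT = "rearrangement"
BREAK_POOR_SCAFFOLDING = "poor-scaffolding"
BREAK_PARTNER_END = "partner-end-adjacency"


# ---------------------------------------------------------------------------
# Haplotig purging
# ---------------------------------------------------------------------------

@dataclass
class PurgeParams:
    max_secondary_ratio: float = 0.5
    max_divergence: float = 0.60
    min_mapq: int = 60
    max_repeat_overlap: float = 0.40

    def validate(self) -> None:
        for name in ("max_secondary_ratio", "max_divergence", "max_repeat_overlap"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} outside [0,1]")


@dataclass
class PurgeReport:
    retained: List[SelfAlignment]
    removed_regions: Dict[str, List[Tuple[int, int]]]
    removed_bp: int
    dropped_scaffolds: List[str]
    skipped_stale: int = 0


def _max_single_repeat_overlap(mask: Optional[IntervalMask], scaffold: str,
                               start: int, end: int) -> float:
    """Largest fraction of [start, end) covered by any ONE repeat interval."""
    if mask is None:
        return 0.0
    best = 0
    for s, e in mask.intervals.get(scaffold, []):
        overlap = min(e, end) - max(s, start)
        if overlap > best:
            best = overlap
    return best / (end - start) if end > start else 0.0


def _passes_filters(a: SelfAlignment, repeat_mask: Optional[IntervalMask],
                    params: PurgeParams) -> bool:
    if a.mapq < params.min_mapq:
        return False
    if a.divergence > params.max_divergence:
        return False
    if a.chain_score_primary > 0 and (
            a.chain_score_secondary / a.chain_score_primary
            > params.max_secondary_ratio):
        return False
    for scaf, start, end in ((a.q_name, a.q_start, a.q_end),
                             (a.t_name, a.t_start, a.t_end)):
        if _max_single_repeat_overlap(repeat_mask, scaf, start, end) \
                > params.max_repeat_overlap:
            return False
    return True


def _reciprocal_best(alignments: Sequence[SelfAlignment]) -> Set[int]:
    """Indices of alignments whose scaffold pair is reciprocal-best.

    A scaffold's best partner is the one with the largest summed matched
    bases; an alignment is one-to-one iff each of its two scaffolds is the
    other's best partner.
    """
    match_sum: Dict[str, Dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for a in alignments:
        match_sum[a.q_name][a.t_name] += a.n_match
        match_sum[a.t_name][a.q_name] += a.n_match
    best: Dict[str, str] = {
        s: max(partners, key=lambda p: (partners[p], p))
        for s, partners in match_sum.items()
    }
    return {
        i for i, a in enumerate(alignments)
        if best.get(a.q_name) == a.t_name and best.get(a.t_name) == a.q_name
    }


def purge_haplotigs(alignments: Sequence[SelfAlignment], genome: Genome,
                    repeat_mask: Optional[IntervalMask] = None,
                    params: Optional[PurgeParams] = None,
                    min_scaffold_length: int = 1000
                    ) -> Tuple[Genome, PurgeReport]:
    """Excise confidently duplicated regions from the shorter scaffold.

    Self-hits (q_name == t_name) are ignored; alignments naming unknown
    scaffolds raise; alignments whose coordinates no longer fit the current
    scaffold lengths (stale evidence from an earlier purge pass) are skipped,
    which makes a second pass on the output a no-op. Overlapping removals are
    merged before excision and scaffolds left shorter than
    ``min_scaffold_length`` are dropped.
    """
    params = params or PurgeParams()
    params.validate()
    live: List[SelfAlignment] = []
    skipped_stale = 0
    for a in alignments:
        for name in (a.q_name, a.t_name):
            if name not in genome:
                raise ValueError(f"alignment references unknown scaffold {name!r}")
        if a.q_name == a.t_name:
            continue
        if (a.q_len != len(genome[a.q_name]) or a.t_len != len(genome[a.t_name])
                or a.q_end > len(genome[a.q_name])
                or a.t_end > len(genome[a.t_name])):
            skipped_stale += 1
            continue
        live.append(a)

    filtered = [a for a in live if _passes_filters(a, repeat_mask, params)]
    keep = _reciprocal_best(filtered)
    retained = [a for i, a in enumerate(filtered) if i in keep]

    raw_removals: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for a in retained:
        # excise from the shorter scaffold (by total length)
        if len(genome[a.q_name]) <= len(genome[a.t_name]):
            raw_removals[a.q_name].append((a.q_start, a.q_end))
        else:
            raw_removals[a.t_name].append((a.t_start, a.t_end))

    removed_regions = {s: merge_intervals(iv) for s, iv in raw_removals.items()}
    removed_bp = sum(e - s for ivs in removed_regions.values() for s, e in ivs)

    sequences: Dict[str, str] = {}
    dropped: List[str] = []
    for name, seq in genome.sequences.items():
        if name in removed_regions:
            kept_parts = []
            cursor = 0
            for s, e in removed_regions[name]:
                kept_parts.append(seq[cursor:s])
                cursor = e
            kept_parts.append(seq[cursor:])
            new_seq = "".join(kept_parts)
            if len(new_seq) < min_scaffold_length:
                dropped.append(name)
                continue
            sequences[name] = new_seq
        else:
            sequences[name] = seq
    return Genome(sequences), PurgeReport(
        retained=retained, removed_regions=dict(removed_regions),
        removed_bp=removed_bp, dropped_scaffolds=dropped,
        skipped_stale=skipped_stale,
    )


# ---------------------------------------------------------------------------
# Assembly statistics
# ---------------------------------------------------------------------------

@dataclass
class AssemblyStats:
    total_length: int
    n_scaffolds: int
    n50: int
    gc_ratio: float


def assembly_stats(genome: Genome) -> AssemblyStats:
    """Total length, scaffold count, N50 and GC ratio (N bases excluded
    from the GC denominator)."""
    lengths = sorted((len(s) for s in genome.sequences.values()), reverse=True)
    total = sum(lengths)
    half = total / 2
    cumulative = 0
    n50 = lengths[-1]
    for length in lengths:
        cumulative += length
        if cumulative >= half:
            n50 = length
            break
    gc = sum(seq.count("G") + seq.count("C")
             for seq in genome.sequences.values())
    acgt = sum(len(seq) - seq.count("N") for seq in genome.sequences.values())
    return AssemblyStats(total_length=total, n_scaffolds=len(lengths),
                         n50=n50, gc_ratio=gc / acgt if acgt else 0.0)


# ---------------------------------------------------------------------------
# Synteny links
# ---------------------------------------------------------------------------

@dataclass
class GeneAnchor:
    """A transcript back-mapped onto a scaffold, with its ortholog's position
    in the partner assembly."""

    transcript: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"
    masked_fraction: float = 0.0
    nested: bool = False
    one_to_one: bool = True
    partner_scaffold: Optional[str] = None
    partner_start: int = 0
    partner_end: int = 0
    partner_length: int = 0

    @property
    def mapped_length(self) -> int:
        return self.end - self.start

    def passes_filters(self) -> bool:
        return (self.masked_fraction < 0.10 and self.mapped_length > 300
                and not self.nested and self.one_to_one
                and self.partner_scaffold is not None)


def filter_anchors(anchors: Iterable[GeneAnchor]) -> List[GeneAnchor]:
    """Keep anchors masked on <10% of their length, mapped over >300 bp,
    not nested in another gene, and with one-to-one homology."""
    return [a for a in anchors if a.passes_filters()]


@dataclass
class BreakSite:
    scaffold: str
    pos0: int                   # midpoint between the flanking anchor runs
    left_partner: str
    right_partner: str
    left_genes: int
    right_genes: int
    klass: str


@dataclass
class SyntenyReport:
    links: Dict[str, Dict[str, int]]      # scaffold -> partner -> gene count
    link_class: Dict[str, str]            # scaffold -> single-link/multi-link
    break_sites: List[BreakSite]

    @property
    def n_single_link(self) -> int:
        return sum(1 for c in self.link_class.values() if c == SINGLE_LINK)


def _runs(anchors: Sequence[GeneAnchor]) -> List[List[GeneAnchor]]:
    """Maximal runs of consecutive anchors sharing a partner scaffold."""
    runs: List[List[GeneAnchor]] = []
    for a in anchors:
        if runs and runs[-1][0].partner_scaffold == a.partner_scaffold:
            runs[-1].append(a)
        else:
            runs.append([a])
    return runs


def _run_orientation_consistent(run: Sequence[GeneAnchor]) -> bool:
    """Consistent strand and coherent (monotone) partner coordinates."""
    if len({a.strand for a in run}) > 1:
        return False
    if len(run) < 2:
        return True
    starts = [a.partner_start for a in run]
    increasing = all(b >= a for a, b in zip(starts, starts[1:]))
    decreasing = all(b <= a for a, b in zip(starts, starts[1:]))
    return increasing or decreasing


def _run_at_partner_end(run: Sequence[GeneAnchor], end_window: int) -> bool:
    lo = min(a.partner_start for a in run)
    hi = max(a.partner_end for a in run)
    plen = run[0].partner_length
    return lo < end_window or (plen > 0 and plen - hi < end_window)


def synteny_links(anchors: Sequence[GeneAnchor], min_run_genes: int = 2,
                  end_window: int = 50_000,
                  adjacency: Optional[Set[Tuple[str, str]]] = None
                  ) -> SyntenyReport:
    """Classify scaffolds by partner count and break sites by evidence.

    A break site is emitted between consecutive anchor runs with different
    partner scaffolds when both runs hold >= min_run_genes genes. It is
    classed partner-end-adjacency when both runs sit within ``end_window``
    of their partner-scaffold ends (or when user-supplied ``adjacency``
    evidence names the partner pair), rearrangement when both flanking runs
    are orientation-consistent, else poor-scaffolding.
    """
    anchors = list(anchors)
    not_clean = [a for a in anchors if not a.passes_filters()]
    if not_clean:
        raise ValueError(
            f"{len(not_clean)} anchors fail the synteny filters; "
            "run filter_anchors first"
        )
    by_scaffold: Dict[str, List[GeneAnchor]] = defaultdict(list)
    for a in anchors:
        by_scaffold[a.scaffold].append(a)

    links: Dict[str, Dict[str, int]] = {}
    link_class: Dict[str, str] = {}
    break_sites: List[BreakSite] = []
    for scaffold, scaffold_anchors in by_scaffold.items():
        scaffold_anchors.sort(key=lambda a: a.start)
        counts: Dict[str, int] = defaultdict(int)
        for a in scaffold_anchors:
            counts[a.partner_scaffold] += 1
        links[scaffold] = dict(counts)
        link_class[scaffold] = SINGLE_LINK if len(counts) == 1 else MULTI_LINK
        if len(counts) == 1:
            continue
        runs = _runs(scaffold_anchors)
        for left, right in zip(runs, runs[1:]):
            if len(left) < min_run_genes or len(right) < min_run_genes:
                continue
            pair = tuple(sorted((left[0].partner_scaffold,
                                 right[0].partner_scaffold)))
            if (_run_at_partner_end(left, end_window)
                    and _run_at_partner_end(right, end_window)) \
                    or (adjacency is not None and pair in adjacency):
                klass = BREAK_PARTNER_END
            elif (_run_orientation_consistent(left)
                  and _run_orientation_consistent(right)):
                klass = BREAK_REARRANGEMENT
            else:
                klass = BREAK_POOR_SCAFFOLDING
            break_sites.append(BreakSite(
                scaffold=scaffold,
                pos0=(left[-1].end + right[0].start) // 2,
                left_partner=left[0].partner_scaffold,
                right_partner=right[0].partner_scaffold,
                left_genes=len(left), right_genes=len(right),
                klass=klass,
            ))
    return SyntenyReport(links=links, link_class=link_class,
                         break_sites=break_sites)


def read_anchors_tsv(path) -> List[GeneAnchor]:
    """Anchor table: transcript, scaffold, start, end, strand,
    masked_fraction, nested, partner_scaffold, partner_start, partner_end,
    partner_len, homology_type (one-to-one / other)."""
    out: List[GeneAnchor] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"anchor line has {len(f)} columns, 12 required")
            out.append(GeneAnchor(
                transcript=f[0], scaffold=f[1], start=int(f[2]), end=int(f[3]),
                strand=f[4], masked_fraction=float(f[5]),
                nested=f[6].lower() in ("1", "true", "yes"),
                partner_scaffold=f[7] if f[7] != "." else None,
                partner_start=int(f[8]), partner_end=int(f[9]),
                partner_length=int(f[10]),
                one_to_one=f[11] == "one-to-one",
            ))
    return out
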