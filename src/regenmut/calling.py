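"""Count-based variant calling from multi-sample pileups.

The caller embodies the two-stage scheme used for isogenic cohorts: a
permissive per-sample scan (alt fraction >= 0.15, depth >= 20, every other
sample >= 90% reference) followed by hard postfilters (>= 7 supporting reads,
<= 1 alt read in any other sample, candidate depth within 25-130x, mean
mapping quality >= 40). All thresholds are configurable via CallerParams.

Both the unique (sample-private) and the shared caller operate on the same
PileupTable; shared variants carried by every sample are labeled
``germline-shared``, the rest ``lineage-specific``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .io import Genome, PileupSite, PileupTable

GERMLINE_SHARED = "germline-shared"
LINEAGE_SPECIFIC = "lineage-specific"
DE_NOVO_CLONAL = "de-novo-clonal"
SUBCLONAL = "subclonal"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PYRIMIDINES = frozenset("CT")
SUBSTITUTION_CHANNELS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CallerParams:
    """Thresholds of the permissive scan and the postfilter."""

    min_sample_freq: float = 0.15
    min_other_ref_freq: float = 0.9
    cov_limit: int = 20
    min_support: int = 7
    max_other_alt: int = 1
    cov_range: Tuple[int, int] = (25, 130)
    min_mean_mq: float = 40.0

    def validate(self) -> None:
        if not 0 < self.min_sample_freq < 1:
            raise ValueError(f"min_sample_freq {self.min_sample_freq} not in (0,1)")
        if not 0 <= self.min_other_ref_freq <= 1:
            raise ValueError("min_other_ref_freq outside [0,1]")
        lo, hi = self.cov_range
        if lo >= hi:
            raise ValueError(f"cov_range low {lo} must be < high {hi}")
        if min(self.cov_limit, self.min_support, self.max_other_alt, lo) < 0:
            raise ValueError("read thresholds must be >= 0")


@dataclass
class VariantCall:
    """A located ref -> alt event with its carriers and per-sample evidence."""

    scaffold: str
    pos0: int
    ref: str
    alt: str  # base, or indel key "I:<seq>" / "D:<len>"
    carriers: List[str]
    allele_fractions: Dict[str, float] = field(default_factory=dict)
    support: Dict[str, int] = field(default_factory=dict)
    label: Optional[str] = None
    context: Optional[str] = None   # reference trinucleotide around pos0
    channel: Optional[str] = None   # pyrimidine-collapsed, e.g. "A[C>T]G"

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.scaffold, self.pos0, self.ref, self.alt)

    @property
    def variant_type(self) -> str:
        return classify_alt(self.ref, self.alt)


def classify_alt(ref: str, alt: str) -> str:
    """Classify an alt key as 'SNV', 'insertion' or 'deletion'."""
    if alt.startswith("I:"):
        return "insertion"
    if alt.startswith("D:"):
        return "deletion"
    if alt == ref:
        raise ValueError(f"alt equals ref ({ref!r})")
    if alt in "ACGT" and len(alt) == 1:
        return "SNV"
    raise ValueError(f"unrecognized alt key {alt!r}")


def _site_alleles(site: PileupSite) -> List[str]:
    """Alleles with any read support at a site, reference excluded."""
    alleles = set()
    for cell in site.cells.values():
        for key, count in cell.counts.items():
            if count > 0 and key != site.ref:
                alleles.add(key)
    return sorted(alleles)


def call_unique(pileup: PileupTable, params: Optional[CallerParams] = None
                ) -> List[VariantCall]:
    """Detect sample-private variants.

    A call for sample s, allele a is emitted iff the permissive criteria hold
    (alt fraction >= min_sample_freq in s, depth >= cov_limit in s, reference
    fraction >= min_other_ref_freq in every other sample) AND the postfilter
    passes (support >= min_support, <= max_other_alt reads of a in every other
    sample, depth within cov_range, mean MQ >= min_mean_mq). An other-sample
    with zero depth cannot confirm its reference state and fails the check.
    """
    params = params or CallerParams()
    params.validate()
    if len(pileup.samples) < 3:
        raise ValueError("unique calling requires >= 3 samples for noise filtering")
    lo, hi = params.cov_range
    calls: List[VariantCall] = []
    for site in pileup.sites:
        for allele in _site_alleles(site):
            for s in pileup.samples:
                cell = site.cells[s]
                if cell.depth < params.cov_limit:
                    continue
                if cell.allele_fraction(allele) < params.min_sample_freq:
                    continue
                others = [o for o in pileup.samples if o != s]
                if any(
                    site.cells[o].depth == 0
                    or site.cells[o].allele_fraction(site.ref)
                    < params.min_other_ref_freq
                    for o in others
                ):
                    continue
                # postfilter
                if cell.allele_count(allele) < params.min_support:
                    continue
                if any(site.cells[o].allele_count(allele) > params.max_other_alt
                       for o in others):
                    continue
                if not lo <= cell.depth <= hi:
                    continue
                if cell.mean_mq < params.min_mean_mq:
                    continue
                calls.append(VariantCall(
                    scaffold=site.scaffold, pos0=site.pos0, ref=site.ref,
                    alt=allele, carriers=[s],
                    allele_fractions={s: cell.allele_fraction(allele)},
                    support={s: cell.allele_count(allele)},
                ))
    return calls


def call_shared(pileup: PileupTable, params: Optional[CallerParams] = None,
                min_carriers: int = 2) -> List[VariantCall]:
    """Detect variants shared by >= min_carriers samples.

    Carriers are samples with alt fraction >= min_sample_freq; all remaining
    samples must show <= max_other_alt reads of the allele. Variants carried
    by every sample are labeled germline-shared, the rest lineage-specific.
    """
    params = params or CallerParams()
    params.validate()
    if min_carriers < 2:
        raise ValueError("min_carriers must be >= 2 (use call_unique)")
    calls: List[VariantCall] = []
    n = len(pileup.samples)
    for site in pileup.sites:
        for allele in _site_alleles(site):
            carriers = [
                s for s in pileup.samples
                if site.cells[s].allele_fraction(allele) >= params.min_sample_freq
            ]
            if len(carriers) < min_carriers:
                continue
            rest = [s for s in pileup.samples if s not in carriers]
            if any(site.cells[o].allele_count(allele) > params.max_other_alt
                   for o in rest):
                continue
            label = GERMLINE_SHARED if len(carriers) == n else LINEAGE_SPECIFIC
            calls.append(VariantCall(
                scaffold=site.scaffold, pos0=site.pos0, ref=site.ref,
                alt=allele, carriers=carriers,
                allele_fractions={
                    s: site.cells[s].allele_fraction(allele) for s in carriers
                },
                support={s: site.cells[s].allele_count(allele) for s in carriers},
                label=label,
            ))
    return calls


# ---------------------------------------------------------------------------
# Trinucleotide context annotation (pyrimidine collapse)
# ---------------------------------------------------------------------------

def collapse_substitution(context: str, ref: str, alt: str) -> Tuple[str, str]:
    """Map a strand-resolved (context, ref>alt) onto its pyrimidine channel.

    Returns (collapsed context, 'C>T'-style substitution). When the mutated
    base is a purine, both the trinucleotide and the substitution are
    reverse-complemented so that the central base is C or T.
    """
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} not centered on ref {ref!r}")
    if ref == alt:
        raise ValueError("ref == alt")
    if ref in PYRIMIDINES:
        return context, f"{ref}>{alt}"
    return revcomp(context), f"{revcomp(ref)}>{revcomp(alt)}"


def annotate_context(genome: Genome, call: VariantCall) -> VariantCall:
    """Attach the reference trinucleotide and the collapsed channel to an SNV.

    Sites whose context contains N get channel=None (excluded from spectra).
    """
    if call.variant_type != "SNV":
        raise ValueError("context annotation applies to SNVs only")
    seq = genome[call.scaffold]
    if call.pos0 < 1 or call.pos0 > len(seq) - 2:
        raise ValueError(
            f"SNV at {call.scaffold}:{call.pos0} too close to scaffold edge"
        )
    context = seq[call.pos0 - 1: call.pos0 + 2]
    call.context = context
    if "N" in context:
        call.channel = None
        return call
    ctx, sub = collapse_substitution(context, call.ref, call.alt)
    call.channel = f"{ctx[0]}[{sub}]{ctx[2]}"
    return call


def partition_by_sample(calls: Iterable[VariantCall]) -> Dict[str, List[VariantCall]]:
    """Group single-carrier calls by their carrier sample."""
    out: Dict[str, List[VariantCall]] = {}
    for call in calls:
        for s in call.carriers:
            out.setdefault(s, []).append(call)
    return out
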