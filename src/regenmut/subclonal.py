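"""Ploidy inference, subclonal support of filial mutations in ancestors,
cell-fraction conversion and mosaicism summaries.

A clonal heterozygous single-copy variant sits at allele fraction 1/ploidy;
a subclonal one confined to a fraction c of cells sits at c/ploidy, so the
carrying cell fraction is ploidy x allele fraction (capped at 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .calling import VariantCall
from .io import IntervalMask, PileupTable


@dataclass
class AFObservation:
    variant: Tuple[str, int, str, str]   # scaffold, pos0, ref, alt
    sample: str
    alt_reads: int
    depth: int
    supported: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.depth <= 0 or not 0 <= self.alt_reads <= self.depth:
            raise ValueError("invalid alt/depth pair")

    @property
    def allele_fraction(self) -> float:
        return self.alt_reads / self.depth


@dataclass
class PloidyCall:
    peaks: List[float]              # peak locations as allele fractions
    ploidy: Optional[int]           # None when undetermined
    consistent: bool = True


def infer_ploidy(af_values: Sequence[float], bin_width: float = 0.02,
                 min_observations: int = 100) -> PloidyCall:
    """Infer ploidy from the allele-fraction histogram of germline variants.

    The histogram (smoothed by a 3-bin moving average) of heterozygous
    germline allele fractions peaks at k/ploidy; the lowest peak determines
    the ploidy and the remaining peaks are checked for consistency
    (each within half a bin + 0.03 of a multiple of 1/ploidy).
    """
    af = np.asarray(af_values, dtype=float)
    if len(af) < min_observations:
        raise ValueError(
            f"need >= {min_observations} germline AF observations, got {len(af)}"
        )
    from scipy.signal import find_peaks

    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    hist, _ = np.histogram(af, bins=edges)
    smooth = np.convolve(hist, np.ones(3) / 3, mode="same")
    # prominence and a 3-bin separation suppress the comb artifacts that
    # integer read counts at near-constant depth leave in the AF histogram
    idx, _ = find_peaks(smooth, height=0.5 * smooth.max(),
                        prominence=0.25 * smooth.max(), distance=3)
    # refine each peak as the mean AF of observations nearest to it
    peaks: List[float] = []
    if len(idx):
        centers = (edges[idx] + edges[idx + 1]) / 2
        nearest = np.argmin(np.abs(af[:, None] - centers[None, :]), axis=1)
        for j in range(len(centers)):
            sel = af[nearest == j]
            peaks.append(float(sel.mean()) if len(sel) else float(centers[j]))
    if not peaks:
        return PloidyCall(peaks=[], ploidy=None, consistent=False)
    lowest = min(peaks)
    ploidy = int(round(1 / lowest))
    tol = bin_width / 2 + 0.03
    consistent = all(
        abs(p - round(p * ploidy) / ploidy) <= tol and round(p * ploidy) >= 1
        for p in peaks
    )
    return PloidyCall(peaks=sorted(peaks), ploidy=ploidy, consistent=consistent)


def subclonal_support(filial_calls: Iterable[VariantCall], pileup: PileupTable,
                      target_sample: str, min_reads: int = 2,
                      error_rate: float = 0.002, alpha: float = 0.05
                      ) -> List[AFObservation]:
    """Extract the target sample's alt/depth at each filial clonal variant.

    An observation is flagged supported iff alt reads >= min_reads and a
    one-sided binomial test against the per-allele error rate (error_rate/3)
    rejects at level alpha. Variants whose site is absent from the pileup
    are skipped with a warning.
    """
    if target_sample not in pileup.samples:
        raise ValueError(f"sample {target_sample!r} not in pileup")
    by_pos = {(s.scaffold, s.pos0): s for s in pileup.sites}
    out: List[AFObservation] = []
    for call in filial_calls:
        site = by_pos.get((call.scaffold, call.pos0))
        if site is None:
            warnings.warn(
                f"site {call.scaffold}:{call.pos0} absent from pileup; skipped"
            )
            continue
        cell = site.cells[target_sample]
        if cell.depth == 0:
            continue
        alt = cell.allele_count(call.alt)
        supported = False
        if alt >= min_reads:
            p = stats.binomtest(alt, cell.depth, error_rate / 3,
                                alternative="greater").pvalue
            supported = p < alpha
        out.append(AFObservation(
            variant=call.key, sample=target_sample,
            alt_reads=alt, depth=cell.depth, supported=supported,
        ))
    return out


def cell_fraction(af: float, ploidy: int) -> float:
    """Fraction of cells carrying a single-copy heterozygous variant."""
    if not 0 <= af <= 1:
        raise ValueError("allele fraction outside [0,1]")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    return min(1.0, ploidy * af)


@dataclass
class MosaicismSummary:
    median_af: float
    af_range: Tuple[float, float]
    median_cell_fraction: float
    max_cell_fraction: float
    observations: List[AFObservation] = field(default_factory=list)


def mosaicism_summary(observations: Sequence[AFObservation], ploidy: int
                      ) -> Optional[MosaicismSummary]:
    """Summaries over SUPPORTED observations only; None when none supported."""
    supported = [o for o in observations if o.supported]
    if not supported:
        warnings.warn("no supported subclonal observations")
        return None
    afs = np.array([o.allele_fraction for o in supported])
    cfs = np.array([cell_fraction(float(a), ploidy) for a in afs])
    return MosaicismSummary(
        median_af=float(np.median(afs)),
        af_range=(float(afs.min()), float(afs.max())),
        median_cell_fraction=float(np.median(cfs)),
        max_cell_fraction=float(cfs.max()),
        observations=supported,
    )


def af_agreement(obs_method1: Sequence[AFObservation],
                 obs_method2: Sequence[AFObservation]) -> float:
    """Pearson r of allele fractions over variants measured by both methods."""
    af1 = {o.variant: o.allele_fraction for o in obs_method1}
    af2 = {o.variant: o.allele_fraction for o in obs_method2}
    shared = sorted(set(af1) & set(af2))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} variants shared between methods")
    a = np.array([af1[v] for v in shared])
    b = np.array([af2[v] for v in shared])
    return float(np.corrcoef(a, b)[0, 1])


def amplicon_resample(true_fractions: Dict[Tuple[str, int, str, str], float],
                      depth: int, rng, sample: str = "amplicon"
                      ) -> List[AFObservation]:
    """Model deep amplicon sequencing as a second binomial readout of the
    same true site fractions at a fixed (much higher) depth."""
    if depth <= 0:
        raise ValueError("amplicon depth must be positive")
    return [
        AFObservation(variant=v, sample=sample,
                      alt_reads=int(rng.binomial(depth, f)), depth=depth,
                      supported=True)
        for v, f in true_fractions.items()
    ]


def uniqueness_window_check(variant: Tuple[str, int], mask: IntervalMask,
                            scaffold_length: int, window: int = 250) -> bool:
    """True iff the whole +-window around the variant is uniquely mappable.

    Windows straddling scaffold bounds are not fully checkable and return
    False.
    """
    scaffold, pos0 = variant
    start, end = pos0 - window, pos0 + window + 1
    if start < 0 or end > scaffold_length:
        return False
    return mask.contains_interval(scaffold, start, end)
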