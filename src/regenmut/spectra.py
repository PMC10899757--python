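"""Substitution spectra, spectrum correlation, genome triplet frequencies and
CpG-depletion analysis.

Spectra use the pyrimidine-collapse convention: each SNV is reported on the
strand whose mutated base is C or T, giving 6 substitution classes or 96
trinucleotide-resolved channels (COSMIC channel ordering).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .calling import SUBSTITUTION_CHANNELS, VariantCall, revcomp
from .io import Genome

CHANNELS_6 = SUBSTITUTION_CHANNELS
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in CHANNELS_6
    for five in "ACGT"
    for three in "ACGT"
)


@dataclass
class Spectrum:
    channels: Tuple[str, ...]
    values: np.ndarray            # counts, or frequencies if normalized
    n_mutations: int
    normalized: bool = False

    def normalize(self) -> "Spectrum":
        if self.n_mutations == 0:
            raise ValueError("cannot normalize an empty spectrum")
        return Spectrum(self.channels, self.values / self.values.sum(),
                        self.n_mutations, normalized=True)

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.channels, self.values.tolist()))


def build_spectrum(calls: Iterable[VariantCall], genome: Optional[Genome] = None,
                   n_channels: int = 6) -> Spectrum:
    """Accumulate SNV calls into a 6- or 96-channel spectrum.

    Calls must carry a collapsed channel (annotate_context); calls without one
    are annotated on the fly when a genome is given. Indels and N-context
    SNVs are skipped (their number is not part of n_mutations).
    """
    if n_channels not in (6, 96):
        raise ValueError("n_channels must be 6 or 96")
    from .calling import annotate_context

    channels = CHANNELS_6 if n_channels == 6 else CHANNELS_96
    index = {c: i for i, c in enumerate(channels)}
    values = np.zeros(len(channels))
    n = 0
    for call in calls:
        if call.variant_type != "SNV":
            continue
        if call.channel is None and genome is not None:
            annotate_context(genome, call)
        if call.channel is None:
            continue
        key = call.channel if n_channels == 96 else call.channel[2:5]
        values[index[key]] += 1
        n += 1
    return Spectrum(channels=channels, values=values, n_mutations=n)


def spectrum_correlation(s1: Spectrum, s2: Spectrum) -> float:
    """Pearson correlation of two spectra over their shared channel set."""
    if s1.channels != s2.channels:
        raise ValueError("spectra have different channel sets")
    a = s1.normalize().values if not s1.normalized else s1.values
    b = s2.normalize().values if not s2.normalized else s2.values
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance spectrum: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Genome triplets and CpG
# ---------------------------------------------------------------------------

ALL_TRIPLETS = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)


def _collapse_triplet(t: str) -> str:
    return min(t, revcomp(t))


@dataclass
class TripletProfile:
    """Forward-strand 64-triplet frequencies plus a strand-collapsed view."""

    frequencies: Dict[str, float]            # 64 forward-strand triplets
    collapsed: Dict[str, float]              # 32 canonical triplets
    gc_count: Dict[str, int]                 # G/C bases per triplet (0-3)
    cpg_flag: Dict[str, bool]                # triplet contains the CG dinucleotide
    n_windows: int


def genome_triplets(genome: Genome) -> TripletProfile:
    """Count overlapping 3-mers on the forward strand (N windows skipped)."""
    counts: Counter = Counter()
    for seq in genome.sequences.values():
        for i in range(len(seq) - 2):
            t = seq[i: i + 3]
            if "N" not in t:
                counts[t] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("all triplet windows contain N")
    freqs = {t: counts.get(t, 0) / total for t in ALL_TRIPLETS}
    collapsed: Dict[str, float] = {}
    for t, f in freqs.items():
        collapsed[_collapse_triplet(t)] = collapsed.get(_collapse_triplet(t), 0) + f
    return TripletProfile(
        frequencies=freqs,
        collapsed=collapsed,
        gc_count={t: sum(b in "GC" for b in t) for t in ALL_TRIPLETS},
        cpg_flag={t: "CG" in t for t in ALL_TRIPLETS},
        n_windows=total,
    )


@dataclass
class CpGDepletion:
    per_stratum: Dict[int, float]   # G/C count -> mean CpG freq / mean non-CpG freq
    ratio: float                    # mean of stratum ratios


def cpg_depletion(profile: TripletProfile) -> CpGDepletion:
    """Compare CpG-containing triplets with GC-matched non-CpG triplets.

    For each G/C-count stratum the mean frequency of CpG-containing triplets
    is divided by the mean frequency of non-CpG triplets of the same
    composition; a ratio near 1 means no depletion signal (hence no evidence
    of CpG methylation), well below 1 means CpG depletion as in heavily
    methylated vertebrate genomes.
    """
    per_stratum: Dict[int, float] = {}
    for gc in range(4):
        cpg = [profile.frequencies[t] for t in ALL_TRIPLETS
               if profile.gc_count[t] == gc and profile.cpg_flag[t]]
        non = [profile.frequencies[t] for t in ALL_TRIPLETS
               if profile.gc_count[t] == gc and not profile.cpg_flag[t]]
        if not cpg or not non:
            continue
        mean_non = float(np.mean(non))
        if mean_non == 0:
            continue
        per_stratum[gc] = float(np.mean(cpg)) / mean_non
    if not per_stratum:
        raise ValueError("no stratum contains both CpG and non-CpG triplets")
    return CpGDepletion(per_stratum=per_stratum,
                        ratio=float(np.mean(list(per_stratum.values()))))
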