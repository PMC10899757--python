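"""Mappability masking, de novo mutation-rate estimation and burden tests.

The per-generation rate is count / (n_offspring x L_mappable) per mutation
type, i.e. each heterozygous event is counted once per surveyed haploid
position (the normalization under which the worked-example rates are
arithmetically consistent); a per-allele variant (dividing by the ploidy) is
available behind ``per_allele=True``. Printed rates are truncated, not
rounded, to three significant digits (see :func:`display_rate`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .calling import VariantCall
from .io import Genome, IntervalMask, mask_from_intervals


# ---------------------------------------------------------------------------
# k-mer mappability
# ---------------------------------------------------------------------------

_ENC = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
_ENC_RC = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _ENC_RC[_b] = 3 - _i


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack k consecutive 2-bit codes into one integer per window.

    For k <= 31 a single uint64 suffices; windows touching an invalid base
    (N) are marked with -1 in the validity pass by the caller.
    """
    n = len(codes) - k + 1
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | codes[j: j + n].astype(np.uint64)
    return out


def kmer_mappability_mask(genome: Genome, k: int = 50) -> IntervalMask:
    """Positions whose k-mer (canonical form: lexicographic min of the k-mer
    and its reverse complement) occurs exactly once in the genome.

    The mask holds merged intervals of mappable k-mer START positions.
    """
    if any(len(s) < k for s in genome.sequences.values()):
        raise ValueError(f"k={k} exceeds the shortest scaffold")
    # 2-bit packing: k<=31 fits one uint64, else high/low word pair
    per_scaf: List[Tuple[str, np.ndarray, List[np.ndarray]]] = []
    all_words: List[np.ndarray] = []
    for scaf, seq in genome.sequences.items():
        raw = np.frombuffer(seq.encode(), dtype=np.uint8)
        fwd = _ENC[raw]
        rc = _ENC_RC[raw][::-1]
        n = len(seq) - k + 1
        valid = np.ones(n, dtype=bool)
        bad = np.flatnonzero(fwd < 0)
        for b in bad:
            valid[max(0, b - k + 1): b + 1] = False
        fwd_safe = np.where(fwd < 0, 0, fwd)
        rc_safe = np.where(rc < 0, 0, rc)
        if k <= 31:
            fwd_words = _kmer_codes(fwd_safe, k)[:, None]
            rc_words_rev = _kmer_codes(rc_safe, k)[:, None]
        else:
            k_hi = k - 31
            fwd_words = np.stack(
                [_kmer_codes(fwd_safe[:len(fwd_safe) - 31], k_hi),
                 _kmer_codes(fwd_safe[k_hi:], 31)], axis=1)
            rc_words_rev = np.stack(
                [_kmer_codes(rc_safe[:len(rc_safe) - 31], k_hi),
                 _kmer_codes(rc_safe[k_hi:], 31)], axis=1)
        # rc_words_rev[i] is the word of the rc k-mer starting at rc-pos i,
        # which corresponds to the forward k-mer starting at n-1-i
        rc_words = rc_words_rev[::-1]
        # canonical: lexicographic min of (fwd, rc) word tuples
        if fwd_words.shape[1] == 1:
            take_rc = rc_words[:, 0] < fwd_words[:, 0]
        else:
            take_rc = (rc_words[:, 0] < fwd_words[:, 0]) | (
                (rc_words[:, 0] == fwd_words[:, 0])
                & (rc_words[:, 1] < fwd_words[:, 1]))
        canon = np.where(take_rc[:, None], rc_words, fwd_words)
        per_scaf.append((scaf, valid, canon))
        all_words.append(canon[valid])
    if not all_words or all(len(w) == 0 for w in all_words):
        return IntervalMask({})
    stacked = np.concatenate(all_words, axis=0)
    # count duplicates among valid canonical words
    view_cols = [stacked[:, j] for j in range(stacked.shape[1])]
    order = np.lexsort(view_cols[::-1])
    s = stacked[order]
    new_group = np.ones(len(s), dtype=bool)
    new_group[1:] = np.any(s[1:] != s[:-1], axis=1)
    group_id = np.cumsum(new_group) - 1
    group_sizes = np.bincount(group_id)
    unique_sorted = group_sizes[group_id] == 1
    unique_flag = np.empty(len(s), dtype=bool)
    unique_flag[order] = unique_sorted

    intervals: Dict[str, List[Tuple[int, int]]] = {}
    cursor = 0
    for scaf, valid, canon in per_scaf:
        n_valid = int(valid.sum())
        flags = np.zeros(len(valid), dtype=bool)
        flags[valid] = unique_flag[cursor: cursor + n_valid]
        cursor += n_valid
        if flags.any():
            idx = np.flatnonzero(flags)
            breaks = np.flatnonzero(np.diff(idx) > 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [len(idx) - 1]))
            intervals[scaf] = [
                (int(idx[a]), int(idx[b]) + 1) for a, b in zip(starts, ends)
            ]
    return mask_from_intervals(intervals)


def restrict_calls(calls: Iterable[VariantCall], mask: IntervalMask
                   ) -> List[VariantCall]:
    """Keep calls whose position lies within the mask (half-open intervals)."""
    return [c for c in calls if mask.contains(c.scaffold, c.pos0)]


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

@dataclass
class RateEstimate:
    n_offspring: int
    L_mappable: int
    counts: Dict[str, int]          # keys: SNV, indel, overall
    rates: Dict[str, float]

    def display(self, kind: str) -> str:
        return display_rate(self.rates[kind])


def display_rate(x: float) -> str:
    """Three significant digits by truncation toward zero, scientific form.

    display(1.316e-8) == '1.31e-08'; display(1.727e-8) == '1.72e-08'.
    """
    if x == 0:
        return "0.00e+00"
    exp = math.floor(math.log10(abs(x)))
    mantissa = x / 10 ** exp
    mantissa = math.trunc(mantissa * 100) / 100
    # guard against float droop at the representation boundary, e.g.
    # 1.31 stored as 1.3099999...
    if math.trunc((abs(x) / 10 ** exp) * 100 + 1e-9) != math.trunc(
            abs(mantissa) * 100):
        mantissa = math.trunc((x / 10 ** exp) * 100 + math.copysign(1e-9, x)) / 100
    return f"{mantissa:.2f}e{exp:+03d}"


def estimate_rate(mappable_calls: Sequence[VariantCall], n_offspring: int,
                  L_mappable: int, per_allele: bool = False,
                  ploidy: int = 3) -> RateEstimate:
    """Per-type de novo rate: count / (n_offspring x L_mappable).

    ``per_allele=True`` divides additionally by the ploidy, counting each
    surveyed haploid position ploidy times.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    if L_mappable <= 0:
        raise ValueError("L_mappable must be positive")
    n_snv = sum(1 for c in mappable_calls if c.variant_type == "SNV")
    n_indel = len(list(mappable_calls)) - n_snv
    denom = n_offspring * L_mappable * (ploidy if per_allele else 1)
    counts = {"SNV": n_snv, "indel": n_indel, "overall": n_snv + n_indel}
    rates = {k: v / denom for k, v in counts.items()}
    return RateEstimate(n_offspring=n_offspring, L_mappable=L_mappable,
                        counts=counts, rates=rates)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass
class BurdenComparison:
    mean_control: float
    mean_regenerated: float
    sd_control: float
    sd_regenerated: float
    fold_change: Optional[float]
    t_statistic: Optional[float]
    degrees_of_freedom: Optional[float]
    p_value: Optional[float]


def compare_burden(counts_control: Sequence[float],
                   counts_regenerated: Sequence[float],
                   equal_var: bool = False) -> BurdenComparison:
    """Unpaired two-sided t-test on per-offspring mutation counts.

    Welch (unequal-variance) by default; sample SDs use the n-1 denominator.
    Groups with fewer than 2 values get means only, with a warning.
    """
    a = np.asarray(counts_control, dtype=float)
    b = np.asarray(counts_regenerated, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    mean_c, mean_r = float(a.mean()), float(b.mean())
    sd_c = float(a.std(ddof=1)) if len(a) > 1 else float("nan")
    sd_r = float(b.std(ddof=1)) if len(b) > 1 else float("nan")
    fold = mean_r / mean_c if mean_c > 0 and mean_r > 0 else None
    if len(a) < 2 or len(b) < 2:
        warnings.warn("a group has < 2 values; t-test skipped")
        return BurdenComparison(mean_c, mean_r, sd_c, sd_r, fold,
                                None, None, None)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return BurdenComparison(mean_c, mean_r, sd_c, sd_r, fold,
                            float(res.statistic), float(res.df),
                            float(res.pvalue))


def two_proportion_chi2(k1: int, n1: int, k2: int, n2: int,
                        correction: bool = False) -> Tuple[float, float]:
    """Pearson chi-square on the 2x2 table (no continuity correction by
    default). Returns (statistic, p)."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError(f"invalid proportion {k}/{n}")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 1).any():
        warnings.warn("expected cell count below 1")
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def lander_waterman(read_length: float, n_reads: float, coverage: float) -> float:
    """Genome size G = L * N / C."""
    if read_length <= 0 or n_reads <= 0:
        raise ValueError("read length and read count must be positive")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    return read_length * n_reads / coverage
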