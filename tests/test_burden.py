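"""Mappability, rate arithmetic, display truncation, burden statistics —
each checked against an independent oracle where one exists."""

import numpy as np
import pytest
from scipy import stats

from regenmut.burden import (compare_burden, display_rate, estimate_rate,
                             kmer_mappability_mask, lander_waterman,
                             restrict_calls, two_proportion_chi2)
from regenmut.calling import VariantCall
from regenmut.io import Genome, mask_from_intervals

L_MAPPABLE = 303_930_000  # uniquely mappable assembly fraction, bp


def snv_calls(n, sample="F", start=10):
    return [VariantCall("s", start + 10 * i, "A", "T", [sample])
            for i in range(n)]


def indel_calls(n, sample="F", start=5000):
    return [VariantCall("s", start + 10 * i, "A", "D:1", [sample])
            for i in range(n)]


# ---------------------------------------------------------------------------
# k-mer mappability
# ---------------------------------------------------------------------------

def brute_force_mappable(genome: Genome, k: int):
    """Independent oracle: dictionary count of canonical k-mers."""
    from collections import Counter

    def rc(s):
        return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]

    counts = Counter()
    for seq in genome.sequences.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i: i + k]
            if "N" not in kmer:
                counts[min(kmer, rc(kmer))] += 1
    out = {}
    for scaf, seq in genome.sequences.items():
        flags = []
        for i in range(len(seq) - k + 1):
            kmer = seq[i: i + k]
            flags.append("N" not in kmer and counts[min(kmer, rc(kmer))] == 1)
        out[scaf] = flags
    return out


class TestKmerMappability:
    @pytest.mark.parametrize("k", [21, 50])
    def test_agreement_with_brute_force_on_20kb(self, k):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=18_000))
        # plant a duplicated 2 kb block and an N patch
        dup = seq[1000:3000]
        genome = Genome({"a": seq[:9000] + dup + seq[9000:],
                         "b": dup[:500] + "N" * 30 + seq[-1000:]})
        mask = kmer_mappability_mask(genome, k=k)
        expected = brute_force_mappable(genome, k)
        for scaf, flags in expected.items():
            for pos, flag in enumerate(flags):
                assert mask.contains(scaf, pos) == flag, (scaf, pos)

    def test_unique_random_genome_fully_mappable(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        mask = kmer_mappability_mask(Genome({"x": seq}), k=31)
        assert mask.total_length == 5000 - 31 + 1

    def test_duplicated_block_interior_unmappable(self):
        rng = np.random.default_rng(2)
        block = "".join(rng.choice(list("ACGT"), size=10_000))
        flank = "".join(rng.choice(list("ACGT"), size=5_000))
        genome = Genome({"x": block + flank + block})
        mask = kmer_mappability_mask(genome, k=50)
        assert not mask.contains("x", 5000)          # inside first copy
        assert not mask.contains("x", 15_000 + 5000)  # inside second copy
        assert mask.contains("x", 10_000 + 2500)      # unique flank

    def test_k_longer_than_scaffold_rejected(self):
        with pytest.raises(ValueError):
            kmer_mappability_mask(Genome({"x": "ACGTACGT"}), k=50)


class TestRestrictCalls:
    def test_half_open_boundaries(self):
        mask = mask_from_intervals({"s": [(100, 200)]})
        kept = restrict_calls(
            [VariantCall("s", 100, "A", "T", ["F"]),
             VariantCall("s", 199, "A", "T", ["F"]),
             VariantCall("s", 200, "A", "T", ["F"])], mask)
        assert [c.pos0 for c in kept] == [100, 199]

    def test_empty_and_full_masks(self):
        calls = snv_calls(5)
        assert restrict_calls(calls, mask_from_intervals({})) == []
        full = mask_from_intervals({"s": [(0, 10_000)]})
        assert restrict_calls(calls, full) == calls


# ---------------------------------------------------------------------------
# Rates and the truncation display rule
# ---------------------------------------------------------------------------

class TestEstimateRate:
    def test_snv_worked_example(self):
        """16 mappable SNVs over 4 offspring at L = 303.93 Mb."""
        est = estimate_rate(snv_calls(16), n_offspring=4,
                            L_mappable=L_MAPPABLE)
        assert est.rates["SNV"] == pytest.approx(1.316e-8, rel=1e-3)
        assert est.display("SNV") == "1.31e-08"

    def test_overall_worked_example(self):
        est = estimate_rate(snv_calls(16) + indel_calls(5), n_offspring=4,
                            L_mappable=L_MAPPABLE)
        assert est.counts == {"SNV": 16, "indel": 5, "overall": 21}
        assert est.rates["overall"] == pytest.approx(1.727e-8, rel=1e-3)
        assert est.display("overall") == "1.72e-08"

    def test_empty_call_set_rate_zero(self):
        est = estimate_rate([], n_offspring=4, L_mappable=L_MAPPABLE)
        assert est.rates["overall"] == 0.0

    def test_zero_offspring_rejected(self):
        with pytest.raises(ValueError):
            estimate_rate(snv_calls(1), n_offspring=0, L_mappable=100)

    def test_per_allele_divides_by_ploidy(self):
        a = estimate_rate(snv_calls(6), 2, 1000)
        b = estimate_rate(snv_calls(6), 2, 1000, per_allele=True)
        assert a.rates["SNV"] == pytest.approx(3 * b.rates["SNV"])

    def test_rate_estimator_consistency(self):
        """Poisson-planted counts at lambda in {4, 13.5}, n = 200 offspring:
        relative error of the estimated rate vs lambda/L below 5%."""
        rng = np.random.default_rng(17)
        L = 1_000_000
        for lam in (4.0, 13.5):
            total = int(rng.poisson(lam, size=200).sum())
            est = estimate_rate(snv_calls(total), n_offspring=200, L_mappable=L)
            assert abs(est.rates["SNV"] / (lam / L) - 1) < 0.05


class TestDisplayRate:
    @pytest.mark.parametrize("x,expected", [
        (1.316e-8, "1.31e-08"),
        (1.727e-8, "1.72e-08"),
        (9.999e-9, "9.99e-09"),
        (1.0, "1.00e+00"),
        (0.0, "0.00e+00"),
        (-2.345e-3, "-2.34e-03"),
    ])
    def test_truncation_not_rounding(self, x, expected):
        assert display_rate(x) == expected


# ---------------------------------------------------------------------------
# Burden comparison
# ---------------------------------------------------------------------------

def welch_oracle(a, b):
    """Textbook Welch t: independent of scipy's implementation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestCompareBurden:
    def test_study_counts(self):
        """Per-offspring SNV tuples matching the printed 5 +/- 2.94 and
        13.5 +/- 2.52 group summaries."""
        cmp = compare_burden([2, 4, 5, 9], [11, 13, 13, 17])
        assert cmp.mean_control == 5 and cmp.mean_regenerated == 13.5
        assert cmp.sd_control == pytest.approx(2.94, abs=0.005)
        assert cmp.sd_regenerated == pytest.approx(2.52, abs=0.005)
        assert cmp.fold_change == pytest.approx(2.7)
        assert cmp.p_value < 0.05

    def test_identical_groups(self):
        cmp = compare_burden([1, 2, 3], [1, 2, 3])
        assert cmp.fold_change == pytest.approx(1.0)
        assert cmp.t_statistic == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)

    def test_single_value_group_skips_test(self):
        with pytest.warns(UserWarning, match="skipped"):
            cmp = compare_burden([5], [1, 2, 3])
        assert cmp.p_value is None and cmp.mean_control == 5

    def test_welch_matches_textbook_formula(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3),
                           size=rng.integers(3, 12))
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3),
                           size=rng.integers(3, 12))
            cmp = compare_burden(a, b)
            t, df, p = welch_oracle(a, b)
            assert cmp.t_statistic == pytest.approx(t, abs=1e-10)
            assert cmp.degrees_of_freedom == pytest.approx(df, abs=1e-10)
            assert cmp.p_value == pytest.approx(p, abs=1e-10)


class TestTwoProportionChi2:
    def test_equal_proportions_null(self):
        chi2, p = two_proportion_chi2(50, 100, 25, 50)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        """Pearson 2x2 formula: chi2 = N(ad - bc)^2 / (row/col products)."""
        for (k1, n1, k2, n2) in [(50, 100, 100, 120), (30, 90, 60, 80),
                                 (737, 1000, 833, 1000)]:
            a, b = k1, n1 - k1
            c, d = k2, n2 - k2
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d))
            chi2, _ = two_proportion_chi2(k1, n1, k2, n2)
            assert chi2 == pytest.approx(expected, abs=1e-10)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_chi2(10, 5, 1, 10)


class TestLanderWaterman:
    def test_arithmetic(self):
        assert lander_waterman(150, 1_000_000, 50) == pytest.approx(3e6)
        assert lander_waterman(1, 12345, 1) == 12345

    def test_doubling_coverage_halves_size(self):
        assert lander_waterman(100, 1000, 20) \
            == pytest.approx(lander_waterman(100, 1000, 10) / 2)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            lander_waterman(100, 1000, 0)
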