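"""Haplotig purging, assembly statistics and synteny-link classification."""

import numpy as np
import pytest

from regenmut.assembly_qc import (BREAK_PARTNER_END, BREAK_POOR_SCAFFOLDING,
                                  BREAK_REARRANGEMENT, GeneAnchor, PurgeParams,
                                  assembly_stats, filter_anchors,
                                  purge_haplotigs, synteny_links)
from regenmut.io import Genome, SelfAlignment, mask_from_intervals


def random_genome(rng, lengths):
    return Genome({name: "".join(rng.choice(list("ACGT"), size=n))
                   for name, n in lengths.items()})


def aln(q, ql, qs, qe, t, tl, ts, te, mapq=60, div=0.02, s1=1000, s2=0,
        n_match=None):
    span = qe - qs
    return SelfAlignment(q_name=q, q_len=ql, q_start=qs, q_end=qe, strand="+",
                         t_name=t, t_len=tl, t_start=ts, t_end=te,
                         n_match=n_match if n_match is not None
                         else int(span * (1 - div)),
                         aln_len=span, mapq=mapq, divergence=div,
                         chain_score_primary=s1, chain_score_secondary=s2)


@pytest.fixture
def dup_setting():
    """Scaffold B (20 kb) duplicates a 15 kb block of A (100 kb)."""
    rng = np.random.default_rng(0)
    genome = random_genome(rng, {"A": 100_000, "B": 20_000})
    alignment = aln("B", 20_000, 2_000, 17_000, "A", 100_000, 40_000, 55_000)
    return genome, alignment


class TestPurgeHaplotigs:
    def test_duplicated_block_excised_from_shorter(self, dup_setting):
        genome, alignment = dup_setting
        purged, report = purge_haplotigs([alignment], genome)
        assert len(purged["B"]) == 20_000 - 15_000
        assert purged["A"] == genome["A"]
        assert report.removed_bp == 15_000
        assert purged["B"] == genome["B"][:2_000] + genome["B"][17_000:]

    @pytest.mark.parametrize("override,why", [
        (dict(mapq=30), "mapping quality below 60"),
        (dict(div=0.7), "divergence above 60%"),
        (dict(s1=1000, s2=600), "secondary chain score above half of primary"),
    ])
    def test_single_criterion_violations_prevent_excision(self, dup_setting,
                                                          override, why):
        genome, _ = dup_setting
        alignment = aln("B", 20_000, 2_000, 17_000, "A", 100_000,
                        40_000, 55_000, **override)
        purged, report = purge_haplotigs([alignment], genome)
        assert purged.sequences == genome.sequences, why
        assert report.removed_bp == 0

    def test_repeat_overlap_above_40_percent_blocks(self, dup_setting):
        genome, alignment = dup_setting
        # one repeat interval covering 50% of the aligned region on B
        repeats = mask_from_intervals({"B": [(2_000, 9_500)]})
        purged, report = purge_haplotigs([alignment], genome, repeats)
        assert report.removed_bp == 0
        # 30% overlap does not block
        repeats_ok = mask_from_intervals({"B": [(2_000, 6_500)]})
        _, report2 = purge_haplotigs([alignment], genome, repeats_ok)
        assert report2.removed_bp == 15_000

    def test_non_reciprocal_hit_not_excised(self):
        """B's best partner is C, so the A-B alignment is not one-to-one."""
        rng = np.random.default_rng(1)
        genome = random_genome(rng, {"A": 100_000, "B": 20_000, "C": 50_000})
        a_b = aln("B", 20_000, 0, 5_000, "A", 100_000, 10_000, 15_000)
        b_c = aln("B", 20_000, 5_000, 19_000, "C", 50_000, 0, 14_000)
        purged, report = purge_haplotigs([a_b, b_c], genome)
        assert "A" not in report.removed_regions
        removed_from_b = report.removed_regions.get("B", [])
        assert removed_from_b == [(5_000, 19_000)]  # only the reciprocal pair

    def test_self_alignment_ignored(self, dup_setting):
        genome, _ = dup_setting
        self_hit = aln("A", 100_000, 0, 50_000, "A", 100_000, 50_000, 100_000)
        purged, report = purge_haplotigs([self_hit], genome)
        assert purged.sequences == genome.sequences

    def test_unknown_scaffold_rejected(self, dup_setting):
        genome, _ = dup_setting
        bad = aln("Z", 20_000, 0, 5_000, "A", 100_000, 0, 5_000)
        with pytest.raises(ValueError, match="unknown scaffold"):
            purge_haplotigs([bad], genome)

    def test_idempotent_second_pass(self, dup_setting):
        genome, alignment = dup_setting
        purged, report = purge_haplotigs([alignment], genome)
        assert report.removed_bp > 0
        purged2, report2 = purge_haplotigs([alignment], purged)
        assert report2.removed_bp == 0
        assert report2.skipped_stale == 1
        assert purged2.sequences == purged.sequences

    def test_removed_bp_conservation(self):
        """Total removed equals merged retained-alignment length on the
        shorter scaffolds."""
        rng = np.random.default_rng(2)
        genome = random_genome(rng, {"A": 80_000, "B": 30_000})
        a1 = aln("B", 30_000, 1_000, 11_000, "A", 80_000, 0, 10_000)
        a2 = aln("B", 30_000, 8_000, 20_000, "A", 80_000, 30_000, 42_000)
        purged, report = purge_haplotigs([a1, a2], genome)
        merged_len = 20_000 - 1_000  # overlapping removals merged
        assert report.removed_bp == merged_len
        assert len(purged["B"]) == 30_000 - merged_len
        assert genome.total_length - purged.total_length == merged_len

    def test_emptied_scaffold_dropped(self):
        rng = np.random.default_rng(3)
        genome = random_genome(rng, {"A": 50_000, "B": 5_000})
        a = aln("B", 5_000, 0, 4_500, "A", 50_000, 0, 4_500)
        purged, report = purge_haplotigs([a], genome)
        assert "B" not in purged.sequences
        assert report.dropped_scaffolds == ["B"]


class TestAssemblyStats:
    def test_n50_worked_example(self):
        genome = Genome({f"s{i}": "A" * n for i, n in
                         enumerate([10, 20, 30, 40])})
        s = assembly_stats(genome)
        assert s.total_length == 100
        assert s.n50 == 30

    def test_single_scaffold(self):
        s = assembly_stats(Genome({"x": "ACGT" * 100}))
        assert s.n50 == 400 and s.n_scaffolds == 1

    def test_gc_ratio(self):
        assert assembly_stats(Genome({"x": "GGCC"})).gc_ratio == 1.0
        assert assembly_stats(Genome({"x": "GGCCNN"})).gc_ratio == 1.0

    def test_n50_matches_brute_force_definition(self):
        rng = np.random.default_rng(4)
        lengths = rng.integers(5, 500, size=30).tolist()
        genome = Genome({f"s{i}": "A" * n for i, n in enumerate(lengths)})
        # oracle: smallest length such that the sum of all scaffolds at
        # least that long reaches half the total
        total = sum(lengths)
        candidates = sorted(set(lengths), reverse=True)
        n50 = next(c for c in candidates
                   if sum(x for x in lengths if x >= c) >= total / 2)
        assert assembly_stats(genome).n50 == n50


def anchor(transcript, scaffold, start, partner, p_start, strand="+",
           length=500, masked=0.0, nested=False, one_to_one=True,
           p_len=200_000):
    return GeneAnchor(transcript=transcript, scaffold=scaffold, start=start,
                      end=start + length, strand=strand,
                      masked_fraction=masked, nested=nested,
                      one_to_one=one_to_one, partner_scaffold=partner,
                      partner_start=p_start, partner_end=p_start + length,
                      partner_length=p_len)


class TestFilterAnchors:
    def test_filters(self):
        anchors = [
            anchor("keep", "s", 0, "p", 0),
            anchor("masked", "s", 1000, "p", 0, masked=0.15),
            anchor("short", "s", 2000, "p", 0, length=300),
            anchor("nested", "s", 3000, "p", 0, nested=True),
            anchor("paralog", "s", 4000, "p", 0, one_to_one=False),
        ]
        kept = filter_anchors(anchors)
        assert [a.transcript for a in kept] == ["keep"]

    def test_boundary_is_strict(self):
        assert not anchor("x", "s", 0, "p", 0, length=300).passes_filters()
        assert anchor("x", "s", 0, "p", 0, length=301).passes_filters()
        assert not anchor("x", "s", 0, "p", 0, masked=0.10).passes_filters()


class TestSyntenyLinks:
    def test_single_partner_scaffolds(self):
        anchors = [anchor(f"t{i}", "s1", 1000 * i, "p1", 5000 * i)
                   for i in range(4)]
        report = synteny_links(anchors)
        assert report.link_class["s1"] == "single-link"
        assert report.break_sites == []
        assert report.n_single_link == 1

    def test_break_site_needs_two_genes_per_side(self):
        # A,A,A,B,B: break emitted; A,B,A: none (B run of one gene)
        good = [anchor(f"a{i}", "s", 1000 * i, "pA", 100_000 + 600 * i)
                for i in range(3)] \
            + [anchor(f"b{i}", "s", 5000 + 1000 * i, "pB", 100_000 + 600 * i)
               for i in range(2)]
        report = synteny_links(good)
        assert report.link_class["s"] == "multi-link"
        assert len(report.break_sites) == 1

        weak = [anchor("a0", "s", 0, "pA", 100_000),
                anchor("b0", "s", 1000, "pB", 100_000),
                anchor("a1", "s", 2000, "pA", 100_600)]
        assert synteny_links(weak).break_sites == []

    def test_reciprocal_translocation_classed_rearrangement(self):
        """Two scaffolds swapping partner blocks with consistent
        orientations: both break sites are rearrangements."""
        anchors = []
        for scaf, (first, second) in {"s1": ("pA", "pB"),
                                      "s2": ("pB", "pA")}.items():
            anchors += [anchor(f"{scaf}{first}{i}", scaf, 1000 * i, first,
                               100_000 + 600 * i) for i in range(2)]
            anchors += [anchor(f"{scaf}{second}{i}", scaf, 5000 + 1000 * i,
                               second, 100_000 + 600 * i) for i in range(2)]
        report = synteny_links(anchors)
        assert len(report.break_sites) == 2
        assert all(b.klass == BREAK_REARRANGEMENT for b in report.break_sites)

    def test_incoherent_orientation_classed_poor_scaffolding(self):
        left = [anchor("a0", "s", 0, "pA", 100_000, strand="+"),
                anchor("a1", "s", 1000, "pA", 120_000, strand="-")]
        right = [anchor(f"b{i}", "s", 5000 + 1000 * i, "pB", 100_000 + 600 * i)
                 for i in range(2)]
        report = synteny_links(left + right)
        assert report.break_sites[0].klass == BREAK_POOR_SCAFFOLDING

    def test_partner_end_adjacency(self):
        """Both runs at their partner scaffolds' very ends: the break marks
        sequences that are adjacent in a more contiguous assembly."""
        left = [anchor(f"a{i}", "s", 1000 * i, "pA", 190_000 + 600 * i)
                for i in range(2)]  # partner end is 200 kb
        right = [anchor(f"b{i}", "s", 5000 + 1000 * i, "pB", 600 * i)
                 for i in range(2)]  # partner start
        report = synteny_links(left + right)
        assert report.break_sites[0].klass == BREAK_PARTNER_END

    def test_unfiltered_anchors_rejected(self):
        bad = [anchor("x", "s", 0, "p", 0, masked=0.5),
               anchor("y", "s", 1000, "p", 600)]
        with pytest.raises(ValueError, match="filter_anchors"):
            synteny_links(bad)
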