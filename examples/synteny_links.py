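"""Classify scaffold-partner links from transcript anchors.

Gene anchors (transcripts back-mapped onto scaffolds, with one-to-one
orthologs located in a partner assembly) link each scaffold to partner
scaffolds. A scaffold whose anchors all point at one partner is a direct
synteny candidate (single-link); a scaffold whose anchors switch partner
mid-scaffold, with at least two genes on both sides, holds a break site —
classed as a rearrangement when both anchor runs are orientation-coherent,
as poor scaffolding otherwise, or as partner-end adjacency when both runs
sit at the very ends of their partners.
"""

from regenmut.assembly_qc import GeneAnchor, filter_anchors, synteny_links


def anchor(transcript, scaffold, start, partner, p_start, strand="+"):
    return GeneAnchor(transcript=transcript, scaffold=scaffold, start=start,
                      end=start + 500, strand=strand, masked_fraction=0.02,
                      nested=False, one_to_one=True,
                      partner_scaffold=partner, partner_start=p_start,
                      partner_end=p_start + 500, partner_length=200_000)


anchors = filter_anchors(
    # scaffold_1: all genes on partner pA -> single-link
    [anchor(f"t{i}", "scaffold_1", 1_000 * i, "pA", 100_000 + 600 * i)
     for i in range(4)]
    # scaffold_2: three genes on pA then two on pB -> break site
    + [anchor(f"u{i}", "scaffold_2", 1_000 * i, "pA", 50_000 + 600 * i)
       for i in range(3)]
    + [anchor(f"v{i}", "scaffold_2", 6_000 + 1_000 * i, "pB", 80_000 + 600 * i)
       for i in range(2)]
)
report = synteny_links(anchors)
n = len(report.link_class)
print(f"{report.n_single_link}/{n} scaffolds single-link")
for scaffold, klass in report.link_class.items():
    print(f"  {scaffold}: {klass}, partners {report.links[scaffold]}")
for b in report.break_sites:
    print(f"break on {b.scaffold} at ~{b.pos0} bp: {b.left_partner} | "
          f"{b.right_partner} ({b.left_genes}+{b.right_genes} genes) -> "
          f"{b.klass}")
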