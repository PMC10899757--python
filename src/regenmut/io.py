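"""Readers and writers for every external representation the pipeline touches.

Internal coordinates are uniformly 0-based half-open. On disk, positions follow
each format's own convention: pileup TSV and VCF are 1-based, BED is 0-based.

The pileup TSV dialect is the project's own (fully specified so independent
implementations interoperate):

* comment header ``##samples=<s1>,<s2>,...``
* column header ``#chrom  pos  ref`` followed by 8 columns per sample:
  ``<s>_depth <s>_A <s>_C <s>_G <s>_T <s>_ins <s>_del <s>_mq``
* ``pos`` is 1-based; ``<s>_ins`` / ``<s>_del`` carry ``count:key``
  (e.g. ``3:I:TG`` or ``2:D:1``) or ``0`` when no indel allele was seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
REF_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class IntegrityError(ValueError):
    """Parsed content violates an internal consistency invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """An assembly: ordered mapping scaffold name -> uppercase ACGTN string."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise IntegrityError("genome has no scaffolds")
        for name, seq in self.sequences.items():
            if not name:
                raise IntegrityError("empty scaffold name")
            if not seq:
                raise IntegrityError(f"scaffold {name!r} has empty sequence")
            if set(seq) - VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise IntegrityError(
                    f"scaffold {name!r} contains invalid characters {bad}"
                )

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self.sequences

    def __getitem__(self, scaffold: str) -> str:
        return self.sequences[scaffold]

    @property
    def scaffold_names(self) -> List[str]:
        return list(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class IntervalMask:
    """Per-scaffold sorted, merged, 0-based half-open intervals."""

    intervals: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for scaf, ivs in self.intervals.items():
            prev_end = -1
            for start, end in ivs:
                if end <= start:
                    raise IntegrityError(
                        f"empty/inverted interval ({start},{end}) on {scaf}"
                    )
                if start < prev_end:
                    raise IntegrityError(f"unsorted/overlapping intervals on {scaf}")
                prev_end = end

    @property
    def total_length(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def contains(self, scaffold: str, pos0: int) -> bool:
        """True iff position pos0 lies within the mask."""
        import bisect

        ivs = self.intervals.get(scaffold)
        if not ivs:
            return False
        i = bisect.bisect_right(ivs, (pos0, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos0 < ivs[i][1]

    def contains_interval(self, scaffold: str, start: int, end: int) -> bool:
        """True iff [start, end) lies entirely within one mask interval."""
        import bisect

        ivs = self.intervals.get(scaffold)
        if not ivs or end <= start:
            return False
        i = bisect.bisect_right(ivs, (start, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= start and end <= ivs[i][1]


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    out: List[Tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def mask_from_intervals(raw: Dict[str, Iterable[Tuple[int, int]]]) -> IntervalMask:
    return IntervalMask({s: merge_intervals(iv) for s, iv in raw.items() if list(iv)})


def complement_mask(mask: IntervalMask, genome: Genome) -> IntervalMask:
    """Genome-wide complement of a mask."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    for scaf, seq in genome.sequences.items():
        gaps: List[Tuple[int, int]] = []
        cursor = 0
        for start, end in mask.intervals.get(scaf, []):
            if start > cursor:
                gaps.append((cursor, start))
            cursor = max(cursor, end)
        if cursor < len(seq):
            gaps.append((cursor, len(seq)))
        if gaps:
            out[scaf] = gaps
    return IntervalMask(out)


@dataclass
class PileupCell:
    """Per-sample, per-site read counts.

    ``counts`` maps allele keys (A/C/G/T plus optional ``I:<seq>`` / ``D:<len>``)
    to read counts; depth must equal their sum; mean_mq is Phred-scaled in [0, 60].
    """

    depth: int
    counts: Dict[str, int]
    mean_mq: float

    def validate(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise IntegrityError("negative allele count")
        if self.depth != sum(self.counts.values()):
            raise IntegrityError(
                f"depth {self.depth} != sum of counts {sum(self.counts.values())}"
            )
        if not 0 <= self.mean_mq <= 60:
            raise IntegrityError(f"mean_mq {self.mean_mq} outside [0, 60]")

    def allele_count(self, allele: str) -> int:
        return self.counts.get(allele, 0)

    def allele_fraction(self, allele: str) -> float:
        return self.counts.get(allele, 0) / self.depth if self.depth else 0.0


@dataclass
class PileupSite:
    scaffold: str
    pos0: int
    ref: str
    cells: Dict[str, PileupCell]


@dataclass
class PileupTable:
    """Multi-sample per-site read-count table: the caller's substrate."""

    samples: List[str]
    sites: List[PileupSite]

    def __post_init__(self) -> None:
        sample_set = set(self.samples)
        prev: Dict[str, int] = {}
        for site in self.sites:
            if site.ref not in REF_BASES:
                raise IntegrityError(
                    f"ref base {site.ref!r} at {site.scaffold}:{site.pos0}"
                )
            if set(site.cells) != sample_set:
                raise IntegrityError(
                    f"site {site.scaffold}:{site.pos0} cells do not match samples"
                )
            if site.scaffold in prev and site.pos0 <= prev[site.scaffold]:
                raise IntegrityError(
                    f"positions not strictly increasing on {site.scaffold}"
                )
            prev[site.scaffold] = site.pos0

    def __len__(self) -> int:
        return len(self.sites)

    def site_at(self, scaffold: str, pos0: int) -> Optional[PileupSite]:
        for site in self.sites:  # tables are small; linear scan is fine
            if site.scaffold == scaffold and site.pos0 == pos0:
                return site
        return None


@dataclass
class SelfAlignment:
    """One assembly-vs-assembly alignment record with PAF semantics."""

    q_name: str
    q_len: int
    q_start: int
    q_end: int
    strand: str
    t_name: str
    t_len: int
    t_start: int
    t_end: int
    n_match: int
    aln_len: int
    mapq: int
    primary: bool = True
    chain_score_primary: int = 0
    chain_score_secondary: int = 0
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end <= self.q_len):
            raise IntegrityError(f"bad query span {self.q_start}-{self.q_end}")
        if not (0 <= self.t_start < self.t_end <= self.t_len):
            raise IntegrityError(f"bad target span {self.t_start}-{self.t_end}")
        if not 0 <= self.divergence <= 1:
            raise IntegrityError(f"divergence {self.divergence} outside [0,1]")
        if not 0 <= self.mapq <= 60:
            raise IntegrityError(f"mapq {self.mapq} outside [0,60]")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Genome:
    """Read a FASTA file into a Genome; sequences are upper-cased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no records in {path}")
    sequences: Dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise FormatError(f"duplicate scaffold name {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper()
    return Genome(sequences)


def write_fasta(genome: Genome, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Pileup TSV
# ---------------------------------------------------------------------------

_PER_SAMPLE = ("depth", "A", "C", "G", "T", "ins", "del", "mq")


def _format_indel(cell: PileupCell, kind: str) -> str:
    for key, count in cell.counts.items():
        if key.startswith(kind) and count > 0:
            return f"{count}:{key}"
    return "0"


def write_pileup(table: PileupTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("##samples=" + ",".join(table.samples) + "\n")
        header = ["#chrom", "pos", "ref"]
        for s in table.samples:
            header.extend(f"{s}_{c}" for c in _PER_SAMPLE)
        fh.write("\t".join(header) + "\n")
        for site in table.sites:
            row = [site.scaffold, str(site.pos0 + 1), site.ref]
            for s in table.samples:
                cell = site.cells[s]
                row.append(str(cell.depth))
                row.extend(str(cell.allele_count(b)) for b in "ACGT")
                row.append(_format_indel(cell, "I:"))
                row.append(_format_indel(cell, "D:"))
                row.append(f"{cell.mean_mq:g}")
            fh.write("\t".join(row) + "\n")


def _parse_indel_field(field_str: str, where: str) -> Dict[str, int]:
    if field_str == "0":
        return {}
    try:
        count_str, key = field_str.split(":", 1)
        count = int(count_str)
    except ValueError as exc:
        raise FormatError(f"bad indel field {field_str!r} at {where}") from exc
    if not (key.startswith("I:") or key.startswith("D:")):
        raise FormatError(f"bad indel key {key!r} at {where}")
    return {key: count}


def read_pileup(path) -> PileupTable:
    """Parse the project pileup dialect; 1-based file positions become 0-based."""
    samples: List[str] = []
    sites: List[PileupSite] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("##samples="):
            raise FormatError(f"{path}: missing ##samples= header")
        samples = first[len("##samples="):].split(",")
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["#chrom", "pos", "ref"]
        for s in samples:
            expected.extend(f"{s}_{c}" for c in _PER_SAMPLE)
        if header != expected:
            unknown = [c for c in header[3:] if c not in expected]
            if unknown:
                raise FormatError(f"{path}: unknown sample column(s) {unknown[:3]}")
            raise FormatError(f"{path}: malformed column header")
        for lineno, line in enumerate(fh, start=3):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(expected):
                raise FormatError(f"{path}:{lineno}: wrong number of columns")
            scaffold, pos_str, ref = fields[0], fields[1], fields[2]
            pos1 = int(pos_str)
            if pos1 < 1:
                raise FormatError(
                    f"{path}:{lineno}: position {pos1} (positions are 1-based on disk)"
                )
            where = f"{scaffold}:{pos1}"
            cells: Dict[str, PileupCell] = {}
            for i, s in enumerate(samples):
                base = 3 + 8 * i
                depth = int(fields[base])
                counts: Dict[str, int] = {
                    b: int(fields[base + 1 + j]) for j, b in enumerate("ACGT")
                }
                counts = {k: v for k, v in counts.items() if v}
                counts.update(_parse_indel_field(fields[base + 5], where))
                counts.update(_parse_indel_field(fields[base + 6], where))
                cell = PileupCell(depth=depth, counts=counts,
                                  mean_mq=float(fields[base + 7]))
                try:
                    cell.validate()
                except IntegrityError as exc:
                    raise IntegrityError(f"{where} sample {s}: {exc}") from exc
                cells[s] = cell
            sites.append(PileupSite(scaffold, pos1 - 1, ref, cells))
    return PileupTable(samples=samples, sites=sites)


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

def read_paf(path) -> List[SelfAlignment]:
    """Parse PAF; honors tp/s1/s2/de tags, computing divergence as
    1 - n_match/aln_len when the de tag is absent."""
    out: List[SelfAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: {len(fields)} columns (12 required)"
                )
            tags: Dict[str, str] = {}
            for tag in fields[12:]:
                parts = tag.split(":", 2)
                if len(parts) == 3:
                    tags[parts[0]] = parts[2]
            n_match, aln_len = int(fields[9]), int(fields[10])
            divergence = (
                float(tags["de"]) if "de" in tags
                else 1.0 - (n_match / aln_len if aln_len else 0.0)
            )
            out.append(SelfAlignment(
                q_name=fields[0], q_len=int(fields[1]),
                q_start=int(fields[2]), q_end=int(fields[3]),
                strand=fields[4],
                t_name=fields[5], t_len=int(fields[6]),
                t_start=int(fields[7]), t_end=int(fields[8]),
                n_match=n_match, aln_len=aln_len, mapq=int(fields[11]),
                primary=tags.get("tp", "P") == "P",
                chain_score_primary=int(tags.get("s1", 0)),
                chain_score_secondary=int(tags.get("s2", 0)),
                divergence=divergence,
            ))
    return out


def write_paf(alignments: Sequence[SelfAlignment], path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            fields = [
                a.q_name, a.q_len, a.q_start, a.q_end, a.strand,
                a.t_name, a.t_len, a.t_start, a.t_end,
                a.n_match, a.aln_len, a.mapq,
                f"tp:A:{'P' if a.primary else 'S'}",
                f"s1:i:{a.chain_score_primary}",
                f"s2:i:{a.chain_score_secondary}",
                f"de:f:{a.divergence:g}",
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


# ---------------------------------------------------------------------------
# BED3 masks
# ---------------------------------------------------------------------------

def read_bed_mask(path, genome: Genome) -> IntervalMask:
    """Read a 3-column BED into a merged mask clipped to scaffold bounds."""
    raw: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            scaf, start, end = fields[0], int(fields[1]), int(fields[2])
            if scaf not in genome:
                raise FormatError(f"{path}:{lineno}: unknown scaffold {scaf!r}")
            if end > len(genome[scaf]):
                raise FormatError(
                    f"{path}:{lineno}: interval end {end} beyond scaffold "
                    f"{scaf!r} length {len(genome[scaf])}"
                )
            if end > start:
                raw.setdefault(scaf, []).append((max(0, start), end))
    return mask_from_intervals(raw)


def write_bed_mask(mask: IntervalMask, path) -> None:
    with open(path, "w") as fh:
        for scaf, ivs in mask.intervals.items():
            for start, end in ivs:
                fh.write(f"{scaf}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# VCF out
# ---------------------------------------------------------------------------

def write_calls_vcf(calls, genome: Genome, path) -> None:
    """Write calls as minimal VCF 4.2 with per-sample AF and DP fields.

    Indels use the anchor-base convention: a deletion of n bases at pos0 is
    written as REF = anchor + deleted bases, ALT = anchor, at POS = pos0 + 1.
    """
    samples = sorted({s for call in calls for s in call.carriers})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in genome.sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n')
        fh.write('##FORMAT=<ID=AD,Number=1,Type=Integer,Description="Alt-supporting reads">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for call in calls:
            if call.scaffold not in genome:
                raise IntegrityError(f"call on unknown scaffold {call.scaffold!r}")
            seq = genome[call.scaffold]
            if seq[call.pos0] != call.ref:
                raise IntegrityError(
                    f"call ref {call.ref!r} disagrees with genome "
                    f"{seq[call.pos0]!r} at {call.scaffold}:{call.pos0}"
                )
            if call.alt.startswith("I:"):
                ref_field = call.ref
                alt_field = call.ref + call.alt[2:]
            elif call.alt.startswith("D:"):
                n_del = int(call.alt[2:])
                if call.pos0 + 1 + n_del > len(seq):
                    raise IntegrityError(
                        f"deletion at {call.scaffold}:{call.pos0} exceeds scaffold"
                    )
                ref_field = seq[call.pos0: call.pos0 + 1 + n_del]
                alt_field = call.ref
            else:
                ref_field, alt_field = call.ref, call.alt
            fmt_cells = []
            for s in samples:
                if s in call.carriers:
                    af = call.allele_fractions.get(s, 0.0)
                    ad = call.support.get(s, 0)
                    fmt_cells.append(f"{af:.4f}:{ad}")
                else:
                    fmt_cells.append(".:.")
            info = f"CLASS={call.label}" if getattr(call, "label", None) else "."
            fh.write("\t".join([
                call.scaffold, str(call.pos0 + 1), ".", ref_field, alt_field,
                ".", "PASS", info, "AF:AD", *fmt_cells,
            ]) + "\n")
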