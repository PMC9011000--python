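"""Back-splice junction detection: the circRNA identification procedure.

The stages mirror a find_circ-style workflow at desk scale: quality filter,
contiguous (linear) mapping filter, unique 20-mer terminal-anchor pairing,
head-to-tail breakpoint calling with a canonical GT/AG splice-flank check,
support-based candidate filtering, and annotation-based classification.

Coordinates are 0-based half-open; ``start`` is the acceptor breakpoint
(first base of the circle) and ``end`` the donor breakpoint (exclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .reference import Gene, ReferenceBundle, ReferenceError, revcomp

logger = logging.getLogger(__name__)


class FastqParseError(ValueError):
    """Malformed FASTQ record; carries the record index."""


@dataclass
class ReadRecord:
    id: str
    sequence: str
    quality: str  # Phred+33
    sample: str = "S01"

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FastqParseError(
                f"read {self.id}: sequence and quality lengths differ"
            )

    def phred(self) -> np.ndarray:
        return np.frombuffer(self.quality.encode(), dtype=np.uint8) - 33


def read_fastq(path: str | Path, sample: str = "S01") -> list[ReadRecord]:
    """Parse a Phred+33 FASTQ file into ReadRecords."""
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        quals = rec.letter_annotations["phred_quality"]
        out.append(
            ReadRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                quality="".join(chr(q + 33) for q in quals),
                sample=sample,
            )
        )
    return out


# --------------------------------------------------------------------- QC


@dataclass
class QCReport:
    total: int = 0
    passed: int = 0
    failed_adapter: int = 0
    failed_n_fraction: int = 0
    failed_low_quality: int = 0


def qc_filter_reads(
    reads: list[ReadRecord],
    adapter: str | None = None,
    max_n_fraction: float = 0.10,
    q_threshold: int = 20,
    max_lowq_fraction: float = 0.50,
) -> tuple[list[ReadRecord], QCReport]:
    """Discard adapter-bearing reads, reads with >10% N, and reads with >50%
    low-quality (Q ≤ 20) bases.  Each discarded read is counted once, under
    the first rule it fails."""
    report = QCReport(total=len(reads))
    clean = []
    for r in reads:
        n = len(r.sequence)
        if n == 0:
            report.failed_n_fraction += 1
            continue
        if adapter and adapter in r.sequence:
            report.failed_adapter += 1
            continue
        if r.sequence.count("N") / n > max_n_fraction:
            report.failed_n_fraction += 1
            continue
        if (r.phred() <= q_threshold).sum() / n > max_lowq_fraction:
            report.failed_low_quality += 1
            continue
        clean.append(r)
    report.passed = len(clean)
    return clean, report


# ------------------------------------------------------------------ index


class GenomeIndex:
    """Exact k-mer index of both genome strands.

    A stored position ``(chrom, offset, strand)`` dereferences to the k-mer:
    on '+' it is ``seq[offset:offset+k]``, on '-' its reverse complement.
    k-mers containing N are not indexed.
    """

    def __init__(self, k: int, positions: dict[str, list[tuple[str, int, str]]],
                 chrom_lengths: dict[str, int]):
        self.k = k
        self.positions = positions
        self.chrom_lengths = chrom_lengths

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        return self.positions.get(kmer, [])


def build_index(bundle: ReferenceBundle, k: int = 20) -> GenomeIndex:
    if any(len(s) < k for s in bundle.sequences.values()):
        raise ReferenceError(f"k={k} exceeds the shortest chromosome length")
    positions: dict[str, list[tuple[str, int, str]]] = {}
    for chrom in bundle.sequences:
        seq = bundle.sequences[chrom]
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            positions.setdefault(kmer, []).append((chrom, i, "+"))
            positions.setdefault(revcomp(kmer), []).append((chrom, i, "-"))
    return GenomeIndex(k=k, positions=positions,
                       chrom_lengths={c: len(s) for c, s in bundle.sequences.items()})


# -------------------------------------------------------------- alignment


def _mismatches(read: str, genome: str, limit: int) -> int:
    """Hamming distance with early exit; N in the read never matches."""
    mm = 0
    for a, b in zip(read, genome):
        if a != b or a == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


@dataclass
class LinearAlignment:
    chrom: str
    start: int
    strand: str
    mismatches: int


def map_linear(
    read: ReadRecord, index: GenomeIndex, bundle: ReferenceBundle,
    max_mismatches: int = 2
) -> LinearAlignment | None:
    """Contiguous end-to-end alignment on either strand, seeded by the
    terminal k-mers, verified by direct comparison.  Returns the best (fewest
    mismatches) alignment with ≤ max_mismatches, or None."""
    k = index.k
    L = len(read.sequence)
    if L < k:
        return None
    best: LinearAlignment | None = None
    for seq, strand in ((read.sequence, "+"), (revcomp(read.sequence), "-")):
        starts: set[tuple[str, int]] = set()
        for chrom, off, hstrand in index.lookup(seq[:k]):
            if hstrand == "+":
                starts.add((chrom, off))
        for chrom, off, hstrand in index.lookup(seq[-k:]):
            if hstrand == "+":
                starts.add((chrom, off - (L - k)))
        for chrom, start in sorted(starts):
            if start < 0 or start + L > index.chrom_lengths[chrom]:
                continue
            mm = _mismatches(seq, bundle.sequences[chrom][start : start + L],
                             max_mismatches)
            if mm <= max_mismatches and (best is None or mm < best.mismatches):
                best = LinearAlignment(chrom, start, strand, mm)
    return best


# ---------------------------------------------------------------- anchors


@dataclass
class AnchorPair:
    chrom: str
    strand: str
    head_offset: int  # genomic offset of the read's first k bases
    tail_offset: int  # genomic offset of the read's last k bases
    k: int = 20


def find_anchors(read: ReadRecord, index: GenomeIndex) -> AnchorPair | None:
    """Terminal 20-mers of the read, each required to occur exactly once in
    the genome, on a common chromosome and strand."""
    k = index.k
    if len(read.sequence) < 2 * k:
        return None
    head_hits = index.lookup(read.sequence[:k])
    tail_hits = index.lookup(read.sequence[-k:])
    if len(head_hits) != 1 or len(tail_hits) != 1:
        return None
    (hc, ho, hs), (tc, to, ts) = head_hits[0], tail_hits[0]
    if hc != tc or hs != ts:
        return None
    return AnchorPair(chrom=hc, strand=hs, head_offset=ho, tail_offset=to, k=k)


# ----------------------------------------------------------- junction call


@dataclass
class JunctionCandidate:
    chrom: str
    start: int  # acceptor breakpoint, 0-based
    end: int  # donor breakpoint, exclusive
    strand: str
    read_id: str
    sample: str
    read_seq: str
    mismatches: int
    flanks: tuple[str, str]  # (acceptor-side, donor-side) genomic dinucleotides

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


def _flanks_ok(chrom_seq: str, s: int, e: int, strand: str) -> bool:
    """Canonical splice flanks on the candidate strand: the donor
    dinucleotide 3' of ``end`` is GT and the acceptor dinucleotide 5' of
    ``start`` is AG (read on the transcript strand)."""
    if s - 2 < 0 or e + 2 > len(chrom_seq):
        return False
    acc, don = chrom_seq[s - 2 : s], chrom_seq[e : e + 2]
    if strand == "+":
        return don == "GT" and acc == "AG"
    return acc == "AC" and don == "CT"  # revcomp(GT), revcomp(AG)


def call_junction(
    read: ReadRecord,
    anchors: AnchorPair,
    bundle: ReferenceBundle,
    max_extension_mismatches: int = 2,
) -> JunctionCandidate | None:
    """Extend a head-to-tail anchor pair to a full back-splice alignment.

    Works in plus-strand space: a minus-strand read is reverse-complemented,
    which swaps the roles of its two anchors.  The read is split at every
    admissible offset j into a donor-side suffix of the circle and an
    acceptor-side prefix; the split minimising mismatches wins, ties broken
    first by satisfying the GT/AG flank rule, then by leftmost start.
    """
    k = anchors.k
    seq = read.sequence
    L = len(seq)
    if anchors.strand == "+":
        head_off, tail_off = anchors.head_offset, anchors.tail_offset
    else:
        seq = revcomp(seq)
        head_off, tail_off = anchors.tail_offset, anchors.head_offset
    if head_off <= tail_off:
        return None  # colinear orientation: a linear splice, not circular

    chrom_seq = bundle.sequences[anchors.chrom]
    clen = len(chrom_seq)
    best: tuple[int, int, int, int] | None = None  # (mm, not_flank, s, e)
    for j in range(k, L - k + 1):
        e = head_off + j
        s = tail_off + k - (L - j)
        if s < 0 or e > clen or s >= e:
            continue
        mm = _mismatches(seq[:j], chrom_seq[e - j : e], max_extension_mismatches)
        if mm > max_extension_mismatches:
            continue
        mm += _mismatches(seq[j:], chrom_seq[s : s + L - j],
                          max_extension_mismatches - mm)
        if mm > max_extension_mismatches:
            continue
        flank = 0 if _flanks_ok(chrom_seq, s, e, anchors.strand) else 1
        cand = (mm, flank, s, e)
        if best is None or cand < best:
            best = cand
    if best is None or best[1] == 1:
        return None
    mm, _, s, e = best
    return JunctionCandidate(
        chrom=anchors.chrom,
        start=s,
        end=e,
        strand=anchors.strand,
        read_id=read.id,
        sample=read.sample,
        read_seq=read.sequence,
        mismatches=mm,
        flanks=(chrom_seq[s - 2 : s], chrom_seq[e : e + 2]),
    )


# ----------------------------------------------------------------- records


@dataclass
class CircRecord:
    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    support: dict[str, int] = field(default_factory=dict)  # sample → unique reads
    circ_class: str = "unclassified"
    gene_id: str | None = None
    spliced_length: int | None = None

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def genomic_span(self) -> int:
        return self.end - self.start

    @property
    def max_support(self) -> int:
        return max(self.support.values()) if self.support else 0


def collapse_candidates(
    candidates: list[JunctionCandidate],
    min_support: int = 2,
) -> list[CircRecord]:
    """Group candidates by breakpoint pair; count unique supporting reads per
    sample (unique = distinct read sequences, so PCR duplicates collapse);
    retain junctions with ≥ min_support unique reads in at least one sample.
    Ids are assigned sequentially in (chromosome, start, end) order."""
    seqs: dict[tuple, dict[str, set[str]]] = {}
    for c in candidates:
        seqs.setdefault(c.key, {}).setdefault(c.sample, set()).add(c.read_seq)
    records = []
    for key in sorted(seqs, key=lambda t: (t[0], t[1], t[2], t[3])):
        support = {sample: len(s) for sample, s in sorted(seqs[key].items())}
        if max(support.values()) >= min_support:
            chrom, start, end, strand = key
            records.append(
                CircRecord(circ_id="", chrom=chrom, start=start, end=end,
                           strand=strand, support=support)
            )
    for i, rec in enumerate(records, start=1):
        rec.circ_id = f"circ_{i:06d}"
    return records


# ----------------------------------------------------------- classification


def classify_circ(record: CircRecord, bundle: ReferenceBundle) -> CircRecord:
    """Assign class and source gene from the annotation.

    exonic: both breakpoints fall within exons of one same-strand gene;
    intronic: the whole span lies inside a single intron of a same-strand
    gene; antisense: overlaps gene(s) only on the opposite strand (that gene
    is recorded); intergenic otherwise (no source gene).
    """
    overlapping = [
        g
        for g in bundle.genes
        if g.chrom == record.chrom and g.start < record.end and record.start < g.end
    ]
    same = [g for g in overlapping if g.strand == record.strand]
    anti = [g for g in overlapping if g.strand != record.strand]

    for g in same:
        start_in = any(s <= record.start < e for s, e in g.exons)
        end_in = any(s < record.end <= e for s, e in g.exons)
        if start_in and end_in:
            record.circ_class = "exonic"
            record.gene_id = g.gene_id
            record.spliced_length = _spliced_length(record, g)
            return record
    for g in same:
        if any(s <= record.start and record.end <= e for s, e in g.introns):
            record.circ_class = "intronic"
            record.gene_id = g.gene_id
            record.spliced_length = record.genomic_span
            return record
    if anti and not same:
        record.circ_class = "antisense"
        record.gene_id = anti[0].gene_id  # opposite-strand gene, recorded
        record.spliced_length = record.genomic_span
        return record
    record.circ_class = "intergenic"
    record.gene_id = None
    record.spliced_length = record.genomic_span
    return record


def _spliced_length(record: CircRecord, gene: Gene) -> int:
    """Sum of exon overlap with the circle span (mature circle length)."""
    return sum(
        max(0, min(e, record.end) - max(s, record.start)) for s, e in gene.exons
    )


# ------------------------------------------------------------------ driver


@dataclass
class DetectionResult:
    records: list[CircRecord]
    qc_report: QCReport
    n_linear_mapped: int
    n_junction_reads: int


def detect_circrnas(
    bundle: ReferenceBundle,
    reads: list[ReadRecord],
    k: int = 20,
    min_support: int = 2,
    adapter: str | None = None,
    max_mismatches: int = 2,
    index: GenomeIndex | None = None,
) -> DetectionResult:
    """Full detection pipeline: QC → linear filter → anchors → junction call
    → support filter → classification.  A read never contributes to both a
    linear alignment and a junction candidate."""
    if index is None:
        index = build_index(bundle, k=k)
    clean, qc = qc_filter_reads(reads, adapter=adapter)
    candidates = []
    n_mapped = 0
    for read in clean:
        if map_linear(read, index, bundle, max_mismatches=max_mismatches):
            n_mapped += 1
            continue
        if len(read.sequence) < 2 * k:
            continue
        anchors = find_anchors(read, index)
        if anchors is None:
            continue
        cand = call_junction(read, anchors, bundle,
                             max_extension_mismatches=max_mismatches)
        if cand is not None:
            candidates.append(cand)
    records = collapse_candidates(candidates, min_support=min_support)
    for rec in records:
        classify_circ(rec, bundle)
    return DetectionResult(
        records=records,
        qc_report=qc,
        n_linear_mapped=n_mapped,
        n_junction_reads=len(candidates),
    )


# ----------------------------------------------------------------- summary


def summarize_catalog(
    records: list[CircRecord],
    sample_groups: dict[str, str] | None = None,
    length_bins: tuple[int, ...] = (0, 200, 400, 600, 800, 1000, 2000, 5000),
) -> dict:
    """Per-chromosome counts, genomic-span histogram, class proportions, and
    per-group presence sets (for Venn-style overlap counts)."""
    per_chrom: dict[str, int] = {}
    classes: dict[str, int] = {}
    spans = []
    for r in records:
        per_chrom[r.chrom] = per_chrom.get(r.chrom, 0) + 1
        classes[r.circ_class] = classes.get(r.circ_class, 0) + 1
        spans.append(r.genomic_span)
    hist, edges = np.histogram(spans, bins=list(length_bins) + [np.inf]) if spans else (
        np.zeros(len(length_bins), dtype=int), np.array(list(length_bins) + [np.inf])
    )
    total = len(records)
    class_prop = {c: n / total for c, n in classes.items()} if total else {}

    presence: dict[str, set[str]] = {}
    if sample_groups:
        for r in records:
            for sample, count in r.support.items():
                if count > 0 and sample in sample_groups:
                    presence.setdefault(sample_groups[sample], set()).add(r.circ_id)
    overlap = {}
    if presence:
        names = sorted(presence)
        for mask in range(1, 2 ** len(names)):
            subset = [names[i] for i in range(len(names)) if mask >> i & 1]
            inter = set.intersection(*(presence[g] for g in subset))
            overlap["&".join(subset)] = len(inter)
    return {
        "n_circ": total,
        "per_chromosome": dict(sorted(per_chrom.items())),
        "length_histogram": {"edges": list(edges[:-1]), "counts": hist.tolist()},
        "class_counts": dict(sorted(classes.items())),
        "class_proportions": dict(sorted(class_prop.items())),
        "group_presence": {g: sorted(s) for g, s in sorted(presence.items())},
        "group_overlap": overlap,
    }


# -------------------------------------------------------------------- BED


def write_bed(records: list[CircRecord], path: str | Path) -> None:
    """BED6 + class, source gene, per-sample support columns.

    Deterministic formatting: support serialized as ``sample:count`` pairs
    sorted by sample, so write→read→write is byte-stable.
    """
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.chrom, r.start, r.end, r.strand)):
            support = ",".join(f"{s}:{c}" for s, c in sorted(r.support.items()))
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        r.circ_id,
                        str(r.max_support),
                        r.strand,
                        r.circ_class,
                        r.gene_id if r.gene_id is not None else ".",
                        support or ".",
                    ]
                )
                + "\n"
            )


def read_bed(path: str | Path) -> list[CircRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            support = {}
            if len(f) > 8 and f[8] != ".":
                for pair in f[8].split(","):
                    sample, count = pair.rsplit(":", 1)
                    support[sample] = int(count)
            records.append(
                CircRecord(
                    circ_id=f[3],
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5],
                    support=support,
                    circ_class=f[6] if len(f) > 6 else "unclassified",
                    gene_id=None if len(f) <= 7 or f[7] == "." else f[7],
                )
            )
    return records
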