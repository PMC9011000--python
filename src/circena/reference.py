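"""Reference genome and annotation handling.

Internal coordinates are 0-based, half-open throughout the package.  GTF is
1-based inclusive; the conversion happens here, at the I/O boundary, and
nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceError(ValueError):
    """Malformed reference sequence or annotation."""


@dataclass
class Gene:
    """A gene with its exon structure.

    ``exons`` are 0-based half-open intervals on the genome, sorted and
    non-overlapping; introns are the gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ReferenceError(
                    f"overlapping exons in gene {self.gene_id}: "
                    f"({s1},{e1}) and ({s2},{e2})"
                )

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def spliced_sequence(self, chrom_seq: str) -> str:
        """Mature (exon-joined) transcript sequence on the gene's strand."""
        seq = "".join(chrom_seq[s:e] for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class ReferenceBundle:
    """Genome sequences plus gene/exon annotation.

    The coordinate authority for every pipeline stage.
    """

    sequences: dict[str, str]
    genes: list[Gene]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ReferenceError(
                    f"chromosome {name} contains non-ACGTN characters: {sorted(bad)}"
                )
        for g in self.genes:
            if g.chrom not in self.sequences:
                raise ReferenceError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")

    def genes_by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out

    # ---------------------------------------------------------------- I/O

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.sequences:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gtf(self, path: str | Path, source: str = "circena") -> None:
        """Write gene/exon features, converting to 1-based inclusive."""
        with open(path, "w") as fh:
            for g in self.genes:
                attrs = f'gene_id "{g.gene_id}";'
                fh.write(
                    f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
                for i, (s, e) in enumerate(g.exons, start=1):
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{attrs} exon_number \"{i}\";\n"
                    )

    @classmethod
    def from_files(cls, fasta: str | Path, gtf: str | Path) -> "ReferenceBundle":
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        genes = read_gtf_genes(gtf)
        return cls(sequences=sequences, genes=genes)


_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_gtf_genes(path: str | Path) -> list[Gene]:
    """Parse gene and exon features from a GTF file (1-based inclusive)."""
    spans: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ReferenceError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = fields
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                raise ReferenceError(f"{path}:{lineno}: missing gene_id attribute")
            gid = m.group(1)
            start, end = int(start1) - 1, int(end1)  # to 0-based half-open
            if feature == "gene":
                spans[gid] = (chrom, strand, start, end)
                if gid not in order:
                    order.append(gid)
            elif feature == "exon":
                exons.setdefault(gid, []).append((start, end))
                if gid not in order:
                    order.append(gid)
    genes = []
    for gid in order:
        ex = sorted(exons.get(gid, []))
        if gid in spans:
            chrom, strand, start, end = spans[gid]
        else:
            chrom = strand = None  # type: ignore[assignment]
            raise ReferenceError(f"exons for {gid} without a gene feature")
        genes.append(
            Gene(gene_id=gid, chrom=chrom, strand=strand, start=start, end=end, exons=ex)
        )
    return genes
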