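"""Synthetic data generator for the whole pipeline.

Emits every input the pipeline consumes — a toy multi-chromosome genome with
gene/exon structure, planted back-splice junctions with canonical splice-site
flanks, junction-spanning and linear reads, a four-group expression design
containing planted ceRNA triads and differentially expressed circRNAs, and a
group-structured trait table — together with the ground truth needed to score
every downstream stage.

Geometry of a planted circle (plus strand): the acceptor breakpoint ``start``
and donor breakpoint ``end`` delimit a 0-based half-open genomic span; the
genome carries ``AG`` immediately 5' of ``start`` and ``GT`` immediately 3'
of ``end``.  On the minus strand the same rule read on the transcript strand
places ``AC`` before ``start`` and ``CT`` after ``end`` on the plus strand.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .reference import Gene, ReferenceBundle, revcomp

DEFAULT_TRAIT_NAMES = (
    "live_weight_kg",
    "hot_carcass_weight_kg",
    "dressing_percentage",
    "IMF_pct",
    "protein_pct",
    "shear_force_N",
)

# Group-level trait means loosely shaped like growth-stage data: weights rise
# with age and plateau, IMF peaks mid-life, shear force (toughness) rises
# monotonically with age.  Magnitudes are arbitrary; only the ordinal
# structure matters downstream.
DEFAULT_TRAIT_MEANS = {
    "live_weight_kg": (20.0, 45.0, 55.0, 52.0),
    "hot_carcass_weight_kg": (9.0, 23.0, 27.0, 25.0),
    "dressing_percentage": (45.0, 51.0, 48.0, 47.0),
    "IMF_pct": (2.5, 4.5, 4.3, 3.0),
    "protein_pct": (18.0, 20.0, 21.5, 21.6),
    "shear_force_N": (30.0, 42.0, 55.0, 68.0),
}


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass
class SimConfig:
    """All knobs of the simulator.  Same seed ⇒ bit-identical outputs."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 100_000
    n_genes: int = 20
    exons_per_gene: int = 4
    exon_length: int = 200
    intron_length: int = 300
    gene_spacing: int = 600
    n_planted_circ: int = 20
    n_flank_decoys: int = 3
    n_single_read_circ: int = 3
    duplicate_copies: int = 2
    reads_per_circ: int = 3
    linear_read_depth: float = 100.0  # mean linear reads per gene
    read_length: int = 100
    base_error_rate: float = 0.0
    read_samples: int = 1
    n_groups: int = 4
    replicates_per_group: int = 4
    group_names: tuple[str, ...] | None = None
    n_triads: int = 20
    n_decoy_circ: int = 200
    n_decoy_mirna: int = 50
    n_decoy_mrna: int = 50
    triad_noise_sd: float = 10.0
    n_planted_de: int = 20
    de_fold_change: float = 4.0
    n_trait_couplings: int = 2
    trait_names: tuple[str, ...] = DEFAULT_TRAIT_NAMES

    def __post_init__(self) -> None:
        if self.read_length <= 40:
            raise ConfigError("read_length must exceed 40 (two 20-mer anchors)")
        if self.reads_per_circ < 0:
            raise ConfigError("reads_per_circ must be non-negative")
        if self.group_names is None:
            if self.n_groups == 4:
                self.group_names = ("4m", "1.5y", "3.5y", "6y")
            else:
                self.group_names = tuple(f"g{i + 1}" for i in range(self.n_groups))
        if len(self.group_names) != self.n_groups:
            raise ConfigError("group_names length must equal n_groups")

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{g}_{r + 1}"
            for g in self.group_names
            for r in range(self.replicates_per_group)
        ]


@dataclass
class PlantedJunction:
    circ_key: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # exonic / intronic / antisense / intergenic
    gene_id: str | None = None


@dataclass
class SimTruth:
    """Ground truth for scoring every downstream stage."""

    planted_junctions: list[PlantedJunction] = field(default_factory=list)
    flank_decoys: list[PlantedJunction] = field(default_factory=list)
    single_read_junctions: list[PlantedJunction] = field(default_factory=list)
    planted_triads: list[tuple[str, str, str]] = field(default_factory=list)
    planted_de: list[tuple[str, tuple[str, str], float]] = field(default_factory=list)
    planted_trait_associations: list[tuple[str, str, int]] = field(default_factory=list)

    def junction_set(self) -> set[tuple[str, int, int, str]]:
        return {(j.chrom, j.start, j.end, j.strand) for j in self.planted_junctions}

    def write(self, path: str | Path) -> None:
        """Write the truth manifest as JSON (plain-text, key-value)."""
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)

    @classmethod
    def read(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            planted_junctions=[PlantedJunction(**j) for j in raw["planted_junctions"]],
            flank_decoys=[PlantedJunction(**j) for j in raw["flank_decoys"]],
            single_read_junctions=[
                PlantedJunction(**j) for j in raw["single_read_junctions"]
            ],
            planted_triads=[tuple(t) for t in raw["planted_triads"]],
            planted_de=[(f, tuple(c), fc) for f, c, fc in raw["planted_de"]],
            planted_trait_associations=[
                (f, t, int(s)) for f, t, s in raw["planted_trait_associations"]
            ],
        )


# ------------------------------------------------------------------ genome


def _plant_flanks(genome: bytearray, start: int, end: int, strand: str,
                  acceptor: bytes | None = None, donor: bytes | None = None) -> None:
    """Overwrite the dinucleotides flanking a breakpoint pair.

    Defaults plant the canonical donor/acceptor (GT/AG on the transcript
    strand); pass explicit bytes to plant a non-canonical decoy.
    """
    if strand == "+":
        genome[start - 2 : start] = acceptor if acceptor is not None else b"AG"
        genome[end : end + 2] = donor if donor is not None else b"GT"
    else:
        genome[start - 2 : start] = (
            revcomp((donor if donor is not None else b"GT").decode()).encode()
        )
        genome[end : end + 2] = (
            revcomp((acceptor if acceptor is not None else b"AG").decode()).encode()
        )


def simulate_reference(config: SimConfig) -> tuple[ReferenceBundle, SimTruth]:
    """Build the toy genome, gene models, and planted junctions.

    Genes are laid out left to right on each chromosome with fixed exon and
    intron sizes; the tail of each chromosome is reserved for intergenic
    plants.  Planted circles recycle exon-boundary pairs across genes, so
    several exonic circles may share a gene (their breakpoints differ).
    """
    rng = np.random.default_rng(config.seed)
    L = config.read_length

    gene_len = (
        config.exons_per_gene * config.exon_length
        + (config.exons_per_gene - 1) * config.intron_length
    )
    slot = gene_len + config.gene_spacing
    n_extra = config.n_flank_decoys + config.n_single_read_circ
    n_intergenic = sum(
        1 for i in range(config.n_planted_circ) if _kind_for(i) == "intergenic"
    )
    tail_needed = 400 * (n_intergenic + n_extra) + 400

    genes_per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if c < config.n_genes % config.n_chromosomes else 0)
        for c in range(config.n_chromosomes)
    ]
    for c, npg in enumerate(genes_per_chrom):
        if 100 + npg * slot + tail_needed > config.chromosome_length:
            raise ConfigError(
                f"chromosome {c + 1} too short for {npg} genes plus planted features"
            )

    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    genomes: dict[str, bytearray] = {}
    genes: list[Gene] = []
    chrom_names = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    tail_starts: dict[str, int] = {}

    gi = 0
    for c, chrom in enumerate(chrom_names):
        seq = bytearray(
            letters[rng.integers(0, 4, config.chromosome_length)].tobytes()
        )
        genomes[chrom] = seq
        pos = 100
        for _ in range(genes_per_chrom[c]):
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            p = pos
            for _e in range(config.exons_per_gene):
                exons.append((p, p + config.exon_length))
                p += config.exon_length + config.intron_length
            p -= config.intron_length
            genes.append(
                Gene(
                    gene_id=f"gene_{gi + 1:03d}",
                    chrom=chrom,
                    strand=strand,
                    start=pos,
                    end=p,
                    exons=exons,
                )
            )
            gi += 1
            pos += slot
        tail_starts[chrom] = pos + 200

    truth = SimTruth()
    genes_by_chrom = {c: [g for g in genes if g.chrom == c] for c in chrom_names}

    # exon-boundary pairs cycled per gene: (i, j) with i <= j
    pair_cycle = [
        (i, j)
        for i in range(config.exons_per_gene)
        for j in range(i, config.exons_per_gene)
    ]
    used_pairs: dict[str, int] = {g.gene_id: 0 for g in genes}
    intron_used: dict[str, int] = {g.gene_id: 0 for g in genes}
    tail_cursor = dict(tail_starts)
    intergenic_counter = [0]

    def place_intergenic(strand: str) -> tuple[str, int, int]:
        chrom = chrom_names[intergenic_counter[0] % len(chrom_names)]
        intergenic_counter[0] += 1
        s = tail_cursor[chrom]
        e = s + 250
        tail_cursor[chrom] += 400
        if e + 2 > config.chromosome_length:
            raise ConfigError("intergenic tail region exhausted")
        return chrom, s, e

    exonic_gene_idx = 0
    antisense_gene_idx = len(genes) - 1
    for i in range(config.n_planted_circ):
        kind = _kind_for(i)
        key = f"junc_{i + 1:03d}"
        if kind == "exonic":
            for _scan in range(len(genes) * len(pair_cycle)):
                g = genes[exonic_gene_idx % len(genes)]
                if used_pairs[g.gene_id] < len(pair_cycle):
                    break
                exonic_gene_idx += 1
            else:
                raise ConfigError("too many exonic circles for the gene models")
            ei, ej = pair_cycle[used_pairs[g.gene_id]]
            used_pairs[g.gene_id] += 1
            exonic_gene_idx += 1
            s, e = g.exons[ei][0], g.exons[ej][1]
            strand, gid, chrom = g.strand, g.gene_id, g.chrom
        elif kind == "intronic":
            for _scan in range(len(genes)):
                g = genes[exonic_gene_idx % len(genes)]
                if intron_used[g.gene_id] < config.exons_per_gene - 1:
                    break
                exonic_gene_idx += 1
            else:
                raise ConfigError("no intron left for an intronic circle")
            intron = g.introns[intron_used[g.gene_id]]
            intron_used[g.gene_id] += 1
            exonic_gene_idx += 1
            s = intron[0] + 40
            e = s + max(L, 200)
            if e + 2 > intron[1]:
                raise ConfigError("intron too short for an intronic circle")
            strand, gid, chrom = g.strand, g.gene_id, g.chrom
        elif kind == "antisense":
            g = genes[antisense_gene_idx % len(genes)]
            antisense_gene_idx -= 1
            s = g.exons[0][0] + 50
            e = g.exons[1][1] - 50
            strand = "-" if g.strand == "+" else "+"
            gid, chrom = g.gene_id, g.chrom
        else:  # intergenic
            chrom, s, e = place_intergenic("+")
            strand = "+" if i % 2 == 0 else "-"
            gid = None
        _plant_flanks(genomes[chrom], s, e, strand)
        truth.planted_junctions.append(
            PlantedJunction(key, chrom, s, e, strand, kind, gid)
        )

    for i in range(config.n_flank_decoys):
        chrom, s, e = place_intergenic("+")
        strand = "+"
        # canonical donor but a GT/AC decoy acceptor: must be rejected
        _plant_flanks(genomes[chrom], s, e, strand, acceptor=b"AC")
        truth.flank_decoys.append(
            PlantedJunction(f"decoy_{i + 1:03d}", chrom, s, e, strand, "intergenic")
        )

    for i in range(config.n_single_read_circ):
        chrom, s, e = place_intergenic("+")
        strand = "+"
        _plant_flanks(genomes[chrom], s, e, strand)
        truth.single_read_junctions.append(
            PlantedJunction(f"single_{i + 1:03d}", chrom, s, e, strand, "intergenic")
        )

    bundle = ReferenceBundle(
        sequences={c: genomes[c].decode() for c in chrom_names}, genes=genes
    )
    _populate_expression_truth(config, truth)
    return bundle, truth


def _kind_for(i: int) -> str:
    """Class pattern for planted circle i: mostly exonic, a sprinkling of the
    other classes (mirrors the empirical predominance of exonic circles)."""
    r = i % 10
    if r == 7:
        return "intronic"
    if r == 8:
        return "intergenic"
    if r == 9:
        return "antisense"
    return "exonic"


def _populate_expression_truth(config: SimConfig, truth: SimTruth) -> None:
    for t in range(config.n_triads):
        truth.planted_triads.append(
            (f"circ_p{t + 1:03d}", f"mir_p{t + 1:03d}", f"mrna_p{t + 1:03d}")
        )
    contrast = (config.group_names[0], config.group_names[1])
    n_de = min(config.n_planted_de, config.n_decoy_circ)
    for d in range(n_de):
        truth.planted_de.append((f"circ_d{d + 1:03d}", contrast, config.de_fold_change))
    for c in range(config.n_trait_couplings):
        feat = f"circ_d{config.n_decoy_circ - c:03d}"
        trait = config.trait_names[c % len(config.trait_names)]
        sign = 1 if c % 2 == 0 else -1
        truth.planted_trait_associations.append((feat, trait, sign))


# ------------------------------------------------------------------- reads


@dataclass
class SimRead:
    id: str
    sequence: str
    quality: str
    sample: str
    junction: tuple[str, int, int, str] | None = None


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = letters[letters != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def simulate_reads(
    bundle: ReferenceBundle, truth: SimTruth, config: SimConfig
) -> list[SimRead]:
    """Generate back-splice-spanning and linear reads.

    A back-splice read concatenates the circle's 3' terminal segment to its
    5' initial segment; the junction offset is drawn uniformly in
    [25, read_length − 25] so both terminal 20-mers sit clear of the joint.
    Reads for one circle all land in that circle's home sample.
    """
    rng = np.random.default_rng(config.seed + 1)
    L = config.read_length
    samples = [f"S{i + 1:02d}" for i in range(config.read_samples)]
    reads: list[SimRead] = []

    def bs_read(j: PlantedJunction, rid: str, sample: str,
                offset: int | None = None) -> SimRead:
        if L > j.end - j.start:
            raise ConfigError(
                f"read_length {L} exceeds planted circle length {j.end - j.start}"
            )
        chrom = bundle.sequences[j.chrom]
        off = int(rng.integers(25, L - 25 + 1)) if offset is None else offset
        seq = chrom[j.end - off : j.end] + chrom[j.start : j.start + L - off]
        if j.strand == "-":
            seq = revcomp(seq)
        seq = _inject_errors(seq, config.base_error_rate, rng)
        return SimRead(rid, seq, "I" * L, sample,
                       (j.chrom, j.start, j.end, j.strand))

    def junction_offsets(count: int) -> list[int]:
        # distinct offsets whenever the admissible range allows, so each
        # error-free read is a distinct sequence (a unique supporting read)
        choices = np.arange(25, L - 25 + 1)
        replace = count > len(choices)
        return [int(o) for o in rng.choice(choices, size=count, replace=replace)]

    for idx, j in enumerate(truth.planted_junctions):
        home = samples[idx % len(samples)]
        for r, off in enumerate(junction_offsets(config.reads_per_circ)):
            reads.append(bs_read(j, f"{j.circ_key}_r{r + 1}", home, offset=off))
    for idx, j in enumerate(truth.flank_decoys):
        home = samples[idx % len(samples)]
        for r, off in enumerate(junction_offsets(config.reads_per_circ)):
            reads.append(bs_read(j, f"{j.circ_key}_r{r + 1}", home, offset=off))
    for idx, j in enumerate(truth.single_read_junctions):
        home = samples[idx % len(samples)]
        one = bs_read(j, f"{j.circ_key}_r1", home)
        reads.append(one)
        for d in range(config.duplicate_copies):
            # byte-identical PCR duplicates: collapse to one unique read
            reads.append(
                SimRead(f"{j.circ_key}_dup{d + 1}", one.sequence, one.quality,
                        home, one.junction)
            )

    li = 0
    for g in bundle.genes:
        transcript = g.spliced_sequence(bundle.sequences[g.chrom])
        if len(transcript) < L:
            continue
        n = int(rng.poisson(config.linear_read_depth))
        for _ in range(n):
            pos = int(rng.integers(0, len(transcript) - L + 1))
            seq = _inject_errors(transcript[pos : pos + L],
                                 config.base_error_rate, rng)
            reads.append(SimRead(f"lin_{li + 1:06d}", seq, "I" * L,
                                 samples[li % len(samples)]))
            li += 1
    return reads


def as_read_records(reads: list[SimRead]):
    """Convert simulated reads to detector ReadRecords (in-memory handoff
    that skips the FASTQ round trip)."""
    from .detect import ReadRecord

    return [ReadRecord(r.id, r.sequence, r.quality, r.sample) for r in reads]


def write_fastq(reads: list[SimRead], directory: str | Path,
                prefix: str = "sample") -> dict[str, Path]:
    """Write one Phred+33 FASTQ per sample; returns sample → path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_sample: dict[str, list[SimRead]] = {}
    for r in reads:
        by_sample.setdefault(r.sample, []).append(r)
    paths = {}
    for sample in sorted(by_sample):
        path = directory / f"{prefix}_{sample}.fastq"
        with open(path, "w") as fh:
            for r in by_sample[sample]:
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
        paths[sample] = path
    return paths


# -------------------------------------------------- expression and traits


@dataclass
class SimExpression:
    circ_rpm: ExpressionMatrix
    mirna_rpm: ExpressionMatrix
    mrna_rpm: ExpressionMatrix
    circ_counts: ExpressionMatrix
    mapped_totals: pd.Series
    traits: pd.DataFrame  # sample rows: group column + one column per trait


def simulate_expression_and_traits(
    config: SimConfig, truth: SimTruth
) -> SimExpression:
    """Generate the three abundance matrices, a circRNA count matrix with
    planted fold changes, and the trait table.

    Each planted triad couples miRNA → circRNA (negative slope) → mRNA
    (positive slope) with additive Gaussian noise, so the pair statistics
    approach SCC = −1 / PCC = +1 as ``triad_noise_sd`` → 0.  Decoy features
    are i.i.d. across samples (a clean null).
    """
    rng = np.random.default_rng(config.seed + 2)
    samples = config.sample_names
    n = len(samples)
    groups = pd.Series(
        [g for g in config.group_names for _ in range(config.replicates_per_group)],
        index=samples,
    )
    sd = config.triad_noise_sd

    circ_rows, mir_rows, mrna_rows = {}, {}, {}
    for circ_id, mir_id, mrna_id in truth.planted_triads:
        mir = rng.normal(100.0, 20.0, n)
        circ = 500.0 - 2.0 * mir + rng.normal(0.0, sd, n)
        mrna = 50.0 + circ + rng.normal(0.0, sd, n)
        mir_rows[mir_id] = np.clip(mir, 0.0, None)
        circ_rows[circ_id] = np.clip(circ, 0.0, None)
        mrna_rows[mrna_id] = np.clip(mrna, 0.0, None)
    for d in range(config.n_decoy_circ):
        circ_rows[f"circ_d{d + 1:03d}"] = np.clip(rng.normal(100, 20, n), 0, None)
    for d in range(config.n_decoy_mirna):
        mir_rows[f"mir_d{d + 1:03d}"] = np.clip(rng.normal(100, 20, n), 0, None)
    for d in range(config.n_decoy_mrna):
        mrna_rows[f"mrna_d{d + 1:03d}"] = np.clip(rng.normal(100, 20, n), 0, None)

    def em(rows: dict[str, np.ndarray], units: str = "RPM") -> ExpressionMatrix:
        df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
        return ExpressionMatrix(df, groups, units)

    circ_rpm, mirna_rpm, mrna_rpm = em(circ_rows), em(mir_rows), em(mrna_rows)

    # integer count matrix over the same circRNA features, with planted
    # group-specific fold changes on the decoy (null-background) features
    de_by_feature = {f: (c, fc) for f, c, fc in truth.planted_de}
    base_mean = 50.0
    count_rows = {}
    for feat in circ_rpm.features:
        mu = np.full(n, base_mean)
        if feat in de_by_feature:
            (_ga, gb), fc = de_by_feature[feat]
            mu = np.where(groups.values == gb, base_mean * fc, base_mean)
        count_rows[feat] = rng.poisson(mu)
    circ_counts = ExpressionMatrix(
        pd.DataFrame.from_dict(count_rows, orient="index", columns=samples),
        groups,
        "counts",
    )
    mapped_totals = pd.Series(2_000_000, index=samples, dtype=float)

    traits = _simulate_traits(config, truth, circ_rpm, groups, rng)
    return SimExpression(circ_rpm, mirna_rpm, mrna_rpm, circ_counts,
                         mapped_totals, traits)


def _simulate_traits(
    config: SimConfig,
    truth: SimTruth,
    circ_rpm: ExpressionMatrix,
    groups: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    samples = list(groups.index)
    n = len(samples)
    cols: dict[str, np.ndarray] = {}
    for ti, trait in enumerate(config.trait_names):
        if trait in DEFAULT_TRAIT_MEANS and config.n_groups == 4:
            means = DEFAULT_TRAIT_MEANS[trait]
        elif ti == len(config.trait_names) - 1:
            # last trait carries the planted monotone trend across groups
            means = tuple(30.0 + 12.0 * g for g in range(config.n_groups))
        else:
            means = tuple(50.0 + 10.0 * ((g + ti) % config.n_groups)
                          for g in range(config.n_groups))
        mean_by_group = dict(zip(config.group_names, means))
        mu = np.array([mean_by_group[groups[s]] for s in samples])
        noise_sd = 0.05 * float(np.mean(means))
        cols[trait] = mu + rng.normal(0.0, noise_sd, n)

    for feat, trait, sign in truth.planted_trait_associations:
        expr = circ_rpm.data.loc[feat].to_numpy(dtype=float)
        z = (expr - expr.mean()) / (expr.std() or 1.0)
        noise_sd = 0.05 * float(np.mean(cols[trait]))
        cols[trait] = cols[trait] + sign * 3.0 * noise_sd * z

    df = pd.DataFrame(cols, index=samples)
    df.insert(0, "group", groups.values)
    df.index.name = "sample"
    return df


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, sep="\t", float_format="%.6g")


def read_traits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
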