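"""Shared coordinate model and readers/writers for external formats.

All internal coordinates are 1-based and inclusive at both ends, so the
interval Chr1:212,499,519-213,348,230 has length
213,348,230 - 212,499,519 + 1 = 848,712 nt. Only BED I/O converts to the
0-based half-open convention; VCF symbolic structural-variant records use
the anchor-base convention (POS = start - 1, INFO END = inclusive end).

Alignment files (SAM/BAM) are read through pysam; a plain-text 8-column TSV
pair dialect is supported as an alignment-free alternative so that the
caller can be exercised without binary files or an external aligner:

    pair_id  chrom1  start1  end1  strand1  chrom2  start2  end2

(header line required; coordinates 1-based inclusive). The dialect carries
no mapping quality, so TSV pairs are treated as uniquely mapped (mapq 255).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PAIR_TSV_COLUMNS = (
    "pair_id",
    "chrom1",
    "start1",
    "end1",
    "strand1",
    "chrom2",
    "start2",
    "end2",
)


def round_half_up(x: float) -> int:
    """Round a non-negative value half-up to an integer (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Coordinate model
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, both-ends-inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"invalid interval: start {self.start} < 1")
        if self.end < self.start:
            raise ValueError(
                f"invalid interval: end {self.end} < start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_bed(cls, chrom: str, bed_start: int, bed_end: int) -> "GenomicInterval":
        return cls(chrom, bed_start + 1, bed_end)

    def to_bed(self) -> tuple[str, int, int]:
        return (self.chrom, self.start - 1, self.end)


def interval_length(iv: GenomicInterval) -> int:
    """Inclusive length end - start + 1 (validity is enforced by the type)."""
    return iv.length


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two inclusive intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(ov/len(a), ov/len(b)) — the standard SV-matching statistic."""
    ov = overlap_length(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


# ---------------------------------------------------------------------------
# Aligned pairs
# ---------------------------------------------------------------------------


class ReadFraction(str, Enum):
    """Library fraction: mate-pair (junction-bearing) or shotgun."""

    MP = "MP"
    SG = "SG"


class ReadAln(NamedTuple):
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class AlignedPair:
    pair_id: str
    read1: ReadAln
    read2: ReadAln
    mapq: int = 255
    fraction: ReadFraction = ReadFraction.MP


@dataclass
class ReadPairCounts:
    n_yielded: int = 0
    n_dropped_mapq: int = 0
    n_dropped_unmapped: int = 0
    n_orphans: int = 0


class PairFileError(ValueError):
    """Malformed alignment/pair file."""


def read_pairs(
    path: str | Path,
    min_mapq: int = 30,
    fraction: ReadFraction = ReadFraction.MP,
) -> tuple[list[AlignedPair], ReadPairCounts]:
    """Read aligned pairs from SAM/BAM or the TSV pair dialect.

    Pairs with either mate unmapped or with mapq below ``min_mapq`` are
    dropped and counted; orphan reads (mate never seen) are counted and
    skipped. Returns (pairs, counts).
    """
    p = str(path)
    if p.endswith((".sam", ".bam", ".cram")):
        return _read_pairs_alignment(p, min_mapq, fraction)
    return _read_pairs_tsv(p, min_mapq, fraction)


def _read_pairs_alignment(
    path: str, min_mapq: int, fraction: ReadFraction
) -> tuple[list[AlignedPair], ReadPairCounts]:
    counts = ReadPairCounts()
    pairs: list[AlignedPair] = []
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            if rec.is_unmapped or mate.is_unmapped:
                counts.n_dropped_unmapped += 1
                continue
            if min(rec.mapping_quality, mate.mapping_quality) < min_mapq:
                counts.n_dropped_mapq += 1
                continue
            r1, r2 = (mate, rec) if mate.is_read1 else (rec, mate)
            pairs.append(
                AlignedPair(
                    pair_id=rec.query_name,
                    read1=_aln_of(r1),
                    read2=_aln_of(r2),
                    mapq=min(rec.mapping_quality, mate.mapping_quality),
                    fraction=fraction,
                )
            )
            counts.n_yielded += 1
    counts.n_orphans = len(pending)
    return pairs, counts


def _aln_of(rec: pysam.AlignedSegment) -> ReadAln:
    return ReadAln(
        chrom=rec.reference_name,
        start=rec.reference_start + 1,
        end=rec.reference_end,
        strand="-" if rec.is_reverse else "+",
    )


def _read_pairs_tsv(
    path: str, min_mapq: int, fraction: ReadFraction
) -> tuple[list[AlignedPair], ReadPairCounts]:
    counts = ReadPairCounts()
    pairs: list[AlignedPair] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header) != PAIR_TSV_COLUMNS:
                    raise PairFileError(
                        f"{path}:{lineno}: expected header "
                        f"{' '.join(PAIR_TSV_COLUMNS)}, got {' '.join(header)}"
                    )
                continue
            if len(fields) != len(PAIR_TSV_COLUMNS):
                raise PairFileError(
                    f"{path}:{lineno}: expected {len(PAIR_TSV_COLUMNS)} "
                    f"columns, got {len(fields)}"
                )
            try:
                s1, e1 = int(fields[2]), int(fields[3])
                s2, e2 = int(fields[6]), int(fields[7])
            except ValueError as exc:
                raise PairFileError(f"{path}:{lineno}: {exc}") from None
            strand1 = fields[4]
            if strand1 not in ("+", "-"):
                raise PairFileError(
                    f"{path}:{lineno}: strand must be '+' or '-', got {strand1!r}"
                )
            if e1 < s1 or e2 < s2 or s1 < 1 or s2 < 1:
                raise PairFileError(f"{path}:{lineno}: invalid read interval")
            # The dialect carries no mapq; 255 marks "unavailable" and passes
            # any threshold, matching the simulator's unique placements.
            mapq = 255
            if mapq < min_mapq:
                counts.n_dropped_mapq += 1
                continue
            strand2 = "-" if strand1 == "+" else "+"
            pairs.append(
                AlignedPair(
                    pair_id=fields[0],
                    read1=ReadAln(fields[1], s1, e1, strand1),
                    read2=ReadAln(fields[5], s2, e2, strand2),
                    mapq=mapq,
                    fraction=fraction,
                )
            )
            counts.n_yielded += 1
        if header is None and counts.n_yielded == 0:
            # empty file -> empty stream, zero counts
            pass
    return pairs, counts


def write_pairs_tsv(pairs: Iterable[AlignedPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_TSV_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        p.pair_id,
                        p.read1.chrom,
                        p.read1.start,
                        p.read1.end,
                        p.read1.strand,
                        p.read2.chrom,
                        p.read2.start,
                        p.read2.end,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Structural-variant calls
# ---------------------------------------------------------------------------


class SVType(str, Enum):
    DEL = "DEL"
    INS = "INS"


@dataclass(frozen=True)
class SVCall:
    """A clustered deletion or insertion call.

    For deletions the interval is the estimated deleted region; for
    insertions it is the insertion point with its positional uncertainty.
    """

    sv_type: SVType
    interval: GenomicInterval
    size_estimate: int
    support: int
    sample_id: str = "sample"

    @property
    def point(self) -> int:
        """Midpoint, used as the insertion breakpoint estimate."""
        return (self.interval.start + self.interval.end) // 2


def _check_sorted(calls: Sequence[SVCall]) -> None:
    keys = [(c.interval.chrom, c.interval.start) for c in calls]
    if keys != sorted(keys):
        raise ValueError(
            "calls are not sorted by (chrom, start); sort them, e.g. "
            "sorted(calls, key=lambda c: (c.interval.chrom, c.interval.start))"
        )


def write_calls(
    calls: Sequence[SVCall],
    path: str | Path,
    fmt: str = "bed",
    provenance: Sequence[str] | None = None,
) -> None:
    """Write calls as BED (0-based half-open) or VCF 4.2 (symbolic alleles).

    Input must be sorted by (chrom, start). VCF uses <DEL>/<INS> with INFO
    END (inclusive end), SVLEN (negative for deletions), SUPPORT and SID.
    """
    _check_sorted(calls)
    fmt = fmt.lower()
    if fmt == "bed":
        _write_bed(calls, path, provenance)
    elif fmt == "vcf":
        _write_vcf(calls, path, provenance)
    else:
        raise ValueError(f"unknown call format {fmt!r} (expected 'bed' or 'vcf')")


def _write_bed(
    calls: Sequence[SVCall], path: str | Path, provenance: Sequence[str] | None
) -> None:
    with open(path, "w") as fh:
        for line in provenance or ():
            fh.write(f"#{line}\n")
        for c in calls:
            chrom, b_start, b_end = c.interval.to_bed()
            name = f"{c.sv_type.value}:{c.size_estimate}:{c.support}:{c.sample_id}"
            fh.write(f"{chrom}\t{b_start}\t{b_end}\t{name}\t{c.support}\t+\n")


def _write_vcf(
    calls: Sequence[SVCall], path: str | Path, provenance: Sequence[str] | None
) -> None:
    contigs: list[str] = []
    for c in calls:
        if c.interval.start < 2:
            raise ValueError(
                "VCF anchor-base convention requires call start >= 2; "
                f"got start {c.interval.start} (use BED for telomeric calls)"
            )
        if c.interval.chrom not in contigs:
            contigs.append(c.interval.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=allseq\n")
        for line in provenance or ():
            fh.write(f"##allseq_{line}\n")
        for chrom in sorted(contigs):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=INS,Description="Insertion">\n')
        fh.write(
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n'
            '##INFO=<ID=END,Number=1,Type=Integer,Description="Inclusive end">\n'
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,'
            'Description="SV length, negative for deletions">\n'
            '##INFO=<ID=SUPPORT,Number=1,Type=Integer,'
            'Description="Supporting mate pairs">\n'
            '##INFO=<ID=SID,Number=1,Type=String,Description="Sample id">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls, start=1):
            svlen = -c.size_estimate if c.sv_type is SVType.DEL else c.size_estimate
            info = (
                f"SVTYPE={c.sv_type.value};END={c.interval.end};SVLEN={svlen};"
                f"SUPPORT={c.support};SID={c.sample_id}"
            )
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start - 1}\t"
                f"allseq_{c.sv_type.value.lower()}_{i}\tN\t<{c.sv_type.value}>\t"
                f".\tPASS\t{info}\n"
            )


def read_calls(path: str | Path, fmt: str | None = None) -> list[SVCall]:
    """Read calls back from BED or VCF into 1-based inclusive coordinates."""
    p = str(path)
    if fmt is None:
        fmt = "vcf" if p.endswith(".vcf") else "bed"
    return _read_vcf(p) if fmt.lower() == "vcf" else _read_bed(p)


def _read_bed(path: str) -> list[SVCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED call line needs >= 4 columns")
            chrom, b_start, b_end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            parts = name.split(":")
            sv_type = SVType(parts[0])
            size = int(parts[1]) if len(parts) > 1 else b_end - b_start
            support = int(parts[2]) if len(parts) > 2 else 0
            sample = parts[3] if len(parts) > 3 else "sample"
            calls.append(
                SVCall(sv_type, GenomicInterval.from_bed(chrom, b_start, b_end),
                       size, support, sample)
            )
    return calls


def _read_vcf(path: str) -> list[SVCall]:
    calls = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            sv_type = SVType(rec.info["SVTYPE"])
            svlen = rec.info["SVLEN"]
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            end = rec.stop  # pysam exposes INFO END as the inclusive stop
            calls.append(
                SVCall(
                    sv_type,
                    GenomicInterval(rec.chrom, rec.pos + 1, end),
                    abs(int(svlen)),
                    int(rec.info.get("SUPPORT", 0)),
                    str(rec.info.get("SID", "sample")),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Expression tables, gene models, TADs, FASTA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    sample_id: str
    rpkm: float

    def __post_init__(self) -> None:
        if self.rpkm < 0:
            raise ValueError(f"rpkm must be >= 0, got {self.rpkm} for {self.gene_id}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    strand: str = "+"


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Long-format expression TSV with columns gene_id, sample_id, rpkm."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "sample_id", "rpkm"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"expression table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if (df["rpkm"] < 0).any():
        bad = df.loc[df["rpkm"] < 0, "gene_id"].iloc[0]
        raise ValueError(f"negative rpkm for gene {bad}")
    return df


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Gene models from GFF3 (``gene`` features, via gffutils) or BED."""
    p = str(path)
    if p.endswith((".gff", ".gff3")):
        import gffutils

        db = gffutils.create_db(
            p, ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes = []
        for g in db.features_of_type("gene"):
            gene_id = g.attributes.get("ID", [g.id])[0]
            genes.append(
                GeneModel(gene_id, GenomicInterval(g.seqid, g.start, g.end),
                          g.strand or "+")
            )
        return genes
    genes = []
    with open(p) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, b_start, b_end = fields[0], int(fields[1]), int(fields[2])
            gene_id = fields[3] if len(fields) > 3 else f"{chrom}:{b_start}-{b_end}"
            strand = fields[5] if len(fields) > 5 else "+"
            genes.append(
                GeneModel(gene_id, GenomicInterval.from_bed(chrom, b_start, b_end), strand)
            )
    return genes


def read_intervals_bed(path: str | Path) -> list[GenomicInterval]:
    """Plain intervals from BED (used for TAD domains)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append(GenomicInterval.from_bed(fields[0], int(fields[1]), int(fields[2])))
    return sorted(out)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def chrom_lengths(source: str | Path | Mapping[str, str]) -> dict[str, int]:
    """Chromosome lengths from a genome dict, a .fai index, or a FASTA."""
    if isinstance(source, Mapping):
        return {name: len(seq) for name, seq in source.items()}
    p = str(source)
    if p.endswith(".fai"):
        lengths = {}
        with open(p) as fh:
            for line in fh:
                fields = line.split("\t")
                lengths[fields[0]] = int(fields[1])
        return lengths
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(p, "fasta")}
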