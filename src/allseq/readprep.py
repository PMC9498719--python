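"""Split raw All-seq reads into mate-pair and shotgun fractions.

An All-seq library mixes two fragment populations: mate-pair (MP) fragments
that carry the Tn5 adapter at the junction where the two ends of a long
circularized molecule were joined, and shotgun (SG) fragments with no
junction. A read containing the adapter is cut at it; the two genomic
flanks become an MP read pair (written as _1/_2 mates) whose aligned outer
distance reports the original long-fragment span. Junction-free reads pass
through as SG.

Adapter matching is Hamming-distance substring search (the Tn5 junction is
fixed-length, so no indels are modelled), scanning both the adapter and its
reverse complement; the best hit is the one with fewest mismatches,
breaking ties leftmost and then forward-orientation first. Reads containing
more than one junction (re-circularization chimeras) are discarded and
counted, as are reads whose junction sits too close to an end to leave
``min_flank`` bases on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Seq import reverse_complement
from Bio.SeqRecord import SeqRecord

_VALID_BASES = set("ACGT")


@dataclass(frozen=True)
class JunctionScanConfig:
    adapter_seq: str
    max_mismatches: int = 0
    min_flank: int = 20

    def __post_init__(self) -> None:
        if not self.adapter_seq or set(self.adapter_seq.upper()) - _VALID_BASES:
            raise ValueError("adapter_seq must be a non-empty A/C/G/T string")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.min_flank < 1:
            raise ValueError("min_flank must be >= 1")


class JunctionHit(NamedTuple):
    offset: int  # 0-based start of the adapter occurrence in the read
    mismatches: int
    strand: str  # '+' adapter as given, '-' reverse complement


def _hamming_best(seq: str, pattern: str, max_mm: int) -> tuple[int, int] | None:
    """Best (offset, mismatches) of pattern in seq, fewest-mismatch then
    leftmost; None if no occurrence within max_mm. Brute-force-equivalent."""
    n, m = len(seq), len(pattern)
    if m > n:
        return None
    best: tuple[int, int] | None = None
    for off in range(n - m + 1):
        mm = 0
        window = seq[off : off + m]
        if max_mm == 0:
            if window != pattern:
                continue
        else:
            for a, b in zip(window, pattern):
                if a != b:
                    mm += 1
                    if mm > max_mm:
                        break
            if mm > max_mm:
                continue
        if best is None or mm < best[1]:
            best = (off, mm)
            if mm == 0:
                break  # cannot improve; leftmost exact wins
    return best


def scan_junction(read_seq: str, cfg: JunctionScanConfig) -> JunctionHit | None:
    """Locate the junction adapter in a read, or return None.

    Both adapter orientations are scanned; the hit with fewest mismatches
    wins, ties broken leftmost and then by forward orientation.
    """
    seq = read_seq.upper()
    adapter = cfg.adapter_seq.upper()
    candidates: list[tuple[int, int, int, str]] = []  # (mm, offset, orient_rank, strand)
    fwd = _hamming_best(seq, adapter, cfg.max_mismatches)
    if fwd is not None:
        candidates.append((fwd[1], fwd[0], 0, "+"))
    rc = reverse_complement(adapter)
    if rc != adapter:
        rev = _hamming_best(seq, rc, cfg.max_mismatches)
        if rev is not None:
            candidates.append((rev[1], rev[0], 1, "-"))
    if not candidates:
        return None
    mm, off, _, strand = min(candidates)
    return JunctionHit(offset=off, mismatches=mm, strand=strand)


@dataclass
class SplitCounts:
    n_mp: int = 0
    n_sg: int = 0
    n_discarded: int = 0
    n_short_flank: int = 0
    n_multi_junction: int = 0

    @property
    def total(self) -> int:
        return self.n_mp + self.n_sg + self.n_discarded


@dataclass
class SplitResult:
    """Partitioned reads: MP flank pairs, SG pass-through, and counts."""

    mp_read_pairs: list[tuple[SeqRecord, SeqRecord]] = field(default_factory=list)
    sg_reads: list[SeqRecord] = field(default_factory=list)
    counts: SplitCounts = field(default_factory=SplitCounts)


def _has_any_hit(seq: str, adapter: str, rc: str, max_mm: int) -> bool:
    if _hamming_best(seq, adapter, max_mm) is not None:
        return True
    return rc != adapter and _hamming_best(seq, rc, max_mm) is not None


def split_reads(
    fastq_in: str | Path | Iterable[SeqRecord],
    cfg: JunctionScanConfig,
) -> SplitResult:
    """Partition a FASTQ into MP flank pairs and SG reads.

    Junction-bearing reads are cut at the adapter; each flank must be at
    least ``min_flank`` bases or the read is discarded. Qualities are
    preserved by record slicing. Reads with a second junction in either
    flank are discarded as chimeras.
    """
    if isinstance(fastq_in, (str, Path)):
        records = _parse_fastq(str(fastq_in))
    else:
        records = fastq_in
    result = SplitResult()
    adapter = cfg.adapter_seq.upper()
    rc = reverse_complement(adapter)
    alen = len(adapter)
    for rec in records:
        seq = str(rec.seq).upper()
        hit = scan_junction(seq, cfg)
        if hit is None:
            result.sg_reads.append(rec)
            result.counts.n_sg += 1
            continue
        left = rec[: hit.offset]
        right = rec[hit.offset + alen :]
        if len(left) < cfg.min_flank or len(right) < cfg.min_flank:
            result.counts.n_discarded += 1
            result.counts.n_short_flank += 1
            continue
        if _has_any_hit(str(left.seq).upper(), adapter, rc, cfg.max_mismatches) or \
           _has_any_hit(str(right.seq).upper(), adapter, rc, cfg.max_mismatches):
            result.counts.n_discarded += 1
            result.counts.n_multi_junction += 1
            continue
        left.id, left.description = f"{rec.id}/1", ""
        right.id, right.description = f"{rec.id}/2", ""
        result.mp_read_pairs.append((left, right))
        result.counts.n_mp += 1
    return result


def _parse_fastq(path: str) -> Iterable[SeqRecord]:
    idx = 0
    try:
        for rec in SeqIO.parse(path, "fastq"):
            idx += 1
            yield rec
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTQ after record {idx}: {exc}") from exc


def write_split(
    result: SplitResult,
    mp1_path: str | Path,
    mp2_path: str | Path,
    sg_path: str | Path,
) -> None:
    """Write MP flanks as _1/_2 FASTQ mates and SG reads as a third FASTQ."""
    SeqIO.write((p[0] for p in result.mp_read_pairs), str(mp1_path), "fastq")
    SeqIO.write((p[1] for p in result.mp_read_pairs), str(mp2_path), "fastq")
    SeqIO.write(result.sg_reads, str(sg_path), "fastq")
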