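"""All-seq read simulator with implanted truth-set InDels.

Generates a uniform-random genome, applies non-overlapping deletions and
insertions while keeping an exact coordinate map back to the reference,
and draws All-seq fragments from the altered genome:

* mate-pair (MP) fragments with spans from a normal distribution whose
  median and IQR default to the library statistics of the method this
  package implements (6 kb median, 0.6 kb IQR; sigma = IQR / 1.349 by the
  normal-theory conversion, since only median and IQR are reported);
* shotgun (SG) fragments near 330 bp with no junction;
* an inter-chromosomal pair rate of ~0.76%, matching the observed
  inter/total MP share, when the genome has several chromosomes.

Reads can be emitted two ways: raw FASTQ junction reads (each MP read
carries the adapter between its two genomic flanks, for exercising the
read-splitting stage; truth labels ride in read names as ``id:fraction``)
or an already-"aligned" pair table in *reference* coordinates via the
coordinate map, which decouples caller tests from any external aligner. A
pair straddling an implanted deletion therefore maps with span equal to the
library span plus the deletion size, exactly the signal the caller fits.

``evaluate_calls`` scores a call set against the implanted truth at a
reciprocal-overlap threshold (deletions) or breakpoint distance
(insertions).
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    AlignedPair,
    GenomicInterval,
    ReadAln,
    ReadFraction,
    SVCall,
    SVType,
    reciprocal_overlap,
)

# Tn5 mosaic-end sequence: the standard 19 bp transposase junction left at
# the circularization point of the mate-pair fragments.
DEFAULT_ADAPTER = "AGATGTGTATAAGAGACAG"

# IQR of a normal distribution = 2 * Phi^-1(0.75) * sigma = 1.349 * sigma
IQR_TO_SIGMA = 1.349

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic All-seq library.

    Defaults mirror the reported library: MP spans concentrated at 6 kb
    with 0.6 kb IQR at 1.43x depth, SG fragments near 330 bp at 37.83x
    depth, 150 bp reads, error-free bases unless substitution_rate > 0.
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 1
    mp_span_median: int = 6_000
    mp_span_iqr: int = 600
    sg_size_mean: int = 330
    sg_size_sd: int = 35
    read_length: int = 150
    mp_depth: float = 1.43
    sg_depth: float = 37.83
    inter_rate: float = 4473 / 586071  # observed inter-chromosomal MP share
    substitution_rate: float = 0.0
    adapter_seq: str = DEFAULT_ADAPTER
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.genome_length, self.n_chromosomes, self.mp_span_median,
               self.read_length) <= 0:
            raise ValueError("simulation sizes must be positive")
        if self.mp_depth <= 0 or self.sg_depth <= 0:
            raise ValueError("depths must be positive")

    @property
    def mp_span_sigma(self) -> float:
        return self.mp_span_iqr / IQR_TO_SIGMA


@dataclass(frozen=True)
class Variant:
    """A truth variant in reference coordinates.

    For deletions the interval is the removed region (size = length). For
    insertions start == end is the base AFTER which ``size`` random bases
    are inserted.
    """

    sv_type: SVType
    chrom: str
    start: int
    end: int
    size: int

    @classmethod
    def deletion(cls, chrom: str, start: int, end: int) -> "Variant":
        return cls(SVType.DEL, chrom, start, end, end - start + 1)

    @classmethod
    def insertion(cls, chrom: str, pos: int, size: int) -> "Variant":
        return cls(SVType.INS, chrom, pos, pos, size)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


class _CoordMap:
    """Piecewise map from altered-genome to reference coordinates."""

    def __init__(self) -> None:
        self.alt_starts: list[int] = []
        self.ref_starts: list[int | None] = []  # None for inserted segments
        self.seg_lens: list[int] = []

    def add(self, alt_start: int, ref_start: int | None, length: int) -> None:
        if length > 0:
            self.alt_starts.append(alt_start)
            self.ref_starts.append(ref_start)
            self.seg_lens.append(length)

    def to_ref(self, pos: int) -> int | None:
        """Reference coordinate of an altered-genome position (1-based);
        None inside inserted sequence."""
        i = bisect_right(self.alt_starts, pos) - 1
        if i < 0:
            return None
        off = pos - self.alt_starts[i]
        if off >= self.seg_lens[i]:
            return None
        ref = self.ref_starts[i]
        return None if ref is None else ref + off

    def to_ref_clamped(self, pos: int) -> int | None:
        """Like to_ref, but positions inside inserted sequence clamp to the
        last reference base before the insertion (None only if there is no
        mapped segment to the left)."""
        i = bisect_right(self.alt_starts, pos) - 1
        if i < 0:
            return None
        off = pos - self.alt_starts[i]
        if off >= self.seg_lens[i]:
            i, off = len(self.alt_starts) - 1, self.seg_lens[-1] - 1
        while i >= 0 and self.ref_starts[i] is None:
            i -= 1
            if i >= 0:
                off = self.seg_lens[i] - 1
        if i < 0:
            return None
        return self.ref_starts[i] + off

    def in_insertion(self, pos: int) -> bool:
        return self.to_ref(pos) is None and bisect_right(self.alt_starts, pos) > 0


@dataclass
class TruthSet:
    """Implanted variants plus the altered->reference coordinate map."""

    variants: list[Variant]
    maps: dict[str, _CoordMap] = field(default_factory=dict)
    ref_lengths: dict[str, int] = field(default_factory=dict)
    alt_lengths: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sv_type": [v.sv_type.value for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "start": [v.start for v in self.variants],
                "end": [v.end for v in self.variants],
                "size": [v.size for v in self.variants],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        variants = [
            Variant(SVType(r.sv_type), str(r.chrom), int(r.start), int(r.end),
                    int(r.size))
            for r in df.itertuples()
        ]
        return cls(variants)


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def make_genome(cfg: SimulationConfig) -> dict[str, str]:
    """Uniform-random genome, reproducible from cfg.seed.

    ``genome_length`` is split evenly across ``n_chromosomes`` named
    chr1..chrN.
    """
    rng = np.random.default_rng(cfg.seed)
    per = cfg.genome_length // cfg.n_chromosomes
    genome = {}
    for i in range(cfg.n_chromosomes):
        length = per if i < cfg.n_chromosomes - 1 else cfg.genome_length - per * (
            cfg.n_chromosomes - 1
        )
        genome[f"chr{i + 1}"] = _random_seq(rng, length)
    return genome


def apply_variants(
    genome: Mapping[str, str],
    variants: Sequence[Variant],
    seed: int = 0,
) -> tuple[dict[str, str], TruthSet]:
    """Apply deletions/insertions to a genome, returning the altered genome
    and a TruthSet with the exact coordinate map.

    Deletions remove the inclusive interval; insertions add ``size`` random
    bases after ``start``. Variants must be non-overlapping and in bounds.
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        if v.chrom not in genome:
            raise ValueError(f"variant on unknown chromosome {v.chrom!r}")
        if v.start < 1 or v.end > len(genome[v.chrom]):
            raise ValueError(f"variant out of bounds: {v}")
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom, vs in by_chrom.items():
        vs.sort(key=lambda v: v.start)
        for a, b in zip(vs, vs[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping variants on {chrom}: {a} and {b}")

    truth = TruthSet(variants=sorted(variants, key=lambda v: (v.chrom, v.start)))
    altered: dict[str, str] = {}
    for chrom, seq in genome.items():
        cmap = _CoordMap()
        pieces: list[str] = []
        ref_cursor = 1  # next reference base to copy (1-based)
        alt_cursor = 1
        for v in by_chrom.get(chrom, []):
            if v.sv_type is SVType.DEL:
                keep = v.start - ref_cursor  # bases before the deletion
                if keep > 0:
                    pieces.append(seq[ref_cursor - 1 : v.start - 1])
                    cmap.add(alt_cursor, ref_cursor, keep)
                    alt_cursor += keep
                ref_cursor = v.end + 1
            else:  # insertion after v.start
                keep = v.start - ref_cursor + 1
                if keep > 0:
                    pieces.append(seq[ref_cursor - 1 : v.start])
                    cmap.add(alt_cursor, ref_cursor, keep)
                    alt_cursor += keep
                ref_cursor = v.start + 1
                pieces.append(_random_seq(rng, v.size))
                cmap.add(alt_cursor, None, v.size)
                alt_cursor += v.size
        tail = len(seq) - ref_cursor + 1
        if tail > 0:
            pieces.append(seq[ref_cursor - 1 :])
            cmap.add(alt_cursor, ref_cursor, tail)
            alt_cursor += tail
        altered[chrom] = "".join(pieces)
        truth.maps[chrom] = cmap
        truth.ref_lengths[chrom] = len(seq)
        truth.alt_lengths[chrom] = len(altered[chrom])
    return altered, truth


def random_deletions(
    genome: Mapping[str, str],
    n: int,
    size_range: tuple[int, int] = (10_000, 200_000),
    seed: int = 0,
    margin: int = 40_000,
    end_buffer: int = 50_000,
) -> list[Variant]:
    """Non-overlapping random deletions with log-uniform sizes.

    ``margin`` keeps events far enough apart that their discordant-pair
    clusters stay distinct; ``end_buffer`` keeps them away from chromosome
    ends.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[Variant] = []
    lo, hi = size_range
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("could not place non-overlapping deletions")
        size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
        max_start = len(genome[chrom]) - end_buffer - size
        if max_start <= end_buffer:
            continue
        start = int(rng.integers(end_buffer, max_start))
        end = start + size - 1
        if any(start - margin <= e and s - margin <= end for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        out.append(Variant.deletion(chrom, start, end))
    return sorted(out, key=lambda v: (v.chrom, v.start))


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class PairSimResult:
    pairs: list[AlignedPair]
    n_resampled: int  # fragments redrawn because the span exceeded the chromosome
    n_unmappable: int  # pairs dropped because a read lay wholly in novel sequence


def _pick_chroms(
    rng: np.random.Generator, genome: Mapping[str, str], n: int
) -> list[str]:
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    idx = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    return [chroms[i] for i in idx]


def simulate_pairs(
    genome: Mapping[str, str],
    cfg: SimulationConfig,
    truth: TruthSet | None = None,
) -> PairSimResult:
    """Draw MP fragments from the (altered) genome and emit aligned pairs
    in reference coordinates.

    Each fragment of span S places a plus-strand read on its first
    ``read_length`` bases and a minus-strand read on its last; coordinates
    are pushed through the truth coordinate map, so pairs straddling an
    implanted deletion acquire reference spans inflated by the deletion
    size. With no truth set the map is the identity. Fragments that do not
    fit their chromosome are resampled (counted); pairs with a read wholly
    inside inserted (novel) sequence are unmappable and dropped (counted).
    """
    rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_length
    total_len = sum(len(s) for s in genome.values())
    n_pairs = int(round(cfg.mp_depth * total_len / (2.0 * rl)))
    chroms = _pick_chroms(rng, genome, n_pairs)
    spans = rng.normal(cfg.mp_span_median, cfg.mp_span_sigma, size=n_pairs)
    inter = (
        rng.random(n_pairs) < cfg.inter_rate if len(genome) > 1
        else np.zeros(n_pairs, dtype=bool)
    )
    pairs: list[AlignedPair] = []
    n_resampled = 0
    n_unmappable = 0
    all_chroms = sorted(genome)
    for i in range(n_pairs):
        chrom = chroms[i]
        clen = len(genome[chrom])
        span = int(round(spans[i]))
        while span < 2 * rl + 1 or span > clen:
            n_resampled += 1
            span = int(round(rng.normal(cfg.mp_span_median, cfg.mp_span_sigma)))
        start = int(rng.integers(1, clen - span + 2))
        if inter[i]:
            # mate lands on another chromosome: a translocation-free library
            # artifact class, reported but never called
            others = [c for c in all_chroms if c != chrom]
            chrom2 = others[int(rng.integers(0, len(others)))]
            pos2 = int(rng.integers(1, len(genome[chrom2]) - rl + 1))
            r1 = _map_read(chrom, start, start + rl - 1, "+", truth)
            r2 = _map_read(chrom2, pos2, pos2 + rl - 1, "-", truth)
            if r1 is None or r2 is None:
                n_unmappable += 1
                continue
            pairs.append(AlignedPair(f"mp{i}", r1, r2, 60, ReadFraction.MP))
            continue
        end = start + span - 1
        r1 = _map_read(chrom, start, start + rl - 1, "+", truth)
        r2 = _map_read(chrom, end - rl + 1, end, "-", truth)
        if r1 is None or r2 is None:
            n_unmappable += 1
            continue
        pairs.append(AlignedPair(f"mp{i}", r1, r2, 60, ReadFraction.MP))
    return PairSimResult(pairs, n_resampled, n_unmappable)


def _map_read(
    chrom: str, start: int, end: int, strand: str, truth: TruthSet | None
) -> ReadAln | None:
    """Reference placement of one simulated read.

    A read crossing a variant breakpoint is anchored at its outermost base
    (5' end: the start for a plus read, the end for a minus read) and
    extends contiguously from there, mimicking an aligner's clipped primary
    alignment; interpolating both endpoints through the coordinate map
    would stretch the read across the event. Reads wholly inside inserted
    (novel) sequence have no reference placement and drop the pair.
    """
    if truth is None or chrom not in truth.maps:
        return ReadAln(chrom, start, end, strand)
    cmap = truth.maps[chrom]
    # a read wholly inside inserted sequence has no reference placement
    if cmap.to_ref(start) is None and cmap.to_ref(end) is None:
        return None
    length = end - start + 1
    if strand == "+":
        ref_start = cmap.to_ref_clamped(start)
        if ref_start is None:
            return None
        ref_end = ref_start + length - 1
    else:
        ref_end = cmap.to_ref_clamped(end)
        if ref_end is None:
            return None
        ref_start = max(1, ref_end - length + 1)
    return ReadAln(chrom, ref_start, ref_end, strand)


def simulate_reads(
    genome: Mapping[str, str],
    cfg: SimulationConfig,
) -> list[tuple[str, str]]:
    """Raw All-seq reads as (read_id, sequence) with truth labels in ids.

    MP junction reads carry the adapter between the two genomic flanks
    (fragment end + adapter + fragment start, the junction left by
    circularization); SG reads are adapter-free fragment prefixes. Ids end
    in ``:MP`` / ``:SG``. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_length
    adapter = cfg.adapter_seq.upper()
    alen = len(adapter)
    flank1 = (rl - alen) // 2
    flank2 = rl - alen - flank1
    if flank1 < 1:
        raise ValueError("read_length too short for the adapter plus flanks")
    total_len = sum(len(s) for s in genome.values())
    n_mp = int(round(cfg.mp_depth * total_len / (2.0 * max(flank1, 1))))
    n_sg = int(round(cfg.sg_depth * total_len / rl))
    reads: list[tuple[str, str]] = []

    mp_chroms = _pick_chroms(rng, genome, n_mp)
    for i in range(n_mp):
        chrom = mp_chroms[i]
        seq = genome[chrom]
        clen = len(seq)
        span = int(round(rng.normal(cfg.mp_span_median, cfg.mp_span_sigma)))
        while span < flank1 + flank2 + 1 or span > clen:
            span = int(round(rng.normal(cfg.mp_span_median, cfg.mp_span_sigma)))
        start = int(rng.integers(1, clen - span + 2))
        end = start + span - 1
        read = seq[end - flank1 : end] + adapter + seq[start - 1 : start - 1 + flank2]
        reads.append((f"mp{i}:MP", read))

    sg_chroms = _pick_chroms(rng, genome, n_sg)
    for i in range(n_sg):
        chrom = sg_chroms[i]
        seq = genome[chrom]
        clen = len(seq)
        size = int(round(rng.normal(cfg.sg_size_mean, cfg.sg_size_sd)))
        size = max(50, min(size, clen))
        start = int(rng.integers(1, clen - size + 2))
        reads.append((f"sg{i}:SG", seq[start - 1 : start - 1 + min(size, rl)]))

    if cfg.substitution_rate > 0:
        reads = [(rid, _mutate(rng, seq, cfg.substitution_rate)) for rid, seq in reads]
    return reads


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    arr[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
    return arr.tobytes().decode()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Truth-based evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    precision: float | None  # None when there are no calls (reported as NA)
    recall: float | None  # None when the truth set is empty
    n_calls: int
    n_true_positive_calls: int
    n_truth: int
    n_recovered: int
    table: pd.DataFrame  # one row per truth variant

    def to_json(self) -> str:
        payload = {
            "precision": self.precision,
            "recall": self.recall,
            "n_calls": self.n_calls,
            "n_true_positive_calls": self.n_true_positive_calls,
            "n_truth": self.n_truth,
            "n_recovered": self.n_recovered,
        }
        return json.dumps(payload, indent=2)


def _matches(call: SVCall, variant: Variant, ro: float, ins_tol: float) -> bool:
    if call.sv_type is not variant.sv_type or call.interval.chrom != variant.chrom:
        return False
    if variant.sv_type is SVType.DEL:
        return reciprocal_overlap(call.interval, variant.interval) >= ro
    return abs(call.point - variant.start) <= ins_tol


def evaluate_calls(
    calls: Sequence[SVCall],
    truth: TruthSet,
    ro: float = 0.5,
    ins_tolerance: float = 6_000,
) -> EvalReport:
    """Score calls against the implanted truth.

    A deletion is recovered when a DEL call matches it at reciprocal
    overlap >= ro; an insertion when an INS call's breakpoint lies within
    ``ins_tolerance`` (default the library median span, the positional
    resolution of the method). Precision counts calls matching any truth
    variant; with no calls precision is undefined (None).
    """
    rows = []
    recovered = 0
    for v in truth.variants:
        matching = [c for c in calls if _matches(c, v, ro, ins_tolerance)]
        best = max(
            matching,
            key=lambda c: reciprocal_overlap(c.interval, v.interval),
            default=None,
        )
        recovered += bool(matching)
        rows.append(
            {
                "sv_type": v.sv_type.value,
                "chrom": v.chrom,
                "start": v.start,
                "end": v.end,
                "size": v.size,
                "recovered": bool(matching),
                "best_call_start": best.interval.start if best else pd.NA,
                "best_call_end": best.interval.end if best else pd.NA,
                "best_call_size": best.size_estimate if best else pd.NA,
            }
        )
    tp_calls = sum(
        1
        for c in calls
        if any(_matches(c, v, ro, ins_tolerance) for v in truth.variants)
    )
    precision = tp_calls / len(calls) if calls else None
    recall = recovered / len(truth.variants) if truth.variants else None
    table = pd.DataFrame(
        rows,
        columns=[
            "sv_type", "chrom", "start", "end", "size", "recovered",
            "best_call_start", "best_call_end", "best_call_size",
        ],
    )
    return EvalReport(
        precision=precision,
        recall=recall,
        n_calls=len(calls),
        n_true_positive_calls=tp_calls,
        n_truth=len(truth.variants),
        n_recovered=recovered,
        table=table,
    )
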