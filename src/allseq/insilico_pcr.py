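"""In-silico PCR: predict band presence/absence for primer pairs.

Used to design and predict the wet-lab validation pattern for a deletion:
primers flanking the deleted region only amplify from the genome carrying
the deletion (on the reference the amplicon is longer than the amplifiable
ceiling), while primers internal to the deleted region amplify only from
reference genomes (the binding sites are gone in the deleted genome).

The model is positional, not thermodynamic: a product forms when a
plus-strand site of one primer faces a minus-strand site of the other on
the same chromosome, and the 5'-to-5' inclusive distance (the
gel-observable amplicon length) is within ``max_product``. Primer matching
is Hamming-distance with 0 mismatches by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward_seq: str
    reverse_seq: str
    max_product: int = 3_000

    def __post_init__(self) -> None:
        for seq in (self.forward_seq, self.reverse_seq):
            if len(seq) < 15:
                raise ValueError(f"primer {seq!r} shorter than 15 nt")
            if set(seq.upper()) - set("ACGT"):
                raise ValueError(f"primer {seq!r} contains non-ACGT bases")
        if self.max_product <= len(self.forward_seq) + len(self.reverse_seq):
            raise ValueError("max_product must exceed the summed primer lengths")


class SiteStatus(str, Enum):
    BOTH_SITES = "BOTH_SITES"
    MISSING_SITE = "MISSING_SITE"
    TOO_LONG = "TOO_LONG"


@dataclass(frozen=True)
class PCRPrediction:
    sample_id: str
    band: bool
    product_size: int | None
    site_status: SiteStatus


def _hamming_hits(seq: str, pattern: str, max_mm: int) -> list[int]:
    """0-based start offsets of pattern occurrences within max_mm mismatches."""
    n, m = len(seq), len(pattern)
    if m > n:
        return []
    if max_mm == 0:
        hits = []
        i = seq.find(pattern)
        while i != -1:
            hits.append(i)
            i = seq.find(pattern, i + 1)
        return hits
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    mm = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        mm += a[j : j + n - m + 1] != p[j]
    return [int(i) for i in np.nonzero(mm <= max_mm)[0]]


def find_primer_sites(
    genome: Mapping[str, str], primer: str, max_mismatches: int = 0
) -> list[tuple[str, int, str]]:
    """All binding sites of a primer on both strands.

    Returns (chrom, position, strand) with the 1-based position of the
    primer's 5' end: for a plus-strand site that is the leftmost matched
    base, for a minus-strand site (the reverse complement occurring on the
    plus strand) the rightmost.
    """
    primer = primer.upper()
    rc = reverse_complement(primer)
    m = len(primer)
    sites: list[tuple[str, int, str]] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for off in _hamming_hits(seq, primer, max_mismatches):
            sites.append((chrom, off + 1, "+"))
        for off in _hamming_hits(seq, rc, max_mismatches):
            sites.append((chrom, off + m, "-"))
    return sites


def predict_product(
    genome: Mapping[str, str],
    pair: PrimerPair,
    max_mismatches: int = 0,
    sample_id: str = "sample",
) -> PCRPrediction:
    """Predict the PCR outcome of a primer pair on one (variant-applied)
    genome.

    A product requires a plus-strand site of one primer and a downstream
    minus-strand site of the other primer on the same chromosome (both
    primer orderings are considered, since amplification does not know
    which primer was labelled forward). The smallest geometrically possible
    product is reported; a band appears when it is within ``max_product``.
    """
    fwd_sites = find_primer_sites(genome, pair.forward_seq, max_mismatches)
    rev_sites = find_primer_sites(genome, pair.reverse_seq, max_mismatches)
    len_f, len_r = len(pair.forward_seq), len(pair.reverse_seq)

    best: int | None = None
    for plus, minus, min_len in (
        (fwd_sites, rev_sites, len_f + len_r - 1),
        (rev_sites, fwd_sites, len_f + len_r - 1),
    ):
        plus_by_chrom: dict[str, list[int]] = {}
        for chrom, pos, strand in plus:
            if strand == "+":
                plus_by_chrom.setdefault(chrom, []).append(pos)
        for chrom, pos, strand in minus:
            if strand != "-":
                continue
            for p5 in plus_by_chrom.get(chrom, ()):
                size = pos - p5 + 1
                if size > min_len and (best is None or size < best):
                    best = size
    if best is None:
        return PCRPrediction(sample_id, False, None, SiteStatus.MISSING_SITE)
    if best > pair.max_product:
        return PCRPrediction(sample_id, False, best, SiteStatus.TOO_LONG)
    return PCRPrediction(sample_id, True, best, SiteStatus.BOTH_SITES)


def design_flanking_primers(
    genome: Mapping[str, str],
    chrom: str,
    start: int,
    end: int,
    offset: int = 1_000,
    primer_len: int = 20,
    max_product: int = 3_000,
    name: str = "flanking",
) -> PrimerPair:
    """Primers outside an interval, pointing inward (band after deletion).

    The forward primer starts ``offset`` bases left of ``start``; the
    reverse primer is the reverse complement of the sequence ending
    ``offset`` bases right of ``end``. Coordinates are 1-based inclusive.
    """
    seq = genome[chrom]
    f_start0 = start - 1 - offset
    r_end0 = end + offset
    if f_start0 < 0 or r_end0 > len(seq):
        raise ValueError("flanking primer offset outside the chromosome")
    forward = seq[f_start0 : f_start0 + primer_len]
    reverse = reverse_complement(seq[r_end0 - primer_len : r_end0])
    return PrimerPair(name, forward, reverse, max_product)


def design_internal_primers(
    genome: Mapping[str, str],
    chrom: str,
    start: int,
    end: int,
    primer_len: int = 20,
    product: int = 500,
    max_product: int = 3_000,
    name: str = "internal",
) -> PrimerPair:
    """Primers inside an interval (band only while the sequence exists)."""
    seq = genome[chrom]
    mid0 = (start + end) // 2 - 1
    f_start0 = mid0 - product // 2
    r_end0 = f_start0 + product
    if f_start0 < start - 1 or r_end0 > end:
        raise ValueError("requested product does not fit inside the interval")
    forward = seq[f_start0 : f_start0 + primer_len]
    reverse = reverse_complement(seq[r_end0 - primer_len : r_end0])
    return PrimerPair(name, forward, reverse, max_product)


def read_primers(path: str | Path) -> list[PrimerPair]:
    """Primer TSV with columns name, forward, reverse, max_product."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "forward", "reverse"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"primer table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            PrimerPair(
                str(row["name"]),
                str(row["forward"]).upper(),
                str(row["reverse"]).upper(),
                int(row.get("max_product", 3_000)),
            )
        )
    return pairs


def predictions_table(predictions: list[PCRPrediction], primer_name: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "primer": primer_name,
            "sample_id": [p.sample_id for p in predictions],
            "band": [p.band for p in predictions],
            "product_size": [p.product_size for p in predictions],
            "site_status": [p.site_status.value for p in predictions],
        }
    )
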