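"""Multi-sample comparison and annotation of InDel calls.

Covers the downstream analyses around a call set: which calls are specific
to a focal sample (reciprocal-overlap matching against reference call
sets), how sizes distribute across bins, which genes a deletion removes,
which genes lost or gained transcription between two samples (RPKM
presence/absence with a two-threshold hysteresis rule, not differential
expression), whether a deletion spans a TAD boundary and therefore fuses
neighbouring domains, and per-chromosome distributions for plotting.

Percentages throughout are rounded half-up to integers, which reproduces
printed shares such as 87/971 -> 9% and 65/87, 10/87, 12/87 -> 75%, 11%,
14%.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .formats_io import (
    GeneModel,
    GenomicInterval,
    SVCall,
    SVType,
    reciprocal_overlap,
    round_half_up,
)


# ---------------------------------------------------------------------------
# Sample specificity
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    focal_sample: str
    labels: list[str]  # 'SPECIFIC' or 'SHARED', aligned with the focal calls
    n_specific: int
    n_shared: int
    pct_specific: int
    reciprocal_overlap_threshold: float


def compare_samples(
    focal: Sequence[SVCall],
    references: Mapping[str, Sequence[SVCall]] | Sequence[Sequence[SVCall]],
    ro: float = 0.5,
    focal_sample: str = "focal",
) -> ComparisonResult:
    """Label each focal call SHARED or SPECIFIC against reference call sets.

    A focal call is SHARED if any same-type call in ANY reference sample
    overlaps it with reciprocal overlap >= ro, SPECIFIC otherwise. Labels
    do not depend on reference ordering.
    """
    if not (0 < ro <= 1):
        raise ValueError(f"reciprocal overlap threshold must be in (0, 1], got {ro}")
    if isinstance(references, Mapping):
        ref_sets = list(references.values())
    else:
        ref_sets = list(references)
    labels = []
    for call in focal:
        shared = any(
            other.sv_type == call.sv_type
            and reciprocal_overlap(call.interval, other.interval) >= ro
            for ref in ref_sets
            for other in ref
        )
        labels.append("SHARED" if shared else "SPECIFIC")
    n_specific = labels.count("SPECIFIC")
    n_shared = labels.count("SHARED")
    pct = round_half_up(100.0 * n_specific / len(labels)) if labels else 0
    return ComparisonResult(
        focal_sample=focal_sample,
        labels=labels,
        n_specific=n_specific,
        n_shared=n_shared,
        pct_specific=pct,
        reciprocal_overlap_threshold=ro,
    )


# ---------------------------------------------------------------------------
# Size binning
# ---------------------------------------------------------------------------

DEFAULT_SIZE_EDGES = (10_000, 50_000, 100_000)


@dataclass
class SizeBinSummary:
    edges: tuple[int, ...]
    labels: list[str]
    counts: list[int]
    percentages: list[int]
    n_underflow: int

    @property
    def total(self) -> int:
        return sum(self.counts) + self.n_underflow


def bin_by_size(
    calls: Sequence[SVCall], edges: Sequence[int] = DEFAULT_SIZE_EDGES
) -> SizeBinSummary:
    """Bin call sizes into half-open bins [e_i, e_{i+1}) plus a final
    [e_last, inf) bin; calls below the first edge land in an explicit
    underflow bin. Percentages (of all input calls) are rounded half-up."""
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("size bin edges must be strictly increasing")
    labels = [f"[{a}, {b})" for a, b in zip(edges, edges[1:])] + [f">= {edges[-1]}"]
    counts = [0] * len(labels)
    n_under = 0
    for call in calls:
        size = call.size_estimate
        if size < edges[0]:
            n_under += 1
            continue
        counts[bisect_right(edges, size) - 1] += 1
    total = len(calls)
    pct = [round_half_up(100.0 * c / total) if total else 0 for c in counts]
    return SizeBinSummary(edges, labels, counts, pct, n_under)


# ---------------------------------------------------------------------------
# Gene overlap and expression status
# ---------------------------------------------------------------------------


def gene_overlap(
    calls: Sequence[SVCall], genes: Sequence[GeneModel]
) -> list[list[GeneModel]]:
    """Per-call lists of genes intersecting the call interval (inclusive)."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # intervaltree is half-open; +1 on the end converts from inclusive
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end + 1, g
        )
    out: list[list[GeneModel]] = []
    for call in calls:
        tree = trees.get(call.interval.chrom)
        if tree is None:
            out.append([])
            continue
        hits = tree.overlap(call.interval.start, call.interval.end + 1)
        out.append(sorted((h.data for h in hits), key=lambda g: g.gene_id))
    return out


@dataclass(frozen=True)
class GeneStatusChange:
    gene_id: str
    status: str  # 'LOSS', 'GAIN' or 'UNCHANGED'
    rpkm_ref: float
    rpkm_focal: float
    on_threshold: float
    off_threshold: float


def expression_status(
    expr: pd.DataFrame,
    ref_sample: str,
    focal_sample: str,
    on_threshold: float = 1.0,
    off_threshold: float = 0.1,
) -> list[GeneStatusChange]:
    """Label genes LOSS/GAIN/UNCHANGED between two samples from RPKM values.

    LOSS: expressed in the reference (rpkm >= on_threshold) and silent in
    the focal sample (rpkm < off_threshold); GAIN is the mirror image. The
    two-threshold (hysteresis) rule avoids labelling noise-level changes.
    Genes missing in one sample count as 0 RPKM with a warning. Output is
    sorted by |rpkm_ref - rpkm_focal| descending, so the head of the list
    is the top-changes report.
    """
    if off_threshold >= on_threshold:
        raise ValueError("off_threshold must be below on_threshold")
    if (expr["rpkm"] < 0).any():
        raise ValueError("negative rpkm values are invalid")
    wide = expr.pivot_table(
        index="gene_id", columns="sample_id", values="rpkm", aggfunc="first"
    )
    for sample in (ref_sample, focal_sample):
        if sample not in wide.columns:
            wide[sample] = float("nan")
    pair = wide[[ref_sample, focal_sample]]
    n_missing = int(pair.isna().any(axis=1).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} gene(s) missing an RPKM value in one sample; treated as 0",
            stacklevel=2,
        )
        pair = pair.fillna(0.0)
    changes = []
    for gene_id, row in pair.iterrows():
        r, f = float(row[ref_sample]), float(row[focal_sample])
        if r >= on_threshold and f < off_threshold:
            status = "LOSS"
        elif f >= on_threshold and r < off_threshold:
            status = "GAIN"
        else:
            status = "UNCHANGED"
        changes.append(
            GeneStatusChange(str(gene_id), status, r, f, on_threshold, off_threshold)
        )
    changes.sort(key=lambda c: (-abs(c.rpkm_ref - c.rpkm_focal), c.gene_id))
    return changes


# ---------------------------------------------------------------------------
# TAD fusion
# ---------------------------------------------------------------------------


@dataclass
class TADFusionFlag:
    deletion: SVCall
    left_tad: GenomicInterval | None
    right_tad: GenomicInterval | None
    fused: bool
    removed_boundaries: int
    note: str = ""


def tad_fusion_flags(
    deletions: Sequence[SVCall], tads: Sequence[GenomicInterval]
) -> list[TADFusionFlag]:
    """Flag deletions whose endpoints fall in different TADs.

    A deletion that starts in one domain and ends in another removes the
    boundary between them, fusing the flanking domains; removed_boundaries
    counts the adjacent-domain transitions strictly inside the deletion. A
    deletion endpoint falling in no TAD yields fused=False with an
    'unassigned' note. TADs must be non-overlapping and sorted per
    chromosome.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in sorted(tads):
        chrom_list = by_chrom.setdefault(t.chrom, [])
        if chrom_list and t.start <= chrom_list[-1].end:
            raise ValueError(
                f"TADs overlap on {t.chrom}: {chrom_list[-1]} and {t}"
            )
        chrom_list.append(t)
    flags = []
    for call in deletions:
        if call.sv_type is not SVType.DEL:
            continue
        chrom_tads = by_chrom.get(call.interval.chrom, [])
        starts = [t.start for t in chrom_tads]
        left = _containing(chrom_tads, starts, call.interval.start)
        right = _containing(chrom_tads, starts, call.interval.end)
        boundaries = sum(
            1
            for a, b in zip(chrom_tads, chrom_tads[1:])
            if call.interval.start <= a.end and b.start <= call.interval.end
        )
        if left is None or right is None:
            flags.append(
                TADFusionFlag(call, left, right, False, boundaries,
                              note="unassigned endpoint")
            )
        else:
            flags.append(
                TADFusionFlag(call, left, right, left != right, boundaries)
            )
    return flags


def _containing(
    tads: list[GenomicInterval], starts: list[int], pos: int
) -> GenomicInterval | None:
    i = bisect_right(starts, pos) - 1
    if i >= 0 and tads[i].start <= pos <= tads[i].end:
        return tads[i]
    return None


# ---------------------------------------------------------------------------
# Chromosome distribution
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeDistribution:
    counts: pd.DataFrame  # index chrom; columns n_del, n_ins, n_loss, n_gain, length
    features: pd.DataFrame  # columns chrom, pos, kind


def chromosome_distribution(
    calls: Sequence[SVCall],
    gene_changes: Sequence[GeneStatusChange],
    gene_models: Sequence[GeneModel],
    lengths: Mapping[str, int],
) -> ChromosomeDistribution:
    """Per-chromosome counts and positions of DEL/INS calls and LOSS/GAIN
    genes, for the genome-wide distribution view."""
    gene_pos = {g.gene_id: g.interval for g in gene_models}
    rows = []
    for call in calls:
        chrom = call.interval.chrom
        if chrom not in lengths:
            raise ValueError(f"call on unknown chromosome {chrom!r}")
        kind = "DEL" if call.sv_type is SVType.DEL else "INS"
        rows.append({"chrom": chrom, "pos": call.interval.start, "kind": kind})
    for change in gene_changes:
        if change.status == "UNCHANGED":
            continue
        iv = gene_pos.get(change.gene_id)
        if iv is None:
            continue
        if iv.chrom not in lengths:
            raise ValueError(f"gene {change.gene_id} on unknown chromosome {iv.chrom!r}")
        rows.append({"chrom": iv.chrom, "pos": iv.start, "kind": change.status})
    features = pd.DataFrame(rows, columns=["chrom", "pos", "kind"])
    counts = pd.DataFrame(
        0,
        index=sorted(lengths),
        columns=["n_del", "n_ins", "n_loss", "n_gain"],
        dtype=int,
    )
    if not features.empty:
        key = {"DEL": "n_del", "INS": "n_ins", "LOSS": "n_loss", "GAIN": "n_gain"}
        for (chrom, kind), n in features.groupby(["chrom", "kind"]).size().items():
            counts.loc[chrom, key[kind]] = int(n)
    counts["length"] = [lengths[c] for c in counts.index]
    counts.index.name = "chrom"
    return ChromosomeDistribution(counts=counts, features=features)


def plot_chromosome_distribution(
    dist: ChromosomeDistribution, path: str
) -> None:
    """Render the per-chromosome ideogram-style distribution to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dist.counts.index)
    fig, ax = plt.subplots(figsize=(8, 0.6 * max(len(chroms), 2) + 1))
    colors = {"DEL": "red", "INS": "blue", "LOSS": "brown", "GAIN": "green"}
    for y, chrom in enumerate(chroms):
        ax.hlines(y, 0, dist.counts.loc[chrom, "length"], color="0.8", lw=6)
        sub = dist.features[dist.features["chrom"] == chrom]
        for kind, grp in sub.groupby("kind"):
            ax.plot(grp["pos"], [y] * len(grp), "|", color=colors[kind],
                    ms=12, label=kind)
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    ax.legend(seen.values(), seen.keys(), loc="upper right", fontsize=8)
    ax.set_yticks(range(len(chroms)), chroms)
    ax.set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
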