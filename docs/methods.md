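# Methods

## Model and assumptions

An All-seq library mixes two fragment populations sequenced together:
mate-pair (MP) fragments carrying a fixed Tn5 adapter at the junction
where the ends of a long circularized molecule were joined, and shotgun
(SG) fragments with no junction. The caller uses only the MP fraction and
only one statistic per pair: the reference-mapped outer span of
same-chromosome pairs (inclusive at both ends, matching the package-wide
1-based inclusive coordinate convention). Assumptions:

* the library span distribution is unimodal and stable across the genome,
  so a single genome-wide pair of Tukey fences (Q1 − 1.5·IQR,
  Q3 + 1.5·IQR) separates concordant from discordant pairs;
* a deletion of size D shifts straddling-pair spans by exactly +D, an
  insertion by −D (no micro-homology or complex-event modelling);
* read orientation is not used for classification — it is recorded for
  diagnostics only. Inversions, duplications and translocations are out
  of scope; inter-chromosomal pairs are reported as translocation
  candidates and never promoted to calls.

Consequences of the span-only model, verified by tests: a deletion is
detectable only when D + Q1 clears the upper fence (≈1.5 kb here, so the
1 kb reporting floor is close to the physical floor), and an insertion
larger than the library span can never be straddled and is invisible —
the insertion detection ceiling.

## Quartile estimator and boundary convention

The quartile rule is fixed to linear interpolation on the sorted sample
("type 7", numpy's default); the estimator choice is otherwise
unidentified by a quartile statement alone, and determinism requires
pinning one. Spans exactly equal to a fence are classified normal
(discordance is strict inequality). Thresholds may also be supplied fixed
(e.g. 4,800/7,200 bp) to reproduce a published run; in that mode the
quartiles are back-derived by inverting the fence equations
(IQR = (upper − lower)/4), which maps 4,800/7,200 to Q1 = 5,700,
Q3 = 6,300, median 6,000.

## Clustering and call aggregation

Same-class, same-chromosome discordant pairs are merged by single-linkage
on their outer intervals with gap allowance `cluster_window` (default:
the library median span). Single linkage over intervals is computed by a
left-to-right sweep, which is exact for interval graphs; a brute-force
union-find closure serves as the test oracle.

Each cluster is then refined for **span consistency**: every pair
supporting the same event must share span ≈ event size + library span, so
members whose span deviates from the cluster median span by more than
`span_spread_iqr_mult` × IQR (default 3) are removed before support
counting and breakpoint aggregation. Without this step a single
concordant-tail pair chained into a true cluster collapses the
min/max-based breakpoint interval.

A refined cluster becomes a call when it retains `min_support` pairs and
its size estimate (mean cluster span − library median span for deletions,
the mirror for insertions, rounded half-up) reaches `min_size` (default
1,000 bp, the method's reporting floor). The deletion interval runs from
the innermost left-read end + 1 to the innermost right-read start − 1,
clipped to a single midpoint base when the edges cross (which is also the
natural representation for insertion points, whose inner gap contracts to
the breakpoint).

### Why `min_support` defaults to 4

With spans ~N(6,000, 444.8) the per-pair probability of a concordant span
beyond the 7.2 kb fence is ≈0.0035; at 1.43× MP depth that is ~1.7×10⁻⁵
deletion-support pairs per bp from the null distribution alone. With a
6 kb linkage window, chance chains of 3 such pairs are expected several
times per 10 Mb — and each passes the 1 kb size floor (tail-mean span
≈7.4 kb ⇒ size ≈1.4 kb) — while chains of 4 are rare (measured 1–4 false
calls per 10 Mb at support 3 vs 0–1 at support 4 on null simulations). A
true event collects ≈ depth·(span − 2·read_length)/(2·read_length) ≈ 25
pairs regardless of its size at this depth, so support 4 costs no
sensitivity. Users reproducing lower-depth libraries can lower it.

## Downstream analyses

* **Sample specificity**: a focal call is SHARED when any same-type call
  in any reference sample matches at reciprocal overlap ≥ `ro` (default
  0.5, the conventional SV-matching criterion); otherwise SPECIFIC.
* **Size bins**: half-open bins `[10 kb, 50 kb)`, `[50 kb, 100 kb)`,
  `≥100 kb` by default, with an explicit underflow bin; percentages are
  rounded half-up, which reproduces printed shares such as 9% and
  75/11/14.
* **Transcription loss/gain**: presence/absence with a two-threshold
  hysteresis rule — LOSS when the reference sample has RPKM ≥ 1.0 and the
  focal sample < 0.1, GAIN the mirror. This is deliberately not
  differential-expression testing; the thresholds are configurable
  because no numeric rule is identified by loss/gain counts alone.
* **TAD fusion**: a deletion whose endpoints fall in different domains
  removes the boundary between them (fused = true); removed boundaries
  count adjacent-domain transitions inside the deletion. Endpoints in no
  domain yield an "unassigned" note, not a fusion.
* **In-silico PCR**: positional model only — a product forms when a
  plus-strand site of one primer faces a minus-strand site of the other
  on one chromosome, sized 5′-end to 5′-end inclusive; a band requires
  the smallest product ≤ `max_product` (default 3,000 bp, consistent with
  a short-extension PCR programme). Primer matching is exact by default;
  no thermodynamics. For a deletion D with flanking primers the reference
  product exceeds the deleted-genome product by exactly |D|.

## Simulator: what it emulates, and what it does not

The generator reproduces the All-seq library's reported statistics:
MP spans normal with median 6,000 bp and IQR 600 bp (σ = IQR/1.349; the
distribution family itself is an assumption — only median and IQR are
constrained), MP depth 1.43×, SG fragments ~N(330, 35) at 37.83×, 150 bp
reads, and an inter-chromosomal pair rate of 4,473/586,071 ≈ 0.76%.
Junction reads are fragment-end + adapter + fragment-start with the Tn5
mosaic-end 19-mer as the default adapter (the read-splitting stage itself
has no default and always requires an explicit adapter). Bases are
uniform-random and error-free by default (a substitution rate is
configurable); qualities are constant.

"Aligned" pairs are emitted directly in reference coordinates through an
exact coordinate map, bypassing an external aligner. A read crossing a
variant breakpoint is anchored at its 5′ base and extended contiguously,
mimicking a clipped primary alignment; reads wholly inside inserted novel
sequence drop their pair as unmappable. Not modelled: repeat-induced
mis-mapping, chimeric artifacts, PCR duplicates, GC bias, real base-error
profiles. Passing tests therefore demonstrate the span logic, clustering
arithmetic and bookkeeping — not robustness to alignment artifacts in
repetitive real genomes, where the mapq filter (default 30 as a
unique-mapping proxy) carries the load.

Simulation scale in the test suite: parameter-recovery runs use 10 Mb
genomes with 20 implanted 10–200 kb deletions over 5 fixed seeds (the
smallest scale at which per-seed counts are stable); read-level tests use
50–200 kb genomes.

## Numerical and I/O choices

* Quartiles/fences in float; size estimates rounded half-up to integer bp.
* TSV pair dialect (8 columns, header required) carries no mapq — such
  pairs are treated as uniquely mapped (mapq 255) — and no second strand,
  which is recorded as the FR complement of strand 1.
* VCF output uses symbolic `<DEL>`/`<INS>` with the anchor-base
  convention (POS = start − 1, so start ≥ 2 is required for VCF; BED has
  no such limit) and INFO `END`/`SVLEN`/`SUPPORT`/`SID`. For insertions
  `END` is set to the end of the positional-uncertainty interval so
  write→read round-trips are exact.
* Degenerate inputs: < 4 spans refuse to fit; zero-IQR samples classify
  everything normal and disable the span-consistency refinement; empty
  files produce empty streams and all-zero reports.

## Known limitations

Breakpoints are span-derived, so positions are resolved to ~read length
and sizes to library-span noise (σ/√support); no split-read refinement.
Insertions are bounded by the span ceiling and sized only within the
library span. Overlapping or nested true events closer than the linkage
window can merge into one call. The expression loss/gain rule is a
presence/absence heuristic, not a statistical test.
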