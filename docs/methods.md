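# Methods

## Model and assumptions

The reconstruction model treats a transcript as its **junction chain**: the
ordered list of introns spliced out of the pre-mRNA. Exons follow from the
chain (the intervals between consecutive junctions) plus two terminal
boundaries. Everything operates on genome coordinates — no sequence is
read, so the method assumes junction calls and annotation refer to the same
assembly. Internally all coordinates are 0-based half-open; GTF's 1-based
inclusive convention is converted at the file boundary, BED is native.

Prior knowledge enters in four forms derived from the reference
annotation: the annotated junction universe (exact-coordinate identity),
the **co-occurrence** relation (two annotated junctions observed together
on ≥ 1 annotated transcript — *all* pairs on a transcript, not only
adjacent ones), the deduplicated annotated exon set, and per-gene
transcript start/end coordinates. Genes come from annotation `gene_id`;
there is no de-novo gene clustering, so novel junctions falling outside
every annotated gene span are reported in a discard list rather than
assembled.

## Exon definition

For a novel junction with donor *d* and acceptor *a*, the left candidate
exon is [*p*, *d*) where *p* is the **nearest** exon-start boundary
(junction acceptor, or annotated transcript left boundary) with
*d* − *p* ≤ *W*; the right exon [*a*, *q*) is symmetric over exon-end
boundaries (donors, right transcript boundaries). Nearest-partner pairing
is the default because one junction pair defines one exon; `pairing=all`
emits every boundary in the window for sensitivity studies. When a
coordinate is backed by both a junction and a transcript boundary, the
junction wins as provenance — it is the stronger evidence class. A side
with no boundary in the window yields nothing: the method never invents
coordinates.

Exon novelty uses total boundary displacement |Δstart| + |Δend| against the
closest annotated exon on the same chromosome/strand; a candidate is novel
iff the displacement is ≥ `novelty_min_diff` (default 4, inclusive at 4).
Total displacement is the simplest measure consistent with a "differs by at
least *k* bases" criterion; it is configurable.

## Walk semantics and numerical choices

- **Pairwise-consecutive conditions.** The five compatibility conditions
  are evaluated between consecutive junctions only, exactly as the walk
  proceeds. A consequence worth knowing: a chain may combine novel
  elements of different co-expressed isoforms when admitted exons link
  them, since non-adjacent pairs are never re-checked. This is inherent to
  junction-graph walking, and the exhaustive-enumeration oracle used in
  testing shares the semantics by construction.
- **Condition 2 is strict** (introns disjoint with ≥ 1 base between): a
  zero-length exon is not an exon.
- **Transcription order.** "First junction" and "upstream" are read in
  transcription order; on the minus strand the walk runs right-to-left on
  the genome and the rules mirror symmetrically.
- **Terminal exons.** If an annotated exon ends exactly at the chain's
  first donor, the first exon adopts that exon's start (the nearest such
  start when isoforms share the donor with different starts); otherwise
  the nearest annotated transcript boundary below the donor is used —
  needed when the chain starts or ends on a novel junction. The right
  terminal is symmetric. A chain with no annotated boundary to anchor a
  side is rejected with a diagnostic, never padded.
- **Support = min.** A reconstructed transcript's support is the minimum
  read count over its novel junctions and novel exons, so thresholding
  transcripts at *k* reads is consistent with thresholding their elements
  at *k*.
- **Determinism and the branch guard.** Junctions and branches are
  explored in a fixed order, so identical inputs give byte-identical
  outputs regardless of input file ordering. Depth-first enumeration is
  exponential in the worst case; a per-gene cap (default 1,000 chains)
  truncates enumeration with an explicit flag and warning, never silently.
- **Ties and duplicates.** Junction identity is the exact
  (chrom, start, end, strand) tuple; duplicate junction calls merge by
  summing counts; duplicate chains deduplicate by junction-chain key.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window` | 10,000 bp | maximum exon length searched around a novel junction; matches the upper tail of annotated exon lengths |
| `min_junction_reads` | 20 | reads required to trust a novel junction (inclusive) |
| `min_exon_reads` | 20 | reads required to admit a novel exon (inclusive); annotated exons exempt |
| `novelty_min_diff` | 4 bp | total boundary displacement for an exon to count as novel (inclusive) |
| `min_terminal_default` | 1,000 bp | floor of the gene-specific exon-length cap, max(floor, longest annotated exon) |
| `verify_threshold` | 0.5 | verification needs strictly more than this fraction of exonic bases covered |
| `max_transcripts_per_gene` | 1,000 | branch-explosion guard |

## Synthetic data: what it emulates, what it does not

The generator builds non-overlapping multi-isoform genes on two synthetic
chromosomes and both strands. Isoform variants either skip an internal exon
or use an alternative first exon converging on a shared acceptor, so genes
carry both shared junctions and isoform-private junction pairs — the
structure the co-occurrence condition exists to police. Exon lengths
default to 50–650 bp (keeping the gene-specific cap at its 1,000 bp floor),
introns to 200–2,000 bp.

Read evidence is per-element Poisson: annotated junctions at mean 18 and
exons at mean 22, placing a substantial fraction of elements below the
20-read cutoff as in real bulk data where most observed junctions are
shallowly covered; planted novel elements draw at mean 100, which saturates
the cutoff (P(X ≥ 20) > 0.999). A configurable 20% of exons is left with
under-half coverage. `exact_evidence` bypasses sampling with uniform exact
counts for filter-boundary studies.

Planted events realize the four archetypes: a bridging junction (skip), a
new exon with two new junctions inside a known intron (insert), two new
introns strictly inside a known exon (split), and a junction sharing one
coordinate with an annotated junction (alternative boundary). Each event
owns its host gene — two events in one gene would extend each other's
maximal chains, making single-event recovery undecidable — and an
alternative boundary never replaces a transcript's transcription-first
junction, which no legal walk could reach.

Not modeled: sequencing errors, mappability, amplification bias, fragment
length, paired ends, or reads as such (evidence is emitted as counts; a toy
SAM writer exists to exercise the alignment-extraction path). Passing tests
therefore demonstrate the combinatorial and filtering behavior of the
method, not robustness to alignment artifacts in real data.

The two worked-example fixtures use invented coordinates constructed to
realize the published example topologies exactly (shared-acceptor isoforms
plus two novel junctions; a shared-intron exon insertion); they are not
genome data.

## Degenerate inputs

Empty annotation is an error (the method is knowledge-based); empty
evidence is not (the result is simply zero novel transcripts). Junction
calls with zero reads are rejected at parse time. Unstranded junction
calls are legal evidence and inherit the strand of the gene they are
assigned to; annotated transcripts must be stranded. Evidence on
chromosomes absent from the annotation is a hard error naming the
offenders, since it usually signals mismatched references.

## Known limitations

- Terminal exons come from annotated boundaries, so a novel transcript
  whose true ends extend beyond every annotated boundary is truncated to
  the annotation's extent, and genes without any annotated transcript
  cannot be assembled at all.
- Pairwise condition checking can chain novel elements of distinct
  isoforms (see above); downstream support filtering bounds but does not
  eliminate such combinations.
- No abundance estimation: support is a confidence statistic, not an
  expression level.
- Exact-coordinate junction identity means a 1-bp alignment shift makes a
  known junction "novel"; the novelty margin applies to exons only.
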