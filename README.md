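# junction-walker

Reference-guided reconstruction of full-length mRNA transcripts from
short-read RNA-Seq splice junctions.

## The problem

Short sequencing reads (50–100 bp) rarely tile a transcript end to end:
lowly expressed isoforms, repeat regions and library artifacts leave exons
partially covered or missed entirely, so de-novo assemblers recover
fragments rather than full-length isoforms. But transcript databases
already describe most exon boundaries, junctions and transcript ends. This
package reconstructs **novel** isoforms by combining observed splice
junctions (with their supporting read counts) with that prior knowledge,
for anyone building transcript catalogues for isoform-level analysis or
array design.

## The method

Two cooperating algorithms operate purely on genome coordinates:

**Exon mapping.** An internal exon is exactly the interval between the two
junctions that splice it to its neighbours. For each novel junction, both
sides are searched within a window *W* (default 10,000 bp) for the nearest
compatible boundary — the acceptor/donor of another junction (novel or
annotated) or an annotated transcript start/end — and one candidate exon is
defined between them. A candidate is *novel* when its boundaries differ
from every annotated exon by ≥ 4 bases in total, and novel exons must carry
≥ 20 mapped reads; annotated exons are prior knowledge and need no reads.

**Junction walking.** Per gene, candidate transcripts are enumerated by
depth-first walking over junctions in transcription order. Junctions
*j₁, j₂* may be adjacent on one transcript iff:

1. same chromosome and strand;
2. non-overlapping introns (the exon between them has ≥ 1 base);
3. the exon they delimit is in the admitted exon set;
4. that exon is no longer than max(1,000 bp, longest annotated exon of the
   gene);
5. if both are annotated, they co-occur on at least one annotated
   transcript.

Walks start at the first junction of any annotated isoform (or a novel
junction upstream of all of them), every compatible continuation is
branched, and each maximal chain becomes a candidate transcript whose
terminal exons are anchored at the nearest annotated boundary. A
transcript's support is the minimum read count over its novel junctions
and exons. Reconstructions are verified against an independent annotation
set by exonic-base overlap (> 50% of the query's bases) and labeled with
the alternative-splicing events that distinguish them from the annotation
(exon skipping / insertion / splitting, alternative boundary).

## Worked example

The package ships a two-isoform demonstration gene: isoforms A1 and A2
share their last junction, and RNA-Seq contributes two well-supported novel
junctions (30 and 25 reads) downstream of the shared acceptor.

```
$ walker fixture figure2 --out-dir fx
$ walker reconstruct --annotation fx/ref.gtf --junctions fx/junctions.bed \
      --exon-counts fx/exon_counts.tsv --out-dir out
novel_junctions	2
novel_exons	3
novel_transcripts	2
```

The two novel junctions define three novel exons (one closed by the shared
annotated acceptor, one between the two novel junctions, one terminal exon
closed by the annotated transcript end), and the walk splices them onto
*each* annotated backbone, yielding two reconstructed transcripts. The
report shows both with support 25 — the smallest read count among their
novel elements:

```
$ grep walk out/report.tsv | cut -f1,5,6,7
DEMO1.walk1	3	2	25
DEMO1.walk2	3	2	25
```

The companion `tpm2` fixture shows why enumeration matters: a novel exon
inserted into an intron shared by two reference isoforms is integrated into
*both* backbones (two transcripts, both labeled `exon_insertion`), where a
parsimonious assembler would attach it to only one.

All thresholds are CLI flags whose defaults are the canonical values above,
so a zero-flag run is the standard configuration. See `walker --help` for
the subcommands (`annotate-stats`, `evidence`, `exonmap`, `reconstruct`,
`verify`, `classify`, `simulate`, `fixture`).

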