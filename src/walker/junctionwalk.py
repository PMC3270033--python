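"""JunctionWalk: transcript enumeration over compatible junctions.

Candidate full-length transcripts of a gene are enumerated by depth-first
walking over splice junctions in transcription order.  Two junctions may be
adjacent on the same transcript only when five conditions all hold:

1. they are on the same strand of the same chromosome;
2. their introns do not overlap (strictly, so the exon between them has at
   least one base);
3. the exon delimited by them exists in the admitted exon set (annotated
   exons plus support-filtered novel exons);
4. that exon is no longer than a gene-specific threshold, the larger of
   1,000 bases and the gene's longest annotated exon;
5. if both junctions are annotated, they have been observed together on at
   least one annotated transcript (co-occurrence) — junctions private to
   different isoforms are never chained without experimental evidence.

A walk may start at the first junction (in transcription order) of any
annotated transcript of the gene, or at a novel junction upstream of all of
those.  Every branch is followed; each maximal chain becomes one candidate
transcript whose terminal exons are anchored at the nearest annotated
transcript boundary.  Chains identical to an annotated isoform are reported
only on request.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from intervaltree import IntervalTree

from .annotation import (
    ANNOTATED,
    NOVEL,
    RECONSTRUCTED,
    SOURCE_BOUNDARY,
    SOURCE_JUNCTION,
    AnnotationSet,
    Exon,
    Gene,
    GenomeInterval,
    Junction,
    Transcript,
)
from .evidence import JunctionCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkConfig:
    min_terminal_default: int = 1_000
    max_transcripts_per_gene: int = 1_000
    report_annotated: bool = False

    def __post_init__(self) -> None:
        if self.min_terminal_default < 1:
            raise ValueError("min_terminal_default must be >= 1")


@dataclass
class WalkResult:
    gene_id: str
    transcripts: list[Transcript] = field(default_factory=list)
    #: every maximal chain found (junction key tuples, genomic order),
    #: including chains identical to annotated isoforms
    chain_keys: list[tuple] = field(default_factory=list)
    n_chains: int = 0
    n_branch_points: int = 0
    truncated: bool = False
    rejected: list[str] = field(default_factory=list)

    @property
    def reconstructed(self) -> list[Transcript]:
        return [t for t in self.transcripts if t.status == RECONSTRUCTED]


def gene_exon_length_threshold(g: Gene, cfg: WalkConfig | None = None) -> int:
    """Maximum admissible inter-junction exon length for this gene: the
    larger of the global floor (1,000 bases by default) and the gene's
    longest annotated exon."""
    cfg = cfg or WalkConfig()
    return max(cfg.min_terminal_default, g.max_annotated_exon_len)


class _ExonIndex:
    """Exact-coordinate membership for the admitted exon set, with
    unstranded entries acting as wildcards."""

    def __init__(self, exons: Sequence[Exon]):
        self._strands: dict[tuple[str, int, int], set[str]] = {}
        self._by_key: dict[tuple, Exon] = {}
        for e in exons:
            c, s, t, strand = e.key
            self._strands.setdefault((c, s, t), set()).add(strand)
            self._by_key[e.key] = e

    def contains(self, chrom: str, start: int, end: int, strand: str) -> bool:
        strands = self._strands.get((chrom, start, end))
        if not strands:
            return False
        return strand == "." or "." in strands or strand in strands

    def get(self, chrom: str, start: int, end: int, strand: str) -> Exon | None:
        for s in (strand, "."):
            e = self._by_key.get((chrom, start, end, s))
            if e is not None:
                return e
        return None


def compatible(
    j1: Junction,
    j2: Junction,
    exon_set: Sequence[Exon] | _ExonIndex,
    threshold: int,
    ann: AnnotationSet,
) -> bool:
    """True iff the two junctions may be adjacent on one transcript
    (conditions 1-5).  Input order is irrelevant; the pair is evaluated in
    genomic order."""
    if not isinstance(exon_set, _ExonIndex):
        exon_set = _ExonIndex(list(exon_set))
    if j1.intron.start > j2.intron.start:
        j1, j2 = j2, j1
    # 1: same strand of the same chromosome
    if j1.intron.chrom != j2.intron.chrom:
        return False
    if not (
        j1.intron.strand == "."
        or j2.intron.strand == "."
        or j1.intron.strand == j2.intron.strand
    ):
        return False
    # 2: non-overlapping introns with a >= 1 base exon between them
    if j1.intron.end >= j2.intron.start:
        return False
    # 3: the inter-junction exon is admitted
    strand = (
        j1.intron.strand if j1.intron.strand != "." else j2.intron.strand
    )
    if not exon_set.contains(
        j1.intron.chrom, j1.intron.end, j2.intron.start, strand
    ):
        return False
    # 4: the exon respects the gene-specific length cap
    if j2.intron.start - j1.intron.end > threshold:
        return False
    # 5: two annotated junctions need co-occurrence evidence
    if j1.status == ANNOTATED and j2.status == ANNOTATED:
        if frozenset((j1.key, j2.key)) not in ann.cooccurrence:
            return False
    return True


def _tx_order_key(strand: str):
    """Sort key putting junctions in transcription order."""
    if strand == "-":
        return lambda j: (-j.intron.end, -j.intron.start)
    return lambda j: (j.intron.start, j.intron.end)


def _first_tx_junction(t: Transcript) -> Junction:
    return t.junction_chain[-1] if t.strand == "-" else t.junction_chain[0]


def starting_junctions(
    g: Gene, novel: Sequence[Junction] = ()
) -> list[Junction]:
    """Walk entry points: the first junction (transcription order) of every
    annotated transcript, plus any novel junction upstream of all of them.
    For a gene without annotated junctions every novel junction may start."""
    order = _tx_order_key(g.strand)
    starts: dict[tuple, Junction] = {}
    firsts = [
        _first_tx_junction(t)
        for t in g.transcripts
        if t.status == ANNOTATED and t.junction_chain
    ]
    for j in firsts:
        starts.setdefault(j.key, j)
    if firsts:
        earliest = min(order(j) for j in firsts)
        upstream = [j for j in novel if order(j) < earliest]
    else:
        upstream = list(novel)
    for j in upstream:
        starts.setdefault(j.key, j)
    return sorted(starts.values(), key=order)


def walk(
    g: Gene,
    junctions: Sequence[Junction],
    exon_set: Sequence[Exon],
    ann: AnnotationSet,
    cfg: WalkConfig | None = None,
) -> WalkResult:
    """Enumerate all maximal compatible junction chains of a gene.

    ``junctions`` is the union of the gene's annotated junctions and its
    assigned, support-filtered novel junctions.  The walk is depth-first in
    transcription order with every compatible continuation branched;
    exceeding ``max_transcripts_per_gene`` chains flags the gene truncated
    (never silently).  Chains equal to an annotated isoform are returned
    only with ``report_annotated``.
    """
    cfg = cfg or WalkConfig()
    index = _ExonIndex(list(exon_set))
    threshold = gene_exon_length_threshold(g, cfg)
    order = _tx_order_key(g.strand)
    ordered = sorted(
        {j.key: j for j in junctions}.values(), key=order
    )
    novel = [j for j in ordered if j.status != ANNOTATED]
    starts = starting_junctions(g, novel)
    result = WalkResult(gene_id=g.id)

    chains: list[list[Junction]] = []
    # iterative DFS; successors explored in transcription order
    pos = {j.key: i for i, j in enumerate(ordered)}
    stack = [[s] for s in reversed(starts)]
    while stack:
        if len(chains) >= cfg.max_transcripts_per_gene:
            result.truncated = True
            logger.warning(
                "gene %s: chain enumeration truncated at %d",
                g.id,
                cfg.max_transcripts_per_gene,
            )
            break
        chain = stack.pop()
        current = chain[-1]
        nexts = [
            j
            for j in ordered[pos[current.key] + 1 :]
            if compatible(current, j, index, threshold, ann)
        ]
        if not nexts:
            chains.append(chain)
            continue
        if len(nexts) > 1:
            result.n_branch_points += 1
        for j in reversed(nexts):
            stack.append(chain + [j])

    annotated_chains = {
        t.chain_key: t
        for t in g.transcripts
        if t.status == ANNOTATED and t.junction_chain
    }
    seen: set[tuple] = set()
    n_new = 0
    for chain in chains:
        genomic = sorted(chain, key=lambda j: j.intron.start)
        key = tuple(j.key for j in genomic)
        if key in seen:
            continue
        seen.add(key)
        result.chain_keys.append(key)
        result.n_chains += 1
        known = annotated_chains.get(key)
        if known is not None:
            if cfg.report_annotated:
                result.transcripts.append(known)
            continue
        t = finalize_transcript(genomic, g, exon_set, ann, index=index)
        if t is None:
            result.rejected.append(
                f"{g.id}: chain {key} has no annotated boundary to anchor "
                "a terminal exon"
            )
            continue
        n_new += 1
        t.id = f"{g.id}.walk{n_new}"
        result.transcripts.append(t)
    return result


def finalize_transcript(
    chain: Sequence[Junction],
    g: Gene,
    exon_set: Sequence[Exon],
    ann: AnnotationSet,
    index: _ExonIndex | None = None,
) -> Transcript | None:
    """Build a Transcript from a junction chain (genomic order).

    Internal exons are the inter-junction intervals (present in the exon
    set by condition 3).  Terminal exons are anchored at the nearest
    annotated boundary of the gene: when an annotated exon ends exactly at
    the chain's first donor the first exon reuses that exon's start (the
    figure-book case of adopting an isoform's first exon); otherwise the
    nearest annotated transcript left boundary below the donor is used.
    The right terminal is symmetric.  With no boundary available on a side
    the chain is rejected (returns None) — the method never invents
    coordinates.  Support is the minimum read count over the chain's novel
    junctions and novel exons.
    """
    if index is None:
        index = _ExonIndex(list(exon_set))
    chain = sorted(chain, key=lambda j: j.intron.start)
    chrom = chain[0].intron.chrom
    strand = g.strand
    ann_exons = {
        (e.region.start, e.region.end)
        for t in g.transcripts
        if t.status == ANNOTATED
        for e in t.exons
    }
    lefts, rights = ann.boundaries[g.id]
    donor, acceptor = chain[0].donor, chain[-1].acceptor
    left_opts = [s for s, e in ann_exons if e == donor]
    if not left_opts:
        left_opts = [b for b in lefts if b < donor]
    right_opts = [e for s, e in ann_exons if s == acceptor]
    if not right_opts:
        right_opts = [b for b in rights if b > acceptor]
    if not left_opts or not right_opts:
        return None
    left_b = max(left_opts)
    right_b = min(right_opts)

    exons: list[Exon] = []
    support_values: list[int] = []

    def lookup(start: int, end: int, left_src: str, right_src: str) -> Exon:
        e = index.get(chrom, start, end, strand)
        if e is None:
            e = Exon(
                GenomeInterval(chrom, start, end, strand),
                left_source=left_src,
                right_source=right_src,
                status=(
                    ANNOTATED
                    if (chrom, start, end, strand) in ann.exons
                    else NOVEL
                ),
            )
        if e.status == NOVEL:
            support_values.append(e.read_count)
        return Exon(
            GenomeInterval(chrom, start, end, strand),
            left_source=left_src,
            right_source=right_src,
            status=e.status,
            read_count=e.read_count,
            coverage_fraction=e.coverage_fraction,
        )

    exons.append(
        lookup(left_b, chain[0].donor, SOURCE_BOUNDARY, SOURCE_JUNCTION)
    )
    for j1, j2 in zip(chain, chain[1:]):
        exons.append(
            lookup(j1.acceptor, j2.donor, SOURCE_JUNCTION, SOURCE_JUNCTION)
        )
    exons.append(
        lookup(
            chain[-1].acceptor, right_b, SOURCE_JUNCTION, SOURCE_BOUNDARY
        )
    )

    oriented = [
        Junction(
            GenomeInterval(chrom, j.intron.start, j.intron.end, strand),
            status=j.status,
            read_count=j.read_count,
        )
        for j in chain
    ]
    support_values.extend(
        j.read_count for j in oriented if j.status != ANNOTATED
    )
    support = min(support_values) if support_values else None
    status = RECONSTRUCTED if support_values else ANNOTATED
    return Transcript(
        id=f"{g.id}.candidate",
        gene_id=g.id,
        exons=exons,
        junction_chain=oriented,
        status=status,
        support=support,
    )


def assign_to_genes(
    novel: Sequence[JunctionCall], ann: AnnotationSet
) -> tuple[dict[str, list[Junction]], list[JunctionCall], list[tuple]]:
    """Assign novel junction calls to genes.

    A call goes to every gene whose span contains the whole intron and
    whose strand matches (unstranded calls match either strand and take the
    gene's strand on assignment).  Returns (gene_id -> junctions,
    discarded calls, ambiguous (call key, gene ids) records).
    """
    trees: dict[str, IntervalTree] = {}
    for gid, gene in ann.genes.items():
        trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.span.start, gene.span.end, gid
        )
    assigned: dict[str, list[Junction]] = {}
    discarded: list[JunctionCall] = []
    ambiguous: list[tuple] = []
    for call in novel:
        hits = []
        tree = trees.get(call.intron.chrom)
        if tree is not None:
            for iv in tree.overlap(call.intron.start, call.intron.end):
                gene = ann.genes[iv.data]
                if (
                    iv.begin <= call.intron.start
                    and call.intron.end <= iv.end
                    and (
                        call.intron.strand == "."
                        or call.intron.strand == gene.strand
                    )
                ):
                    hits.append(gene)
        if not hits:
            discarded.append(call)
            continue
        if len(hits) > 1:
            ambiguous.append((call.key, sorted(g.id for g in hits)))
        for gene in hits:
            j = Junction(
                GenomeInterval(
                    call.intron.chrom,
                    call.intron.start,
                    call.intron.end,
                    gene.strand,
                ),
                status=NOVEL,
                read_count=call.read_count,
            )
            assigned.setdefault(gene.id, []).append(j)
    for gid in assigned:
        assigned[gid].sort(key=lambda j: j.key)
    return assigned, discarded, ambiguous
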