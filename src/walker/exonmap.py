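"""ExonMap: candidate exon definition from junction pairs.

An internal exon is precisely delimited by the two junctions that splice it
to its neighbours.  For every newly observed junction we therefore search
both sides, within a window, for the nearest compatible boundary — the
acceptor or donor of another junction (novel or annotated), or an annotated
transcript start/end — and define one candidate exon between the two.  The
window (default 10,000 bases) is the maximum exon length admitted; in human
reference annotation fewer than 0.03% of exons are longer.

A candidate exon counts as novel only when its boundaries differ from every
annotated exon by at least ``novelty_min_diff`` bases in total (default 4),
so alignment jitter of a base or two does not inflate novelty.  Novel exons
additionally require ``min_exon_reads`` mapped reads (default 20);
annotated exons are prior knowledge and bypass the read filter.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from typing import Sequence

from .annotation import (
    ANNOTATED,
    NOVEL,
    SOURCE_BOUNDARY,
    SOURCE_JUNCTION,
    AnnotationSet,
    Exon,
    GenomeInterval,
    Junction,
)
from .evidence import EvidenceSet


@dataclass(frozen=True)
class ExonMapConfig:
    window: int = 10_000
    novelty_min_diff: int = 4
    min_exon_reads: int = 20
    pairing: str = "nearest"  # or "all": every boundary in the window

    def __post_init__(self) -> None:
        if self.window < 1 or self.novelty_min_diff < 1:
            raise ValueError("window and novelty_min_diff must be >= 1")
        if self.pairing not in ("nearest", "all"):
            raise ValueError(f"unknown pairing mode {self.pairing!r}")


def _strand_ok(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


class _BoundaryIndex:
    """Sorted per-chromosome boundary coordinates with provenance.

    Boundary classes: junction acceptors and annotated transcript left
    boundaries (candidate exon *starts*); junction donors and annotated
    transcript right boundaries (candidate exon *ends*).  A coordinate
    backed by both a junction and a transcript boundary resolves to
    junction provenance, the stronger evidence class.
    """

    def __init__(
        self,
        novel_junctions: Sequence[Junction],
        ann: AnnotationSet,
    ):
        starts: dict[str, dict[int, tuple[str, str]]] = {}
        ends: dict[str, dict[int, tuple[str, str]]] = {}

        def add(pool, chrom, coord, strand, source):
            slot = pool.setdefault(chrom, {})
            prev = slot.get(coord)
            if prev is None or (
                prev[1] == SOURCE_BOUNDARY and source == SOURCE_JUNCTION
            ):
                slot[coord] = (strand, source)
            elif prev[1] == source and prev[0] != strand:
                slot[coord] = (".", source)  # both strands present

        for j in list(ann.junctions.values()) + list(novel_junctions):
            chrom, strand = j.intron.chrom, j.intron.strand
            add(starts, chrom, j.acceptor, strand, SOURCE_JUNCTION)
            add(ends, chrom, j.donor, strand, SOURCE_JUNCTION)
        for gid, (lefts, rights) in ann.boundaries.items():
            gene = ann.genes[gid]
            for b in lefts:
                add(starts, gene.chrom, b, gene.strand, SOURCE_BOUNDARY)
            for b in rights:
                add(ends, gene.chrom, b, gene.strand, SOURCE_BOUNDARY)

        self.starts = {
            c: sorted(d.items()) for c, d in starts.items()
        }
        self.ends = {c: sorted(d.items()) for c, d in ends.items()}

    @staticmethod
    def _below(pool, coord, strand, limit):
        """Boundaries p with limit <= p < coord, nearest (largest) first."""
        idx = bisect.bisect_left(pool, (coord, ("", "")))
        out = []
        for i in range(idx - 1, -1, -1):
            p, (s, src) = pool[i]
            if p < limit:
                break
            if _strand_ok(s, strand):
                out.append((p, src))
        return out

    @staticmethod
    def _above(pool, coord, strand, limit):
        """Boundaries q with coord < q <= limit, nearest (smallest) first."""
        idx = bisect.bisect_right(pool, (coord, ("￿", "￿")))
        out = []
        for i in range(idx, len(pool)):
            q, (s, src) = pool[i]
            if q > limit:
                break
            if _strand_ok(s, strand):
                out.append((q, src))
        return out

    def exon_starts_before(self, chrom, coord, strand, window):
        return self._below(
            self.starts.get(chrom, []), coord, strand, coord - window
        )

    def exon_ends_after(self, chrom, coord, strand, window):
        return self._above(
            self.ends.get(chrom, []), coord, strand, coord + window
        )


def classify_exon_novelty(
    e: Exon, ann: AnnotationSet, cfg: ExonMapConfig
) -> str:
    """'annotated' when some annotated exon on the same chromosome/strand
    lies within ``novelty_min_diff`` total boundary displacement
    (|dstart| + |dend|), else 'novel'."""
    best = None
    for key in ann.exons:
        chrom, start, end, strand = key
        if chrom != e.region.chrom or not _strand_ok(
            strand, e.region.strand
        ):
            continue
        d = abs(start - e.region.start) + abs(end - e.region.end)
        best = d if best is None else min(best, d)
    if best is not None and best < cfg.novelty_min_diff:
        return ANNOTATED
    return NOVEL


def define_exons(
    novel_junctions: Sequence[Junction],
    ann: AnnotationSet,
    cfg: ExonMapConfig | None = None,
) -> list[Exon]:
    """Define candidate exons on both sides of each novel junction.

    For a novel junction with donor d and acceptor a, the left exon is
    [p, d) with p the nearest valid exon-start boundary (junction acceptor
    or annotated transcript left boundary) within the window, and the right
    exon is [a, q) symmetrically.  With ``pairing='all'`` every boundary in
    the window yields an exon instead of only the nearest.  A side with no
    boundary in the window contributes nothing.  Output is deduplicated by
    coordinates and independent of input ordering.
    """
    cfg = cfg or ExonMapConfig()
    index = _BoundaryIndex(novel_junctions, ann)
    out: dict[tuple, Exon] = {}

    def emit(chrom, start, end, strand, left_src, right_src):
        region = GenomeInterval(chrom, start, end, strand)
        if region.key in out:
            return
        e = Exon(
            region,
            left_source=left_src,
            right_source=right_src,
        )
        e.status = classify_exon_novelty(e, ann, cfg)
        out[region.key] = e

    for j in sorted(novel_junctions, key=lambda j: j.key):
        chrom, strand = j.intron.chrom, j.intron.strand
        lefts = index.exon_starts_before(chrom, j.donor, strand, cfg.window)
        rights = index.exon_ends_after(chrom, j.acceptor, strand, cfg.window)
        if cfg.pairing == "nearest":
            lefts, rights = lefts[:1], rights[:1]
        for p, src in lefts:
            emit(chrom, p, j.donor, strand, src, SOURCE_JUNCTION)
        for q, src in rights:
            emit(chrom, j.acceptor, q, strand, SOURCE_JUNCTION, src)
    return [out[k] for k in sorted(out)]


def filter_exons_by_support(
    exons: Sequence[Exon],
    ev: EvidenceSet,
    min_reads: int = 20,
) -> list[Exon]:
    """Fill in read support from evidence and drop under-supported novel
    exons.  Annotated exons are prior knowledge and always pass (the
    reference fills in transcript regions the sequencing never covered)."""
    kept = []
    for e in exons:
        e = replace(
            e,
            read_count=ev.exon_count(e),
            coverage_fraction=ev.exon_cov(e),
        )
        if e.status == ANNOTATED or e.read_count >= min_reads:
            kept.append(e)
    return kept
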