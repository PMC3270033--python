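"""Verification and alternative-splicing event classification.

Reconstructed transcripts are verified against an independent annotation
set (in the role classically played by EST collections) by the fraction of
their exonic bases covered by a single transcript of the second set; a
transcript is verified when its best overlap strictly exceeds the threshold
(default 50%).  Each reconstructed transcript is also labeled with the
alternative-splicing events that distinguish it from its gene's annotation:
skipping a known exon, inserting a new exon, splitting a known exon, or
using an alternative boundary of a known exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import (
    ANNOTATED,
    AnnotationSet,
    Gene,
    Transcript,
)

EXON_SKIPPING = "exon_skipping"
EXON_INSERTION = "exon_insertion"
EXON_SPLITTING = "exon_splitting"
ALTERNATIVE_BOUNDARY = "alternative_boundary"


@dataclass
class OverlapReport:
    transcript_id: str
    best_overlap_fraction: float
    best_match_id: str | None
    verified: bool


@dataclass
class VerificationResult:
    reports: list[OverlapReport]
    threshold: float
    #: fraction verified, or None for an empty input set
    rate: float | None
    #: (threshold, rate) pairs over 0.05 ... 0.95
    curve: list[tuple[float, float]] = field(default_factory=list)


@dataclass(frozen=True)
class EventLabel:
    labels: frozenset[str]

    def __contains__(self, item: str) -> bool:
        return item in self.labels

    def __bool__(self) -> bool:
        return bool(self.labels)


def _merged_exon_intervals(t: Transcript) -> list[tuple[int, int]]:
    ivs = sorted((e.region.start, e.region.end) for e in t.exons)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def overlap_fraction(t: Transcript, u: Transcript) -> float:
    """Fraction of t's exonic bases that fall in u's exonic bases
    (asymmetric, normalized by the query t).  Different chromosomes give 0;
    strand is ignored, as EST-style evidence is often unstranded."""
    if t.chrom != u.chrom:
        return 0.0
    a = _merged_exon_intervals(t)
    b = _merged_exon_intervals(u)
    total = sum(e - s for s, e in a)
    inter = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            inter += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return inter / total


def verify_against(
    novel: Sequence[Transcript],
    ref2: AnnotationSet,
    threshold: float = 0.5,
) -> VerificationResult:
    """Best-overlap verification of each transcript against a second
    annotation set, with the cumulative verification-rate curve over
    thresholds 0.05 ... 0.95."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    by_chrom: dict[str, list[Transcript]] = {}
    for u in ref2.transcripts:
        by_chrom.setdefault(u.chrom, []).append(u)
    reports = []
    for t in novel:
        best, best_id = 0.0, None
        for u in by_chrom.get(t.chrom, []):
            frac = overlap_fraction(t, u)
            if frac > best:
                best, best_id = frac, u.id
        reports.append(
            OverlapReport(t.id, best, best_id, best > threshold)
        )
    if not reports:
        return VerificationResult(reports, threshold, rate=None)
    fracs = np.array([r.best_overlap_fraction for r in reports])
    rate = float(np.mean([r.verified for r in reports]))
    curve = [
        (round(thr, 2), float((fracs > thr).mean()))
        for thr in np.arange(0.05, 0.951, 0.05)
    ]
    return VerificationResult(reports, threshold, rate, curve)


def _best_matching_annotated(t: Transcript, g: Gene) -> Transcript | None:
    chain = set(t.chain_key)
    best, best_shared = None, -1
    for u in g.transcripts:
        if u.status != ANNOTATED:
            continue
        shared = len(chain & set(u.chain_key))
        if shared > best_shared:
            best, best_shared = u, shared
    return best


def classify_events(t: Transcript, g: Gene) -> EventLabel:
    """Label the alternative-splicing events of a reconstructed transcript
    relative to its gene's annotation.

    - exon_skipping: a novel junction whose donor and acceptor both match
      annotated junction boundaries and which bridges over at least one
      annotated exon absent from the transcript;
    - exon_insertion: a novel exon flanked by two novel junctions whose
      outer boundaries match annotated exon boundaries (a new exon inside
      a known intron);
    - exon_splitting: at least two novel junctions falling strictly inside
      one annotated exon;
    - alternative_boundary: a remaining novel junction sharing its donor or
      its acceptor (exactly one side) with the annotated junction set.

    Labels accumulate; a transcript identical to an annotated isoform gets
    the empty set.
    """
    ann_junction_keys = {
        j.key
        for u in g.transcripts
        if u.status == ANNOTATED
        for j in u.junction_chain
    }
    ann_donors = {k[1] for k in ann_junction_keys}
    ann_acceptors = {k[2] for k in ann_junction_keys}
    ann_exons = {
        (e.region.start, e.region.end)
        for u in g.transcripts
        if u.status == ANNOTATED
        for e in u.exons
    }
    ann_exon_starts = {s for s, _ in ann_exons}
    ann_exon_ends = {e for _, e in ann_exons}

    novel_js = [
        j for j in t.junction_chain if j.key not in ann_junction_keys
    ]
    t_exon_coords = {(e.region.start, e.region.end) for e in t.exons}
    labels: set[str] = set()
    used: set[tuple] = set()

    # insertion: novel exon with both flanking junctions novel, bridging
    # annotated exon boundaries on the outside
    novel_keys = {j.key for j in novel_js}
    for i, e in enumerate(t.exons[1:-1], 1):
        coords = (e.region.start, e.region.end)
        if coords in ann_exons:
            continue
        jl, jr = t.junction_chain[i - 1], t.junction_chain[i]
        if (
            jl.key in novel_keys
            and jr.key in novel_keys
            and jl.donor in ann_exon_ends
            and jr.acceptor in ann_exon_starts
        ):
            labels.add(EXON_INSERTION)
            used.update((jl.key, jr.key))

    # splitting: >= 2 novel junctions strictly inside one annotated exon
    for s, e in ann_exons:
        inside = [
            j
            for j in novel_js
            if s < j.intron.start and j.intron.end < e
        ]
        if len(inside) >= 2:
            labels.add(EXON_SPLITTING)
            used.update(j.key for j in inside)

    # skipping: novel junction bridging the neighbours of a dropped exon
    for j in novel_js:
        if j.donor in ann_donors and j.acceptor in ann_acceptors:
            bridged = [
                (s, e)
                for s, e in ann_exons
                if j.intron.start <= s and e <= j.intron.end
                and (s, e) not in t_exon_coords
            ]
            if bridged:
                labels.add(EXON_SKIPPING)
                used.add(j.key)

    # alternative boundary: one known side, one new side
    for j in novel_js:
        if j.key in used:
            continue
        donor_known = j.donor in ann_donors
        acceptor_known = j.acceptor in ann_acceptors
        if donor_known != acceptor_known:
            labels.add(ALTERNATIVE_BOUNDARY)

    return EventLabel(frozenset(labels))
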