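"""Independent reference implementations used only to check the package.

These deliberately use the dumbest correct strategy available — per-base
boolean masks and exhaustive enumeration — so they share no code path with
the interval arithmetic and depth-first search they verify.
"""

from __future__ import annotations

import itertools

import numpy as np

from walker.annotation import ANNOTATED
from walker.junctionwalk import compatible, starting_junctions


def mask_coverage(exon_span, read_spans):
    """Coverage fraction and overlap-read count of one exon by per-base
    painting. ``read_spans`` is a list of block lists, one per read."""
    start, end = exon_span
    mask = np.zeros(end - start, dtype=bool)
    n_reads = 0
    for blocks in read_spans:
        hit = False
        for s, e in blocks:
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                mask[lo - start : hi - start] = True
                hit = True
        n_reads += hit
    return n_reads, mask.mean()


def mask_overlap_fraction(exons_t, exons_u):
    """Exonic base overlap of t by u via boolean masks on a common grid."""
    hi = max(e for _, e in exons_t + exons_u)
    t = np.zeros(hi, dtype=bool)
    u = np.zeros(hi, dtype=bool)
    for s, e in exons_t:
        t[s:e] = True
    for s, e in exons_u:
        u[s:e] = True
    return (t & u).sum() / t.sum()


def nearest_boundary_exons(novel_junctions, ann, window):
    """Exons around novel junctions by brute force over every boundary.

    Considers every junction acceptor / transcript left boundary as a
    candidate exon start and every donor / right boundary as a candidate
    end, applies the window and nearest rule literally, and returns the
    deduplicated region set."""
    all_junctions = list(ann.junctions.values()) + list(novel_junctions)
    regions = set()
    for n in novel_junctions:
        chrom, strand = n.intron.chrom, n.intron.strand

        def ok(s):
            return s == "." or strand == "." or s == strand

        starts = set()
        ends = set()
        for j in all_junctions:
            if j.intron.chrom != chrom or not ok(j.intron.strand):
                continue
            starts.add(j.acceptor)
            ends.add(j.donor)
        for gid, (lefts, rights) in ann.boundaries.items():
            gene = ann.genes[gid]
            if gene.chrom != chrom or not ok(gene.strand):
                continue
            starts |= set(lefts)
            ends |= set(rights)
        left = [p for p in starts if p < n.donor and n.donor - p <= window]
        if left:
            regions.add((chrom, max(left), n.donor))
        right = [
            q for q in ends if q > n.acceptor and q - n.acceptor <= window
        ]
        if right:
            regions.add((chrom, n.acceptor, min(right)))
    return regions


def enumerate_chains(gene, junctions, exon_set, ann, threshold):
    """All maximal compatible chains by exhaustive subset enumeration.

    Every subset of the gene's junctions, taken in transcription order, is
    tested for: a legal starting junction, pairwise compatibility of every
    consecutive pair, and maximality (no junction downstream of the last
    one can extend the chain).  Feasible only for small junction counts.
    """
    uniq = sorted({j.key: j for j in junctions}.values(), key=lambda j: j.key)
    if gene.strand == "-":
        ordered = sorted(uniq, key=lambda j: (-j.intron.end, -j.intron.start))
    else:
        ordered = sorted(uniq, key=lambda j: (j.intron.start, j.intron.end))
    novel = [j for j in ordered if j.status != ANNOTATED]
    start_keys = {j.key for j in starting_junctions(gene, novel)}
    n = len(ordered)
    chains = set()
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            chain = [ordered[i] for i in combo]
            if chain[0].key not in start_keys:
                continue
            if any(
                not compatible(a, b, exon_set, threshold, ann)
                for a, b in zip(chain, chain[1:])
            ):
                continue
            last = chain[-1]
            if any(
                compatible(last, ordered[i], exon_set, threshold, ann)
                for i in range(combo[-1] + 1, n)
            ):
                continue  # extendable, not maximal
            chains.add(
                tuple(
                    j.key
                    for j in sorted(chain, key=lambda j: j.intron.start)
                )
            )
    return chains
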