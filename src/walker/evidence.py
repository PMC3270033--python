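"""Observed RNA-Seq evidence: junction calls and exon read support.

Junction calls come either from a 6-column junction BED (column 5 = number
of supporting reads, *not* BED display-score semantics) or from spliced
alignments (one junction per N CIGAR operation).  Exon support is the
number of reads whose aligned blocks overlap the exon by at least one base,
plus the fraction of the exon's bases covered by at least one read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import (
    NOVEL,
    AnnotationSet,
    Exon,
    GenomeInterval,
    Junction,
)
from .errors import AnnotationParseError, ValidationError
from ._io import open_text

JUNCTION_BINS = [
    (1, 1),
    (2, 4),
    (5, 9),
    (10, 19),
    (20, 49),
    (50, 99),
    (100, 499),
    (500, None),
]
EXON_BINS = [(0, 0)] + JUNCTION_BINS


@dataclass(frozen=True)
class JunctionCall:
    """An observed splice junction with its supporting read count."""

    intron: GenomeInterval
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValidationError(
                f"junction call {self.intron.key} with read count "
                f"{self.read_count}; a call needs at least one read"
            )

    @property
    def key(self) -> tuple[str, int, int, str]:
        return self.intron.key

    def to_junction(self, status: str = NOVEL) -> Junction:
        return Junction(self.intron, status=status, read_count=self.read_count)


@dataclass
class EvidenceSet:
    """Junction calls plus per-exon read counts and coverage fractions.

    ``exon_counts`` and ``exon_coverage`` are keyed by exon region key
    ``(chrom, start, end, strand)``.
    """

    junction_calls: list[JunctionCall] = field(default_factory=list)
    exon_counts: dict[tuple, int] = field(default_factory=dict)
    exon_coverage: dict[tuple, float] = field(default_factory=dict)

    def exon_count(self, exon: Exon) -> int:
        return self.exon_counts.get(exon.key, 0)

    def exon_cov(self, exon: Exon) -> float:
        return self.exon_coverage.get(exon.key, 0.0)


def _merge_calls(
    raw: Iterable[tuple[GenomeInterval, int]]
) -> list[JunctionCall]:
    counts: dict[tuple, int] = {}
    introns: dict[tuple, GenomeInterval] = {}
    for intron, n in raw:
        counts[intron.key] = counts.get(intron.key, 0) + n
        introns.setdefault(intron.key, intron)
    return [
        JunctionCall(introns[k], counts[k]) for k in sorted(counts)
    ]


def load_junction_bed(path: str | Path) -> list[JunctionCall]:
    """Read junction calls from the 6-column junction-BED dialect.

    Columns 2-3 delimit the intron, column 5 is the supporting read count,
    column 6 the strand ('.' allowed).  Duplicate coordinates are merged by
    summing counts; output is sorted by (chrom, start, end, strand).
    """
    raw: list[tuple[GenomeInterval, int]] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise AnnotationParseError(
                    f"expected 6 columns, got {len(f)}", lineno
                )
            try:
                start, end, count = int(f[1]), int(f[2]), int(f[4])
            except ValueError as exc:
                raise AnnotationParseError(str(exc), lineno) from exc
            if start >= end:
                raise ValidationError(
                    f"line {lineno}: intron start {start} >= end {end}"
                )
            if count < 1:
                raise ValidationError(
                    f"line {lineno}: junction call with read count {count}"
                )
            raw.append((GenomeInterval(f[0], start, end, f[5]), count))
    return _merge_calls(raw)


def extract_junctions_from_alignments(
    path: str | Path,
) -> list[JunctionCall]:
    """Extract junction calls from spliced alignments (SAM/BAM).

    Each N CIGAR operation contributes one junction whose intron is the
    skipped reference span; counts aggregate across reads.  Strand is taken
    from the XS attribute when present, else unstranded.  Unmapped and
    secondary records are skipped.
    """
    raw: list[tuple[GenomeInterval, int]] = []
    with pysam.AlignmentFile(str(path)) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary:
                continue
            strand = (
                read.get_tag("XS") if read.has_tag("XS") else "."
            )
            pos = read.reference_start
            for op, length in read.cigartuples or []:
                if op == 3:  # N: skipped reference region
                    raw.append(
                        (
                            GenomeInterval(
                                read.reference_name,
                                pos,
                                pos + length,
                                strand,
                            ),
                            1,
                        )
                    )
                if op in (0, 2, 3, 7, 8):  # consumes reference
                    pos += length
    return _merge_calls(raw)


def classify_junctions(
    calls: Sequence[JunctionCall], ann: AnnotationSet
) -> tuple[list[JunctionCall], list[JunctionCall]]:
    """Partition calls into (known, novel) by exact coordinate identity
    against the annotated junction universe."""
    known, novel = [], []
    for c in calls:
        (known if c.key in ann.junctions else novel).append(c)
    return known, novel


def filter_by_support(
    calls: Sequence[JunctionCall], min_reads: int = 20
) -> list[JunctionCall]:
    """Keep calls supported by at least ``min_reads`` reads (inclusive)."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return [c for c in calls if c.read_count >= min_reads]


def _blocks_from_alignments(
    path: str | Path,
) -> Iterable[tuple[str, list[tuple[int, int]]]]:
    with pysam.AlignmentFile(str(path)) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary:
                continue
            yield read.reference_name, read.get_blocks()


def exon_support(
    exons: Sequence[Exon],
    alignments: str | Path | None = None,
    coverage: Iterable[tuple[str, int, int, float]] | None = None,
) -> tuple[dict[tuple, int], dict[tuple, float]]:
    """Per-exon read counts and coverage fractions.

    A read counts for an exon when any of its aligned blocks overlaps the
    exon by at least one base (spliced reads do not cover their introns).
    Coverage is the fraction of exon bases under at least one read.  When
    only a per-base ``coverage`` track (bedGraph-style tuples of
    chrom/start/end/value) is given, counts stay 0 and coverage fractions
    are computed from the intervals with value > 0.
    """
    counts = {e.key: 0 for e in exons}
    masks = {e.key: np.zeros(e.region.length, dtype=bool) for e in exons}
    trees: dict[str, IntervalTree] = {}
    for e in exons:
        trees.setdefault(e.region.chrom, IntervalTree()).addi(
            e.region.start, e.region.end, e.key
        )

    def paint(chrom: str, start: int, end: int, count_hit: bool) -> None:
        tree = trees.get(chrom)
        if tree is None:
            return
        for iv in tree.overlap(start, end):
            key = iv.data
            lo = max(start, iv.begin) - iv.begin
            hi = min(end, iv.end) - iv.begin
            masks[key][lo:hi] = True
            if count_hit:
                hit.add(key)

    if alignments is not None:
        for chrom, blocks in _blocks_from_alignments(alignments):
            hit: set[tuple] = set()
            for bstart, bend in blocks:
                paint(chrom, bstart, bend, count_hit=True)
            for key in hit:
                counts[key] += 1
    if coverage is not None:
        hit = set()
        for chrom, start, end, value in coverage:
            if value > 0:
                paint(chrom, start, end, count_hit=False)
    cov = {k: float(m.mean()) for k, m in masks.items()}
    return counts, cov


def load_exon_table(path: str | Path) -> tuple[dict, dict]:
    """Read a per-exon support table (TSV: chrom start end strand count
    coverage) as written by the simulator or by `walker evidence`."""
    counts: dict[tuple, int] = {}
    cov: dict[tuple, float] = {}
    df = pd.read_csv(path, sep="\t", comment="#")
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.start), int(row.end), row.strand)
        counts[key] = int(row.count)
        cov[key] = float(row.coverage)
    return counts, cov


def write_exon_table(
    exons: Sequence[Exon], counts: dict, cov: dict, path: str | Path
) -> None:
    rows = [
        {
            "chrom": e.region.chrom,
            "start": e.region.start,
            "end": e.region.end,
            "strand": e.region.strand,
            "count": counts.get(e.key, 0),
            "coverage": round(cov.get(e.key, 0.0), 6),
        }
        for e in sorted(exons, key=lambda e: e.key)
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "count", "coverage"],
    ).to_csv(path, sep="\t", index=False)


def _bin_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f"{lo}+"
    if lo == hi:
        return str(lo)
    return f"{lo}-{hi}"


def _bin_counts(values: Iterable[int], bins) -> dict[str, int]:
    out = {_bin_label(lo, hi): 0 for lo, hi in bins}
    for v in values:
        for lo, hi in bins:
            if v >= lo and (hi is None or v <= hi):
                out[_bin_label(lo, hi)] += 1
                break
    return out

def evidence_summary(ev: EvidenceSet) -> pd.DataFrame:
    """Junction and exon counts binned by read support.

    Junction rows: 1, 2-4, 5-9, 10-19, 20-49, 50-99, 100-499, 500+.
    Exon rows add a 0 bin (an exon can be defined yet unsequenced; a
    junction call cannot).
    """
    jbins = _bin_counts(
        (c.read_count for c in ev.junction_calls), JUNCTION_BINS
    )
    ebins = _bin_counts(ev.exon_counts.values(), EXON_BINS)
    labels = [_bin_label(lo, hi) for lo, hi in EXON_BINS]
    return pd.DataFrame(
        {
            "reads": labels,
            "junctions": [jbins.get(l, 0) for l in labels],
            "exons": [ebins.get(l, 0) for l in labels],
        }
    )
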