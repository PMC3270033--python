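"""Transcript annotation model and I/O.

The reference annotation is the prior knowledge of the reconstruction
method: from a set of annotated transcripts we derive (i) the universe of
annotated splice junctions, (ii) the pairs of junctions that co-occur on at
least one transcript (the evidence required to chain two annotated
junctions), (iii) the deduplicated annotated exon set, and (iv) per gene the
annotated transcript start/end coordinates used to anchor terminal exons.

Coordinates are 0-based half-open on the genome everywhere inside the
package.  GTF input/output converts from/to the 1-based inclusive
convention at the file boundary; BED12 is native.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import gffutils.feature

from ._io import open_text as _open_text
from .errors import AnnotationParseError, EmptyInputError, ValidationError

STRANDS = ("+", "-", ".")

ANNOTATED = "annotated"
NOVEL = "novel"
RECONSTRUCTED = "reconstructed"

SOURCE_JUNCTION = "junction"
SOURCE_BOUNDARY = "transcript_boundary"


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Half-open genomic interval [start, end) on a chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Junction:
    """A splice junction, represented by its intron.

    ``intron.start`` is the donor site (end of the upstream exon) and
    ``intron.end`` the acceptor site (start of the downstream exon).
    Identity is the exact intron coordinate tuple; read counts and status
    never enter identity comparisons (use :attr:`key`).
    """

    intron: GenomeInterval
    status: str = NOVEL
    read_count: int = 0

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValidationError("negative junction read count")
        if self.status not in (ANNOTATED, NOVEL):
            raise ValidationError(f"bad junction status {self.status!r}")

    @property
    def donor(self) -> int:
        return self.intron.start

    @property
    def acceptor(self) -> int:
        return self.intron.end

    @property
    def key(self) -> tuple[str, int, int, str]:
        return self.intron.key


@dataclass
class Exon:
    """A genomic exon with boundary provenance and read support."""

    region: GenomeInterval
    left_source: str = SOURCE_JUNCTION
    right_source: str = SOURCE_JUNCTION
    status: str = ANNOTATED
    read_count: int = 0
    coverage_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValidationError("coverage fraction outside [0, 1]")
        for src in (self.left_source, self.right_source):
            if src not in (SOURCE_JUNCTION, SOURCE_BOUNDARY):
                raise ValidationError(f"bad boundary source {src!r}")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return self.region.key


@dataclass
class Transcript:
    """An ordered exon chain with the junction chain between the exons.

    Exons are stored in genomic (left-to-right) order regardless of strand;
    ``junction_chain[i]`` is the intron between ``exons[i]`` and
    ``exons[i + 1]``.  ``support`` is the minimum read count over the novel
    elements of a reconstructed transcript and ``None`` for fully annotated
    transcripts.
    """

    id: str
    gene_id: str
    exons: list[Exon]
    junction_chain: list[Junction] = field(default_factory=list)
    status: str = ANNOTATED
    support: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.id} has no exons")
        chrom = self.exons[0].region.chrom
        strand = self.exons[0].region.strand
        if len(self.junction_chain) != len(self.exons) - 1:
            raise ValidationError(
                f"transcript {self.id}: {len(self.exons)} exons require "
                f"{len(self.exons) - 1} junctions, "
                f"got {len(self.junction_chain)}"
            )
        for e in self.exons:
            if e.region.chrom != chrom or e.region.strand != strand:
                raise ValidationError(
                    f"transcript {self.id} mixes chromosomes or strands"
                )
        for left, right, j in zip(
            self.exons, self.exons[1:], self.junction_chain
        ):
            if left.region.end >= right.region.start:
                raise ValidationError(
                    f"transcript {self.id}: exons out of order or overlapping"
                )
            if (
                j.intron.start != left.region.end
                or j.intron.end != right.region.start
            ):
                raise ValidationError(
                    f"transcript {self.id}: junction {j.key} does not match "
                    "its flanking exons"
                )
            if j.intron.chrom != chrom:
                raise ValidationError(
                    f"transcript {self.id}: junction on wrong chromosome"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].region.chrom

    @property
    def strand(self) -> str:
        return self.exons[0].region.strand

    @property
    def start(self) -> int:
        return self.exons[0].region.start

    @property
    def end(self) -> int:
        return self.exons[-1].region.end

    @property
    def chain_key(self) -> tuple[tuple[str, int, int, str], ...]:
        """Junction-chain identity: two transcripts are the same isoform
        for this method iff their chains are identical."""
        return tuple(j.key for j in self.junction_chain)

    @property
    def exonic_length(self) -> int:
        return sum(e.region.length for e in self.exons)


def junctions_from_exons(
    exons: Sequence[Exon], status: str = ANNOTATED
) -> list[Junction]:
    """The introns between consecutive exons, in genomic order."""
    out = []
    for left, right in zip(exons, exons[1:]):
        out.append(
            Junction(
                GenomeInterval(
                    left.region.chrom,
                    left.region.end,
                    right.region.start,
                    left.region.strand,
                ),
                status=status,
            )
        )
    return out


def make_transcript(
    tid: str,
    gene_id: str,
    chrom: str,
    strand: str,
    exon_coords: Sequence[tuple[int, int]],
    status: str = ANNOTATED,
    support: int | None = None,
) -> Transcript:
    """Convenience constructor from bare exon coordinate pairs."""
    exons = [
        Exon(GenomeInterval(chrom, s, e, strand), status=status)
        for s, e in sorted(exon_coords)
    ]
    jstatus = ANNOTATED if status == ANNOTATED else NOVEL
    return Transcript(
        id=tid,
        gene_id=gene_id,
        exons=exons,
        junction_chain=junctions_from_exons(exons, status=jstatus),
        status=status,
        support=support,
    )


@dataclass
class Gene:
    id: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.id} has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"gene {self.id} spans multiple chromosomes or strands"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom,
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
            self.strand,
        )

    @property
    def max_annotated_exon_len(self) -> int:
        return max(
            e.region.length
            for t in self.transcripts
            if t.status == ANNOTATED
            for e in t.exons
        )

    @property
    def annotated_junctions(self) -> list[Junction]:
        seen: dict[tuple, Junction] = {}
        for t in self.transcripts:
            if t.status != ANNOTATED:
                continue
            for j in t.junction_chain:
                seen.setdefault(j.key, j)
        return sorted(seen.values(), key=lambda j: j.key)


@dataclass
class AnnotationSet:
    """Genes plus everything derived from them.

    ``cooccurrence`` holds every unordered pair of annotated junctions that
    appear together on at least one annotated transcript (not only adjacent
    pairs); it is the experimental-evidence requirement for chaining two
    annotated junctions during the walk.  ``boundaries`` maps each gene to
    its (left, right) transcript boundary coordinate sets in genomic
    orientation; on the minus strand the left boundaries are the 3' ends.
    """

    genes: dict[str, Gene]
    junctions: dict[tuple, Junction]
    cooccurrence: set[frozenset]
    exons: dict[tuple, Exon]
    boundaries: dict[str, tuple[frozenset, frozenset]]

    @classmethod
    def from_transcripts(
        cls, transcripts: Iterable[Transcript]
    ) -> "AnnotationSet":
        by_gene: dict[str, list[Transcript]] = {}
        for t in transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        if not by_gene:
            raise EmptyInputError("annotation contains zero transcripts")
        genes = {
            gid: Gene(gid, sorted(ts, key=lambda t: (t.start, t.end, t.id)))
            for gid, ts in by_gene.items()
        }
        junctions: dict[tuple, Junction] = {}
        cooccurrence: set[frozenset] = set()
        exons: dict[tuple, Exon] = {}
        boundaries: dict[str, tuple[frozenset, frozenset]] = {}
        for gid, gene in genes.items():
            lefts, rights = set(), set()
            for t in gene.transcripts:
                lefts.add(t.start)
                rights.add(t.end)
                for e in t.exons:
                    exons.setdefault(
                        e.key, replace(e, status=ANNOTATED)
                    )
                keys = []
                for j in t.junction_chain:
                    ann_j = replace(j, status=ANNOTATED)
                    junctions.setdefault(ann_j.key, ann_j)
                    keys.append(ann_j.key)
                for a, b in itertools.combinations(keys, 2):
                    cooccurrence.add(frozenset((a, b)))
            boundaries[gid] = (frozenset(lefts), frozenset(rights))
        return cls(genes, junctions, cooccurrence, exons, boundaries)

    @property
    def transcripts(self) -> list[Transcript]:
        return [
            t
            for gid in sorted(self.genes)
            for t in self.genes[gid].transcripts
        ]

    @property
    def chromosomes(self) -> set[str]:
        return {g.chrom for g in self.genes.values()}

    def stats(self) -> dict[str, int]:
        return {
            "genes": len(self.genes),
            "transcripts": sum(
                len(g.transcripts) for g in self.genes.values()
            ),
            "exons": len(self.exons),
            "junctions": len(self.junctions),
            "cooccurring_pairs": len(self.cooccurrence),
        }


# ---------------------------------------------------------------------------
# File I/O


def _sniff_format(path: str | Path) -> str:
    name = Path(path).name.removesuffix(".gz")
    if name.endswith((".gtf", ".gff")):
        return "gtf"
    if name.endswith(".bed"):
        return "bed12"
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            return "bed12" if len(fields) >= 12 else "gtf"
    raise EmptyInputError(f"{path}: no data lines")


def _iter_gtf_exons(
    fh: IO[str],
) -> Iterator[tuple[int, str, str, int, int, str, dict]]:
    for lineno, line in enumerate(fh, 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise AnnotationParseError(
                f"expected 9 tab-separated columns, got {len(fields)}",
                lineno,
            )
        if fields[2] != "exon":
            continue
        try:
            feat = gffutils.feature.feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted types
            raise AnnotationParseError(str(exc), lineno) from exc
        attrs = dict(feat.attributes)
        if "transcript_id" not in attrs or "gene_id" not in attrs:
            raise AnnotationParseError(
                "exon record lacks transcript_id/gene_id", lineno
            )
        try:
            start = int(fields[3]) - 1  # GTF is 1-based inclusive
            end = int(fields[4])
        except ValueError as exc:
            raise AnnotationParseError(str(exc), lineno) from exc
        yield lineno, fields[0], fields[6], start, end, attrs[
            "transcript_id"
        ][0], attrs


def _read_gtf(path: str | Path) -> list[Transcript]:
    per_tx: dict[str, dict] = {}
    with _open_text(path) as fh:
        for lineno, chrom, strand, start, end, tid, attrs in _iter_gtf_exons(
            fh
        ):
            if strand not in ("+", "-"):
                raise AnnotationParseError(
                    f"annotated transcript {tid} must be stranded", lineno
                )
            rec = per_tx.setdefault(
                tid,
                {
                    "gene_id": attrs["gene_id"][0],
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                },
            )
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise ValidationError(
                    f"transcript {tid} mixes chromosomes or strands"
                )
            rec["exons"].append((start, end))
    return _assemble(per_tx)


def _read_bed12(path: str | Path) -> list[Transcript]:
    per_tx: dict[str, dict] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(
                ("#", "track", "browser")
            ):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise AnnotationParseError(
                    f"expected 12 BED columns, got {len(f)}", lineno
                )
            try:
                chrom_start = int(f[1])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationParseError(str(exc), lineno) from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise AnnotationParseError(
                    "blockCount disagrees with blockSizes/blockStarts",
                    lineno,
                )
            strand = f[5]
            if strand not in ("+", "-"):
                raise AnnotationParseError(
                    "annotated transcript must be stranded", lineno
                )
            name = f[3]
            gene_id, _, tid = name.partition("|")
            if not tid:
                gene_id, tid = name, name
            exons = [
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(offsets, sizes)
            ]
            if tid in per_tx:
                raise ValidationError(f"duplicate transcript id {tid}")
            per_tx[tid] = {
                "gene_id": gene_id,
                "chrom": f[0],
                "strand": strand,
                "exons": exons,
            }
    return _assemble(per_tx)


def _assemble(per_tx: dict[str, dict]) -> list[Transcript]:
    transcripts = []
    for tid, rec in per_tx.items():
        coords = sorted(rec["exons"])
        for (s1, e1), (s2, e2) in zip(coords, coords[1:]):
            if e1 >= s2:
                raise ValidationError(
                    f"transcript {tid} has overlapping or abutting exon "
                    f"blocks [{s1},{e1}) and [{s2},{e2})"
                )
        transcripts.append(
            make_transcript(
                tid, rec["gene_id"], rec["chrom"], rec["strand"], coords
            )
        )
    return transcripts


def read_annotation(
    path: str | Path, format: str = "auto"
) -> AnnotationSet:
    """Read a GTF or BED12 annotation into an :class:`AnnotationSet`.

    GTF coordinates are converted to the internal 0-based half-open
    convention; BED12 block structure is expanded into exons.  The junction
    universe, co-occurrence pairs, exon set and transcript boundaries are
    derived on load.
    """
    if format == "auto":
        format = _sniff_format(path)
    if format == "gtf":
        transcripts = _read_gtf(path)
    elif format == "bed12":
        transcripts = _read_bed12(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if not transcripts:
        raise EmptyInputError(f"{path}: annotation contains zero transcripts")
    return AnnotationSet.from_transcripts(transcripts)


def write_transcripts(
    transcripts: Sequence[Transcript],
    path: str | Path,
    format: str = "gtf",
) -> None:
    """Write transcripts to GTF or BED12.

    Every transcript is validated before anything is written, so a failing
    call leaves no partial file.  Reconstructed transcripts carry their
    status and support score (GTF attributes; BED12 score column).
    """
    for t in transcripts:
        t.validate()
    lines: list[str] = []
    if format == "gtf":
        for t in transcripts:
            for i, e in enumerate(t.exons, 1):
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.id}"; '
                    f'exon_number "{i}"; status "{t.status}";'
                )
                if t.support is not None:
                    attrs += f' support "{t.support}";'
                lines.append(
                    "\t".join(
                        (
                            e.region.chrom,
                            "walker",
                            "exon",
                            str(e.region.start + 1),
                            str(e.region.end),
                            ".",
                            e.region.strand,
                            ".",
                            attrs,
                        )
                    )
                )
    elif format == "bed12":
        for t in transcripts:
            sizes = ",".join(str(e.region.length) for e in t.exons)
            offsets = ",".join(
                str(e.region.start - t.start) for e in t.exons
            )
            score = t.support if t.support is not None else 0
            lines.append(
                "\t".join(
                    (
                        t.chrom,
                        str(t.start),
                        str(t.end),
                        f"{t.gene_id}|{t.id}",
                        str(min(score, 1000)),
                        t.strand,
                        str(t.start),
                        str(t.end),
                        "0",
                        str(len(t.exons)),
                        sizes,
                        offsets,
                    )
                )
            )
    else:
        raise ValueError(f"unknown output format {format!r}")
    with _open_text(path, "wt") as fh:
        for line in lines:
            fh.write(line + "\n")
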