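"""Synthetic gene models, planted splicing events, and simulated evidence.

The simulator produces the inputs the reconstruction method consumes, with
the statistical structure of real short-read data that matters to it:
multi-isoform genes whose isoforms share subsets of junctions (so the
co-occurrence condition is exercised), planted novel events of the four
archetypes (skipped exon, inserted exon, split exon, shifted boundary), and
Poisson read counts over junctions and exons with a configurable fraction
of exons only partially covered.  Everything is deterministic under the
seed.

Two hand-constructed fixtures reproduce the canonical worked examples: a
two-isoform gene extended by two novel junctions and three novel exons into
two reconstructed transcripts, and a TPM2-style gene where one novel exon
inserted into a shared intron must be integrated into *both* reference
backbones.  Their coordinates are synthetic — chosen to realize the
published topologies, not taken from any genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import (
    NOVEL,
    RECONSTRUCTED,
    AnnotationSet,
    Exon,
    GenomeInterval,
    Junction,
    Transcript,
    make_transcript,
    write_transcripts,
)
from .evidence import EvidenceSet, JunctionCall, write_exon_table

EVENT_TYPES = ("skip", "insert", "split", "alt_boundary")

_GENE_GAP = 10_000
_CHROMS = ("chrS1", "chrS2")


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (4, 9)
    exon_length: tuple[int, int] = (50, 650)
    intron_length: tuple[int, int] = (200, 2_000)
    isoforms_per_gene: tuple[int, int] = (1, 3)
    #: mean junction depth; with the 20-read confidence filter most of the
    #: mass of Poisson(18) sits below the cutoff, mirroring the depth
    #: spread seen in real bulk data where ~60% of observed junctions fall
    #: under 20 reads
    mean_junction_depth: float = 18.0
    mean_exon_depth: float = 22.0
    #: depth of planted novel elements; 100 saturates the 20-read filter
    planted_mean_depth: float = 100.0
    #: fraction of exons whose genomic span is less than half covered
    partial_coverage_fraction: float = 0.2
    planted_events: tuple[str, ...] = ()
    seed: int = 0


@dataclass
class TruthSet:
    """Planted novel transcripts and the elements that define them."""

    transcripts: list[Transcript] = field(default_factory=list)
    novel_junctions: list[Junction] = field(default_factory=list)
    novel_exons: list[Exon] = field(default_factory=list)
    #: transcript id -> planted event type
    events: dict[str, str] = field(default_factory=dict)


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, salt])


def make_genes(cfg: SimConfig) -> AnnotationSet:
    """Random non-overlapping multi-isoform gene models.

    Each gene gets a full-length base isoform; additional isoforms either
    skip one internal exon or use an alternative leftmost exon (its own
    private junction converging on the shared acceptor), so genes carry
    both shared and private junctions.
    """
    rng = _rng(cfg, 11)
    cursors = {c: 1_000 for c in _CHROMS}
    transcripts: list[Transcript] = []
    e_lo, e_hi = cfg.exon_length
    i_lo, i_hi = cfg.intron_length
    k_lo, k_hi = cfg.exons_per_gene
    n_lo, n_hi = cfg.isoforms_per_gene
    for gi in range(cfg.n_genes):
        chrom = _CHROMS[gi % len(_CHROMS)]
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{gi + 1:04d}"
        k = int(rng.integers(k_lo, k_hi + 1))
        lens = rng.integers(e_lo, e_hi + 1, size=k)
        gaps = rng.integers(i_lo, i_hi + 1, size=max(k - 1, 1))
        pos = cursors[chrom] + _GENE_GAP
        coords = []
        for idx in range(k):
            coords.append((pos, pos + int(lens[idx])))
            pos += int(lens[idx])
            if idx < k - 1:
                pos += int(gaps[idx])
        cursors[chrom] = pos
        isoforms = [coords]
        n_iso = int(rng.integers(n_lo, n_hi + 1))
        skipped: set[int] = set()
        has_alt_first = False
        for _ in range(n_iso - 1):
            options = []
            candidates = [
                i for i in range(1, k - 1) if i not in skipped
            ]
            if candidates:
                options.append("skip")
            intron1 = coords[1][0] - coords[0][1] if k >= 2 else 0
            if not has_alt_first and intron1 >= 60:
                options.append("alt_first")
            if not options:
                break
            choice = options[int(rng.integers(0, len(options)))]
            if choice == "skip":
                i = candidates[int(rng.integers(0, len(candidates)))]
                skipped.add(i)
                isoforms.append(coords[:i] + coords[i + 1 :])
            else:
                has_alt_first = True
                off = int(rng.integers(10, min(intron1 - 10, 300) + 1))
                s_off = int(rng.integers(-40, 41))
                s0, e0 = coords[0]
                first = (max(s0 + s_off, 1), e0 + off)
                isoforms.append([first] + coords[1:])
        for ti, iso in enumerate(isoforms, 1):
            transcripts.append(
                make_transcript(f"{gid}.t{ti}", gid, chrom, strand, iso)
            )
    return AnnotationSet.from_transcripts(transcripts)


def plant_events(ann: AnnotationSet, cfg: SimConfig) -> TruthSet:
    """Edit host isoforms into truth transcripts carrying novel events.

    Each event gets its own host gene (two planted events in one gene
    would extend each other's chains, so no single-event chain would be
    maximal), and planted junctions are checked against the annotated
    junction universe so every planted element really is novel.
    """
    rng = _rng(cfg, 23)
    truth = TruthSet()
    used_genes: set[str] = set()
    used_spans: list[tuple[str, int, int]] = []
    gene_ids = sorted(ann.genes)
    if len(cfg.planted_events) > len(gene_ids):
        raise ValueError(
            "more planted events than genes; raise n_genes"
        )

    def collides(chrom: str, start: int, end: int) -> bool:
        return any(
            c == chrom and start < e and s < end
            for c, s, e in used_spans
        )

    def claim(chrom: str, start: int, end: int) -> None:
        used_spans.append((chrom, start, end))

    def add_truth(gid, host, coords, event, novel_js, novel_es):
        tid = f"{gid}.{event}{len(truth.transcripts) + 1}"
        t = make_transcript(
            tid, gid, host.chrom, host.strand, coords, status=RECONSTRUCTED
        )
        truth.transcripts.append(t)
        truth.events[tid] = event
        truth.novel_junctions.extend(novel_js)
        truth.novel_exons.extend(novel_es)

    for event in cfg.planted_events:
        if event not in EVENT_TYPES:
            raise ValueError(f"unknown event type {event!r}")
        planted = False
        start_at = int(rng.integers(0, len(gene_ids)))
        for gid in gene_ids[start_at:] + gene_ids[:start_at]:
            if gid in used_genes:
                continue
            gene = ann.genes[gid]
            host = gene.transcripts[0]
            exons = [(e.region.start, e.region.end) for e in host.exons]
            chrom, strand = host.chrom, host.strand
            k = len(exons)
            if event == "skip" and k >= 3:
                for i in range(1, k - 1):
                    d, a = exons[i - 1][1], exons[i + 1][0]
                    key = (chrom, d, a, strand)
                    if key in ann.junctions or collides(chrom, d, a):
                        continue
                    nj = Junction(
                        GenomeInterval(chrom, d, a, strand), status=NOVEL
                    )
                    claim(chrom, d, a)
                    add_truth(
                        gid,
                        host,
                        exons[:i] + exons[i + 1 :],
                        event,
                        [nj],
                        [],
                    )
                    planted = True
                    break
            elif event == "insert" and k >= 2:
                for i in range(k - 1):
                    d, a = exons[i][1], exons[i + 1][0]
                    if a - d < 150 or collides(chrom, d, a):
                        continue
                    mid = (d + a) // 2
                    half = int(rng.integers(30, 61))
                    x, y = mid - half, mid + half
                    nj1 = Junction(
                        GenomeInterval(chrom, d, x, strand), status=NOVEL
                    )
                    nj2 = Junction(
                        GenomeInterval(chrom, y, a, strand), status=NOVEL
                    )
                    ne = Exon(
                        GenomeInterval(chrom, x, y, strand), status=NOVEL
                    )
                    claim(chrom, d, a)
                    add_truth(
                        gid,
                        host,
                        exons[: i + 1] + [(x, y)] + exons[i + 1 :],
                        event,
                        [nj1, nj2],
                        [ne],
                    )
                    planted = True
                    break
            elif event == "split":
                for i in range(k):
                    s, e = exons[i]
                    if e - s < 150 or collides(chrom, s, e):
                        continue
                    third = (e - s) // 3
                    x1 = s + max(third - 10, 30)
                    y1 = x1 + 25
                    x2 = s + 2 * third
                    y2 = x2 + 25
                    if y2 >= e - 30:
                        continue
                    nj1 = Junction(
                        GenomeInterval(chrom, x1, y1, strand), status=NOVEL
                    )
                    nj2 = Junction(
                        GenomeInterval(chrom, x2, y2, strand), status=NOVEL
                    )
                    pieces = [(s, x1), (y1, x2), (y2, e)]
                    nes = [
                        Exon(GenomeInterval(chrom, a, b, strand), status=NOVEL)
                        for a, b in pieces
                    ]
                    claim(chrom, s, e)
                    add_truth(
                        gid,
                        host,
                        exons[:i] + pieces + exons[i + 1 :],
                        event,
                        [nj1, nj2],
                        nes,
                    )
                    planted = True
                    break
            elif event == "alt_boundary" and k >= 3:
                # keep the transcription-first junction intact: a novel
                # junction replacing it could never be a legal walk start
                indices = range(2, k) if strand == "+" else range(1, k - 1)
                for i in indices:
                    s, e = exons[i]
                    d = exons[i - 1][1]
                    if e - s < 60 or collides(chrom, d, e):
                        continue
                    delta = int(rng.integers(10, 31))
                    nj = Junction(
                        GenomeInterval(chrom, d, s + delta, strand),
                        status=NOVEL,
                    )
                    if nj.key in ann.junctions:
                        continue
                    ne = Exon(
                        GenomeInterval(chrom, s + delta, e, strand),
                        status=NOVEL,
                    )
                    claim(chrom, d, e)
                    add_truth(
                        gid,
                        host,
                        exons[:i] + [(s + delta, e)] + exons[i + 1 :],
                        event,
                        [nj],
                        [ne],
                    )
                    planted = True
                    break
            if planted:
                used_genes.add(gid)
                break
        if not planted:
            raise ValueError(
                f"could not place event {event!r}; enlarge the gene models"
            )
    return truth


def simulate_evidence(
    truth: TruthSet, ann: AnnotationSet, cfg: SimConfig
) -> EvidenceSet:
    """Poisson read counts over expressed junctions and exons.

    Annotated elements draw from the background means; planted novel
    elements draw from ``planted_mean_depth``.  A junction with zero reads
    yields no call.  A configurable fraction of exons is left with partial
    coverage (< 50% of bases).
    """
    rng = _rng(cfg, 37)
    calls: list[JunctionCall] = []
    for key in sorted(ann.junctions):
        c = int(rng.poisson(cfg.mean_junction_depth))
        if c >= 1:
            calls.append(JunctionCall(GenomeInterval(*key), c))
    for j in sorted(truth.novel_junctions, key=lambda j: j.key):
        c = int(rng.poisson(cfg.planted_mean_depth))
        if c >= 1:
            calls.append(JunctionCall(j.intron, c))
    counts: dict[tuple, int] = {}
    cov: dict[tuple, float] = {}
    for key in sorted(ann.exons):
        c = int(rng.poisson(cfg.mean_exon_depth))
        counts[key] = c
        if c == 0:
            cov[key] = 0.0
        elif rng.random() < cfg.partial_coverage_fraction:
            cov[key] = float(rng.uniform(0.05, 0.5))
        else:
            cov[key] = float(rng.uniform(0.8, 1.0))
    for e in sorted(truth.novel_exons, key=lambda e: e.key):
        c = int(rng.poisson(cfg.planted_mean_depth))
        counts[e.key] = c
        cov[e.key] = float(rng.uniform(0.9, 1.0)) if c else 0.0
    calls.sort(key=lambda c: c.key)
    return EvidenceSet(calls, counts, cov)


def exact_evidence(
    truth: TruthSet,
    ann: AnnotationSet,
    novel_count: int,
    annotated_count: int = 50,
) -> EvidenceSet:
    """Evidence with exact, uniform read counts (no sampling): every
    annotated junction/exon at ``annotated_count`` reads and every planted
    novel element at ``novel_count``.  Useful for filter-boundary studies
    where the count, not the depth model, is the variable of interest."""
    calls = [
        JunctionCall(GenomeInterval(*key), annotated_count)
        for key in sorted(ann.junctions)
    ]
    counts = {key: annotated_count for key in ann.exons}
    cov = {key: 1.0 for key in ann.exons}
    if novel_count >= 1:
        calls += [
            JunctionCall(j.intron, novel_count)
            for j in sorted(truth.novel_junctions, key=lambda j: j.key)
        ]
    for e in truth.novel_exons:
        counts[e.key] = novel_count
        cov[e.key] = 1.0 if novel_count else 0.0
    calls.sort(key=lambda c: c.key)
    return EvidenceSet(calls, counts, cov)


# ---------------------------------------------------------------------------
# Worked-example fixtures (synthetic coordinates realizing the published
# topologies)


@dataclass(frozen=True)
class FixtureExpectation:
    #: regions (start, end) of the novel exons the exon mapper must find
    novel_exons: frozenset[tuple[int, int]]
    #: junction chains (tuples of (start, end) introns) of the transcripts
    #: the walk must reconstruct
    chains: frozenset[tuple[tuple[int, int], ...]]


def figure2_fixture() -> tuple[AnnotationSet, EvidenceSet, FixtureExpectation]:
    """Two annotated isoforms converging on a shared tail, plus two novel
    junctions that open a new 3' structure.

    A1 = exons [100,200) [300,400) [500,650) [800,900), junctions a11, a12,
    a3; A2 = exons [50,150) [250,420) [500,650) [800,900), junctions a21,
    a22, a3 (a12 and a22 share the acceptor 500; a3 is shared).  Novel
    junctions n1 = [560,600) and n2 = [620,700) define three novel exons
    [500,560), [600,620) and [700,900), and the walk must reconstruct
    exactly two new transcripts: a11-a12-n1-n2 and a21-a22-n1-n2.
    """
    chrom, strand = "chrF", "+"
    a1 = make_transcript(
        "A1", "DEMO1", chrom, strand, [(100, 200), (300, 400), (500, 650), (800, 900)]
    )
    a2 = make_transcript(
        "A2", "DEMO1", chrom, strand, [(50, 150), (250, 420), (500, 650), (800, 900)]
    )
    ann = AnnotationSet.from_transcripts([a1, a2])
    calls = [
        JunctionCall(GenomeInterval(chrom, 560, 600, strand), 30),
        JunctionCall(GenomeInterval(chrom, 620, 700, strand), 25),
    ]
    counts = {key: 100 for key in ann.exons}
    cov = {key: 1.0 for key in ann.exons}
    for region, c in (((500, 560), 30), ((600, 620), 28), ((700, 900), 40)):
        key = (chrom, region[0], region[1], strand)
        counts[key] = c
        cov[key] = 1.0
    expected = FixtureExpectation(
        novel_exons=frozenset({(500, 560), (600, 620), (700, 900)}),
        chains=frozenset(
            {
                ((200, 300), (400, 500), (560, 600), (620, 700)),
                ((150, 250), (420, 500), (560, 600), (620, 700)),
            }
        ),
    )
    return ann, EvidenceSet(calls, counts, cov), expected


def tpm2_fixture() -> tuple[AnnotationSet, EvidenceSet, FixtureExpectation]:
    """Two reference isoforms sharing the intron into which one novel exon
    is inserted (via two novel junctions).  A parsimony-style assembler
    attaches the new exon to a single isoform; junction walking must
    integrate it into both backbones, reconstructing two new transcripts,
    each an exon-insertion event.
    """
    chrom, strand = "chrF", "+"
    ref1 = make_transcript(
        "Ref1", "TPM2", chrom, strand,
        [(100, 200), (400, 500), (900, 1000), (1200, 1300)],
    )
    ref2 = make_transcript(
        "Ref2", "TPM2", chrom, strand,
        [(150, 300), (400, 500), (900, 1000), (1200, 1300)],
    )
    ann = AnnotationSet.from_transcripts([ref1, ref2])
    calls = [
        JunctionCall(GenomeInterval(chrom, 500, 650, strand), 30),
        JunctionCall(GenomeInterval(chrom, 720, 900, strand), 30),
    ]
    counts = {key: 100 for key in ann.exons}
    cov = {key: 1.0 for key in ann.exons}
    counts[(chrom, 650, 720, strand)] = 35
    cov[(chrom, 650, 720, strand)] = 1.0
    expected = FixtureExpectation(
        novel_exons=frozenset({(650, 720)}),
        chains=frozenset(
            {
                ((200, 400), (500, 650), (720, 900), (1000, 1200)),
                ((300, 400), (500, 650), (720, 900), (1000, 1200)),
            }
        ),
    )
    return ann, EvidenceSet(calls, counts, cov), expected


# ---------------------------------------------------------------------------
# File emission


def write_junction_bed(
    calls: Sequence[JunctionCall], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(sorted(calls, key=lambda c: c.key), 1):
            fh.write(
                "\t".join(
                    (
                        c.intron.chrom,
                        str(c.intron.start),
                        str(c.intron.end),
                        f"J{i}",
                        str(c.read_count),
                        c.intron.strand,
                    )
                )
                + "\n"
            )


def write_evidence(
    ev: EvidenceSet, junction_path: str | Path, exon_path: str | Path
) -> None:
    write_junction_bed(ev.junction_calls, junction_path)
    exons = [Exon(GenomeInterval(*key)) for key in sorted(ev.exon_counts)]
    write_exon_table(exons, ev.exon_counts, ev.exon_coverage, exon_path)


def write_toy_sam(
    calls: Sequence[JunctionCall],
    path: str | Path,
    anchor: int = 25,
) -> None:
    """Emit spliced single-end alignments realizing the junction calls.

    Each call becomes ``read_count`` identical reads with an
    ``{anchor}M{intron}N{anchor}M`` CIGAR across the intron — enough to
    exercise the alignment-extraction path end to end."""
    maxima: dict[str, int] = {}
    for c in calls:
        maxima[c.intron.chrom] = max(
            maxima.get(c.intron.chrom, 0), c.intron.end + anchor + 10
        )
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom in sorted(maxima):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{maxima[chrom]}\n")
        rid = 0
        for c in sorted(calls, key=lambda c: c.key):
            pos = c.intron.start - anchor + 1  # SAM is 1-based
            cigar = f"{anchor}M{c.intron.length}N{anchor}M"
            seq = "A" * (2 * anchor)
            for _ in range(c.read_count):
                rid += 1
                tags = (
                    f"\tXS:A:{c.intron.strand}"
                    if c.intron.strand in "+-"
                    else ""
                )
                fh.write(
                    f"r{rid}\t0\t{c.intron.chrom}\t{pos}\t60\t{cigar}\t*"
                    f"\t0\t0\t{seq}\t*{tags}\n"
                )


def write_simulation(
    ann: AnnotationSet,
    truth: TruthSet,
    ev: EvidenceSet,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write ref.gtf, junctions.bed, exon_counts.tsv, truth.gtf and
    truth_events.tsv into ``out_dir``; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ref": out / "ref.gtf",
        "junctions": out / "junctions.bed",
        "exon_counts": out / "exon_counts.tsv",
        "truth": out / "truth.gtf",
        "truth_events": out / "truth_events.tsv",
    }
    write_transcripts(ann.transcripts, paths["ref"], format="gtf")
    write_evidence(ev, paths["junctions"], paths["exon_counts"])
    write_transcripts(truth.transcripts, paths["truth"], format="gtf")
    with open(paths["truth_events"], "w") as fh:
        fh.write("transcript_id\tevent\n")
        for tid in sorted(truth.events):
            fh.write(f"{tid}\t{truth.events[tid]}\n")
    return paths
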