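"""End-to-end reconstruction pipeline.

Wires the stages in their natural order: ingest junction evidence ->
classify against the reference -> support-filter -> define candidate exons
-> support-filter exons -> per-gene junction walk -> optional verification
against a second annotation set -> event classification -> reports.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .annotation import (
    ANNOTATED,
    AnnotationSet,
    Exon,
    Junction,
    Transcript,
    read_annotation,
    write_transcripts,
)
from .errors import ValidationError
from .evidence import (
    EvidenceSet,
    JunctionCall,
    classify_junctions,
    evidence_summary,
    exon_support,
    extract_junctions_from_alignments,
    filter_by_support,
    load_exon_table,
    load_junction_bed,
)
from .evaluation import VerificationResult, classify_events, verify_against
from .exonmap import ExonMapConfig, define_exons, filter_exons_by_support
from .junctionwalk import (
    WalkConfig,
    WalkResult,
    assign_to_genes,
    walk,
)
from .simdata import write_junction_bed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline, with the published defaults, so the
    canonical configuration is the zero-flag run."""

    window: int = 10_000
    min_junction_reads: int = 20
    min_exon_reads: int = 20
    novelty_min_diff: int = 4
    min_terminal_default: int = 1_000
    verify_threshold: float = 0.5
    pairing: str = "nearest"
    max_transcripts_per_gene: int = 1_000
    report_annotated: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from YAML or flat key=value text; keyword overrides win."""
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text) or {}
        except yaml.YAMLError:
            data = {}
        if not isinstance(data, dict):
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                k, _, v = line.partition("=")
                data[k.strip()] = yaml.safe_load(v.strip())
        known = cls.__dataclass_fields__
        data = {k: v for k, v in data.items() if k in known}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def exonmap(self) -> ExonMapConfig:
        return ExonMapConfig(
            window=self.window,
            novelty_min_diff=self.novelty_min_diff,
            min_exon_reads=self.min_exon_reads,
            pairing=self.pairing,
        )

    def walkconfig(self) -> WalkConfig:
        return WalkConfig(
            min_terminal_default=self.min_terminal_default,
            max_transcripts_per_gene=self.max_transcripts_per_gene,
            report_annotated=self.report_annotated,
        )

    def header_lines(self) -> list[str]:
        items = "; ".join(f"{k}={v}" for k, v in asdict(self).items())
        return [f"# walker {__version__}", f"# config: {items}"]


@dataclass
class PipelineResult:
    annotation: AnnotationSet
    evidence: EvidenceSet
    novel_junctions: list[Junction]
    novel_exons: list[Exon]
    walks: dict[str, WalkResult]
    transcripts: list[Transcript]
    events: dict[str, frozenset]
    verification: VerificationResult | None
    discarded_junctions: list[JunctionCall]

    @property
    def summary(self) -> dict[str, int]:
        return {
            "novel_junctions": len(self.novel_junctions),
            "novel_exons": len(self.novel_exons),
            "novel_transcripts": len(self.transcripts),
        }


def _check_chromosomes(
    ann: AnnotationSet, calls: Sequence[JunctionCall]
) -> None:
    known = ann.chromosomes
    offenders = sorted({c.intron.chrom for c in calls} - known)
    if offenders:
        raise ValidationError(
            "junction evidence on chromosomes absent from the annotation: "
            + ", ".join(offenders)
        )


def gather_evidence(
    junction_bed: str | Path | None = None,
    alignments: str | Path | None = None,
    exon_table: str | Path | None = None,
) -> EvidenceSet:
    """Merge junction calls from a junction BED and/or spliced alignments,
    plus optional per-exon support from a table."""
    calls: dict[tuple, JunctionCall] = {}

    def add(more: Sequence[JunctionCall]) -> None:
        for c in more:
            prev = calls.get(c.key)
            calls[c.key] = (
                JunctionCall(c.intron, c.read_count + prev.read_count)
                if prev
                else c
            )

    if junction_bed is not None:
        add(load_junction_bed(junction_bed))
    if alignments is not None:
        add(extract_junctions_from_alignments(alignments))
    counts: dict[tuple, int] = {}
    cov: dict[tuple, float] = {}
    if exon_table is not None:
        counts, cov = load_exon_table(exon_table)
    return EvidenceSet(
        [calls[k] for k in sorted(calls)], counts, cov
    )


def run_pipeline(
    cfg: RunConfig,
    ann: AnnotationSet | str | Path,
    evidence: EvidenceSet,
    ref2: AnnotationSet | str | Path | None = None,
    alignments_for_exons: str | Path | None = None,
) -> PipelineResult:
    """Run the full reconstruction on in-memory inputs.

    ``evidence`` must carry junction calls; exon counts/coverage may come
    from the evidence set itself or be computed from
    ``alignments_for_exons`` for the candidate exons.
    """
    if not isinstance(ann, AnnotationSet):
        ann = read_annotation(ann)
    if ref2 is not None and not isinstance(ref2, AnnotationSet):
        ref2 = read_annotation(ref2)
    _check_chromosomes(ann, evidence.junction_calls)

    known, novel_calls = classify_junctions(evidence.junction_calls, ann)
    novel_calls = filter_by_support(novel_calls, cfg.min_junction_reads)
    logger.info(
        "junction calls: %d known, %d novel passing the %d-read filter",
        len(known),
        len(novel_calls),
        cfg.min_junction_reads,
    )
    assigned, discarded, ambiguous = assign_to_genes(novel_calls, ann)
    for key, gids in ambiguous:
        logger.warning(
            "junction %s assigned ambiguously to genes %s", key, gids
        )

    all_novel = sorted(
        {j.key: j for js in assigned.values() for j in js}.values(),
        key=lambda j: j.key,
    )
    exon_cfg = cfg.exonmap()
    candidates = define_exons(all_novel, ann, exon_cfg)
    if alignments_for_exons is not None:
        counts, cov = exon_support(
            candidates, alignments=alignments_for_exons
        )
        evidence = EvidenceSet(evidence.junction_calls, counts, cov)
    admitted = filter_exons_by_support(
        candidates, evidence, cfg.min_exon_reads
    )
    novel_exons = [e for e in admitted if e.status != ANNOTATED]
    exon_universe = list(ann.exons.values()) + novel_exons

    walks: dict[str, WalkResult] = {}
    transcripts: list[Transcript] = []
    wcfg = cfg.walkconfig()
    for gid in sorted(ann.genes):
        gene = ann.genes[gid]
        junctions = gene.annotated_junctions + assigned.get(gid, [])
        if not junctions:
            continue
        res = walk(gene, junctions, exon_universe, ann, wcfg)
        walks[gid] = res
        transcripts.extend(
            res.transcripts if wcfg.report_annotated else res.reconstructed
        )

    events = {
        t.id: classify_events(t, ann.genes[t.gene_id]).labels
        for t in transcripts
        if t.status != ANNOTATED
    }
    verification = None
    if ref2 is not None:
        verification = verify_against(
            [t for t in transcripts if t.status != ANNOTATED],
            ref2,
            cfg.verify_threshold,
        )
    return PipelineResult(
        annotation=ann,
        evidence=evidence,
        novel_junctions=all_novel,
        novel_exons=novel_exons,
        walks=walks,
        transcripts=transcripts,
        events=events,
        verification=verification,
        discarded_junctions=discarded,
    )


def write_outputs(
    result: PipelineResult, cfg: RunConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write the output bundle: novel.gtf, novel_exons.bed,
    novel_junctions.bed, report.tsv and summary.tsv (support-binned counts
    in the style of the published tables)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "novel_gtf": out / "novel.gtf",
        "novel_exons": out / "novel_exons.bed",
        "novel_junctions": out / "novel_junctions.bed",
        "report": out / "report.tsv",
        "summary": out / "summary.tsv",
    }
    write_transcripts(result.transcripts, paths["novel_gtf"], format="gtf")
    with open(paths["novel_exons"], "w") as fh:
        for e in result.novel_exons:
            name = f"{e.left_source[0]}/{e.right_source[0]}"
            fh.write(
                "\t".join(
                    (
                        e.region.chrom,
                        str(e.region.start),
                        str(e.region.end),
                        name,
                        str(e.read_count),
                        e.region.strand,
                    )
                )
                + "\n"
            )
    write_junction_bed(
        [JunctionCall(j.intron, max(j.read_count, 1)) for j in result.novel_junctions],
        paths["novel_junctions"],
    )
    header = cfg.header_lines()
    with open(paths["report"], "w") as fh:
        for line in header:
            fh.write(line + "\n")
        fh.write(
            "transcript_id\tgene_id\tn_exons\tn_junctions\tn_novel_exons\t"
            "n_novel_junctions\tsupport\tevents\tbest_overlap\tverified\n"
        )
        overlap = {}
        if result.verification is not None:
            overlap = {
                r.transcript_id: r for r in result.verification.reports
            }
        for t in result.transcripts:
            n_novel_e = sum(1 for e in t.exons if e.status != ANNOTATED)
            n_novel_j = sum(
                1 for j in t.junction_chain if j.status != ANNOTATED
            )
            ev = ",".join(sorted(result.events.get(t.id, ()))) or "."
            rep = overlap.get(t.id)
            fh.write(
                f"{t.id}\t{t.gene_id}\t{len(t.exons)}\t"
                f"{len(t.junction_chain)}\t{n_novel_e}\t{n_novel_j}\t"
                f"{t.support if t.support is not None else '.'}\t{ev}\t"
                f"{rep.best_overlap_fraction:.4f}\t{rep.verified}\n"
                if rep
                else f"{t.id}\t{t.gene_id}\t{len(t.exons)}\t"
                f"{len(t.junction_chain)}\t{n_novel_e}\t{n_novel_j}\t"
                f"{t.support if t.support is not None else '.'}\t{ev}\t.\t.\n"
            )
    summary = evidence_summary(result.evidence)
    with open(paths["summary"], "w") as fh:
        for line in header:
            fh.write(line + "\n")
        for k, v in result.summary.items():
            fh.write(f"# {k}={v}\n")
        summary.to_csv(fh, sep="\t", index=False)
    return paths
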