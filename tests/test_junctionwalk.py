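from __future__ import annotations

import pytest

from _oracles import enumerate_chains
from walker.annotation import (
    ANNOTATED,
    NOVEL,
    RECONSTRUCTED,
    AnnotationSet,
    Exon,
    GenomeInterval,
    Junction,
    make_transcript,
)
from walker.evidence import JunctionCall
from walker.exonmap import define_exons, filter_exons_by_support
from walker.junctionwalk import (
    WalkConfig,
    assign_to_genes,
    compatible,
    finalize_transcript,
    gene_exon_length_threshold,
    starting_junctions,
    walk,
)
from walker import simdata


def jx(s, e, status=ANNOTATED, chrom="chrF", strand="+", reads=0):
    return Junction(
        GenomeInterval(chrom, s, e, strand), status=status, read_count=reads
    )


@pytest.fixture()
def fig2_parts(figure2):
    ann, ev, expected = figure2
    gene = ann.genes["DEMO1"]
    novel = [
        jx(560, 600, NOVEL, reads=30),
        jx(620, 700, NOVEL, reads=25),
    ]
    exons = filter_exons_by_support(define_exons(novel, ann), ev, 20)
    exon_set = list(ann.exons.values()) + [
        e for e in exons if e.status == NOVEL
    ]
    return ann, gene, novel, exon_set, expected


def test_gene_threshold_floor_and_max():
    long_t = make_transcript("T", "G", "c", "+", [(0, 2500), (3000, 3100)])
    g_long = AnnotationSet.from_transcripts([long_t]).genes["G"]
    assert gene_exon_length_threshold(g_long) == 2500
    short_t = make_transcript("T", "G", "c", "+", [(0, 400), (900, 1000)])
    g_short = AnnotationSet.from_transcripts([short_t]).genes["G"]
    assert gene_exon_length_threshold(g_short) == 1000
    exact = make_transcript("T", "G", "c", "+", [(0, 1000), (1500, 1600)])
    g_exact = AnnotationSet.from_transcripts([exact]).genes["G"]
    assert gene_exon_length_threshold(g_exact) == 1000


def test_compatibility_conditions(fig2_parts):
    ann, gene, novel, exon_set, _ = fig2_parts
    thr = gene_exon_length_threshold(gene)
    a12 = ann.junctions[("chrF", 400, 500, "+")]
    a22 = ann.junctions[("chrF", 420, 500, "+")]
    n1 = novel[0]
    # mixed annotated/novel pair with the exon present
    assert compatible(a12, n1, exon_set, thr, ann)
    # both annotated, never observed together (condition 5)
    assert not compatible(a12, a22, exon_set, thr, ann)
    # identical junction overlaps itself (condition 2)
    assert not compatible(n1, n1, exon_set, thr, ann)
    # argument order is irrelevant
    assert compatible(n1, a12, exon_set, thr, ann)


def test_missing_inter_junction_exon_blocks_walk(fig2_parts):
    """Dropping the exon between n1 and n2 from the admitted set severs
    the walk there (condition 3)."""
    ann, gene, novel, exon_set, _ = fig2_parts
    thr = gene_exon_length_threshold(gene)
    n1, n2 = novel
    assert compatible(n1, n2, exon_set, thr, ann)
    pruned = [e for e in exon_set if (e.region.start, e.region.end) != (600, 620)]
    assert not compatible(n1, n2, pruned, thr, ann)
    junctions = gene.annotated_junctions + novel
    res = walk(gene, junctions, pruned, ann, WalkConfig())
    for t in res.reconstructed:
        assert (("chrF", 620, 700, "+")) not in t.chain_key


def test_length_cap_condition():
    t = make_transcript(
        "T", "G", "c", "+", [(0, 100), (200, 300), (5000, 5100), (5300, 5400)]
    )
    ann = AnnotationSet.from_transcripts([t])
    j1 = ann.junctions[("c", 100, 200, "+")]
    j2 = ann.junctions[("c", 300, 5000, "+")]
    exon_set = list(ann.exons.values())
    assert compatible(j1, j2, exon_set, 1000, ann)
    # inter-junction exon [200,300) is 100 bases; cap below that blocks it
    assert not compatible(j1, j2, exon_set, 99, ann)


def test_starting_junctions_fig2(fig2_parts):
    ann, gene, novel, _, _ = fig2_parts
    starts = {j.key for j in starting_junctions(gene, novel)}
    assert starts == {("chrF", 200, 300, "+"), ("chrF", 150, 250, "+")}


def test_novel_upstream_junction_can_start():
    t = make_transcript("T", "G", "c", "+", [(1000, 1100), (1500, 1600)])
    ann = AnnotationSet.from_transcripts([t])
    gene = ann.genes["G"]
    upstream = jx(700, 900, NOVEL, chrom="c")
    downstream = jx(1520, 1550, NOVEL, chrom="c")
    starts = {j.key for j in starting_junctions(gene, [upstream, downstream])}
    assert starts == {("c", 1100, 1500, "+"), ("c", 700, 900, "+")}


def test_walk_reconstructs_fig2_transcripts(fig2_parts):
    ann, gene, novel, exon_set, expected = fig2_parts
    res = walk(gene, gene.annotated_junctions + novel, exon_set, ann)
    chains = {
        tuple((s, e) for _, s, e, _ in t.chain_key)
        for t in res.reconstructed
    }
    assert chains == set(expected.chains)
    assert len(res.reconstructed) == 2
    # all four maximal chains (two annotated isoforms + two novel)
    assert res.n_chains == 4


def test_walk_conserves_annotation_without_evidence(fig2_parts):
    ann, gene, _, _, _ = fig2_parts
    res = walk(
        gene,
        gene.annotated_junctions,
        list(ann.exons.values()),
        ann,
        WalkConfig(report_annotated=True),
    )
    got = {t.chain_key for t in res.transcripts}
    assert got == {
        t.chain_key for t in gene.transcripts if t.junction_chain
    }
    assert res.reconstructed == []


def test_finalize_support_is_min_over_novel_elements(fig2_parts):
    ann, gene, novel, exon_set, _ = fig2_parts
    a11 = ann.junctions[("chrF", 200, 300, "+")]
    a12 = ann.junctions[("chrF", 400, 500, "+")]
    chain = [a11, a12, novel[0], novel[1]]
    t = finalize_transcript(chain, gene, exon_set, ann)
    novel_counts = [j.read_count for j in chain if j.status == NOVEL]
    novel_counts += [e.read_count for e in t.exons if e.status == NOVEL]
    assert t.support == min(novel_counts) == 25
    assert t.status == RECONSTRUCTED
    assert (t.exons[0].region.start, t.exons[0].region.end) == (100, 200)
    assert (t.exons[-1].region.start, t.exons[-1].region.end) == (700, 900)


def test_finalize_fully_annotated_chain(fig2_parts):
    ann, gene, _, exon_set, _ = fig2_parts
    a1 = gene.transcripts[1]  # [100,200)... isoform
    t = finalize_transcript(a1.junction_chain, gene, exon_set, ann)
    assert t.support is None
    assert t.status == ANNOTATED
    assert [e.region.key for e in t.exons] == [
        e.region.key for e in a1.exons
    ]


def test_walk_minus_strand_gene():
    """A minus-strand gene walks in transcription order (right to left on
    the genome) and anchors terminals symmetrically."""
    t1 = make_transcript(
        "M1", "GM", "c", "-", [(100, 200), (300, 400), (500, 600), (800, 900)]
    )
    t2 = make_transcript(
        "M2", "GM", "c", "-", [(100, 200), (500, 600), (800, 900)]
    )
    ann = AnnotationSet.from_transcripts([t1, t2])
    gene = ann.genes["GM"]
    res = walk(
        gene,
        gene.annotated_junctions,
        list(ann.exons.values()),
        ann,
        WalkConfig(report_annotated=True),
    )
    assert {t.chain_key for t in res.transcripts} == {
        t1.chain_key,
        t2.chain_key,
    }
    starts = {j.key for j in starting_junctions(gene, [])}
    # transcription-first junction of a minus-strand transcript is the
    # genomically rightmost one, shared here
    assert starts == {("c", 600, 800, "-")}


def test_branch_guard_flags_truncation():
    t = make_transcript(
        "T", "G", "c", "+",
        [(i * 200, i * 200 + 100) for i in range(8)],
    )
    ann = AnnotationSet.from_transcripts([t])
    gene = ann.genes["G"]
    # make every exon-skip chain walkable: admit all inter-junction exons
    extra = []
    juncs = gene.annotated_junctions
    for i, j1 in enumerate(juncs):
        for j2 in juncs[i + 1 :]:
            if j1.acceptor < j2.donor:
                extra.append(
                    Exon(
                        GenomeInterval("c", j1.acceptor, j2.donor, "+"),
                        status=NOVEL,
                        read_count=50,
                    )
                )
    novel = [
        jx(s, e, NOVEL, chrom="c", reads=50)
        for s, e in [(110, 380), (310, 580), (510, 780)]
    ]
    exon_set = list(ann.exons.values()) + extra
    res = walk(
        gene,
        juncs + novel,
        exon_set,
        ann,
        WalkConfig(max_transcripts_per_gene=3),
    )
    assert res.truncated
    full = walk(gene, juncs + novel, exon_set, ann, WalkConfig())
    assert not full.truncated
    assert full.n_chains > 3


def test_walk_matches_bruteforce_enumeration():
    """Depth-first walking equals exhaustive subset enumeration of all
    condition-compatible maximal chains on random small genes."""
    checked = 0
    for seed in range(6):
        cfg = simdata.SimConfig(
            n_genes=5,
            seed=400 + seed,
            planted_events=("skip", "insert", "split", "alt_boundary"),
        )
        ann = simdata.make_genes(cfg)
        truth = simdata.plant_events(ann, cfg)
        ev = simdata.exact_evidence(truth, ann, novel_count=60)
        exons = filter_exons_by_support(
            define_exons(truth.novel_junctions, ann), ev, 20
        )
        exon_set = list(ann.exons.values()) + [
            e for e in exons if e.status == NOVEL
        ]
        calls = [
            JunctionCall(j.intron, 60) for j in truth.novel_junctions
        ]
        assigned, _, _ = assign_to_genes(calls, ann)
        for gid in sorted(ann.genes):
            gene = ann.genes[gid]
            junctions = gene.annotated_junctions + assigned.get(gid, [])
            if not junctions or len(junctions) > 12:
                continue
            res = walk(
                gene, junctions, exon_set, ann,
                WalkConfig(report_annotated=True),
            )
            thr = gene_exon_length_threshold(gene)
            expected = enumerate_chains(gene, junctions, exon_set, ann, thr)
            assert set(res.chain_keys) == expected, gid
            checked += 1
    assert checked >= 20


def test_walk_deterministic(fig2_parts):
    ann, gene, novel, exon_set, _ = fig2_parts
    juncs = gene.annotated_junctions + novel
    a = walk(gene, juncs, exon_set, ann)
    b = walk(gene, list(reversed(juncs)), list(reversed(exon_set)), ann)
    assert [t.chain_key for t in a.transcripts] == [
        t.chain_key for t in b.transcripts
    ]


def test_assign_to_genes_rules(figure2):
    ann, _, _ = figure2
    inside = JunctionCall(GenomeInterval("chrF", 560, 600, "+"), 30)
    outside = JunctionCall(GenomeInterval("chrF", 5000, 6000, "+"), 30)
    wrong_strand = JunctionCall(GenomeInterval("chrF", 560, 600, "-"), 30)
    assigned, discarded, ambiguous = assign_to_genes(
        [inside, outside, wrong_strand], ann
    )
    assert [j.key for j in assigned["DEMO1"]] == [("chrF", 560, 600, "+")]
    assert {c.key for c in discarded} == {
        ("chrF", 5000, 6000, "+"),
        ("chrF", 560, 600, "-"),
    }
    assert not ambiguous


def test_unstranded_call_matches_overlapping_genes_on_both_strands():
    plus = make_transcript("P", "GP", "c", "+", [(0, 100), (900, 1000)])
    minus = make_transcript("M", "GM", "c", "-", [(50, 150), (850, 950)])
    ann = AnnotationSet.from_transcripts([plus, minus])
    call = JunctionCall(GenomeInterval("c", 300, 600, "."), 25)
    assigned, _, ambiguous = assign_to_genes([call], ann)
    assert set(assigned) == {"GP", "GM"}
    assert assigned["GP"][0].intron.strand == "+"
    assert assigned["GM"][0].intron.strand == "-"
    assert len(ambiguous) == 1
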