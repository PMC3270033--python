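from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import mask_coverage
from walker.annotation import Exon, GenomeInterval
from walker.errors import ValidationError
from walker.evidence import (
    EvidenceSet,
    JunctionCall,
    classify_junctions,
    evidence_summary,
    exon_support,
    extract_junctions_from_alignments,
    filter_by_support,
    load_junction_bed,
)
from walker.simdata import write_toy_sam


def bed(tmp_path, lines):
    p = tmp_path / "j.bed"
    p.write_text("".join(lines))
    return p


def test_duplicate_calls_merge_by_sum(tmp_path):
    p = bed(
        tmp_path,
        [
            "chr1\t200\t300\tj\t12\t+\n",
            "chr1\t200\t300\tj\t8\t+\n",
        ],
    )
    (call,) = load_junction_bed(p)
    assert call.read_count == 20


def test_zero_read_call_rejected(tmp_path):
    p = bed(tmp_path, ["chr1\t200\t300\tj\t0\t+\n"])
    with pytest.raises(ValidationError):
        load_junction_bed(p)
    with pytest.raises(ValidationError):
        JunctionCall(GenomeInterval("chr1", 200, 300, "+"), 0)


def test_calls_sorted_chrom_major(tmp_path):
    p = bed(
        tmp_path,
        [
            "chr2\t10\t20\tj\t5\t+\n",
            "chr1\t900\t950\tj\t5\t-\n",
            "chr1\t10\t20\tj\t5\t+\n",
        ],
    )
    calls = load_junction_bed(p)
    assert [c.intron.chrom for c in calls] == ["chr1", "chr1", "chr2"]
    assert calls[0].intron.start == 10


def test_inverted_intron_rejected(tmp_path):
    p = bed(tmp_path, ["chr1\t300\t200\tj\t5\t+\n"])
    with pytest.raises(ValidationError):
        load_junction_bed(p)


def test_cigar_junction_extraction(tmp_path):
    """A 20M100N38M read at 1-based position 101 spans the intron
    [120, 220)."""
    sam = tmp_path / "r.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n"
        "r1\t0\tchr1\t101\t60\t20M100N38M\t*\t0\t0\t*\t*\tXS:A:+\n"
        "r2\t0\tchr1\t101\t60\t58M\t*\t0\t0\t*\t*\n"  # no junction
    )
    (call,) = extract_junctions_from_alignments(sam)
    assert call.key == ("chr1", 120, 220, "+")
    assert call.read_count == 1


def test_alignment_extraction_aggregates_reads(tmp_path):
    calls_in = [JunctionCall(GenomeInterval("chr1", 500, 900, "+"), 25)]
    sam = tmp_path / "toy.sam"
    write_toy_sam(calls_in, sam)
    (call,) = extract_junctions_from_alignments(sam)
    assert call.key == ("chr1", 500, 900, "+")
    assert call.read_count == 25


def test_classification_is_exact_match(figure2):
    ann, ev, _ = figure2
    shifted = JunctionCall(GenomeInterval("chrF", 201, 300, "+"), 9)
    exact = JunctionCall(GenomeInterval("chrF", 400, 500, "+"), 9)
    known, novel = classify_junctions(
        list(ev.junction_calls) + [shifted, exact], ann
    )
    assert {c.key for c in known} == {("chrF", 400, 500, "+")}
    assert {c.key[1] for c in novel} == {560, 620, 201}
    assert len(known) + len(novel) == len(ev.junction_calls) + 2


def test_support_filter_boundary_inclusive():
    calls = [
        JunctionCall(GenomeInterval("c", 0, 10, "+"), n)
        for n in (19, 20, 500)
    ]
    kept = filter_by_support(calls, 20)
    assert [c.read_count for c in kept] == [20, 500]
    assert filter_by_support(calls, 1) == calls
    assert filter_by_support([], 20) == []


@given(
    st.lists(st.integers(1, 60), max_size=20),
    st.integers(1, 30),
    st.integers(0, 30),
)
def test_support_filter_idempotent_and_monotone(counts, lo, extra):
    calls = [
        JunctionCall(GenomeInterval("c", i * 100, i * 100 + 50, "+"), n)
        for i, n in enumerate(counts)
    ]
    once = filter_by_support(calls, lo)
    assert filter_by_support(once, lo) == once
    stricter = filter_by_support(calls, lo + extra)
    assert set(c.key for c in stricter) <= set(c.key for c in once)


def test_exon_support_against_mask_oracle(tmp_path):
    """Interval-arithmetic counts/coverage equal per-base painting for the
    documented case: exon [100,200) with one read at [150,208) is hit by
    one read covering half its bases."""
    exon = Exon(GenomeInterval("chr1", 100, 200, "+"))
    sam = tmp_path / "r.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n"
        "r1\t0\tchr1\t151\t60\t58M\t*\t0\t0\t*\t*\n"
    )
    counts, cov = exon_support([exon], alignments=sam)
    assert counts[exon.key] == 1
    assert cov[exon.key] == pytest.approx(0.5)
    n, frac = mask_coverage((100, 200), [[(150, 208)]])
    assert (counts[exon.key], cov[exon.key]) == (n, pytest.approx(frac))


def test_exon_support_randomized_mask_oracle(tmp_path):
    rng = np.random.default_rng(7)
    for trial in range(25):
        estart = int(rng.integers(0, 500))
        elen = int(rng.integers(20, 200))
        exon = Exon(GenomeInterval("chrR", estart, estart + elen, "+"))
        reads = []
        lines = [
            "@HD\tVN:1.6\n@SQ\tSN:chrR\tLN:100000\n",
        ]
        for i in range(int(rng.integers(0, 12))):
            rstart = int(rng.integers(0, 700))
            rlen = int(rng.integers(10, 120))
            reads.append([(rstart, rstart + rlen)])
            lines.append(
                f"q{i}\t0\tchrR\t{rstart + 1}\t60\t{rlen}M\t*\t0\t0\t*\t*\n"
            )
        sam = tmp_path / f"t{trial}.sam"
        sam.write_text("".join(lines))
        counts, cov = exon_support([exon], alignments=sam)
        n, frac = mask_coverage((estart, estart + elen), reads)
        assert counts[exon.key] == n
        assert cov[exon.key] == pytest.approx(frac)


def test_exon_support_defaults():
    exon = Exon(GenomeInterval("chr1", 0, 100, "+"))
    counts, cov = exon_support([exon])
    assert counts[exon.key] == 0 and cov[exon.key] == 0.0
    ev = EvidenceSet()
    assert ev.exon_count(exon) == 0 and ev.exon_cov(exon) == 0.0


def test_read_containing_exon_gives_full_coverage(tmp_path):
    exon = Exon(GenomeInterval("chr1", 100, 150, "+"))
    sam = tmp_path / "r.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n"
        "r1\t0\tchr1\t91\t60\t100M\t*\t0\t0\t*\t*\n"
    )
    counts, cov = exon_support([exon], alignments=sam)
    assert counts[exon.key] == 1 and cov[exon.key] == 1.0


def test_summary_bins_match_table_rows():
    calls = [
        JunctionCall(GenomeInterval("c", i * 10, i * 10 + 5, "+"), n)
        for i, n in enumerate((1, 3, 20, 600))
    ]
    ev = EvidenceSet(
        calls,
        exon_counts={("c", 0, 5, "+"): 0, ("c", 10, 15, "+"): 7},
        exon_coverage={},
    )
    df = evidence_summary(ev).set_index("reads")
    assert df.loc["1", "junctions"] == 1
    assert df.loc["2-4", "junctions"] == 1
    assert df.loc["20-49", "junctions"] == 1
    assert df.loc["500+", "junctions"] == 1
    assert df.loc["0", "exons"] == 1  # the 0 bin exists only for exons
    assert df.loc["5-9", "exons"] == 1
    assert df["junctions"].sum() == len(calls)


def test_summary_empty_evidence_all_zero():
    df = evidence_summary(EvidenceSet())
    assert (df[["junctions", "exons"]].to_numpy() == 0).all()
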