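"""Fusion calling: SA parsing, gene assignment, UMI filtering, species FPR."""

import numpy as np
import pysam
import pytest

from dimerseq import (
    FusionEvent,
    GeneModel,
    Locus,
    call_fusions,
    expand,
    filter_events,
    parse_sa_tag,
    scan_chimeras,
    species_mixing_fpr,
)
from dimerseq.fusion import aggregate_events, assign_fusion, ChimericAlignment

from conftest import make_sam

CELL = "ACGTACGTACGT"


def _umi(i: int) -> str:
    mono = ["AAAAAAAA", "CCCCCCCC", "GGGGGGGG", "TTTTTTTT", "ACGTACGT", "TGCATGCA", "AACCGGTT"]
    return expand(mono[i]).seq


def test_parse_sa_tag_coordinates():
    loci = parse_sa_tag("chr1,100,+,50M,60,0;chr2,200,-,10S40M2D,30,1;")
    assert loci[0] == Locus("chr1", 99, 149, "+")
    assert loci[1] == Locus("chr2", 199, 241, "-")  # 40M + 2D consume reference


def _toy_sam(tmp_path, records):
    return make_sam(tmp_path / "toy.sam", [("chrA", 50000), ("chrB", 50000)], records)


def test_scan_chimeras_flag_mask(tmp_path):
    sam = _toy_sam(
        tmp_path,
        [
            {"qname": f"r1_{CELL}_{_umi(0)}", "flag": 0, "ref": "chrA", "pos": 100,
             "cigar": "100M", "tags": {"SA": "chrB,201,+,100M,60,0;"}},
            {"qname": f"r2_{CELL}_{_umi(1)}", "flag": 2048, "ref": "chrA", "pos": 100,
             "cigar": "100M", "tags": {"SA": "chrB,201,+,100M,60,0;"}},
            {"qname": f"r3_{CELL}_{_umi(2)}", "flag": 256, "ref": "chrA", "pos": 100,
             "cigar": "100M", "tags": {"SA": "chrB,201,+,100M,60,0;"}},
            {"qname": f"r4_{CELL}_{_umi(3)}", "flag": 0, "ref": "chrA", "pos": 100,
             "cigar": "100M"},  # no SA tag: not chimeric
            {"qname": "nobarcode", "flag": 0, "ref": "chrA", "pos": 100,
             "cigar": "100M", "tags": {"SA": "chrB,201,+,100M,60,0;"}},
        ],
    )
    from collections import Counter

    counters = Counter()
    with pysam.AlignmentFile(str(sam)) as fh:
        got = list(scan_chimeras(fh, counters=counters))
    assert [c.read_id for c in got] == ["r1"]
    assert counters["masked"] == 2
    assert counters["missing_cell_umi"] == 1
    assert got[0].primary_locus == Locus("chrA", 100, 200, "+")
    assert got[0].supplementary_loci == [Locus("chrB", 200, 300, "+")]


@pytest.fixture
def genes():
    return GeneModel(
        [
            ("chrA", 1000, 6000, "geneE", "+"),
            ("chrA", 8000, 15000, "geneF", "+"),
            ("chrB", 0, 10000, "geneM", "+"),
        ]
    )


def test_assign_fusion_pairs(genes):
    def chim(primary, supp):
        return ChimericAlignment("r", CELL, _umi(0), primary, [supp])

    both = chim(Locus("chrA", 1500, 2000), Locus("chrA", 8500, 9000))
    assert assign_fusion(both, genes) == [("geneE", "geneF")]

    same = chim(Locus("chrA", 1500, 2000), Locus("chrA", 3000, 3500))
    assert assign_fusion(same, genes) == []  # exonic chimera: removed

    intergenic = chim(Locus("chrA", 1500, 2000), Locus("chrA", 20000, 20500))
    assert assign_fusion(intergenic, genes) == []


def test_gene_assignment_maximal_overlap_and_ties():
    gm = GeneModel(
        [("chr1", 0, 1000, "g1", "+"), ("chr1", 500, 2000, "g2", "+")]
    )
    assert gm.assign(Locus("chr1", 0, 400)) == "g1"
    assert gm.assign(Locus("chr1", 1200, 1400)) == "g2"
    assert gm.assign(Locus("chr1", 5000, 5100)) is None
    # 500-1000 overlaps both genes by 500: ambiguous
    assert gm.assign(Locus("chr1", 500, 1000)) is None


def test_gene_assignment_matches_naive_scan(rng):
    intervals = []
    for i in range(60):
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        start = int(rng.integers(0, 100_000))
        end = start + int(rng.integers(100, 5000))
        intervals.append((chrom, start, end, f"g{i}", "+"))
    gm = GeneModel(intervals)
    for _ in range(300):
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        start = int(rng.integers(0, 105_000))
        locus = Locus(chrom, start, start + int(rng.integers(50, 3000)))
        best, best_ov, tied = None, 0, False
        for c, s, e, g, _ in intervals:
            if c != chrom:
                continue
            ov = min(e, locus.end) - max(s, locus.start)
            if ov > best_ov:
                best, best_ov, tied = g, ov, False
            elif ov == best_ov and best_ov > 0 and g != best:
                tied = True
        expected = None if tied else best
        assert gm.assign(locus) == expected


def test_filter_events_boundary():
    def ev(n):
        return FusionEvent("a", "b", cells={"c": n}, n_umis=n)

    assert filter_events([ev(4)], min_umis=5) == []
    assert len(filter_events([ev(5)], min_umis=5)) == 1
    # monotone: raising the threshold never adds events
    events = [ev(n) for n in range(1, 10)]
    sizes = [len(filter_events(events, min_umis=k)) for k in range(1, 10)]
    assert sizes == sorted(sizes, reverse=True)


def test_reads_sharing_one_umi_count_once(genes):
    chims = [
        ChimericAlignment(f"r{i}", CELL, _umi(0), Locus("chrA", 1500, 2000), [Locus("chrA", 8500, 9000)])
        for i in range(7)
    ]
    events = aggregate_events(chims, genes)
    assert len(events) == 1 and events[0].n_umis == 1
    assert filter_events(events, min_umis=5) == []


def test_planted_breakpoint_yields_single_event(tmp_path, genes):
    # 5' piece of geneE joined to the 3' end of geneF, 5 molecules, PCR copies
    records = []
    for i in range(5):
        for copy in range(3):
            records.append(
                {
                    "qname": f"r{i}c{copy}_{CELL}_{_umi(i)}",
                    "flag": 0,
                    "ref": "chrA",
                    "pos": 1200,
                    "cigar": "400M400S",
                    "tags": {"SA": "chrA,8501,+,400S400M,60,0;"},
                }
            )
    # decoys that must not produce events
    records.append(
        {"qname": f"x0_{CELL}_{_umi(5)}", "flag": 0, "ref": "chrA", "pos": 1200,
         "cigar": "400M", "tags": {}}
    )
    records.append(
        {"qname": f"x1_{CELL}_{_umi(6)}", "flag": 2048, "ref": "chrA", "pos": 8500,
         "cigar": "400M400S", "tags": {"SA": "chrA,1201,+,400S400M,60,0;"}}
    )
    sam = _toy_sam(tmp_path, records)
    with pysam.AlignmentFile(str(sam)) as fh:
        events, counters = call_fusions(fh, genes, min_umis=5)
    assert len(events) == 1
    ev = events[0]
    assert ev.key == ("geneE", "geneF")
    assert ev.n_umis == 5
    assert ev.cells == {CELL: 5}
    assert counters["chimeric"] == 15


def test_event_aggregation_invariant_to_read_order(genes, rng):
    chims = [
        ChimericAlignment(f"r{i}", CELL, _umi(i % 5), Locus("chrA", 1500, 2000), [Locus("chrA", 8500, 9000)])
        for i in range(10)
    ]
    a = aggregate_events(chims, genes)
    shuffled = chims[:]
    rng.shuffle(shuffled)
    b = aggregate_events(shuffled, genes)
    assert [(e.key, e.n_umis, e.cells) for e in a] == [(e.key, e.n_umis, e.cells) for e in b]


def test_species_mixing_toy_fractions():
    species = {"hA": "human", "hB": "human", "mA": "mouse", "mB": "mouse"}
    events = [
        FusionEvent("hA", "hB", cells={"c1": 6}, n_umis=6),
        FusionEvent("hA", "mA", cells={"c1": 2}, n_umis=2),
        FusionEvent("hB", "mB", cells={"c2": 3}, n_umis=3),
        FusionEvent("mA", "mB", cells={"c2": 7}, n_umis=7),
    ]
    rep = species_mixing_fpr(events, species, n_total_reads=400, n_chimeric_reads=20)
    assert rep.fusion_read_fraction == pytest.approx(0.05)
    assert rep.mixed_fraction == pytest.approx(0.5)
    # every cross-species event sits below the 5-UMI threshold
    assert rep.mixed_fraction_after_filter == 0.0

    pure = species_mixing_fpr(events[:1], species, 100, 10)
    assert pure.mixed_fraction == 0.0
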