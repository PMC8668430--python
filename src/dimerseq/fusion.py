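"""Fusion-transcript detection from chimeric long-read alignments.

A chimeric read aligns in pieces to distant loci; the aligner records the
extra pieces in the SA (supplementary alignment) tag of the primary
record.  Fusion candidates are primary records whose SA loci fall in a
*different* gene than the primary locus (same-gene chimeras are presumed
exonic artifacts and discarded).  Candidates are aggregated per unordered
gene pair, UMIs are deduplicated per cell, and events supported by fewer
than ``min_umis`` unique molecules are removed — the threshold calibrated
on a mixed-species control, where any human-mouse fusion is by
construction a false positive.

Input records must carry the cell barcode and UMI in the read name
(``readid_BARCODE_UMI``, as written by the extraction step).
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

from .dedup import count_unique_umis, directional_dedup

__all__ = [
    "GeneModel",
    "Locus",
    "ChimericAlignment",
    "FusionEvent",
    "SpeciesMixingReport",
    "DEFAULT_FLAG_MASK",
    "parse_sa_tag",
    "scan_chimeras",
    "assign_fusion",
    "aggregate_events",
    "filter_events",
    "call_fusions",
    "species_mixing_fpr",
]

logger = logging.getLogger(__name__)

# secondary (256) + duplicate (1024) + supplementary (2048)
DEFAULT_FLAG_MASK = 3328

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


@dataclass(frozen=True)
class Locus:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"


def _cigar_reference_span(cigar: str) -> int:
    span = 0
    for n, op in _CIGAR_RE.findall(cigar):
        if op in _REF_CONSUMING:
            span += int(n)
    return span


def parse_sa_tag(sa: str) -> list[Locus]:
    """Parse ``SA:Z:(rname,pos,strand,CIGAR,mapQ,NM;)+`` into loci.

    SAM positions are 1-based; returned loci are 0-based half-open, with
    the end computed from the reference span of the CIGAR.
    """
    loci = []
    for part in sa.rstrip(";").split(";"):
        if not part:
            continue
        rname, pos, strand, cigar, _mapq, _nm = part.split(",")
        start = int(pos) - 1
        loci.append(Locus(rname, start, start + _cigar_reference_span(cigar), strand))
    return loci


class GeneModel:
    """Gene intervals from a BED file, indexed for overlap queries.

    Accepts BED6 or BED12 (only the first six columns are used);
    coordinates are taken as 0-based half-open, the BED convention.
    Overlapping genes are permitted; assignment is by maximal overlap with
    ties treated as ambiguous.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, str, str]]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.genes: dict[str, Locus] = {}
        for chrom, start, end, gene_id, strand in intervals:
            if end <= start:
                raise ValueError(f"empty interval for {gene_id}: {chrom}:{start}-{end}")
            self._trees[chrom].addi(start, end, gene_id)
            self.genes[gene_id] = Locus(chrom, start, end, strand)

    @classmethod
    def from_bed(cls, path) -> "GeneModel":
        intervals = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                strand = f[5] if len(f) > 5 else "+"
                intervals.append((f[0], int(f[1]), int(f[2]), name, strand))
        return cls(intervals)

    def assign(self, locus: Locus) -> str | None:
        """Gene with maximal overlap, or None (no hit / ambiguous tie)."""
        tree = self._trees.get(locus.chrom)
        if tree is None:
            return None
        best_gene = None
        best_ov = 0
        tied = False
        for iv in tree.overlap(locus.start, locus.end):
            ov = min(iv.end, locus.end) - max(iv.begin, locus.start)
            if ov > best_ov:
                best_ov, best_gene, tied = ov, iv.data, False
            elif ov == best_ov and best_ov > 0 and iv.data != best_gene:
                tied = True
        return None if tied else best_gene


@dataclass
class ChimericAlignment:
    read_id: str
    cell: str
    umi: str
    primary_locus: Locus
    supplementary_loci: list[Locus]


def _split_name(qname: str) -> tuple[str, str, str] | None:
    parts = qname.split("_")
    if len(parts) < 3:
        return None
    return "_".join(parts[:-2]), parts[-2], parts[-1]


def scan_chimeras(
    alignments: Iterable,
    flag_mask: int = DEFAULT_FLAG_MASK,
    counters: Counter | None = None,
) -> Iterator[ChimericAlignment]:
    """Yield primary alignments carrying an SA tag.

    ``alignments`` is any iterable of pysam ``AlignedSegment`` (an opened
    ``AlignmentFile`` works).  Records matching ``flag_mask`` (default
    3328: secondary + duplicate + supplementary) are filtered out; records
    without a recoverable cell/UMI in the read name are skipped and
    counted.
    """
    counters = counters if counters is not None else Counter()
    for rec in alignments:
        counters["total"] += 1
        if rec.flag & flag_mask:
            counters["masked"] += 1
            continue
        if rec.is_unmapped:
            counters["unmapped"] += 1
            continue
        if not rec.has_tag("SA"):
            continue
        counters["chimeric"] += 1
        name = _split_name(rec.query_name)
        if name is None:
            counters["missing_cell_umi"] += 1
            continue
        read_id, cell, umi = name
        primary = Locus(
            rec.reference_name,
            rec.reference_start,
            rec.reference_end,
            "-" if rec.is_reverse else "+",
        )
        yield ChimericAlignment(
            read_id=read_id,
            cell=cell,
            umi=umi,
            primary_locus=primary,
            supplementary_loci=parse_sa_tag(rec.get_tag("SA")),
        )


@dataclass
class FusionEvent:
    """An unordered gene pair with its per-cell molecular support."""

    gene_a: str
    gene_b: str
    cells: dict[str, int] = field(default_factory=dict)  # cell -> unique UMIs
    n_umis: int = 0
    n_reads: int = 0

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))  # type: ignore[return-value]


def assign_fusion(
    chimera: ChimericAlignment,
    genes: GeneModel,
    all_pairs: bool = False,
) -> list[tuple[str, str]]:
    """Gene pairs supported by one chimeric read (read-coordinate order).

    By default only the first supplementary locus is paired with the
    primary; ``all_pairs`` emits every pairwise combination of distinctly
    assigned loci.  Same-gene and unassignable loci produce no candidate.
    """
    loci = [chimera.primary_locus] + (
        chimera.supplementary_loci if all_pairs else chimera.supplementary_loci[:1]
    )
    assigned = [(loc, genes.assign(loc)) for loc in loci]
    pairs = []
    for i in range(len(assigned)):
        for j in range(i + 1, len(assigned)):
            ga, gb = assigned[i][1], assigned[j][1]
            if ga is None or gb is None or ga == gb:
                continue
            pairs.append((ga, gb))
    return pairs


def aggregate_events(
    chimeras: Iterable[ChimericAlignment],
    genes: GeneModel,
    all_pairs: bool = False,
) -> list[FusionEvent]:
    """Group chimeric reads into candidate events by unordered gene pair.

    Per-cell UMIs are deduplicated (dimer 16-mers through split-and-
    collapse + directional; already-collapsed UMIs directly through the
    directional method); ``n_umis`` is the total unique-molecule support
    across cells.
    """
    support: dict[tuple[str, str], dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
    order: dict[tuple[str, str], tuple[str, str]] = {}
    reads: Counter = Counter()
    for ch in chimeras:
        for ga, gb in assign_fusion(ch, genes, all_pairs=all_pairs):
            key = tuple(sorted((ga, gb)))
            order.setdefault(key, (ga, gb))
            support[key][ch.cell].append(ch.umi)
            reads[key] += 1

    events = []
    for key in sorted(support):
        ga, gb = order[key]
        cells = {}
        for cell in sorted(support[key]):
            umis = support[key][cell]
            if umis and len(umis[0]) % 2 == 0 and len(umis[0]) >= 16:
                n = count_unique_umis(umis)
            else:
                n = directional_dedup(Counter(umis)).unique_count
            cells[cell] = n
        events.append(
            FusionEvent(
                gene_a=ga,
                gene_b=gb,
                cells=cells,
                n_umis=sum(cells.values()),
                n_reads=reads[key],
            )
        )
    return events


def filter_events(events: Iterable[FusionEvent], min_umis: int = 5) -> list[FusionEvent]:
    """Keep events supported by at least ``min_umis`` unique molecules."""
    return [e for e in events if e.n_umis >= min_umis]


def call_fusions(
    alignments: Iterable,
    genes: GeneModel,
    min_umis: int = 5,
    flag_mask: int = DEFAULT_FLAG_MASK,
    all_pairs: bool = False,
) -> tuple[list[FusionEvent], Counter]:
    """End-to-end fusion calling: scan, assign, aggregate, filter."""
    counters: Counter = Counter()
    chimeras = scan_chimeras(alignments, flag_mask=flag_mask, counters=counters)
    events = aggregate_events(chimeras, genes, all_pairs=all_pairs)
    counters["candidate_events"] = len(events)
    kept = filter_events(events, min_umis=min_umis)
    counters["events_after_filter"] = len(kept)
    return kept, counters


@dataclass
class SpeciesMixingReport:
    fusion_read_fraction: float
    mixed_fraction: float
    mixed_fraction_after_filter: float
    n_events: int
    n_mixed: int


def species_mixing_fpr(
    events: Sequence[FusionEvent],
    species_of_gene: dict[str, str],
    n_total_reads: int,
    n_chimeric_reads: int,
    min_umis: int = 5,
) -> SpeciesMixingReport:
    """False-positive calibration on a mixed-species control.

    ``mixed_fraction`` is the share of candidate events joining genes of
    different species — biologically impossible, hence artifacts — before
    and after the ``min_umis`` filter.  Events with an unlabelled gene are
    excluded with a warning.
    """
    def classify(evs: Sequence[FusionEvent]) -> tuple[int, int]:
        n = mixed = 0
        for e in evs:
            sa = species_of_gene.get(e.gene_a)
            sb = species_of_gene.get(e.gene_b)
            if sa is None or sb is None:
                logger.warning("event %s-%s has unlabelled gene; excluded", e.gene_a, e.gene_b)
                continue
            n += 1
            if sa != sb:
                mixed += 1
        return n, mixed

    n_events, n_mixed = classify(events)
    kept = filter_events(events, min_umis=min_umis)
    n_kept, n_kept_mixed = classify(kept)
    return SpeciesMixingReport(
        fusion_read_fraction=n_chimeric_reads / n_total_reads if n_total_reads else 0.0,
        mixed_fraction=n_mixed / n_events if n_events else 0.0,
        mixed_fraction_after_filter=n_kept_mixed / n_kept if n_kept else 0.0,
        n_events=n_events,
        n_mixed=n_mixed,
    )
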