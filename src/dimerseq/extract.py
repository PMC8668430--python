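"""Parse raw long reads into barcode, UMI and cDNA segments.

A capture read carries, 5' to 3': the PCR handle, a 24-nt dimer barcode,
a 16-nt dimer UMI, a poly(T) tract and the cDNA.  Nanopore reads come in
both orientations, so extraction tries the read as given and then its
reverse complement.  The handle is located by approximate (bounded edit
distance) substring match; the poly(T) tract anchors the segment
boundaries on the 3' side.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import edlib
import pysam

__all__ = [
    "ReadLayout",
    "ReadStructure",
    "reverse_complement",
    "find_polyA",
    "extract_structure",
    "polyA_detection_rate",
    "extract_fastq",
    "ExtractStats",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadLayout:
    """Geometry and search tolerances of the capture read."""

    handle: str = "AAGCAGTGGTATCAACGCAGAGTAC"
    barcode_len: int = 24
    umi_len: int = 16
    polyT_min_len: int = 15
    handle_max_edits: int = 3
    polyA_mismatch_per_10: int = 1

    def __post_init__(self) -> None:
        if self.barcode_len % 2 or self.umi_len % 2:
            raise ValueError("barcode_len and umi_len must be even (dimer blocks)")


@dataclass
class ReadStructure:
    """One parsed read; ``parse_ok`` is False when any landmark is missing."""

    read_id: str
    orientation: str = "forward"  # "forward" | "reverse-complement"
    barcode_seq: str | None = None
    umi_seq: str | None = None
    cdna_seq: str | None = None
    parse_ok: bool = False
    fail_reason: str | None = None  # "no_polyA" | "no_handle" | "truncated"
    handle_edits: int | None = None


def find_polyA(
    seq: str,
    min_len: int = 15,
    base: str = "A",
    mismatch_per_10: int = 1,
) -> Optional[int]:
    """Locate the start of the first poly(A)-like run.

    A window of ``min_len`` characters qualifies when it begins and ends
    with ``base`` and contains at most ``mismatch_per_10 * (min_len // 10)``
    interior mismatches.  Requiring matching endpoints keeps a shorter run
    plus an adjacent foreign base (e.g. 14 A's next to a G) from passing a
    15-base threshold on the mismatch budget alone.  Returns the 0-based
    window start, or None.
    """
    n = len(seq)
    if n < min_len or not seq:
        return None
    allowed = mismatch_per_10 * (min_len // 10)
    is_base = [c == base for c in seq]
    # prefix sums of mismatches
    pref = [0]
    for b in is_base:
        pref.append(pref[-1] + (0 if b else 1))
    for start in range(0, n - min_len + 1):
        end = start + min_len
        if not (is_base[start] and is_base[end - 1]):
            continue
        if pref[end] - pref[start] <= allowed:
            return start
    return None


def _polyT_end(seq: str, start: int) -> int:
    """End (exclusive) of the poly(T) run starting at ``start``.

    Extends greedily through T's, tolerating isolated single mismatches
    flanked by T on both sides.
    """
    i = start
    n = len(seq)
    while i < n:
        if seq[i] == "T":
            i += 1
        elif i + 1 < n and seq[i + 1] == "T" and i > start:
            i += 2
        else:
            break
    return i


def _locate_handle(seq: str, layout: ReadLayout) -> Optional[tuple[int, int]]:
    """(end position, edits) of the best approximate handle match."""
    res = edlib.align(layout.handle, seq, mode="HW", task="locations", k=layout.handle_max_edits)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    # edlib returns inclusive end coordinates; take the earliest match
    end = min(loc[1] for loc in res["locations"] if loc[1] is not None) + 1
    return end, res["editDistance"]


def _try_orientation(read_id: str, seq: str, layout: ReadLayout, orientation: str) -> ReadStructure:
    out = ReadStructure(read_id=read_id, orientation=orientation)
    hit = _locate_handle(seq, layout)
    if hit is None:
        out.fail_reason = "no_handle"
        return out
    end, edits = hit
    out.handle_edits = edits
    bc_end = end + layout.barcode_len
    umi_end = bc_end + layout.umi_len
    if umi_end + layout.polyT_min_len > len(seq):
        out.fail_reason = "truncated"
        return out
    tail = seq[umi_end:]
    t_start = find_polyA(
        tail,
        min_len=layout.polyT_min_len,
        base="T",
        mismatch_per_10=layout.polyA_mismatch_per_10,
    )
    # the tract must sit right after the UMI (small slack for indels)
    if t_start is None or t_start > 6:
        out.fail_reason = "no_polyA"
        return out
    t_end = _polyT_end(tail, t_start)
    out.barcode_seq = seq[end:bc_end]
    out.umi_seq = seq[bc_end:umi_end]
    out.cdna_seq = tail[t_end:]
    out.parse_ok = True
    out.fail_reason = None
    return out


def extract_structure(read_id: str, seq: str, layout: ReadLayout | None = None) -> ReadStructure:
    """Parse one read, trying forward then reverse-complement orientation.

    When both orientations parse, the one with fewer handle edits wins;
    an exact tie keeps forward.  Never raises on malformed reads — the
    result carries ``parse_ok=False`` and a failure reason instead.
    """
    layout = layout or ReadLayout()
    seq = seq.upper()
    fwd = _try_orientation(read_id, seq, layout, "forward")
    rev = _try_orientation(read_id, reverse_complement(seq), layout, "reverse-complement")
    if fwd.parse_ok and rev.parse_ok:
        return rev if rev.handle_edits < fwd.handle_edits else fwd
    if fwd.parse_ok:
        return fwd
    if rev.parse_ok:
        return rev
    # prefer the more informative failure: handle found but no poly(A)/truncated
    order = {"truncated": 0, "no_polyA": 1, "no_handle": 2}
    return min((fwd, rev), key=lambda r: order[r.fail_reason])


def polyA_detection_rate(
    seqs: Iterable[str],
    min_len: int = 15,
    mismatch_per_10: int = 1,
) -> float:
    """Fraction of reads with a poly(A)/poly(T) tract in either orientation.

    Searching one strand for both an A-run and a T-run is equivalent to
    searching both orientations for a poly(A).
    """
    n = 0
    hits = 0
    for s in seqs:
        s = s.upper()
        n += 1
        if (
            find_polyA(s, min_len=min_len, base="A", mismatch_per_10=mismatch_per_10) is not None
            or find_polyA(s, min_len=min_len, base="T", mismatch_per_10=mismatch_per_10) is not None
        ):
            hits += 1
    if n == 0:
        raise ValueError("polyA_detection_rate requires a non-empty read set")
    return hits / n


@dataclass
class ExtractStats:
    n_reads: int = 0
    n_parsed: int = 0
    fail_counts: dict = field(default_factory=dict)

    @property
    def parse_rate(self) -> float:
        return self.n_parsed / self.n_reads if self.n_reads else 0.0


def iter_structures(fastq_path, layout: ReadLayout | None = None) -> Iterator[ReadStructure]:
    layout = layout or ReadLayout()
    with pysam.FastxFile(str(fastq_path)) as fh:
        for entry in fh:
            yield extract_structure(entry.name, entry.sequence, layout)


def extract_fastq(
    in_path,
    out_path,
    rejected_path=None,
    layout: ReadLayout | None = None,
) -> tuple[list[ReadStructure], ExtractStats]:
    """Extract barcode/UMI into read headers, UMI-tools style.

    Writes parsed reads as ``@{read_id}_{barcode}_{umi}`` with the cDNA as
    the sequence, and optionally a rejected-reads log (read id + failure
    reason).  Returns the parsed structures and summary stats.
    """
    from .io import open_text_writer

    layout = layout or ReadLayout()
    stats = ExtractStats()
    structures: list[ReadStructure] = []
    rej = open(rejected_path, "w") if rejected_path else None
    try:
        with open_text_writer(out_path) as out:
            for s in iter_structures(in_path, layout):
                stats.n_reads += 1
                if s.parse_ok:
                    stats.n_parsed += 1
                    structures.append(s)
                    cdna = s.cdna_seq or "N"
                    out.write(
                        f"@{s.read_id}_{s.barcode_seq}_{s.umi_seq}\n{cdna}\n+\n{'I' * len(cdna)}\n"
                    )
                else:
                    stats.fail_counts[s.fail_reason] = stats.fail_counts.get(s.fail_reason, 0) + 1
                    if rej is not None:
                        rej.write(f"{s.read_id}\t{s.fail_reason}\n")
    finally:
        if rej is not None:
            rej.close()
    return structures, stats
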