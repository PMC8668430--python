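"""Two-pass cell-barcode assignment.

Pass one builds a whitelist from reads whose barcode shows perfect
homodimer complementarity — these need no reference to be trusted.  Pass
two rescues the remaining reads by bounded Levenshtein matching of the raw
24-nt dimer barcode against the whitelist representatives.  Matching works
in dimer space, not on the collapsed 12-mers: the block redundancy is the
signal, and the edit distances explored for long reads (4-7) are
meaningful only against the 24-mer.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

from .dimer import DimerSequence, collapse, diagnose_blocks

__all__ = [
    "Whitelist",
    "CorrectionResult",
    "AssignmentSummary",
    "levenshtein",
    "build_whitelist",
    "correct_barcode",
    "assign_all",
]

logger = logging.getLogger(__name__)


def levenshtein(a: str, b: str, k: int | None = None) -> int | None:
    """Levenshtein distance via edlib; ``None`` if it exceeds ``k``."""
    res = edlib.align(a, b, mode="NW", task="distance", k=-1 if k is None else k)
    d = res["editDistance"]
    return None if d < 0 else d


@dataclass
class Whitelist:
    """Ranked set of trusted (error-free) barcodes.

    ``entries`` maps the collapsed 12-mer barcode to its dimer 24-mer
    representative and total perfect-read count.
    """

    entries: dict[str, tuple[str, int]]
    expected_cells: int = 1000

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, collapsed: str) -> bool:
        return collapsed in self.entries

    @property
    def representatives(self) -> list[str]:
        return [rep for rep, _ in self.entries.values()]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("barcode\trepresentative\tcount\n")
            for bc, (rep, n) in sorted(
                self.entries.items(), key=lambda kv: (-kv[1][1], kv[0])
            ):
                fh.write(f"{bc}\t{rep}\t{n}\n")

    @classmethod
    def from_tsv(cls, path, expected_cells: int = 1000) -> "Whitelist":
        entries: dict[str, tuple[str, int]] = {}
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("barcode")
            for line in fh:
                bc, rep, n = line.rstrip("\n").split("\t")
                entries[bc] = (rep, int(n))
        return cls(entries=entries, expected_cells=expected_cells)


@dataclass(frozen=True)
class CorrectionResult:
    read_id: str
    status: str  # "perfect" | "corrected" | "unassigned"
    assigned_barcode: str | None
    edit_distance_used: int | None


@dataclass
class AssignmentSummary:
    n_reads: int
    fraction_perfect: float
    fraction_corrected: float
    fraction_unassigned: float


def _barcode_of(item) -> str:
    """Accept raw strings, DimerSequence, or parsed read structures."""
    bc = getattr(item, "barcode_seq", item)
    return str(bc)


def build_whitelist(
    barcodes: Iterable, expected_cells: int = 1000
) -> Whitelist:
    """Rank perfect-complementarity barcodes and keep the top cells.

    Candidates are reads whose 12 barcode blocks are all valid; entries
    collapsing to the same 12-mer are merged with counts summed.  Keeps
    the ``expected_cells`` most abundant (warns and keeps all if fewer
    perfect barcodes exist).
    """
    counts: Counter[str] = Counter()
    for item in barcodes:
        bc = _barcode_of(item)
        if diagnose_blocks(bc).all_valid:
            counts[collapse(bc)] += 1
    if not counts:
        logger.warning("no perfect-complementarity barcodes found; whitelist is empty")
        return Whitelist(entries={}, expected_cells=expected_cells)
    if len(counts) < expected_cells:
        logger.warning(
            "only %d perfect barcodes for %d expected cells; keeping all",
            len(counts),
            expected_cells,
        )
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:expected_cells]
    entries = {bc: ("".join(c + c for c in bc), n) for bc, n in ranked}
    return Whitelist(entries=entries, expected_cells=expected_cells)


def correct_barcode(
    observed: "DimerSequence | str", wl: Whitelist, max_edit: int = 6
) -> CorrectionResult:
    """Assign one observed 24-mer to the whitelist.

    Perfect if it collapses cleanly onto a whitelist entry; otherwise the
    unique nearest representative within ``max_edit`` Levenshtein edits
    wins.  A tie at the minimal distance, or no representative within
    range, leaves the read unassigned (conservative: aggressive ties
    inflate cross-species contamination).
    """
    if not wl.entries:
        raise ValueError("whitelist is empty")
    obs = str(observed)
    diag = diagnose_blocks(obs)
    if diag.all_valid:
        c = collapse(obs)
        if c in wl:
            return CorrectionResult("", "perfect", c, 0)

    best_d: int | None = None
    best_bc: str | None = None
    tied = False
    for bc, (rep, _) in wl.entries.items():
        d = levenshtein(obs, rep, k=max_edit)
        if d is None:
            continue
        if best_d is None or d < best_d:
            best_d, best_bc, tied = d, bc, False
        elif d == best_d:
            tied = True
    if best_d is None or tied:
        return CorrectionResult("", "unassigned", None, None)
    return CorrectionResult("", "corrected", best_bc, best_d)


def assign_all(
    items: Iterable, wl: Whitelist, max_edit: int = 6
) -> tuple[list[CorrectionResult], AssignmentSummary]:
    """Apply :func:`correct_barcode` to every read.

    Results for identical observed barcodes are cached, which makes the
    perfect-read majority essentially free.
    """
    cache: dict[str, CorrectionResult] = {}
    results: list[CorrectionResult] = []
    tallies = Counter()
    for item in items:
        read_id = getattr(item, "read_id", "")
        bc = _barcode_of(item)
        hit = cache.get(bc)
        if hit is None:
            hit = correct_barcode(bc, wl, max_edit=max_edit)
            cache[bc] = hit
        res = CorrectionResult(read_id, hit.status, hit.assigned_barcode, hit.edit_distance_used)
        results.append(res)
        tallies[hit.status] += 1
    n = len(results)
    if n == 0:
        raise ValueError("no reads to assign")
    summary = AssignmentSummary(
        n_reads=n,
        fraction_perfect=tallies["perfect"] / n,
        fraction_corrected=tallies["corrected"] / n,
        fraction_unassigned=tallies["unassigned"] / n,
    )
    return results, summary
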