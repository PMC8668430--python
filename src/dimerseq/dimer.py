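"""The homodimer error-detecting code.

Cell barcodes and UMIs are synthesized from dimeric nucleotide building
blocks, so every correctly sequenced barcode position appears as two
identical consecutive bases (``AA``, ``CC``, ``GG`` or ``TT``).  A block
whose two bases disagree flags a sequencing error at that position, which
is what makes the code error-*detecting*: validity can be checked read by
read without any reference whitelist.

This module implements block diagnosis, the collapse/expand maps between
dimer space (length ``2k``) and monomer space (length ``k``), and the two
base-calling-accuracy estimators built on top of block validity:

* theoretical accuracy ``b ** (1/l)``, where ``b`` is the fraction of
  reads whose every block is valid and ``l`` is the barcode length in
  nucleotides;
* measured accuracy, ``1 - erroneous_bases / total_bases``, where each
  invalid block contributes a configurable number of erroneous bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "DimerSequence",
    "BlockDiagnosis",
    "AccuracyEstimate",
    "diagnose_blocks",
    "collapse",
    "expand",
    "theoretical_accuracy",
    "measured_accuracy",
]

_ALPHABET = frozenset("ACGTN")
_BASES = "ACGT"


@dataclass(frozen=True)
class DimerSequence:
    """An even-length nucleotide string interpreted as homodimer blocks.

    Block ``i`` is the base pair ``seq[2*i : 2*i + 2]``.  Both barcodes
    (12 blocks / 24 nt) and UMIs (8 blocks / 16 nt) use this type; the
    block count is whatever the sequence length implies.
    """

    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty sequence")
        if len(self.seq) % 2 != 0:
            raise ValueError(
                f"dimer sequence length must be even, got {len(self.seq)}"
            )
        if not _ALPHABET.issuperset(self.seq):
            bad = sorted(set(self.seq) - _ALPHABET)
            raise ValueError(f"alphabet restricted to A/C/G/T/N, found {bad}")

    @property
    def block_count(self) -> int:
        return len(self.seq) // 2

    def block(self, i: int) -> str:
        return self.seq[2 * i : 2 * i + 2]

    def __len__(self) -> int:
        return len(self.seq)

    def __str__(self) -> str:
        return self.seq


@dataclass(frozen=True)
class BlockDiagnosis:
    """Per-block validity of a dimer sequence."""

    valid_blocks: tuple[bool, ...]
    mismatch_positions: tuple[int, ...] = field(default=())

    @property
    def n_invalid(self) -> int:
        return len(self.mismatch_positions)

    @property
    def all_valid(self) -> bool:
        return not self.mismatch_positions


@dataclass(frozen=True)
class AccuracyEstimate:
    """Accuracy summary for a collection of dimer-encoded reads.

    ``b`` is the fraction of reads with perfect block complementarity,
    ``l`` the read length in nucleotides.
    """

    b: float
    l: int
    theoretical_accuracy: float
    measured_accuracy: float
    n_reads: int
    n_invalid_blocks: int


def _coerce(s: "DimerSequence | str") -> DimerSequence:
    return s if isinstance(s, DimerSequence) else DimerSequence(s)


def diagnose_blocks(s: "DimerSequence | str") -> BlockDiagnosis:
    """Check every block for within-block base identity.

    A block is valid iff its two bases are identical and neither is
    ``N``.  "Complementarity" in the homodimer design means identity of
    the two bases of a block, not Watson-Crick pairing.
    """
    s = _coerce(s)
    seq = s.seq
    valid = []
    mism = []
    for i in range(s.block_count):
        a, b = seq[2 * i], seq[2 * i + 1]
        ok = a == b and a != "N"
        valid.append(ok)
        if not ok:
            mism.append(i)
    return BlockDiagnosis(tuple(valid), tuple(mism))


def collapse(s: "DimerSequence | str") -> str:
    """Map a fully valid dimer sequence to its half-length monomer string.

    Raises ``ValueError`` if any block is invalid; erroneous reads must go
    through splitting (UMIs) or whitelist correction (barcodes) first.
    """
    s = _coerce(s)
    diag = diagnose_blocks(s)
    if not diag.all_valid:
        raise ValueError(
            f"cannot collapse: invalid blocks at {list(diag.mismatch_positions)}"
        )
    return s.seq[::2]


def expand(monomer: str) -> DimerSequence:
    """Inverse of :func:`collapse`: ``ACGT`` -> ``AACCGGTT``."""
    if not monomer:
        raise ValueError("empty sequence")
    if not set(monomer) <= set(_BASES):
        raise ValueError("expand requires a string over A/C/G/T")
    return DimerSequence("".join(c + c for c in monomer))


def theoretical_accuracy(b: float, l: int) -> float:
    """Per-base accuracy implied by a perfect-complementarity fraction.

    If every base survives sequencing independently with probability
    ``p``, a read of ``l`` bases is fully complementary with probability
    ``p**l``; inverting gives ``p = b ** (1/l)``.

    Parameters
    ----------
    b : fraction of reads with all blocks valid, in [0, 1].
    l : barcode length in nucleotides (>= 1).
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"b must lie in [0, 1], got {b}")
    if l < 1:
        raise ValueError(f"l must be >= 1, got {l}")
    return b ** (1.0 / l)


def measured_accuracy(
    reads: Iterable["DimerSequence | str"],
    error_bases_per_block: int = 1,
) -> AccuracyEstimate:
    """Measure base-calling accuracy by counting invalid blocks.

    Each invalid block contributes ``error_bases_per_block`` erroneous
    bases (default 1: a single substitution suffices to break a pair; set
    to 2 for the pessimistic reading where both bases are unusable).
    Also reports ``b``, the perfect-complementarity fraction, and the
    theoretical accuracy it implies.
    """
    if error_bases_per_block not in (1, 2):
        raise ValueError("error_bases_per_block must be 1 or 2")
    seqs = [_coerce(r) for r in reads]
    if not seqs:
        raise ValueError("measured_accuracy requires a non-empty collection")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("all reads must have uniform length")

    n_perfect = 0
    n_invalid_blocks = 0
    for s in seqs:
        diag = diagnose_blocks(s)
        if diag.all_valid:
            n_perfect += 1
        n_invalid_blocks += diag.n_invalid

    total_bases = length * len(seqs)
    b = n_perfect / len(seqs)
    measured = 1.0 - (n_invalid_blocks * error_bases_per_block) / total_bases
    return AccuracyEstimate(
        b=b,
        l=length,
        theoretical_accuracy=theoretical_accuracy(b, length),
        measured_accuracy=measured,
        n_reads=len(seqs),
        n_invalid_blocks=n_invalid_blocks,
    )
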