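"""Synthetic ground-truth generators.

Two simulators drive all desk-scale validation:

* a barcode simulator that emits dimer-encoded 24-nt cell barcodes at a
  given sequencing depth, injecting PCR and sequencing substitution
  errors into an eligible share of reads, and
* a UMI amplification simulator that grows a molecule pool cycle by
  cycle (each molecule duplicates with its own amplification probability
  drawn uniformly from 0.8-1.0; PCR errors create new sequences that
  receive fresh probabilities), subsamples reads to a sequencing depth,
  and applies per-base sequencing errors.

Both keep a truth map from every observed read to the molecule it came
from, so recovery and bias of the downstream correction can be measured
exactly.  Errors are substitutions only, uniform over the three
alternative bases.  All randomness flows through a single seed; a fixed
seed gives bit-identical output.

A third generator writes full-structure synthetic long reads
(PCR handle + barcode + UMI + poly(T) + cDNA, both orientations) as a
gzipped FASTQ plus a truth table, for end-to-end pipeline tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .correct import assign_all, build_whitelist
from .dedup import count_unique_umis
from .dimer import collapse

__all__ = [
    "BarcodeSimParams",
    "UmiSimParams",
    "SimResult",
    "simulate_barcodes",
    "simulate_umis",
    "barcode_recovery",
    "recovery_curve",
    "umi_bias_table",
    "write_synthetic_reads",
    "DEFAULT_HANDLE",
]

DEFAULT_HANDLE = "AAGCAGTGGTATCAACGCAGAGTAC"

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(rows: np.ndarray) -> list[str]:
    return _BASE_BYTES[rows].tobytes().decode()  # type: ignore[return-value]


def _decode_rows(rows: np.ndarray) -> list[str]:
    flat = _BASE_BYTES[rows].tobytes().decode()
    k = rows.shape[1]
    return [flat[i : i + k] for i in range(0, len(flat), k)]


def _distinct_monomers(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """n distinct random monomer k-mers as a (n, k) uint8 array."""
    if n > 4**k:
        raise ValueError(f"cannot draw {n} distinct {k}-mers")
    out: list[tuple] = []
    seen: set[tuple] = set()
    while len(out) < n:
        block = rng.integers(0, 4, size=(n, k), dtype=np.uint8)
        for row in block:
            t = tuple(row)
            if t not in seen:
                seen.add(t)
                out.append(t)
                if len(out) == n:
                    break
    return np.array(out, dtype=np.uint8)


def _expand_dimer(monomers: np.ndarray) -> np.ndarray:
    return np.repeat(monomers, 2, axis=1)


def _substitute(rng: np.random.Generator, arr: np.ndarray, mask: np.ndarray) -> None:
    """In-place uniform substitution over the 3 alternative bases."""
    n = int(mask.sum())
    if n:
        arr[mask] = (arr[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4


@dataclass
class BarcodeSimParams:
    """Parameters of the barcode error simulation.

    Defaults follow the study conditions: 24-nt (12-block) barcodes,
    sequencing depth 400 reads per barcode, PCR error rate 1e-5 over 25
    cycles, errors introduced into 95% of reads.
    """

    n_barcodes: int = 100
    barcode_blocks: int = 12
    seq_error_rate: float = 0.1
    pcr_error_rate: float = 1e-5
    pcr_cycles: int = 25
    depth: int = 400
    error_fraction: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seq_error_rate", "pcr_error_rate", "error_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_barcodes", "barcode_blocks", "pcr_cycles", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class UmiSimParams:
    """Parameters of the UMI amplification simulation.

    Study conditions: 16-nt (8-block) UMIs, amplification probability
    uniform on [0.8, 1.0], 4-12 PCR cycles, sequencing depth 10-400,
    10-100 true UMIs.
    """

    n_umis: int = 50
    umi_blocks: int = 8
    amp_prob_range: tuple[float, float] = (0.8, 1.0)
    pcr_error_rate: float = 1e-5
    seq_error_rate: float = 0.1
    pcr_cycles: int = 8
    depth: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.amp_prob_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"amp_prob_range must be within [0, 1], got {self.amp_prob_range}")
        for name in ("pcr_error_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_umis", "umi_blocks", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pcr_cycles < 0:
            raise ValueError("pcr_cycles must be >= 0")


@dataclass
class SimResult:
    """Observed reads plus the truth they came from."""

    observed_reads: list[str]
    truth_map: np.ndarray  # observed index -> true molecule index
    true_sequences: list[str]  # dimer-space truth
    ground_truth_count: int

    def true_collapsed(self) -> list[str]:
        return [s[::2] for s in self.true_sequences]


def simulate_barcodes(p: BarcodeSimParams) -> SimResult:
    """Emit ``depth`` reads per true barcode with substitution errors.

    An ``error_fraction`` share of reads is eligible for per-base error
    draws (per read, not per barcode); the rest are copied verbatim.  PCR
    errors are applied as the effective per-base probability
    ``1 - (1 - pcr_error_rate) ** pcr_cycles`` accumulated over the
    amplification, combined with the sequencing error rate.
    """
    rng = np.random.default_rng(p.seed)
    truth_mono = _distinct_monomers(rng, p.n_barcodes, p.barcode_blocks)
    truth_dimer = _expand_dimer(truth_mono)

    reads = np.repeat(truth_dimer, p.depth, axis=0).copy()
    truth_map = np.repeat(np.arange(p.n_barcodes), p.depth)

    pcr_total = 1.0 - (1.0 - p.pcr_error_rate) ** p.pcr_cycles
    e_total = 1.0 - (1.0 - p.seq_error_rate) * (1.0 - pcr_total)
    eligible = rng.random(reads.shape[0]) < p.error_fraction
    mask = (rng.random(reads.shape) < e_total) & eligible[:, None]
    _substitute(rng, reads, mask)

    return SimResult(
        observed_reads=_decode_rows(reads),
        truth_map=truth_map,
        true_sequences=_decode_rows(truth_dimer),
        ground_truth_count=p.n_barcodes,
    )


def simulate_umis(p: UmiSimParams) -> SimResult:
    """Grow, subsample and error a pool of dimer UMIs.

    Every pool molecule remembers its founding UMI, so the truth map of
    the sampled reads is exact even through PCR errors.
    """
    rng = np.random.default_rng(p.seed)
    truth_mono = _distinct_monomers(rng, p.n_umis, p.umi_blocks)
    pool = _expand_dimer(truth_mono)
    probs = rng.uniform(*p.amp_prob_range, size=p.n_umis)
    ancestors = np.arange(p.n_umis)

    for _ in range(p.pcr_cycles):
        dup = rng.random(pool.shape[0]) < probs
        copies = pool[dup].copy()
        err = rng.random(copies.shape) < p.pcr_error_rate
        _substitute(rng, copies, err)
        changed = err.any(axis=1)
        new_probs = probs[dup].copy()
        if changed.any():
            new_probs[changed] = rng.uniform(*p.amp_prob_range, size=int(changed.sum()))
        pool = np.concatenate([pool, copies])
        probs = np.concatenate([probs, new_probs])
        ancestors = np.concatenate([ancestors, ancestors[dup]])

    if p.depth > pool.shape[0]:
        warnings.warn(
            f"requested depth {p.depth} exceeds pool size {pool.shape[0]}; "
            "returning the full pool",
            stacklevel=2,
        )
        idx = np.arange(pool.shape[0])
    else:
        idx = rng.choice(pool.shape[0], size=p.depth, replace=False)
    reads = pool[idx].copy()
    mask = rng.random(reads.shape) < p.seq_error_rate
    _substitute(rng, reads, mask)

    return SimResult(
        observed_reads=_decode_rows(reads),
        truth_map=ancestors[idx],
        true_sequences=_decode_rows(_expand_dimer(truth_mono)),
        ground_truth_count=p.n_umis,
    )


def barcode_recovery(p: BarcodeSimParams, edit_distance: int = 6) -> float:
    """Fraction of simulated reads assigned to their true barcode.

    Runs the full two-pass correction: whitelist from
    perfect-complementarity reads (expected cells = number of true
    barcodes), then bounded Levenshtein rescue.
    """
    sim = simulate_barcodes(p)
    wl = build_whitelist(sim.observed_reads, expected_cells=p.n_barcodes)
    results, _ = assign_all(sim.observed_reads, wl, max_edit=edit_distance)
    true_collapsed = sim.true_collapsed()
    hits = sum(
        1
        for res, t in zip(results, sim.truth_map)
        if res.assigned_barcode == true_collapsed[t]
    )
    return hits / len(results)


def recovery_curve(
    error_rates: Sequence[float],
    p: BarcodeSimParams,
    edit_distance: int = 6,
    replicates: int = 3,
) -> pd.DataFrame:
    """Barcode recovery as a function of sequencing error rate.

    Returns a table of (error_rate, fraction_recovered, se) averaged over
    ``replicates`` independent simulations per rate.
    """
    from dataclasses import replace

    rows = []
    for ri, rate in enumerate(error_rates):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"error rate must lie in [0, 1], got {rate}")
        vals = []
        for rep in range(replicates):
            q = replace(
                p,
                seq_error_rate=rate,
                seed=(p.seed * 1000003 + ri * 1009 + rep) % 2**31,
            )
            vals.append(barcode_recovery(q, edit_distance=edit_distance))
        vals_arr = np.asarray(vals)
        se = vals_arr.std(ddof=1) / np.sqrt(len(vals_arr)) if len(vals_arr) > 1 else 0.0
        rows.append((rate, float(vals_arr.mean()), float(se)))
    return pd.DataFrame(rows, columns=["error_rate", "fraction_recovered", "se"])


def umi_bias_table(
    n_umis_grid: Sequence[int] = (10, 50, 100),
    replicates: int = 36,
    seq_error_rate: float = 0.1,
    depth: int = 400,
    pcr_error_rate: float = 1e-5,
    seed: int = 0,
) -> pd.DataFrame:
    """Deduplication bias over the simulation grid.

    For each true UMI count, runs ``replicates`` simulations with the
    number of PCR cycles drawn uniformly from 4-12, deduplicates with the
    split-and-collapse directional method and records the relative bias
    (estimate - truth) / truth of every replicate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_umis_grid:
        for rep in range(replicates):
            cycles = int(rng.integers(4, 13))
            p = UmiSimParams(
                n_umis=n,
                seq_error_rate=seq_error_rate,
                pcr_error_rate=pcr_error_rate,
                pcr_cycles=cycles,
                depth=depth,
                seed=int(rng.integers(0, 2**31)),
            )
            sim = simulate_umis(p)
            est = count_unique_umis(sim.observed_reads)
            rows.append((n, rep, cycles, est, (est - n) / n))
    return pd.DataFrame(
        rows, columns=["n_umis", "replicate", "pcr_cycles", "estimate", "rel_bias"]
    )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def write_synthetic_reads(
    fastq_path,
    truth_path,
    n_cells: int = 20,
    reads_per_cell: int = 20,
    seq_error_rate: float = 0.0,
    polyt_len: int = 30,
    cdna_len_range: tuple[int, int] = (150, 400),
    handle: str = DEFAULT_HANDLE,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a gzipped FASTQ of full synthetic long reads plus truth TSV.

    Read layout: handle + dimer barcode (24 nt) + dimer UMI (16 nt) +
    poly(T) + random cDNA; half the reads are emitted reverse
    complemented.  The truth table records the collapsed barcode and UMI
    and the orientation of every read.
    """
    from .io import open_text_writer

    rng = np.random.default_rng(seed)
    cells = _decode_rows(_expand_dimer(_distinct_monomers(rng, n_cells, 12)))
    rows = []
    with open_text_writer(fastq_path) as fq:
        for ci, cell in enumerate(cells):
            for ri in range(reads_per_cell):
                umi = _decode_rows(_expand_dimer(rng.integers(0, 4, size=(1, 8), dtype=np.uint8)))[0]
                clen = int(rng.integers(*cdna_len_range))
                cdna = _decode_rows(rng.integers(0, 4, size=(1, clen), dtype=np.uint8))[0]
                read = handle + cell + umi + "T" * polyt_len + cdna
                if seq_error_rate > 0:
                    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
                    # map to 0..3 for mutation, then back
                    lut = np.zeros(256, dtype=np.uint8)
                    for i, b in enumerate(b"ACGT"):
                        lut[b] = i
                    codes = lut[arr]
                    mask = rng.random(codes.shape) < seq_error_rate
                    _substitute(rng, codes, mask)
                    read = _decode_rows(codes[None, :])[0]
                orientation = "forward" if rng.random() < 0.5 else "reverse-complement"
                out = read if orientation == "forward" else _revcomp(read)
                rid = f"read_{ci:04d}_{ri:04d}"
                fq.write(f"@{rid}\n{out}\n+\n{'I' * len(out)}\n")
                rows.append((rid, cell[::2], umi[::2], orientation))
    truth = pd.DataFrame(rows, columns=["read_id", "cell", "umi", "orientation"])
    truth.to_csv(truth_path, sep="\t", index=False)
    return truth
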