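"""Error-aware UMI deduplication.

UMIs are 16-nt homodimer sequences (8 blocks).  A UMI whose blocks are all
valid collapses to a single 8-mer.  A UMI with at least one invalid block
is *split* into two collapsed candidates — the first bases of every block
and the second bases of every block — because a single substitution breaks
exactly one strand of one block, so one of the two candidates is usually
the true UMI.

Unique-molecule counting then runs the directional network method of
UMI-tools on the pooled candidate counts (edge A -> B when the Hamming
distance is 1 and ``count(A) >= 2 * count(B) - 1``), with a read-aware
layer on top: every read is one molecule, so each read is assigned to the
best-supported cluster among its candidates, and clusters supported by a
single split read are rescued into a well-supported cluster whose
representative is per-block *consistent* with the read (at an invalid
block the true base must be one of the two observed bases).  Without this
layer the stray split candidates would each found their own cluster and
the molecule count would inflate severely at realistic long-read error
rates; see docs/methods.md.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .dimer import DimerSequence, diagnose_blocks

__all__ = [
    "UMIObservation",
    "DedupResult",
    "split_or_collapse",
    "directional_dedup",
    "count_unique_umis",
    "count_matrix",
    "CountMatrix",
]

_BASES = "ACGT"


def split_or_collapse(umi: "DimerSequence | str") -> list[str]:
    """Collapse a dimer UMI, splitting it in two if any block is invalid.

    Returns one collapsed sequence when every block is valid, otherwise
    the two half-sequences (first base of each block, second base of each
    block).  Candidates still containing ``N`` are dropped, so the result
    may be empty.
    """
    s = umi if isinstance(umi, DimerSequence) else DimerSequence(umi)
    diag = diagnose_blocks(s)
    if diag.all_valid:
        return [s.seq[::2]]
    first, second = s.seq[::2], s.seq[1::2]
    return [c for c in (first, second) if "N" not in c]


@dataclass
class UMIObservation:
    """Collapsed-UMI counts observed for one (cell, feature) pair."""

    cell: str
    feature: str
    umi_counts: dict[str, int]


@dataclass
class DedupResult:
    """Clusters produced by the directional method.

    ``clusters`` partition the observed UMI set; the first member of each
    cluster is its representative (the highest-count node it was seeded
    from).
    """

    unique_count: int
    clusters: list[list[str]]


def _hamming_neighbors(umi: str) -> Iterator[str]:
    for i, c in enumerate(umi):
        for b in _BASES:
            if b != c:
                yield umi[:i] + b + umi[i + 1 :]


def directional_dedup(obs: "UMIObservation | Mapping[str, int]") -> DedupResult:
    """Cluster UMIs with the directional network rule.

    Nodes are visited in descending count (ties broken lexicographically);
    from each unvisited node a depth-first traversal follows edges
    ``u -> v`` where Hamming distance(u, v) == 1 and
    ``count(u) >= 2 * count(v) - 1``.  Each traversal is one cluster, and
    ``unique_count`` is the number of clusters.
    """
    counts = obs.umi_counts if isinstance(obs, UMIObservation) else dict(obs)
    if not counts:
        raise ValueError("directional_dedup requires non-empty counts")
    order = sorted(counts, key=lambda u: (-counts[u], u))
    present = set(counts)
    visited: set[str] = set()
    clusters: list[list[str]] = []
    for seed in order:
        if seed in visited:
            continue
        comp = [seed]
        visited.add(seed)
        stack = [seed]
        while stack:
            u = stack.pop()
            for v in _hamming_neighbors(u):
                if v in present and v not in visited and counts[u] >= 2 * counts[v] - 1:
                    visited.add(v)
                    comp.append(v)
                    stack.append(v)
        clusters.append(comp)
    return DedupResult(unique_count=len(clusters), clusters=clusters)


def _consistent(rep: str, cand_a: str, cand_b: str) -> bool:
    # rep could be the true UMI of the split read: at every collapsed
    # position it must equal one of the two observed bases.
    return all(r == a or r == b for r, a, b in zip(rep, cand_a, cand_b))


def count_unique_umis(raw_umis: Iterable["DimerSequence | str"], rescue: bool = True) -> int:
    """Estimate the number of distinct molecules from raw dimer UMIs.

    Each raw UMI is collapsed (or split into two candidates), candidates
    are pooled with weight 1 and clustered with :func:`directional_dedup`,
    every read is assigned to its best-supported candidate cluster, and —
    when ``rescue`` is on — singleton clusters backed only by a split read
    are merged into the most-supported consistent cluster.  Returns the
    number of clusters with at least one read assigned.
    """
    cand_lists = [split_or_collapse(u) for u in raw_umis]
    counts: Counter[str] = Counter()
    for cands in cand_lists:
        counts.update(cands)
    if not counts:
        return 0

    result = directional_dedup(counts)
    cluster_of: dict[str, int] = {}
    support: dict[int, int] = {}
    reps: dict[int, str] = {}
    for i, comp in enumerate(result.clusters):
        reps[i] = comp[0]
        support[i] = sum(counts[u] for u in comp)
        for u in comp:
            cluster_of[u] = i

    assigned: Counter[int] = Counter()
    read_cluster: list[int | None] = []
    for cands in cand_lists:
        if not cands:
            read_cluster.append(None)
            continue
        best = max(cands, key=lambda u: (support[cluster_of[u]], u))
        cid = cluster_of[best]
        read_cluster.append(cid)
        assigned[cid] += 1

    if not rescue:
        return len(assigned)

    strong = sorted(
        (i for i, n in assigned.items() if n >= 2),
        key=lambda i: (-support[i], reps[i]),
    )
    final: set[int] = set(strong)
    for cands, cid in zip(cand_lists, read_cluster):
        if cid is None or assigned[cid] >= 2:
            continue
        if len(cands) == 2:
            a, b = cands
            if any(_consistent(reps[j], a, b) for j in strong):
                continue  # molecule explained by an existing cluster
        final.add(cid)
    return len(final)


@dataclass
class CountMatrix:
    """Sparse feature-by-cell unique-molecule counts."""

    matrix: sp.csr_matrix
    features: list[str]
    cells: list[str]

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()


def count_matrix(
    records: Iterable[tuple[str, str, str]],
    min_features: int = 200,
    rescue: bool = True,
) -> CountMatrix:
    """Build the feature x cell counts matrix from (cell, feature, raw UMI).

    Raw UMIs are dimer 16-mers; per (cell, feature) group they are
    collapsed/split and deduplicated with :func:`count_unique_umis`.
    Cells expressing fewer than ``min_features`` features are dropped
    (set ``min_features=0`` to keep everything).
    """
    groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    for cell, feature, umi in records:
        groups[(cell, feature)].append(str(umi))

    per_cell: dict[str, dict[str, int]] = defaultdict(dict)
    for (cell, feature), umis in groups.items():
        n = count_unique_umis(umis, rescue=rescue)
        if n > 0:
            per_cell[cell][feature] = n

    kept_cells = sorted(c for c, feats in per_cell.items() if len(feats) >= min_features)
    features = sorted({f for c in kept_cells for f in per_cell[c]})
    fidx = {f: i for i, f in enumerate(features)}
    cidx = {c: j for j, c in enumerate(kept_cells)}

    rows, cols, data = [], [], []
    for c in kept_cells:
        for f, n in per_cell[c].items():
            rows.append(fidx[f])
            cols.append(cidx[c])
            data.append(n)
    mat = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(features), len(kept_cells)), dtype=np.int64
    )
    return CountMatrix(matrix=mat, features=features, cells=kept_cells)
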