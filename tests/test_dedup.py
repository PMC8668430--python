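"""UMI split-and-collapse, directional clustering, per-cell counting."""

import itertools

import numpy as np
import pytest

from dimerseq import (
    count_matrix,
    count_unique_umis,
    directional_dedup,
    expand,
    split_or_collapse,
)


@pytest.mark.parametrize(
    "umi, expected",
    [
        ("AACCGGTTAACCGGTT", ["ACGTACGT"]),
        ("AACCGGTTAACCGGTA", ["ACGTACGT", "ACGTACGA"]),  # odd vs even strand
        ("TACCGGTTAACCGGTT", ["TCGTACGT", "ACGTACGT"]),
        ("NNCCGGTTAACCGGTT", []),  # N propagates into both candidates
        ("ANCCGGTTAACCGGTT", ["ACGTACGT"]),  # only the N-free strand survives
    ],
)
def test_split_or_collapse(umi, expected):
    assert split_or_collapse(umi) == expected


def test_split_or_collapse_rejects_odd_length():
    with pytest.raises(ValueError):
        split_or_collapse("ACGTA")


@pytest.mark.parametrize(
    "counts, n_clusters",
    [
        ({"ACGTACGT": 10, "ACGTACGA": 1}, 1),  # 10 >= 2*1-1, distance 1
        ({"ACGTACGT": 5, "TGCATGCA": 5}, 2),  # distance > 1
        ({"ACGTACGT": 3, "ACGTACGA": 2}, 1),  # boundary: 3 >= 2*2-1
        ({"ACGTACGT": 3, "ACGTACGA": 3}, 2),  # 3 < 2*3-1: no edge
    ],
)
def test_directional_examples(counts, n_clusters):
    res = directional_dedup(counts)
    assert res.unique_count == n_clusters
    assert sorted(u for c in res.clusters for u in c) == sorted(counts)


def test_directional_requires_nonempty():
    with pytest.raises(ValueError):
        directional_dedup({})


def _bruteforce_cluster_counts(counts):
    """All-orderings oracle with pairwise-Hamming adjacency."""
    nodes = list(counts)
    adj = {
        u: [v for v in nodes if v != u and sum(a != b for a, b in zip(u, v)) == 1]
        for u in nodes
    }
    seen = set()
    for perm in itertools.permutations(nodes):
        order = sorted(perm, key=lambda u: -counts[u])  # stable: keeps tie order
        visited, k = set(), 0
        for seed in order:
            if seed in visited:
                continue
            k += 1
            stack = [seed]
            visited.add(seed)
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if v not in visited and counts[u] >= 2 * counts[v] - 1:
                        visited.add(v)
                        stack.append(v)
        seen.add(k)
    return seen


def test_directional_matches_bruteforce_on_small_instances(rng):
    for _ in range(40):
        base = "".join(rng.choice(list("ACGT"), size=4))
        pool = {base}
        while len(pool) < 5:
            u = list(rng.choice(sorted(pool)))
            u[int(rng.integers(4))] = str(rng.choice(list("ACGT")))
            pool.add("".join(u))
        counts = {u: int(rng.integers(1, 12)) for u in sorted(pool)}
        oracle = _bruteforce_cluster_counts(counts)
        assert len(oracle) == 1, "cluster count must not depend on visit order"
        assert directional_dedup(counts).unique_count == oracle.pop()


def test_directional_invariant_to_input_order(rng):
    counts = {"ACGTACGT": 7, "ACGTACGA": 2, "ACGAACGA": 1, "TTTTACGT": 4}
    base = directional_dedup(counts).unique_count
    items = list(counts.items())
    for _ in range(5):
        rng.shuffle(items)
        assert directional_dedup(dict(items)).unique_count == base


def test_unique_count_bounds(rng):
    for _ in range(20):
        n = int(rng.integers(1, 8))
        umis = ["".join(rng.choice(list("ACGT"), size=4)) for _ in range(n)]
        counts = {}
        for u in umis:
            counts[u] = counts.get(u, 0) + 1
        res = directional_dedup(counts)
        assert 1 <= res.unique_count <= len(counts)


def test_count_unique_umis_single_molecule():
    umi = expand("ACGTACGA").seq
    assert count_unique_umis([umi] * 5) == 1


def test_count_unique_umis_split_read_absorbed():
    # 9 clean observations of one UMI plus a split read one error away
    clean = expand("ACGTACGT").seq
    errored = "TA" + clean[2:]  # block 0 invalid
    assert count_unique_umis([clean] * 9 + [errored]) == 1


def test_count_matrix_basic_and_exact_on_error_free():
    cells = ["AAACCCGGGTTT", "ACGTACGTACGT", "TTTTCCCCGGGG"]
    genes = ["tx1", "tx2", "tx3", "tx4"]
    rng = np.random.default_rng(5)
    records = []
    truth = {}
    mono = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
    for ci, cell in enumerate(cells):
        for gi, gene in enumerate(genes):
            k = 1 + (ci + gi) % 4  # 1..4 distinct molecules
            truth[(cell, gene)] = k
            picks = rng.choice(len(mono), size=k, replace=False)
            for pi in picks:
                umi = expand(mono[pi] + mono[(pi + 7) % len(mono)]).seq
                records.extend((cell, gene, umi) for _ in range(3))  # PCR copies
    rng.shuffle(records)
    cm = count_matrix(records, min_features=0)
    assert cm.cells == sorted(cells)
    dense = cm.to_dense()
    for (cell, gene), k in truth.items():
        assert dense[cm.features.index(gene), cm.cells.index(cell)] == k


def test_count_matrix_min_features_filter():
    umi = expand("ACGTACGT").seq
    records = [("CELLA" * 2 + "AC", f"tx{i}", umi) for i in range(5)]
    records += [("CELLB" * 2 + "AC", "tx0", umi)]
    cm = count_matrix(records, min_features=3)
    assert cm.cells == ["CELLA" * 2 + "AC"]
    cm_all = count_matrix(records, min_features=0)
    assert len(cm_all.cells) == 2


def test_count_matrix_invariant_to_record_order(rng):
    umis = [expand("ACGTACGT").seq, expand("ACGTACGA").seq, expand("TTGTACGT").seq]
    records = [("CELL", "tx1", u) for u in umis for _ in range(4)]
    a = count_matrix(records, min_features=0)
    shuffled = records[:]
    rng.shuffle(shuffled)
    b = count_matrix(shuffled, min_features=0)
    assert (a.to_dense() == b.to_dense()).all()
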