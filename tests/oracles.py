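"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: edges by all-pairs gap
evaluation, components by union-find, clustering by edge-list triple
counting, confusion counts by literal per-nucleotide enumeration.
"""

from __future__ import annotations

import numpy as np


def pairwise_gaps(reads) -> tuple[np.ndarray, np.ndarray]:
    """(same-chromosome boolean matrix, gap matrix) over all read pairs.

    gap[i, j] = max(start_i, start_j) - min(end_i, end_j) - 1: negative when
    the intervals overlap, 0 when they abut.
    """
    chroms = np.array([r.chrom for r in reads])
    start = np.array([r.start for r in reads], dtype=np.int64)
    end = np.array([r.end for r in reads], dtype=np.int64)
    same = chroms[:, None] == chroms[None, :]
    gap = np.maximum(start[:, None], start[None, :]) - np.minimum(
        end[:, None], end[None, :]
    ) - 1
    return same, gap


def brute_force_edges(reads, M: int) -> set[tuple[int, int]]:
    """All-pairs edge list: (i, j) with i < j, same chromosome, gap < M."""
    same, gap = pairwise_gaps(reads)
    n = len(reads)
    iu = np.triu_indices(n, k=1)
    mask = same[iu] & (gap[iu] < M)
    return {(int(i), int(j)) for i, j in zip(iu[0][mask], iu[1][mask])}


def edges_at_m(same: np.ndarray, gap: np.ndarray, M: int) -> set[tuple[int, int]]:
    """Edge set at one M from precomputed pairwise matrices."""
    n = same.shape[0]
    iu = np.triu_indices(n, k=1)
    mask = same[iu] & (gap[iu] < M)
    return {(int(i), int(j)) for i, j in zip(iu[0][mask], iu[1][mask])}


def union_find_components(n: int, edges) -> set[frozenset[int]]:
    """Partition of {0..n-1} induced by the edge list, via union-find."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups: dict[int, set[int]] = {}
    for v in range(n):
        groups.setdefault(find(v), set()).add(v)
    return {frozenset(g) for g in groups.values()}


def triple_count_clustering(n: int, edges, v: int) -> float:
    """Local clustering of v computed purely from the edge list."""
    edge_set = {frozenset(e) for e in edges}
    nbrs = sorted({u for e in edges for u in e if v in e and u != v})
    k = len(nbrs)
    if k < 2:
        return 0.0
    closed = sum(
        1
        for a in range(k)
        for b in range(a + 1, k)
        if frozenset((nbrs[a], nbrs[b])) in edge_set
    )
    return closed / (k * (k - 1) / 2)


def enumerate_confusion(locales, reference, genome) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) by marking every genome nucleotide in boolean arrays."""
    tp = tn = fp = fn = 0
    for chrom in genome:
        n = genome[chrom]
        in_locale = np.zeros(n, dtype=bool)
        in_ref = np.zeros(n, dtype=bool)
        for loc in locales:
            if loc.chrom == chrom:
                in_locale[loc.start - 1 : loc.end] = True
        for ref in reference:
            if ref.chrom == chrom:
                in_ref[ref.start - 1 : ref.end] = True
        tp += int(np.sum(in_locale & in_ref))
        tn += int(np.sum(~in_locale & ~in_ref))
        fp += int(np.sum(in_locale & ~in_ref))
        fn += int(np.sum(~in_locale & in_ref))
    return tp, tn, fp, fn


def random_reads(rng: np.random.Generator, n: int, n_chroms: int = 2,
                 genome_span: int = 5000, max_len: int = 30):
    """Random AlignedRead instances for oracle-equivalence testing."""
    from nibls import AlignedRead

    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    reads = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, n_chroms))]
        start = int(rng.integers(1, genome_span))
        length = int(rng.integers(1, max_len + 1))
        reads.append(AlignedRead(f"r{i}", chrom, start, start + length - 1))
    return reads
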