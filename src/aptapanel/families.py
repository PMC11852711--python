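"""Motif-based aptamer families and per-family representatives.

Aptamers that share an extended exact sequence motif are treated as one
family, presumed to bind the same protein epitope; the most abundant
member represents the family in downstream target identification.

Two sequences share a common substring of length >= L exactly when they
share some exact L-mer, so the family graph is built from an L-mer index
(no all-pairs alignment); families are the connected components
(single-linkage closure). Clustering must run on variable regions only —
constant primer flanks would link everything.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .counts import CountMatrix


@dataclass
class AptamerFamily:
    family_id: str
    members: list[str]  # sorted aptamer ids
    motif: str  # longest common substring witnessed on the family's links
    representative: str | None = None


def longest_common_substring(a: str, b: str) -> str:
    """Longest common substring by dynamic programming (ties: the first
    occurrence in ``a``)."""
    if not a or not b:
        return ""
    best_len, best_end = 0, 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best_len:
                    best_len, best_end = cur[j], i
        prev = cur
    return a[best_end - best_len : best_end]


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            # keep the lexicographically smaller root: canonical labelling
            if ry < rx:
                rx, ry = ry, rx
            self.parent[ry] = rx


def cluster_families(
    sequences: dict[str, str], min_motif_length: int = 12
) -> list[AptamerFamily]:
    """Partition aptamers into families by shared exact motifs.

    An edge links two aptamers iff their longest common substring has
    length >= ``min_motif_length``; families are connected components.
    The witness motif of a family is the longest common substring found
    over its discovered links (empty for singletons). Sequences shorter
    than the threshold become singletons by construction. The result is
    invariant to input order: families are sorted by smallest member id.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if min_motif_length < 8:
        raise ValueError("min_motif_length must be >= 8")
    ids = sorted(sequences)
    uf = _UnionFind(ids)
    index: dict[str, list[str]] = defaultdict(list)
    for aid in ids:
        seq = sequences[aid].upper().replace("U", "T")
        seen_kmers = set()
        for i in range(len(seq) - min_motif_length + 1):
            km = seq[i : i + min_motif_length]
            if km not in seen_kmers:
                index[km].append(aid)
                seen_kmers.add(km)
    edges: set[tuple[str, str]] = set()
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        for i in range(len(bucket)):
            for j in range(i + 1, len(bucket)):
                pair = (bucket[i], bucket[j]) if bucket[i] < bucket[j] else (bucket[j], bucket[i])
                edges.add(pair)
    for x, y in edges:
        uf.union(x, y)

    components: dict[str, list[str]] = defaultdict(list)
    for aid in ids:
        components[uf.find(aid)].append(aid)

    witness: dict[str, str] = {root: "" for root in components}
    for x, y in edges:
        root = uf.find(x)
        lcs = longest_common_substring(sequences[x], sequences[y])
        if len(lcs) > len(witness[root]):
            witness[root] = lcs

    families = []
    for k, root in enumerate(sorted(components)):
        members = sorted(components[root])
        families.append(
            AptamerFamily(
                family_id=f"family_{k + 1:03d}",
                members=members,
                motif=witness[root],
            )
        )
    return families


def select_representatives(
    families: list[AptamerFamily],
    matrix: CountMatrix,
    sequences: dict[str, str] | None = None,
) -> dict[str, str]:
    """Pick the most abundant member of each family (by total count).

    Ties break to the lexicographically smallest sequence (falling back
    to the smallest id when no sequences are available). Fills in each
    family's ``representative`` and returns family_id -> aptamer_id.
    """
    seqs = sequences or matrix.sequences or {}
    totals = matrix.counts.sum(axis=0)
    out = {}
    for fam in families:
        missing = [m for m in fam.members if m not in totals.index]
        if missing:
            raise ValueError(
                f"family {fam.family_id}: members missing from count matrix: {missing[:5]}"
            )
        rep = min(fam.members, key=lambda m: (-totals[m], seqs.get(m, m), m))
        fam.representative = rep
        out[fam.family_id] = rep
    return out
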