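"""Exhaustive "information lossless" search for regulator trios and quartets.

Given the co-association network and its transcription-factor (TF) nodes,
every k-combination (k = 3 or 4) of TFs is scored by the number of distinct
network nodes adjacent to at least one member (coverage, members excluded)
and by the summed pairwise overlap of member neighborhoods (redundancy).
Combinations are ranked by coverage descending, redundancy ascending, then
lexicographically — exhaustively, not greedily, because the search space
(e.g. C(68, 4) ~ 8e5) is small with bitset arithmetic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from fenet.awm import CoAssocNetwork

__all__ = ["RegulatorSet", "lossless_search", "lossless_search_reference"]

_GUARD = 10_000_000


@dataclass(frozen=True)
class RegulatorSet:
    members: tuple[str, ...]
    coverage: int
    redundancy: int


def _neighbor_bitsets(
    net: CoAssocNetwork, tf_nodes: list[str]
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    node_index = {v: i for i, v in enumerate(net.nodes)}
    n = len(net.nodes)
    n_words = -(-n // 64)
    adj = np.zeros((len(tf_nodes), n_words), dtype=np.uint64)
    member_bits = np.zeros((len(tf_nodes), n_words), dtype=np.uint64)
    for t, tf in enumerate(tf_nodes):
        member_bits[t, node_index[tf] // 64] |= np.uint64(1) << np.uint64(node_index[tf] % 64)
        for nb in net.neighbors(tf):
            j = node_index[nb]
            adj[t, j // 64] |= np.uint64(1) << np.uint64(j % 64)
    return adj, member_bits, node_index


def lossless_search(
    net: CoAssocNetwork,
    tf_nodes: list[str],
    k: int = 3,
    top_n: int = 10,
    include_members: bool = False,
) -> list[RegulatorSet]:
    """Score and rank every k-combination of TF nodes.

    ``include_members=False`` (default) counts the open-neighborhood union
    excluding the seed TFs themselves. Raises when k is not 3 or 4, when a
    TF is absent from the network, or when the combination count exceeds the
    enumeration guard (pre-filter TFs by degree in that case).
    """
    if k not in (3, 4):
        raise ValueError(f"k must be 3 or 4, got {k}")
    missing = [t for t in tf_nodes if t not in set(net.nodes)]
    if missing:
        raise ValueError(f"TF nodes absent from network: {missing[:5]}")
    n_comb = comb(len(tf_nodes), k)
    if n_comb > _GUARD:
        raise ValueError(
            f"{n_comb} combinations exceed the enumeration guard ({_GUARD}); "
            "pre-filter the TF list by degree"
        )
    tf_nodes = sorted(tf_nodes)
    adj, member_bits, _ = _neighbor_bitsets(net, tf_nodes)
    results: list[RegulatorSet] = []
    for combo in itertools.combinations(range(len(tf_nodes)), k):
        rows = adj[list(combo)]
        union = np.bitwise_or.reduce(rows, axis=0)
        if not include_members:
            members = np.bitwise_or.reduce(member_bits[list(combo)], axis=0)
            union = union & ~members
        coverage = int(np.bitwise_count(union).sum())
        redundancy = 0
        for a, b in itertools.combinations(range(k), 2):
            redundancy += int(np.bitwise_count(rows[a] & rows[b]).sum())
        results.append(
            RegulatorSet(tuple(tf_nodes[i] for i in combo), coverage, redundancy)
        )
    results.sort(key=lambda s: (-s.coverage, s.redundancy, s.members))
    return results[:top_n]


def lossless_search_reference(
    net: CoAssocNetwork,
    tf_nodes: list[str],
    k: int = 3,
    top_n: int = 10,
    include_members: bool = False,
) -> list[RegulatorSet]:
    """Naive set-based scorer used as the independent oracle in tests."""
    tf_nodes = sorted(tf_nodes)
    nbrs = {t: net.neighbors(t) for t in tf_nodes}
    results = []
    for combo in itertools.combinations(tf_nodes, k):
        union: set[str] = set()
        for t in combo:
            union |= nbrs[t]
        if not include_members:
            union -= set(combo)
        redundancy = sum(
            len(nbrs[a] & nbrs[b]) for a, b in itertools.combinations(combo, 2)
        )
        results.append(RegulatorSet(combo, len(union), redundancy))
    results.sort(key=lambda s: (-s.coverage, s.redundancy, s.members))
    return results[:top_n]


def regulator_table(sets: list[RegulatorSet], labels: dict[str, str] | None = None) -> pd.DataFrame:
    """TSV-ready table: combination members, target-gene count, redundancy."""
    labels = labels or {}
    return pd.DataFrame({
        "regulators": ["-".join(labels.get(m, m) for m in s.members) for s in sets],
        "n_targets": [s.coverage for s in sets],
        "redundancy": [s.redundancy for s in sets],
    })
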