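"""Promoter haplotype calling and reduced-median network construction.

Haplotypes are called from an aligned promoter sequence set: SNP columns
and indel blocks (a run of alignment columns with an identical gap pattern
collapses to one binary presence/absence character, so a multi-kilobase
transposon insertion counts as a single mutation, exactly like a SNP).
Variants with minor-allele frequency below 10% are dropped, haplotypes with
frequency above 10% are labeled major, and the network is built on
haplotypes observed more than once ("frequency > 1") by the reduced-median
method: median (consensus-of-three) vectors are added until closure, then
minimum-spanning connections are retained, keeping reticulations where
binary characters conflict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeTable",
    "call_haplotypes",
    "reduced_median_network",
    "TE_MIN_LENGTH",
]

TE_MIN_LENGTH = 50  # indels at least this long are labeled TE insertions


@dataclass
class HaplotypeTable:
    variants: pd.DataFrame  # position (alignment, 0-based), type, alleles, maf
    haplotypes: pd.Series  # accession -> binary haplotype string
    counts: pd.Series  # haplotype string -> accession count
    major_haplotypes: list  # strings with frequency > major_freq
    n_accessions: int


def call_haplotypes(
    alignment,
    maf_min: float = 0.10,
    major_freq: float = 0.10,
) -> HaplotypeTable:
    """Call binary haplotypes from an aligned sequence set.

    ``alignment``: iterable of ``(accession_id, aligned_sequence)``. All
    sequences must share the alignment length (ragged input errors with the
    offending id). Contiguous columns with an identical gap pattern form a
    single indel character; gap-free biallelic columns form SNP characters
    (columns with >2 bases are dropped with a warning — the promoter data
    this models is effectively biallelic). Variants with MAF < ``maf_min``
    are dropped; haplotypes with frequency > ``major_freq`` are major.
    """
    records = list(alignment)
    if not records:
        raise ValueError("empty alignment")
    length = len(records[0][1])
    for acc, seq in records:
        if len(seq) != length:
            raise ValueError(f"ragged alignment: sequence {acc!r} has length {len(seq)} != {length}")
    ids = [acc for acc, _ in records]
    mat = np.array([list(seq.upper()) for _, seq in records])
    n = len(ids)

    is_gap = mat == "-"
    variants = []  # (position, type, alleles, binary column)
    dropped_multiallelic = 0

    # indel blocks: runs of gapped columns with identical gap pattern
    gap_cols = np.flatnonzero(is_gap.any(axis=0))
    used = np.zeros(length, dtype=bool)
    j = 0
    while j < len(gap_cols):
        start = gap_cols[j]
        pattern = is_gap[:, start]
        end = start
        jj = j + 1
        while jj < len(gap_cols) and gap_cols[jj] == end + 1 and np.array_equal(is_gap[:, gap_cols[jj]], pattern):
            end = gap_cols[jj]
            jj += 1
        run_len = end - start + 1
        vtype = "TE_insertion" if run_len >= TE_MIN_LENGTH else "indel"
        present = (~pattern).astype(int)  # 1 = carries the inserted bases
        variants.append((int(start), vtype, ("-", "ins"), present))
        used[start : end + 1] = True
        j = jj

    # SNP columns among gap-free positions
    for col in range(length):
        if used[col]:
            continue
        alleles, counts = np.unique(mat[:, col], return_counts=True)
        if len(alleles) == 1:
            continue
        if len(alleles) > 2:
            dropped_multiallelic += 1
            continue
        minor = alleles[np.argmin(counts)]
        variants.append((col, "SNP", tuple(alleles), (mat[:, col] == minor).astype(int)))
    if dropped_multiallelic:
        warnings.warn(f"dropped {dropped_multiallelic} multi-allelic columns")

    kept = []
    for pos, vtype, alleles, column in variants:
        freq = column.mean()
        maf = min(freq, 1 - freq)
        if maf >= maf_min:
            kept.append((pos, vtype, alleles, maf, column))
    kept.sort(key=lambda v: v[0])

    var_table = pd.DataFrame(
        [(p, t, "/".join(map(str, a)), m) for p, t, a, m, _ in kept],
        columns=["position", "type", "alleles", "maf"],
    )
    if kept:
        columns = np.column_stack([c for *_, c in kept])
        strings = ["".join(map(str, row)) for row in columns]
    else:
        strings = ["" for _ in ids]
    haplotypes = pd.Series(strings, index=pd.Index(ids, name="accession"), name="haplotype")
    counts = haplotypes.value_counts()
    major = [h for h, c in counts.items() if c / n > major_freq]
    return HaplotypeTable(var_table, haplotypes, counts, major, n)


def _median(a: tuple, b: tuple, c: tuple) -> tuple:
    return tuple(1 if (x + y + z) >= 2 else 0 for x, y, z in zip(a, b, c))


def _hamming(a: tuple, b: tuple) -> int:
    return sum(x != y for x, y in zip(a, b))


def reduced_median_network(table: HaplotypeTable, min_freq: int = 2) -> nx.Graph:
    """Reduced-median network of the haplotypes observed >= ``min_freq``
    times (the "frequency > 1" criterion at the default).

    Characters must be binary. Median (majority consensus of three)
    vectors are added until closure; nodes are then connected by
    minimum-spanning connections (all edges of a distance tier that join
    previously separate components, so tied alternatives form
    reticulations); finally unobserved median nodes that resolve nothing
    (degree <= 2) are contracted away. Node attributes: ``kind``
    ("observed"/"median"), ``count``; edge attribute ``variants`` lists the
    indices of the characters separating the endpoints.

    Returns a connected :class:`networkx.Graph` whose node ids are the
    binary haplotype strings.
    """
    counts = {h: int(c) for h, c in table.counts.items() if c >= min_freq}
    if not counts:
        raise ValueError(f"no haplotype observed >= {min_freq} times")
    if len(counts) < 2:
        raise ValueError("need >= 2 retained haplotypes to build a network")
    observed = {tuple(int(ch) for ch in h): h for h in counts}
    for h in counts:
        if any(ch not in "01" for ch in h):
            raise ValueError(
                f"haplotype {h!r} has non-binary characters; recode multi-allelic "
                "variants to binary before network construction"
            )

    # median closure
    nodes = set(observed)
    changed = True
    guard = 0
    while changed and guard < 20:
        changed = False
        guard += 1
        current = sorted(nodes)
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                for k in range(j + 1, len(current)):
                    m = _median(current[i], current[j], current[k])
                    if m not in nodes:
                        nodes.add(m)
                        changed = True

    # minimum-spanning connections with ties kept (reticulations allowed)
    node_list = sorted(nodes)
    graph = nx.Graph()
    for v in node_list:
        s = "".join(map(str, v))
        graph.add_node(
            s,
            vector=v,
            kind="observed" if v in observed else "median",
            count=counts.get("".join(map(str, v)), 0),
        )
    pairs = []
    for i in range(len(node_list)):
        for j in range(i + 1, len(node_list)):
            pairs.append((_hamming(node_list[i], node_list[j]), node_list[i], node_list[j]))
    pairs.sort(key=lambda t: t[0])

    # simple union-find over node indices
    parent = list(range(len(node_list)))

    def root(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    idx = {v: i for i, v in enumerate(node_list)}
    d = 0
    i = 0
    n_comp = len(node_list)
    while i < len(pairs) and n_comp > 1:
        d = pairs[i][0]
        tier = []
        while i < len(pairs) and pairs[i][0] == d:
            tier.append(pairs[i])
            i += 1
        # evaluate membership against components as of the tier start
        roots_before = {v: root(idx[v]) for v in node_list}
        added = []
        for _, u, v in tier:
            if roots_before[u] != roots_before[v]:
                su, sv = "".join(map(str, u)), "".join(map(str, v))
                diffs = [t for t, (x, y) in enumerate(zip(u, v)) if x != y]
                graph.add_edge(su, sv, variants=tuple(diffs), weight=d)
                added.append((u, v))
        for u, v in added:
            ru, rv = root(idx[u]), root(idx[v])
            if ru != rv:
                parent[ru] = rv
                n_comp -= 1

    # drop medians disconnected at this point (never linked)
    graph.remove_nodes_from(
        [n for n, data in list(graph.nodes(data=True)) if data["kind"] == "median" and graph.degree(n) == 0]
    )

    # contract superfluous median vectors
    changed = True
    while changed:
        changed = False
        for n in list(graph.nodes):
            if graph.nodes[n]["kind"] != "median":
                continue
            deg = graph.degree(n)
            if deg <= 1:
                graph.remove_node(n)
                changed = True
            elif deg == 2:
                u, v = list(graph.neighbors(n))
                graph.remove_node(n)
                if not graph.has_edge(u, v):
                    vu = graph.nodes[u]["vector"]
                    vv = graph.nodes[v]["vector"]
                    diffs = [t for t, (x, y) in enumerate(zip(vu, vv)) if x != y]
                    graph.add_edge(u, v, variants=tuple(diffs), weight=len(diffs))
                changed = True

    if not nx.is_connected(graph):
        raise RuntimeError("reduced-median network construction left the graph disconnected")
    return graph
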