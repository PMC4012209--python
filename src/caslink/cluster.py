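"""Greedy single-linkage protein clustering under coverage and score-density thresholds.

This reproduces the BLASTCLUST partition semantics: two proteins are
*linked* when the optimal local alignment covers at least a fraction
``length_coverage`` of **both** sequences and its score density (bit
score divided by alignment-column count) is at least ``score_density``;
clusters are the connected components of the linked relation.

Defaults are the thresholds used for non-redundant set construction:
length coverage 0.8 and score density 0.8 bits per column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .similarity import (
    AlignmentResult,
    ScoringParams,
    local_align,
    min_raw_score,
    profile,
    sw_score_profile,
    validate_protein,
)


@dataclass(frozen=True)
class ClusteringParams:
    """Thresholds of the linked relation.

    length_coverage
        Minimum aligned-span fraction required on each sequence
        (symmetric requirement; set ``symmetric_coverage=False`` to
        require it on the shorter sequence only).
    score_density
        Minimum bit score per alignment column.
    max_pairs
        Guard on the O(n^2) all-pairs schedule; exceeding it is an error
        rather than a silent long run.
    """

    length_coverage: float = 0.8
    score_density: float = 0.8
    scoring: ScoringParams = field(default_factory=ScoringParams)
    symmetric_coverage: bool = True
    max_pairs: int = 20_000_000

    def __post_init__(self) -> None:
        if self.length_coverage <= 0 or self.score_density <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class ClusterSet:
    """A partition of proteins with one representative per cluster."""

    partition: dict[str, str]  # protein id -> cluster id
    representatives: dict[str, str]  # cluster id -> protein id

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def members(self, cluster_id: str) -> list[str]:
        return sorted(p for p, c in self.partition.items() if c == cluster_id)

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in self.representatives}
        for p, c in sorted(self.partition.items()):
            out[c].append(p)
        return out


def link_decision(a: str, b: str, params: ClusteringParams) -> tuple[bool, AlignmentResult]:
    """Evaluate the linked relation and return the alignment evidence."""
    res = local_align(a, b, params.scoring)
    if res.aln_length == 0:
        return False, res
    cov_a, cov_b = res.coverage_a, res.coverage_b
    if params.symmetric_coverage:
        cov_ok = cov_a >= params.length_coverage and cov_b >= params.length_coverage
    else:
        shorter_cov = cov_a if len(a) <= len(b) else cov_b
        cov_ok = shorter_cov >= params.length_coverage
    return cov_ok and res.score_density >= params.score_density, res


def linked(a: str, b: str, params: ClusteringParams | None = None) -> bool:
    """True iff both coverages and the score density meet their thresholds."""
    return link_decision(a, b, params or ClusteringParams())[0]


class _UnionFind:
    def __init__(self, ids: Sequence[str]):
        self.parent = {i: i for i in ids}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _as_mapping(proteins) -> dict[str, str]:
    if isinstance(proteins, Mapping):
        items = list(proteins.items())
    else:
        items = list(proteins)
    seen: dict[str, str] = {}
    for pid, seq in items:
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r}")
        validate_protein(seq)
        seen[pid] = seq
    if not seen:
        raise ValueError("empty protein list")
    return seen


def single_linkage(
    proteins: Mapping[str, str] | Iterable[tuple[str, str]],
    params: ClusteringParams | None = None,
) -> ClusterSet:
    """Single-linkage clustering over all pairs of the input proteins.

    The partition equals the connected components of the graph whose
    edges are the ``linked`` pairs; it is independent of input order.
    The representative of each cluster is its longest member, ties
    broken by lexicographically smallest id.  Cluster ids are ``C1``,
    ``C2``, ... assigned in order of each cluster's smallest member id.

    A cheap exact prescreen skips the traceback alignment for pairs
    whose optimal raw score is provably below the level any linked pair
    must reach (density * coverage * max length, in bits); the prescreen
    uses the same scoring and therefore never changes the partition.
    """
    p = params or ClusteringParams()
    seqs = _as_mapping(proteins)
    ids = sorted(seqs)
    n = len(ids)
    if n * (n - 1) // 2 > p.max_pairs:
        raise ValueError(
            f"{n} proteins imply {n*(n-1)//2} pairs, above max_pairs={p.max_pairs}"
        )
    uf = _UnionFind(ids)
    codes = {i: p.scoring.encode(seqs[i]) for i in ids}
    profs = {i: profile(codes[i], p.scoring) for i in ids}
    ln2, lnk = math.log(2), math.log(p.scoring.karlin_k)
    for ix in range(n):
        a = ids[ix]
        la = len(seqs[a])
        prof_a = profs[a]
        for jx in range(ix + 1, n):
            b = ids[jx]
            if uf.find(a) == uf.find(b):
                continue
            lmax = max(la, len(seqs[b]))
            # any linked pair aligns >= length_coverage*lmax columns at
            # >= score_density bits/column
            need = min_raw_score(p.score_density * p.length_coverage * lmax, p.scoring)
            raw = sw_score_profile(prof_a, codes[b], p.scoring)
            if raw < need:
                continue
            if link_decision(seqs[a], seqs[b], p)[0]:
                uf.union(a, b)
    comps: dict[str, list[str]] = {}
    for i in ids:
        comps.setdefault(uf.find(i), []).append(i)
    ordered = sorted(comps.values(), key=lambda ms: min(ms))
    partition: dict[str, str] = {}
    representatives: dict[str, str] = {}
    for k, members in enumerate(ordered, start=1):
        cid = f"C{k}"
        # representative: longest member, ties to lexicographically smallest id
        longest = max(len(seqs[m]) for m in members)
        rep = min(m for m in members if len(seqs[m]) == longest)
        representatives[cid] = rep
        for m in members:
            partition[m] = cid
    return ClusterSet(partition=partition, representatives=representatives)


def dereplicate(
    proteins: Mapping[str, str] | Iterable[tuple[str, str]],
    params: ClusteringParams | None = None,
) -> list[str]:
    """One representative id per cluster (the non-redundant subset)."""
    cs = single_linkage(proteins, params)
    return [cs.representatives[c] for c in sorted(cs.representatives, key=_cluster_key)]


def _cluster_key(cid: str) -> int:
    return int(cid[1:])


def write_blastclust(clusters: ClusterSet, handle) -> None:
    """BLASTCLUST output dialect: one line per cluster, representative first."""
    for cid in sorted(clusters.representatives, key=_cluster_key):
        rep = clusters.representatives[cid]
        members = [rep] + [m for m in clusters.members(cid) if m != rep]
        handle.write(" ".join(members) + "\n")
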