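"""Gene-neighborhood extraction and neighbor-family co-occurrence counting.

The neighborhood of a query gene is the window of ``window_k`` genes on
either side on the same replicon (truncated at the ends of a linear
replicon, wrapped without duplication on a circular one).  Neighbor
proteins pooled over all query windows are clustered, clusters are
annotated from a domain-hit table, and two summaries are produced:

* the co-occurrence histogram — for each neighbor family, the number of
  query windows containing at least one member of it (window-level
  presence, not gene counts); and
* the reverse linkage — for a family of query genes, how many of their
  windows contain at least one gene annotated with a *cas* family,
  reported as "total (linked)".

Query genes are excluded from their own windows' clustering pool, so a
query never counts as its own neighbor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import GeneRecord, Replicon
from .cluster import ClusteringParams, ClusterSet, single_linkage

logger = logging.getLogger(__name__)

HIT_COLUMNS = ["protein_id", "family", "start", "end", "evalue", "score"]
DEFAULT_EVALUE_CUTOFF = 0.01


@dataclass(frozen=True)
class NeighborhoodParams:
    """window_k genes each side of the query; pseudogenes count as positions."""

    window_k: int = 10
    include_pseudo_positions: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.window_k <= 25:
            raise ValueError("window_k must be in [1, 25]")


@dataclass(frozen=True)
class NeighborhoodWindow:
    """A contiguous run of genes around (and including) one query gene."""

    query: GeneRecord
    members: tuple[GeneRecord, ...]
    replicon_id: str
    genome_id: str

    def __post_init__(self) -> None:
        if self.query.locus_tag not in {m.locus_tag for m in self.members}:
            raise ValueError("query gene must be a window member")

    @property
    def neighbor_genes(self) -> tuple[GeneRecord, ...]:
        return tuple(m for m in self.members if m.index != self.query.index)

    @property
    def member_indices(self) -> tuple[int, ...]:
        return tuple(m.index for m in self.members)


def extract_window(
    replicon: Replicon, query_index: int, params: NeighborhoodParams | None = None
) -> NeighborhoodWindow:
    """Window of genes with index in [query-k, query+k] on one replicon.

    Linear replicons truncate at their ends; circular replicons wrap,
    capped at the replicon's gene count so no gene appears twice.  When
    ``include_pseudo_positions`` is false, pseudogenes are dropped from
    the member list but still occupy index positions (the window does
    not extend to compensate).
    """
    p = params or NeighborhoodParams()
    n = len(replicon.genes)
    if not 0 <= query_index < n:
        raise IndexError(f"query index {query_index} out of range (replicon has {n} genes)")
    k = p.window_k
    if replicon.topology == "circular":
        if 2 * k + 1 >= n:
            offsets = range(-(n // 2), n - n // 2)
            idx = [(query_index + o) % n for o in offsets]
        else:
            idx = [(query_index + o) % n for o in range(-k, k + 1)]
    else:
        idx = list(range(max(0, query_index - k), min(n, query_index + k + 1)))
    members = tuple(replicon.genes[i] for i in idx)
    if not p.include_pseudo_positions:
        members = tuple(
            m for m in members if (not m.is_pseudo) or m.index == query_index
        )
    return NeighborhoodWindow(
        query=replicon.genes[query_index],
        members=members,
        replicon_id=replicon.replicon_id,
        genome_id=replicon.genome_id,
    )


def pool_and_cluster(
    windows: Sequence[NeighborhoodWindow],
    cparams: ClusteringParams | None = None,
) -> ClusterSet:
    """Cluster the union of neighbor proteins across windows.

    Query genes are excluded from the pool; a protein shared between
    overlapping windows enters once.  Genes without a usable protein
    (pseudo, partial, or no sequence) are skipped — they occupy window
    positions but cannot be clustered.
    """
    if not windows:
        raise ValueError("no windows to pool")
    query_ids = {w.query.protein_id for w in windows if w.query.protein_id}
    pool: dict[str, str] = {}
    for w in windows:
        for g in w.neighbor_genes:
            if g.protein_id is None or g.protein_seq is None:
                continue
            if g.is_pseudo or g.is_partial:
                continue
            if g.protein_id in query_ids:
                continue
            pool[g.protein_id] = g.protein_seq
    if not pool:
        return ClusterSet(partition={}, representatives={})
    return single_linkage(pool, cparams)


# ---------------------------------------------------------------------------
# Domain-hit tables and cluster annotation


def read_hits(path, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> pd.DataFrame:
    """Read a domain-hit TSV (hmmscan/rpsblast style) and apply the e-value filter."""
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: hit table missing columns {sorted(missing)}")
    return filter_hits(df, evalue_cutoff)


def filter_hits(hits: pd.DataFrame, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> pd.DataFrame:
    return hits[hits["evalue"] <= evalue_cutoff].reset_index(drop=True)


@dataclass(frozen=True)
class FamilyAnnotation:
    """Cluster id -> family label; clusters without hits are labelled "unknown"."""

    labels: dict[str, str]

    def label(self, cluster_id: str) -> str:
        return self.labels.get(cluster_id, "unknown")

    @property
    def n_unknown(self) -> int:
        return sum(1 for v in self.labels.values() if v == "unknown")


def annotate_clusters(
    clusters: ClusterSet,
    hits: pd.DataFrame,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> FamilyAnnotation:
    """Label each cluster with the most frequent hit family among its members.

    Ties are broken by the best (lowest) e-value among the tied families;
    clusters whose members have no hits are labelled ``"unknown"``.
    """
    hits = filter_hits(hits, evalue_cutoff)
    by_protein: dict[str, pd.DataFrame] = (
        {pid: grp for pid, grp in hits.groupby("protein_id")} if len(hits) else {}
    )
    labels: dict[str, str] = {}
    for cid, members in clusters.clusters().items():
        fam_count: dict[str, int] = {}
        fam_best: dict[str, float] = {}
        for pid in members:
            grp = by_protein.get(pid)
            if grp is None:
                continue
            for fam, ev in zip(grp["family"], grp["evalue"]):
                fam_count[fam] = fam_count.get(fam, 0) + 1
                fam_best[fam] = min(fam_best.get(fam, float("inf")), float(ev))
        if not fam_count:
            labels[cid] = "unknown"
        else:
            labels[cid] = min(
                fam_count, key=lambda f: (-fam_count[f], fam_best[f], f)
            )
    return FamilyAnnotation(labels=labels)


def protein_families(
    hits: pd.DataFrame, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> dict[str, str]:
    """Per-protein best-hit family (lowest e-value, ties by score then name)."""
    hits = filter_hits(hits, evalue_cutoff)
    best: dict[str, tuple[float, float, str]] = {}
    for pid, fam, ev, score in zip(
        hits["protein_id"], hits["family"], hits["evalue"], hits["score"]
    ):
        key = (float(ev), -float(score), fam)
        if pid not in best or key < best[pid]:
            best[pid] = key
    return {pid: key[2] for pid, key in best.items()}


# ---------------------------------------------------------------------------
# Co-occurrence summaries


@dataclass(frozen=True)
class CoOccurrenceTable:
    """family -> number of query windows containing >= 1 member of it."""

    counts: dict[str, int]
    total_queries: int

    def __post_init__(self) -> None:
        bad = {f: c for f, c in self.counts.items() if c > self.total_queries}
        if bad:
            raise ValueError(f"counts exceed total query count: {bad}")

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["family", "n_windows"]).assign(
            total_queries=self.total_queries
        )


def cooccurrence(
    windows: Sequence[NeighborhoodWindow],
    clusters: ClusterSet,
    annotation: FamilyAnnotation,
) -> CoOccurrenceTable:
    """Window-level presence histogram of neighbor families.

    For each family label, counts the query windows with at least one
    neighbor whose cluster carries that label.  The query gene itself is
    never counted.
    """
    counts: dict[str, int] = {}
    for w in windows:
        fams = set()
        for g in w.neighbor_genes:
            if g.protein_id is None:
                continue
            cid = clusters.partition.get(g.protein_id)
            if cid is None:
                continue
            fams.add(annotation.label(cid))
        for fam in fams:
            counts[fam] = counts.get(fam, 0) + 1
    return CoOccurrenceTable(counts=counts, total_queries=len(windows))


def reverse_cas_linkage(
    windows: Sequence[NeighborhoodWindow],
    family_of: Mapping[str, str],
    cas_labels: Iterable[str],
) -> tuple[int, int]:
    """(total, cas_linked) for a set of query windows.

    ``cas_linked`` counts windows containing at least one neighbor gene
    annotated (via ``family_of``, typically the per-protein best hit)
    with any family in ``cas_labels``.  The query gene is excluded.
    """
    cas = set(cas_labels)
    linked = 0
    for w in windows:
        if any(
            g.protein_id is not None and family_of.get(g.protein_id) in cas
            for g in w.neighbor_genes
        ):
            linked += 1
    return len(windows), linked


def format_linkage(total: int, linked: int) -> str:
    """The figure convention: "total (cas_linked)"."""
    return f"{total} ({linked})"
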