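"""CRISPR-Cas locus calling, system typing, and association tables.

A *locus* is a maximal run of cas-annotated genes on one replicon,
merged across gaps of at most ``locus_max_gap`` intervening non-cas
genes.  System types are assigned from signature families:

* cas3  -> type I
* cas9  -> type II
* cas10 -> type III, resolved to III-A by csm2 or III-B by cmr5
  (cas10 without either subtype marker -> III-unspecified)

cas1/cas2/cas4 mark the adaptation module and are cas genes but not
signatures; a locus with cas genes and no signature is "unknown".  A
locus carrying conflicting signatures reports all matching types and is
flagged composite.

On top of locus calls the module computes the per-family association
table (how many query genes lie near a locus of each type), the
genome-level co-occurrence partition (type III systems co-occurring
with type I/II versus standing alone), and the cas1/cas10 presence
summary for a genome collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import Replicon
from .neighborhood import NeighborhoodWindow

ROLES = {
    "signature_type_I",
    "signature_type_II",
    "signature_type_III",
    "signature_III-A",
    "signature_III-B",
    "adaptation",
    "other_cas",
}

DEFAULT_SIGNATURE_ROLES = {
    "cas3": "signature_type_I",
    "cas9": "signature_type_II",
    "cas10": "signature_type_III",
    "csm2": "signature_III-A",
    "cmr5": "signature_III-B",
    "cas1": "adaptation",
    "cas2": "adaptation",
    "cas4": "adaptation",
    "csx19": "other_cas",
    "csx15": "other_cas",
}

TYPES = ("I", "II", "III-A", "III-B")


@dataclass(frozen=True)
class CasSignatureTable:
    """family -> role mapping plus the locus gap tolerance."""

    roles: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SIGNATURE_ROLES))
    locus_max_gap: int = 2

    def __post_init__(self) -> None:
        bad = {f: r for f, r in self.roles.items() if r not in ROLES}
        if bad:
            raise ValueError(f"unknown signature roles: {bad}")
        if self.locus_max_gap < 0:
            raise ValueError("locus_max_gap must be >= 0")

    @property
    def cas_families(self) -> frozenset[str]:
        return frozenset(self.roles)

    @classmethod
    def from_tsv(cls, path, locus_max_gap: int = 2) -> "CasSignatureTable":
        """Two-column TSV (family, role), header optional."""
        roles: dict[str, str] = {}
        for ln in Path(path).read_text().splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            fam, role = ln.split("\t")[:2]
            if fam == "family" and role == "role":
                continue
            roles[fam] = role
        return cls(roles=roles, locus_max_gap=locus_max_gap)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("family\trole\n")
            for fam in sorted(self.roles):
                fh.write(f"{fam}\t{self.roles[fam]}\n")


@dataclass(frozen=True)
class CrisprLocusCall:
    """A gapped-maximal run of cas genes with its assigned system type."""

    genome_id: str
    replicon_id: str
    start_index: int  # gene index of first cas gene
    end_index: int  # gene index of last cas gene (inclusive)
    member_families: tuple[str, ...]  # cas families in gene order
    assigned_type: str = "unknown"
    all_types: tuple[str, ...] = ()
    composite: bool = False

    def __post_init__(self) -> None:
        if not self.member_families:
            raise ValueError("locus without cas genes")
        if self.start_index > self.end_index:
            raise ValueError("locus span inverted")

    def overlaps_indices(self, indices: Iterable[int]) -> bool:
        return any(self.start_index <= i <= self.end_index for i in indices)

    def distance_to_index(self, i: int) -> int:
        if self.start_index <= i <= self.end_index:
            return 0
        return min(abs(i - self.start_index), abs(i - self.end_index))


def call_loci(
    replicon: Replicon,
    family_of: Mapping[str, str],
    sig: CasSignatureTable | None = None,
) -> list[CrisprLocusCall]:
    """Maximal runs of cas-family genes merged across gaps <= locus_max_gap.

    ``family_of`` maps protein id to family label (from a domain-hit
    table or cluster annotation); genes mapping to a family in the
    signature table count as cas genes.  Pseudo and partial genes never
    count as cas genes but do count toward gap length.  Each merged run
    is returned as one typed locus.  The operation is idempotent and
    depends only on the replicon's gene order.
    """
    sig = sig or CasSignatureTable()
    cas_idx: list[int] = []
    for g in replicon.genes:
        if g.is_pseudo or g.is_partial or g.protein_id is None:
            continue
        if family_of.get(g.protein_id) in sig.cas_families:
            cas_idx.append(g.index)
    loci: list[CrisprLocusCall] = []
    run: list[int] = []
    for i in cas_idx:
        if run and i - run[-1] - 1 > sig.locus_max_gap:
            loci.append(_make_locus(replicon, run, family_of, sig))
            run = []
        run.append(i)
    if run:
        loci.append(_make_locus(replicon, run, family_of, sig))
    return loci


def _make_locus(
    replicon: Replicon,
    run: list[int],
    family_of: Mapping[str, str],
    sig: CasSignatureTable,
) -> CrisprLocusCall:
    fams = tuple(family_of[replicon.genes[i].protein_id] for i in run)
    locus = CrisprLocusCall(
        genome_id=replicon.genome_id,
        replicon_id=replicon.replicon_id,
        start_index=run[0],
        end_index=run[-1],
        member_families=fams,
    )
    return assign_type(locus, sig)


def assign_type(locus: CrisprLocusCall, sig: CasSignatureTable | None = None) -> CrisprLocusCall:
    """Return the locus with its system type(s) filled in from signatures."""
    sig = sig or CasSignatureTable()
    roles = {sig.roles.get(f) for f in locus.member_families}
    types: list[str] = []
    if "signature_type_I" in roles:
        types.append("I")
    if "signature_type_II" in roles:
        types.append("II")
    if "signature_type_III" in roles:
        has_a = "signature_III-A" in roles
        has_b = "signature_III-B" in roles
        if has_a:
            types.append("III-A")
        if has_b:
            types.append("III-B")
        if not (has_a or has_b):
            types.append("III-unspecified")
    if not types:
        assigned = "unknown"
    else:
        assigned = types[0]
    composite = len(types) > 1
    return CrisprLocusCall(
        genome_id=locus.genome_id,
        replicon_id=locus.replicon_id,
        start_index=locus.start_index,
        end_index=locus.end_index,
        member_families=locus.member_families,
        assigned_type=assigned,
        all_types=tuple(types),
        composite=composite,
    )


# ---------------------------------------------------------------------------
# Association tables


@dataclass(frozen=True)
class AssociationRow:
    family: str
    total: int
    near_cas: int
    per_type: dict[str, int]

    def __post_init__(self) -> None:
        if self.near_cas > self.total:
            raise ValueError("near_cas exceeds total")


@dataclass(frozen=True)
class AssociationTable:
    """Per query family: total genes, genes near cas, and per-type counts."""

    rows: dict[str, AssociationRow]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for fam in sorted(self.rows):
            r = self.rows[fam]
            rec = {"family": fam, "total": r.total, "near_cas": r.near_cas}
            for t in TYPES + ("III-unspecified", "unknown"):
                rec[t] = r.per_type.get(t, 0)
            recs.append(rec)
        return pd.DataFrame(recs)


def family_type_association(
    query_windows: Mapping[str, Sequence[NeighborhoodWindow]],
    loci: Sequence[CrisprLocusCall],
) -> AssociationTable:
    """Count, per query family, genes near loci of each CRISPR-Cas type.

    A query gene is ``near_cas`` when its window overlaps any called
    locus span on the same replicon; it is associated with the type of
    the nearest overlapping locus (gene-index distance).  When two loci
    of different types tie for nearest, both types are counted and the
    tie does not inflate ``near_cas``.
    """
    by_replicon: dict[tuple[str, str], list[CrisprLocusCall]] = {}
    for lc in loci:
        by_replicon.setdefault((lc.genome_id, lc.replicon_id), []).append(lc)
    rows: dict[str, AssociationRow] = {}
    for fam, windows in query_windows.items():
        total = len(windows)
        near = 0
        per_type: dict[str, int] = {}
        for w in windows:
            cands = [
                lc
                for lc in by_replicon.get((w.genome_id, w.replicon_id), [])
                if lc.overlaps_indices(w.member_indices)
            ]
            if not cands:
                continue
            near += 1
            dmin = min(lc.distance_to_index(w.query.index) for lc in cands)
            nearest = [lc for lc in cands if lc.distance_to_index(w.query.index) == dmin]
            types = sorted({lc.assigned_type for lc in nearest})
            for t in types:
                per_type[t] = per_type.get(t, 0) + 1
        rows[fam] = AssociationRow(family=fam, total=total, near_cas=near, per_type=per_type)
    return AssociationTable(rows=rows)


# ---------------------------------------------------------------------------
# Genome-level inventories


@dataclass(frozen=True)
class GenomeInventory:
    """Per-genome presence of system types, signature genes and query families."""

    genome_id: str
    types_present: frozenset[str]
    has_cas1: bool
    has_cas10: bool
    carf_families: frozenset[str]
    carf_with_effector: bool

    @property
    def has_carf(self) -> bool:
        return bool(self.carf_families)


def build_inventory(
    genome_id: str,
    loci: Sequence[CrisprLocusCall],
    family_of: Mapping[str, str],
    genome_protein_ids: Iterable[str],
    carf_families: Iterable[str],
    effector_proteins: Iterable[str] = (),
) -> GenomeInventory:
    """Assemble one genome's inventory from its locus calls and annotations.

    ``types_present`` is derived only from called loci (all matching
    types of composite loci included).  ``effector_proteins`` is the set
    of protein ids classified effector-bearing by the architecture
    module.
    """
    carf_set = set(carf_families)
    eff = set(effector_proteins)
    fams_present: set[str] = set()
    carf_eff = False
    for pid in genome_protein_ids:
        fam = family_of.get(pid)
        if fam in carf_set:
            fams_present.add(fam)
            if pid in eff:
                carf_eff = True
    types: set[str] = set()
    for lc in loci:
        types.update(t for t in lc.all_types)
    genome_fams = {family_of.get(pid) for pid in genome_protein_ids}
    return GenomeInventory(
        genome_id=genome_id,
        types_present=frozenset(types),
        has_cas1="cas1" in genome_fams,
        has_cas10="cas10" in genome_fams,
        carf_families=frozenset(fams_present),
        carf_with_effector=carf_eff,
    )


GENOME_CATEGORIES = ("III_cooccurring", "III_sole", "I_only", "II_only", "none")


def genome_category(inv: GenomeInventory) -> str:
    """Partition a genome by its CRISPR-Cas type content."""
    has_iii = any(t.startswith("III") for t in inv.types_present)
    has_i = "I" in inv.types_present
    has_ii = "II" in inv.types_present
    if has_iii and (has_i or has_ii):
        return "III_cooccurring"
    if has_iii:
        return "III_sole"
    if has_i and not has_ii:
        return "I_only"
    if has_ii and not has_i:
        return "II_only"
    if has_i and has_ii:
        return "I_only"  # I+II without III: folded into I_only to keep a partition
    return "none"


def genome_cooccurrence(inventories: Sequence[GenomeInventory]) -> pd.DataFrame:
    """Genome counts by type category, cross-tabulated with effector-CARF presence.

    Genomes carrying both type I and type II (and no III) are counted
    under both single-type columns' complement — they fall in a joint
    "I_only"/"II_only" boundary; here they are reported under I_only to
    keep the partition disjoint (the synthetic templates never co-place
    I and II without III, so the case is a real-data corner only).
    """
    recs = []
    for cat in GENOME_CATEGORIES:
        with_eff = sum(
            1
            for inv in inventories
            if genome_category(inv) == cat and inv.carf_with_effector
        )
        without = sum(
            1
            for inv in inventories
            if genome_category(inv) == cat and not inv.carf_with_effector
        )
        recs.append(
            {
                "category": cat,
                "n_genomes": with_eff + without,
                "carf_with_effector": with_eff,
                "carf_without_effector": without,
            }
        )
    return pd.DataFrame(recs)


def presence_summary(
    inventories: Sequence[GenomeInventory],
) -> tuple[int, int]:
    """(genomes with the query family, of those, genomes lacking both cas1 and cas10)."""
    with_query = [inv for inv in inventories if inv.has_carf]
    lacking = sum(1 for inv in with_query if not inv.has_cas1 and not inv.has_cas10)
    return len(with_query), lacking
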