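"""Domain architectures, effector classification, and the CARF sequence motif.

A protein's architecture is the ordered list of domain families along
its sequence after resolving overlapping hits.  Resolution is greedy by
ascending e-value (ties: higher score, then smaller start): a hit is
kept if it overlaps every already-kept hit by at most 30% of the
shorter interval.

CARF proteins are classified by whether a catalytic effector domain
(HEPN, PIN, RelE, ... — typically a nuclease) lies C-terminal of the
CARF domain: such proteins are predicted ligand-activated toxins, while
CARF proteins carrying only DNA-binding domains (wHTH and similar) are
predicted transcriptional regulators.

The ligand-binding site of the CARF domain is marked by the linear
motif [DN]-x-[ST]-x-x-x-[RK]; :func:`scan_motif` finds its occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

DEFAULT_EVALUE_CUTOFF = 0.01
DEFAULT_OVERLAP_TOLERANCE = 0.30


@dataclass(frozen=True)
class DomainHit:
    """One domain assignment on one protein (1-based inclusive residue coords)."""

    protein_id: str
    family: str
    start: int
    end: int
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"hit {self.family} on {self.protein_id}: start > end")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "DomainHit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass(frozen=True)
class Architecture:
    """Ordered, non-overlapping domain families of one protein."""

    protein_id: str
    domains: tuple[DomainHit, ...]  # ordered by start

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(d.family for d in self.domains)

    def __str__(self) -> str:
        return "+".join(self.families) if self.domains else "(none)"


@dataclass(frozen=True)
class EffectorConfig:
    """Domain families counting as catalytic effectors vs DNA-binding domains."""

    carf_families: frozenset[str] = frozenset({"CARF"})
    effector_families: frozenset[str] = frozenset(
        {"HEPN", "PIN", "RelE", "REase", "HD", "Ada", "HNH", "Csx15"}
    )
    dbd_families: frozenset[str] = frozenset({"wHTH", "6H"})

    def __post_init__(self) -> None:
        if self.effector_families & self.dbd_families:
            raise ValueError("effector and DNA-binding family sets must be disjoint")


def hits_from_frame(df: pd.DataFrame, protein_id: str | None = None) -> list[DomainHit]:
    """Rows of a hit table as :class:`DomainHit` objects (optionally one protein)."""
    if protein_id is not None:
        df = df[df["protein_id"] == protein_id]
    return [
        DomainHit(
            protein_id=r.protein_id,
            family=r.family,
            start=int(r.start),
            end=int(r.end),
            evalue=float(r.evalue),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]


def resolve_overlaps(
    hits: Sequence[DomainHit],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    overlap_tolerance: float = DEFAULT_OVERLAP_TOLERANCE,
) -> Architecture:
    """Greedy overlap resolution of one protein's domain hits.

    Hits above the e-value cutoff are dropped first.  Remaining hits are
    taken in order of (evalue asc, score desc, start asc, family) and
    kept when their overlap with every kept hit is at most
    ``overlap_tolerance`` of the shorter of the two intervals.
    """
    if not hits:
        raise ValueError("no hits supplied")
    pids = {h.protein_id for h in hits}
    if len(pids) != 1:
        raise ValueError(f"hits span several proteins: {sorted(pids)}")
    pid = hits[0].protein_id
    usable = [h for h in hits if h.evalue <= evalue_cutoff]
    order = sorted(usable, key=lambda h: (h.evalue, -h.score, h.start, h.family))
    kept: list[DomainHit] = []
    for h in order:
        ok = True
        for k in kept:
            if h.overlap(k) > overlap_tolerance * min(h.length, k.length):
                ok = False
                break
        if ok:
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end, h.family))
    return Architecture(protein_id=pid, domains=tuple(kept))


def classify_effector(arch: Architecture, cfg: EffectorConfig | None = None) -> str:
    """"effector_bearing", "regulatory_only" or "no_carf".

    effector_bearing requires a CARF domain with at least one effector
    family strictly C-terminal of it (start beyond the CARF interval's
    end); any other CARF-containing architecture is regulatory_only.
    Non-effector, non-CARF domains never change the outcome.
    """
    cfg = cfg or EffectorConfig()
    carf_hits = [d for d in arch.domains if d.family in cfg.carf_families]
    if not carf_hits:
        return "no_carf"
    for carf in carf_hits:
        for d in arch.domains:
            if d.family in cfg.effector_families and d.start > carf.end:
                return "effector_bearing"
    return "regulatory_only"


@dataclass(frozen=True)
class MotifPattern:
    """A linear motif as a tuple of allowed-residue classes ("X" = any)."""

    classes: tuple[str, ...] = ("DN", "X", "ST", "X", "X", "X", "RK")

    def __len__(self) -> int:
        return len(self.classes)


CARF_MOTIF = MotifPattern()  # [DN]X[ST]XXX[RK]


def scan_motif(seq: str, pattern: MotifPattern | None = None) -> list[int]:
    """All 1-based start positions where the motif matches the sequence."""
    pat = pattern or CARF_MOTIF
    m = len(pat)
    out: list[int] = []
    for i in range(len(seq) - m + 1):
        for cls, res in zip(pat.classes, seq[i : i + m]):
            if cls != "X" and res not in cls:
                break
        else:
            out.append(i + 1)
    return out


def architectures_table(archs: Sequence[Architecture]) -> pd.DataFrame:
    """TSV-ready table: protein_id, architecture joined with "+"."""
    return pd.DataFrame(
        [{"protein_id": a.protein_id, "architecture": str(a)} for a in archs]
    )
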