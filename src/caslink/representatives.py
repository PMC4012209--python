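"""Genus-level representative-genome selection.

One genome is kept per genus: the genome with the largest total size,
except for genera with a named model-organism override (classically
Bacillus subtilis 168 and Escherichia coli K12 substr. MG1655).  Size
ties break to the lexicographically smallest genome id, so selection is
deterministic and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .annotation_io import TaxonInfo

DEFAULT_OVERRIDES = {
    "Bacillus": "Bacillus subtilis 168",
    "Escherichia": "Escherichia coli K12 substr. MG1655",
}


@dataclass(frozen=True)
class SelectionOverrides:
    """genus -> exact species label that must be selected for that genus."""

    by_genus: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_OVERRIDES))


def select_representatives(
    taxa: Sequence[TaxonInfo],
    overrides: SelectionOverrides | None = None,
) -> list[str]:
    """One genome id per genus, sorted by genus name.

    An override applies only when its genus occurs in the collection; it
    names a species label that must then be present, otherwise selection
    fails.  All other genera take the genome with the largest
    ``total_genome_size_bp`` (ties: smallest genome_id).
    """
    ov = (overrides or SelectionOverrides()).by_genus
    by_genus: dict[str, list[TaxonInfo]] = {}
    for t in taxa:
        by_genus.setdefault(t.genus, []).append(t)
    chosen: list[str] = []
    for genus in sorted(by_genus):
        members = by_genus[genus]
        if genus in ov:
            matches = [t for t in members if t.species == ov[genus]]
            if not matches:
                raise ValueError(
                    f"override for genus {genus} names {ov[genus]!r}, "
                    "absent from the collection"
                )
            chosen.append(min(m.genome_id for m in matches))
        else:
            best = min(members, key=lambda t: (-t.total_genome_size_bp, t.genome_id))
            chosen.append(best.genome_id)
    return chosen
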