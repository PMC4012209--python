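"""Genome annotation I/O: GenBank flat files, NCBI PTT tables and protein FASTA.

All formats are normalised into a uniform per-replicon gene table
(:class:`Replicon` holding ordered :class:`GeneRecord` rows).  Coordinates
are 1-based inclusive throughout, the PTT "Location" convention, so no
conversion happens at module boundaries.

A gene spanning the origin of a circular replicon keeps its annotated
start/end (end may numerically precede start) and is flagged via
``wraps_origin``; it is indexed by its start coordinate like any other
gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    AfterPosition,
    BeforePosition,
    ExactPosition,
    FeatureLocation,
    SeqFeature,
)
from Bio.SeqRecord import SeqRecord

from .similarity import VALID_RESIDUES

logger = logging.getLogger(__name__)

PTT_COLUMNS = [
    "Location",
    "Strand",
    "Length",
    "PID",
    "Gene",
    "Synonym",
    "Code",
    "COG",
    "Product",
]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated protein-coding gene on a replicon."""

    locus_tag: str
    protein_id: str | None
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"
    product: str
    protein_seq: str | None
    is_partial: bool = False
    is_pseudo: bool = False
    index: int = 0
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start > self.end and not self.wraps_origin:
            raise ValueError(
                f"gene {self.locus_tag}: start {self.start} > end {self.end} "
                "on a non-origin-spanning gene"
            )
        if self.protein_seq is not None:
            bad = set(self.protein_seq) - VALID_RESIDUES
            if bad:
                raise ValueError(
                    f"gene {self.locus_tag}: non-standard residue(s) {sorted(bad)}"
                )


@dataclass(frozen=True)
class Replicon:
    """An ordered gene table for one replicon of one genome."""

    genome_id: str
    replicon_id: str
    length_bp: int
    topology: str  # "linear" or "circular"
    genes: tuple[GeneRecord, ...]

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise ValueError(f"replicon {self.replicon_id}: genes not sorted by start")
        for i, g in enumerate(self.genes):
            if g.index != i:
                raise ValueError(f"replicon {self.replicon_id}: bad gene index at {i}")
            if self.topology == "linear" and not 1 <= g.start <= g.end <= self.length_bp:
                raise ValueError(
                    f"gene {g.locus_tag} outside [1, {self.length_bp}]"
                )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class TaxonInfo:
    genome_id: str
    genus: str
    species: str
    total_genome_size_bp: int

    def __post_init__(self) -> None:
        if self.total_genome_size_bp <= 0:
            raise ValueError("total_genome_size_bp must be positive")


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping from :func:`filter_incomplete`."""

    n_input: int
    n_kept: int
    n_partial: int
    n_pseudo: int
    n_missing_seq: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept


def _sort_and_index(genes: list[GeneRecord]) -> tuple[GeneRecord, ...]:
    ordered = sorted(genes, key=lambda g: (g.start, g.end, g.locus_tag))
    return tuple(replace(g, index=i) for i, g in enumerate(ordered))


class AnnotationParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GenBank


def read_genbank(path, genome_id: str | None = None) -> list[Replicon]:
    """Parse a GenBank flat file into one :class:`Replicon` per LOCUS record.

    Each CDS feature becomes one :class:`GeneRecord`; the translation is
    taken from the ``/translation`` qualifier when present.  A ``/pseudo``
    qualifier sets ``is_pseudo``; a fuzzy location operator (``<``/``>``)
    or a ``/partial`` qualifier sets ``is_partial``.  A CDS without a
    usable location is skipped with a warning.

    ``genome_id`` defaults to the first whitespace token of the record
    DEFINITION line, falling back to the record name.
    """
    path = Path(path)
    replicons: list[Replicon] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise AnnotationParseError(f"malformed GenBank file {path}: {exc}") from exc
    if not records:
        raise AnnotationParseError(f"no LOCUS records in {path}")
    for rec in records:
        try:
            replicons.append(_record_to_replicon(rec, genome_id))
        except AnnotationParseError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise AnnotationParseError(f"malformed LOCUS {rec.name}: {exc}") from exc
    return replicons


def _record_to_replicon(rec: SeqRecord, genome_id: str | None) -> Replicon:
    gid = genome_id
    if gid is None:
        desc = (rec.description or "").strip()
        gid = desc.split()[0] if desc else rec.name
    topology = rec.annotations.get("topology", "linear")
    genes: list[GeneRecord] = []
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        if feat.location is None:
            logger.warning("LOCUS %s: CDS without location skipped", rec.name)
            continue
        quals = feat.qualifiers
        start = int(feat.location.start) + 1  # to 1-based inclusive
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        fuzzy = isinstance(feat.location.start, BeforePosition) or isinstance(
            feat.location.end, AfterPosition
        )
        is_partial = fuzzy or "partial" in quals
        is_pseudo = "pseudo" in quals or "pseudogene" in quals
        translation = quals.get("translation", [None])[0]
        genes.append(
            GeneRecord(
                locus_tag=quals.get("locus_tag", [f"CDS_{start}"])[0],
                protein_id=quals.get("protein_id", [None])[0],
                start=start,
                end=end,
                strand=strand,
                product=quals.get("product", [""])[0],
                protein_seq=translation,
                is_partial=is_partial,
                is_pseudo=is_pseudo,
            )
        )
    return Replicon(
        genome_id=gid,
        replicon_id=rec.name,
        length_bp=len(rec.seq),
        topology=topology,
        genes=_sort_and_index(genes),
    )


def write_genbank(replicons: list[Replicon], path, definition_genome_id: bool = True) -> None:
    """Serialize replicons as a GenBank flat file (one LOCUS per replicon).

    The nucleotide sequence is not modelled; an all-N placeholder of the
    annotated length is written.  The LOCUS date is fixed so output is
    byte-reproducible.
    """
    records = []
    for rep in replicons:
        rec = SeqRecord(
            Seq("N" * rep.length_bp),
            id=rep.replicon_id,
            name=rep.replicon_id,
            description=f"{rep.genome_id} replicon {rep.replicon_id}"
            if definition_genome_id
            else rep.replicon_id,
        )
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = rep.topology
        rec.annotations["date"] = "01-JAN-2000"
        for g in rep.genes:
            start_pos = (
                BeforePosition(g.start - 1) if g.is_partial else ExactPosition(g.start - 1)
            )
            end_pos = ExactPosition(g.end)
            loc = FeatureLocation(start_pos, end_pos, strand=1 if g.strand == "+" else -1)
            quals: dict[str, list[str]] = {"locus_tag": [g.locus_tag]}
            if g.product:
                quals["product"] = [g.product]
            if g.protein_id:
                quals["protein_id"] = [g.protein_id]
            if g.is_pseudo:
                quals["pseudo"] = [""]
            if g.protein_seq:
                quals["translation"] = [g.protein_seq]
            rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


# ---------------------------------------------------------------------------
# PTT + FASTA


def read_fasta(path) -> dict[str, str]:
    """Protein FASTA as an id -> sequence mapping (first header token is the id)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise AnnotationParseError(f"duplicate FASTA id {rec.id}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: dict[str, str], path, descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for pid, seq in seqs.items():
            desc = (descriptions or {}).get(pid, "")
            header = f">{pid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_ptt(
    ptt_path,
    faa_path,
    genome_id: str | None = None,
    replicon_id: str | None = None,
) -> Replicon:
    """Parse an NCBI PTT table plus its protein FASTA into a :class:`Replicon`.

    The PTT format has two header lines (title, "<n> proteins") followed
    by the 9-column header row and one row per protein.  A tenth
    ``Flags`` column (comma-separated ``partial``/``pseudo``) is accepted
    as a sidecar for flags the canonical format cannot carry.  Sequences
    are joined from the FASTA by PID, falling back to Synonym; unmatched
    rows keep ``protein_seq`` absent with a warning.
    """
    ptt_path = Path(ptt_path)
    lines = ptt_path.read_text().splitlines()
    if len(lines) < 3:
        raise AnnotationParseError(f"{ptt_path}: missing PTT header lines")
    title = lines[0].strip()
    if "proteins" not in lines[1]:
        raise AnnotationParseError(f"{ptt_path}: second header line must count proteins")
    header = lines[2].split("\t")
    if header[: len(PTT_COLUMNS)] != PTT_COLUMNS:
        raise AnnotationParseError(f"{ptt_path}: unexpected column header {header!r}")
    has_flags = len(header) > len(PTT_COLUMNS) and header[len(PTT_COLUMNS)] == "Flags"
    seqs = read_fasta(faa_path)
    # title convention: "<genome_id> <replicon_id> - <length_bp> bp"
    toks = title.split()
    gid = genome_id or (toks[0] if toks else ptt_path.stem)
    rid = replicon_id or (toks[1] if len(toks) > 1 else ptt_path.stem)
    length_bp = 0
    if "bp" in toks:
        length_bp = int(toks[toks.index("bp") - 1])
    genes: list[GeneRecord] = []
    seen_pids: set[str] = set()
    for ln in lines[3:]:
        if not ln.strip():
            continue
        cols = ln.split("\t")
        if len(cols) < len(PTT_COLUMNS):
            raise AnnotationParseError(f"{ptt_path}: short row {ln!r}")
        loc, strand, _length, pid, _gene, synonym, _code, _cog, product = cols[:9]
        flags = cols[9].split(",") if has_flags and len(cols) > 9 and cols[9] else []
        start_s, end_s = loc.split("..")
        pid = pid if pid not in ("-", "") else None
        if pid is not None:
            if pid in seen_pids:
                raise AnnotationParseError(f"{ptt_path}: duplicate PID {pid}")
            seen_pids.add(pid)
        seq = None
        if pid is not None:
            seq = seqs.get(pid) or seqs.get(synonym)
            if seq is None:
                logger.warning("%s: PID %s absent from FASTA", ptt_path.name, pid)
        genes.append(
            GeneRecord(
                locus_tag=synonym,
                protein_id=pid,
                start=int(start_s),
                end=int(end_s),
                strand=strand,
                product=product,
                protein_seq=seq,
                is_partial="partial" in flags,
                is_pseudo="pseudo" in flags,
            )
        )
    indexed = _sort_and_index(genes)
    length_bp = length_bp or (max(g.end for g in indexed) if indexed else 1)
    return Replicon(
        genome_id=gid,
        replicon_id=rid,
        length_bp=length_bp,
        topology="linear",
        genes=indexed,
    )


def write_ptt(replicon: Replicon, ptt_path, faa_path) -> None:
    """Write the PTT table (with the sidecar Flags column) and its FASTA."""
    rows = []
    seqs: dict[str, str] = {}
    descs: dict[str, str] = {}
    for g in replicon.genes:
        aa_len = len(g.protein_seq) if g.protein_seq else (g.end - g.start + 1) // 3 - 1
        flags = ",".join(
            f for f, on in (("partial", g.is_partial), ("pseudo", g.is_pseudo)) if on
        )
        rows.append(
            "\t".join(
                [
                    f"{g.start}..{g.end}",
                    g.strand,
                    str(aa_len),
                    g.protein_id or "-",
                    "-",
                    g.locus_tag,
                    "-",
                    "-",
                    g.product or "-",
                    flags,
                ]
            )
        )
        if g.protein_id and g.protein_seq:
            seqs[g.protein_id] = g.protein_seq
            descs[g.protein_id] = f"{g.locus_tag} {g.product}".strip()
    with open(ptt_path, "w") as fh:
        fh.write(
            f"{replicon.genome_id} {replicon.replicon_id} - {replicon.length_bp} bp\n"
        )
        fh.write(f"{len(rows)} proteins\n")
        fh.write("\t".join(PTT_COLUMNS + ["Flags"]) + "\n")
        fh.write("\n".join(rows) + ("\n" if rows else ""))
    write_fasta(seqs, faa_path, descs)


# ---------------------------------------------------------------------------
# Taxa tables


def read_taxa(path) -> list[TaxonInfo]:
    """Taxa TSV with header genome_id, genus, species, size_bp."""
    taxa = []
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    if header != ["genome_id", "genus", "species", "size_bp"]:
        raise AnnotationParseError(f"{path}: unexpected taxa header {header!r}")
    for ln in lines[1:]:
        if not ln.strip():
            continue
        gid, genus, species, size = ln.split("\t")
        taxa.append(TaxonInfo(gid, genus, species, int(size)))
    return taxa


def write_taxa(taxa: list[TaxonInfo], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tgenus\tspecies\tsize_bp\n")
        for t in taxa:
            fh.write(f"{t.genome_id}\t{t.genus}\t{t.species}\t{t.total_genome_size_bp}\n")


# ---------------------------------------------------------------------------
# Completeness filter


def filter_incomplete(genes: list[GeneRecord]) -> tuple[list[GeneRecord], FilterReport]:
    """Discard incomplete records: partial, pseudo, or lacking a protein sequence.

    Order is preserved; the report carries the removal counts (a record
    failing several checks is counted once, under the first that applies:
    partial, then pseudo, then missing sequence).
    """
    kept: list[GeneRecord] = []
    n_partial = n_pseudo = n_missing = 0
    for g in genes:
        if g.is_partial:
            n_partial += 1
        elif g.is_pseudo:
            n_pseudo += 1
        elif g.protein_seq is None:
            n_missing += 1
        else:
            kept.append(g)
    return kept, FilterReport(
        n_input=len(genes),
        n_kept=len(kept),
        n_partial=n_partial,
        n_pseudo=n_pseudo,
        n_missing_seq=n_missing,
    )
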