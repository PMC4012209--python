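"""Synthetic multi-genome collections with planted ground truth.

The generator emulates the inputs of the neighborhood/co-occurrence
analysis: a collection of annotated genomes with genus structure,
protein families at controlled identity levels, CRISPR-Cas loci built
from type templates, and CARF/WYL query genes planted near (or away
from) those loci at configured probabilities.  Everything the pipeline
is expected to recover is also emitted as machine-readable ground-truth
tables, so every downstream stage is testable without any download.

Model choices (deliberately simple so recovery is exactly checkable):

* Background genes are unique uniform-random protein sequences — there
  are no background families, so any non-planted cluster of size > 1 is
  a clustering error.
* Family members derive from a single seed sequence by point
  substitutions at rate ``1 - within_identity`` (positions sampled
  without replacement, replacement residue uniform over the other 19);
  no indels unless ``indel_rate`` > 0.  Two members therefore share
  identity ~ w^2 + (1 - w^2)/19 at the configured w.
* Loci are contiguous instantiations of their template's gene list.
* All randomness flows from one integer seed; a fixed config + seed
  reproduces the output byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation_io import (
    GeneRecord,
    Replicon,
    TaxonInfo,
    write_fasta,
    write_genbank,
    write_ptt,
    write_taxa,
)
from .crispr import CasSignatureTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

QUERY_FAMILY = "CARF"
PARTNER_FAMILY = "WYL"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class FamilySpec:
    """A planted protein family: one seed, members at controlled identity."""

    family_id: str
    n_members: int = 20
    within_identity: float = 0.75
    seed_length: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.within_identity <= 1:
            raise ValueError("within_identity must be in (0, 1]")
        if self.seed_length <= 0 or self.n_members <= 0:
            raise ValueError("seed_length and n_members must be positive")


@dataclass(frozen=True)
class LocusTemplate:
    """An ordered cas gene list instantiated as one CRISPR-Cas locus."""

    template_id: str
    true_type: str  # I, II, III-A, III-B
    gene_family_list: tuple[str, ...]

    _REQUIRED = {
        "I": ({"cas3"},),
        "II": ({"cas9"},),
        "III-A": ({"cas10"}, {"csm2"}),
        "III-B": ({"cas10"}, {"cmr5"}),
    }

    def __post_init__(self) -> None:
        if self.true_type not in self._REQUIRED:
            raise ValueError(f"unknown type {self.true_type!r}")
        fams = set(self.gene_family_list)
        for req in self._REQUIRED[self.true_type]:
            if not fams & req:
                raise ValueError(
                    f"template {self.template_id}: type {self.true_type} "
                    f"requires one of {sorted(req)}"
                )


DEFAULT_TEMPLATES = (
    LocusTemplate("tplI", "I", ("cas3", "cas1", "cas2", "cas4")),
    LocusTemplate("tplII", "II", ("cas9", "cas1", "cas2")),
    LocusTemplate("tplIIIA", "III-A", ("cas10", "csm2", "csx19", "cas1", "cas2")),
    LocusTemplate("tplIIIB", "III-B", ("cas10", "cmr5", "cas2")),
)

# per-family domain length and product line used when emitting hits
_FAMILY_SEED_LENGTH = {
    QUERY_FAMILY: 300,
    PARTNER_FAMILY: 200,
    "cas1": 280,
    "cas2": 110,
    "cas3": 350,
    "cas4": 180,
    "cas9": 400,
    "cas10": 380,
    "csm2": 140,
    "cmr5": 160,
    "csx19": 150,
    "csx15": 170,
}


def default_family_specs() -> tuple[FamilySpec, ...]:
    return tuple(
        FamilySpec(fam, n_members=50, within_identity=0.75, seed_length=ln)
        for fam, ln in _FAMILY_SEED_LENGTH.items()
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; see module docstring for the model."""

    seed: int = 0
    n_genera: int = 6
    species_per_genus: tuple[int, int] = (1, 2)
    genes_per_replicon: tuple[int, int] = (70, 100)
    protein_length: tuple[int, int] = (100, 400)
    family_specs: tuple[FamilySpec, ...] = field(default_factory=default_family_specs)
    locus_templates: tuple[LocusTemplate, ...] = DEFAULT_TEMPLATES
    carf_near_cas_prob: float = 0.9
    wyl_near_carf_prob: float = 0.8
    partial_fraction: float = 0.05
    indel_rate: float = 0.0
    window_k: int = 10
    cas_free_fraction: float = 0.1
    template_prob: float = 0.5
    carf_effector_prob: float = 0.7
    locus_gap_prob: float = 0.0
    intergenic_range: tuple[int, int] = (20, 120)

    def __post_init__(self) -> None:
        for name in (
            "carf_near_cas_prob",
            "wyl_near_carf_prob",
            "partial_fraction",
            "indel_rate",
            "cas_free_fraction",
            "template_prob",
            "carf_effector_prob",
            "locus_gap_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("species_per_genus", "genes_per_replicon", "protein_length", "intergenic_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValueError(f"{name}: bad range ({lo}, {hi})")
        if self.n_genera < 1:
            raise ValueError("n_genera must be >= 1")
        if self.window_k < 1:
            raise ValueError("window_k must be >= 1")

    def family(self, family_id: str) -> FamilySpec:
        for spec in self.family_specs:
            if spec.family_id == family_id:
                return spec
        raise KeyError(family_id)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_config_to_dict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return _config_from_dict(yaml.safe_load(fh))


def _config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["family_specs"] = [dataclasses.asdict(s) for s in cfg.family_specs]
    d["locus_templates"] = [
        {
            "template_id": t.template_id,
            "true_type": t.true_type,
            "gene_family_list": list(t.gene_family_list),
        }
        for t in cfg.locus_templates
    ]
    for k in ("species_per_genus", "genes_per_replicon", "protein_length", "intergenic_range"):
        d[k] = list(d[k])
    return d


def _config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["family_specs"] = tuple(FamilySpec(**s) for s in d.get("family_specs", []))
    d["locus_templates"] = tuple(
        LocusTemplate(t["template_id"], t["true_type"], tuple(t["gene_family_list"]))
        for t in d.get("locus_templates", [])
    )
    for k in ("species_per_genus", "genes_per_replicon", "protein_length", "intergenic_range"):
        if k in d:
            d[k] = tuple(d[k])
    return SimulationConfig(**d)


# ---------------------------------------------------------------------------
# Sequence-level generation


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def mutate(seq: str, identity: float, rng: np.random.Generator, indel_rate: float = 0.0) -> str:
    """One family member: substitute round((1-identity)*L) positions of the seed."""
    n_mut = int(round((1.0 - identity) * len(seq)))
    out = list(seq)
    if n_mut:
        pos = rng.choice(len(seq), size=n_mut, replace=False)
        for p in pos:
            alternatives = AMINO_ACIDS.replace(out[p], "")
            out[p] = alternatives[rng.integers(0, len(alternatives))]
    if indel_rate and rng.random() < indel_rate:
        k = int(rng.integers(1, 4))
        p = int(rng.integers(0, len(out)))
        if rng.random() < 0.5 and len(out) > k + 10:
            del out[p : p + k]
        else:
            out[p:p] = list(random_protein(rng, k))
    return "".join(out)


def generate_family(spec: FamilySpec, rng: np.random.Generator) -> list[str]:
    """n_members sequences derived from one random seed at the configured identity."""
    seed_seq = random_protein(rng, spec.seed_length)
    return [mutate(seed_seq, spec.within_identity, rng) for _ in range(spec.n_members)]


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of equal positions over the shorter length (ungapped comparison)."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / n


class _FamilySampler:
    """Yields members of one family on demand, all from a private RNG stream."""

    def __init__(self, spec: FamilySpec, rng: np.random.Generator, indel_rate: float):
        self.spec = spec
        self.rng = rng
        self.indel_rate = indel_rate
        self.seed_seq = random_protein(rng, spec.seed_length)

    def next_member(self) -> str:
        return mutate(self.seed_seq, self.spec.within_identity, self.rng, self.indel_rate)


# ---------------------------------------------------------------------------
# Collection-level generation

_HIT_META = {
    # family -> (evalue, score) used in the emitted hit table
    "default": (1e-50, 180.0),
    QUERY_FAMILY: (1e-60, 220.0),
    "wHTH": (1e-20, 80.0),
    "HEPN": (1e-25, 95.0),
}

_PRODUCTS = {
    QUERY_FAMILY: "CARF domain-containing protein",
    PARTNER_FAMILY: "WYL domain-containing protein",
}


@dataclass
class GroundTruth:
    """Planted truth for one generated collection (all claims re-derivable)."""

    config: SimulationConfig
    genes: pd.DataFrame  # one row per gene, with planted family and flags
    loci: pd.DataFrame  # one row per planted locus
    events: pd.DataFrame  # one row per planted CARF gene (association events)
    taxa: pd.DataFrame  # genome_id, genus, species, size_bp
    identities: pd.DataFrame  # realized member-to-seed identities

    @property
    def proteins(self) -> pd.DataFrame:
        cols = ["protein_id", "family"]
        return self.genes.loc[self.genes.protein_id != "-", cols].reset_index(drop=True)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        self.loci.to_csv(out / "loci.tsv", sep="\t", index=False)
        self.events.to_csv(out / "events.tsv", sep="\t", index=False)
        self.taxa.to_csv(out / "taxa.tsv", sep="\t", index=False)
        self.identities.to_csv(out / "identities.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, out_dir, config: SimulationConfig | None = None) -> "GroundTruth":
        out = Path(out_dir)
        return cls(
            config=config or SimulationConfig(),
            genes=pd.read_csv(out / "genes.tsv", sep="\t"),
            loci=pd.read_csv(out / "loci.tsv", sep="\t"),
            events=pd.read_csv(out / "events.tsv", sep="\t"),
            taxa=pd.read_csv(out / "taxa.tsv", sep="\t"),
            identities=pd.read_csv(out / "identities.tsv", sep="\t"),
        )


def generate_collection(config: SimulationConfig, out_dir) -> GroundTruth:
    """Generate a genome collection under ``config`` and write it to ``out_dir``.

    Writes, per genome, a GenBank file and a PTT+FASTA pair under
    ``genomes/``; collection-wide files ``hits.tsv`` (domain-hit table
    for every planted protein), ``signature.tsv`` (the default cas
    signature roles), ``taxa.tsv``; ground-truth tables under
    ``ground_truth/``; and ``config.yaml`` echoing the configuration
    (seed included).  Returns the in-memory :class:`GroundTruth`.
    """
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    ss_families, ss_layout = root.spawn(2)
    fam_specs = {s.family_id: s for s in config.family_specs}
    needed = {QUERY_FAMILY, PARTNER_FAMILY}
    for t in config.locus_templates:
        needed.update(t.gene_family_list)
    missing = needed - set(fam_specs)
    if missing:
        raise ConfigurationError(f"family_specs missing families {sorted(missing)}")
    fam_order = sorted(needed)
    samplers = {
        fam: _FamilySampler(fam_specs[fam], np.random.default_rng(child), config.indel_rate)
        for fam, child in zip(fam_order, ss_families.spawn(len(fam_order)))
    }
    rng = np.random.default_rng(ss_layout)

    # --- genome roster -----------------------------------------------------
    genomes: list[tuple[str, str, str]] = []  # (genome_id, genus, species)
    for gi in range(config.n_genera):
        genus = f"Genus{gi + 1:02d}"
        lo, hi = config.species_per_genus
        for sj in range(int(rng.integers(lo, hi + 1))):
            gid = f"G{len(genomes) + 1:04d}"
            genomes.append((gid, genus, f"{genus} sp{sj + 1}"))
    n_genomes = len(genomes)
    n_cas_free = int(round(config.cas_free_fraction * n_genomes))
    cas_free = set(rng.choice(n_genomes, size=n_cas_free, replace=False).tolist())

    gene_rows: list[dict] = []
    locus_rows: list[dict] = []
    event_rows: list[dict] = []
    taxa: list[TaxonInfo] = []
    hit_rows: list[dict] = []
    identity_rows: list[dict] = []
    protein_counter = 0

    for g_idx, (gid, genus, species) in enumerate(genomes):
        n_genes = int(rng.integers(config.genes_per_replicon[0], config.genes_per_replicon[1] + 1))
        # rejection-resample layouts that cannot satisfy the placement
        # constraints (e.g. no cas-distant slot left on a crowded replicon);
        # the rng advances deterministically, so retries are reproducible
        layout = None
        last_err: ConfigurationError | None = None
        for _attempt in range(50):
            try:
                layout = _layout_genome(
                    config, rng, n_genes, has_loci=g_idx not in cas_free, genome_id=gid
                )
                break
            except ConfigurationError as err:
                last_err = err
        if layout is None:
            raise ConfigurationError(
                f"{gid}: no feasible layout after 50 attempts ({last_err})"
            )
        replicon_id = f"{gid}_chr"

        # instantiate sequences and gene records
        genes: list[GeneRecord] = []
        cursor = 0
        fam_at: dict[int, str] = layout.family_at
        for idx in range(n_genes):
            fam = fam_at.get(idx, "background")
            if fam == "background":
                aa_len = int(rng.integers(config.protein_length[0], config.protein_length[1] + 1))
                seq = random_protein(rng, aa_len)
            else:
                sampler = samplers[fam]
                seq = sampler.next_member()
                identity_rows.append(
                    {
                        "family": fam,
                        "protein_id": f"P{protein_counter + 1:06d}",
                        "identity_to_seed": round(
                            pairwise_identity(seq, sampler.seed_seq), 6
                        ),
                    }
                )
            protein_counter += 1
            pid = f"P{protein_counter:06d}"
            is_partial = fam == "background" and bool(rng.random() < config.partial_fraction)
            start = cursor + int(rng.integers(*config.intergenic_range)) + 1
            end = start + 3 * (len(seq) + 1) - 1
            cursor = end
            genes.append(
                GeneRecord(
                    locus_tag=f"{gid}_{idx + 1:04d}",
                    protein_id=pid,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    product=_PRODUCTS.get(fam, f"CRISPR-associated protein {fam.capitalize()}"
                                          if fam in needed else "hypothetical protein"),
                    protein_seq=seq,
                    is_partial=is_partial,
                    is_pseudo=False,
                    index=idx,
                )
            )
            gene_rows.append(
                {
                    "genome_id": gid,
                    "replicon_id": replicon_id,
                    "locus_tag": genes[-1].locus_tag,
                    "protein_id": pid,
                    "index": idx,
                    "start": start,
                    "end": end,
                    "strand": genes[-1].strand,
                    "family": fam,
                    "is_partial": int(is_partial),
                    "is_pseudo": 0,
                }
            )
            if fam != "background":
                hit_rows.extend(_hits_for(pid, fam, len(seq), layout.effector_at.get(idx)))

        length_bp = cursor + 50
        replicon = Replicon(
            genome_id=gid,
            replicon_id=replicon_id,
            length_bp=length_bp,
            topology="linear",
            genes=tuple(genes),
        )
        write_genbank([replicon], out / "genomes" / f"{gid}.gbk")
        write_ptt(replicon, out / "genomes" / f"{gid}.ptt", out / "genomes" / f"{gid}.faa")
        taxa.append(TaxonInfo(gid, genus, species, length_bp))

        pid_at = {idx: genes[idx].protein_id for idx in range(n_genes)}
        for locus in layout.loci:
            locus_rows.append(
                {
                    "genome_id": gid,
                    "replicon_id": replicon_id,
                    "template_id": locus.template.template_id,
                    "true_type": locus.template.true_type,
                    "start_index": locus.cas_indices[0],
                    "end_index": locus.cas_indices[-1],
                    "members": ",".join(fam_at[i] for i in locus.cas_indices),
                }
            )
        event_rows.append(
            _derive_event(gid, layout, pid_at, config.window_k)
        )

    # --- collection-wide files --------------------------------------------
    hits = pd.DataFrame(
        hit_rows, columns=["protein_id", "family", "start", "end", "evalue", "score"]
    )
    hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    CasSignatureTable().to_tsv(out / "signature.tsv")
    write_taxa(taxa, out / "taxa.tsv")
    config.to_yaml(out / "config.yaml")

    gt = GroundTruth(
        config=config,
        genes=pd.DataFrame(gene_rows),
        loci=pd.DataFrame(
            locus_rows,
            columns=[
                "genome_id",
                "replicon_id",
                "template_id",
                "true_type",
                "start_index",
                "end_index",
                "members",
            ],
        ),
        events=pd.DataFrame(event_rows),
        taxa=pd.DataFrame(
            [
                {
                    "genome_id": t.genome_id,
                    "genus": t.genus,
                    "species": t.species,
                    "size_bp": t.total_genome_size_bp,
                }
                for t in taxa
            ]
        ),
        identities=pd.DataFrame(
            identity_rows, columns=["family", "protein_id", "identity_to_seed"]
        ),
    )
    gt.write(out / "ground_truth")
    return gt


def _hits_for(pid: str, fam: str, seq_len: int, effector: str | None) -> list[dict]:
    rows = []
    if fam == QUERY_FAMILY:
        ev, sc = _HIT_META[QUERY_FAMILY]
        rows.append(dict(protein_id=pid, family=fam, start=1, end=min(140, seq_len), evalue=ev, score=sc))
        ev, sc = _HIT_META["wHTH"]
        rows.append(dict(protein_id=pid, family="wHTH", start=150, end=min(205, seq_len), evalue=ev, score=sc))
        if effector:
            ev, sc = _HIT_META["HEPN"]
            rows.append(dict(protein_id=pid, family=effector, start=215, end=min(275, seq_len), evalue=ev, score=sc))
    else:
        ev, sc = _HIT_META["default"]
        rows.append(dict(protein_id=pid, family=fam, start=1, end=seq_len, evalue=ev, score=sc))
    return rows


@dataclass
class _PlantedLocus:
    template: LocusTemplate
    cas_indices: list[int]  # gene indices of cas members (ascending)


@dataclass
class _GenomeLayout:
    family_at: dict[int, str]  # gene index -> planted family
    effector_at: dict[int, str]  # CARF gene index -> effector family (if any)
    loci: list[_PlantedLocus]
    carf_index: int
    wyl_index: int
    carf_near_intent: bool
    wyl_near_intent: bool


def _layout_genome(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_genes: int,
    has_loci: bool,
    genome_id: str,
) -> _GenomeLayout:
    """Choose gene-index positions for loci, the CARF gene and the WYL gene."""
    occupied = np.zeros(n_genes, dtype=bool)
    family_at: dict[int, str] = {}
    loci: list[_PlantedLocus] = []
    k = config.window_k
    gap_guard = 3  # > locus_max_gap default so separate loci never merge

    if has_loci:
        chosen = [t for t in config.locus_templates if rng.random() < config.template_prob]
        if not chosen:
            chosen = [config.locus_templates[int(rng.integers(len(config.locus_templates)))]]
        for tpl in chosen:
            span = len(tpl.gene_family_list)
            insert_gap = span > 1 and rng.random() < config.locus_gap_prob
            width = span + (1 if insert_gap else 0)
            start = _find_run(rng, occupied, width, gap_guard, n_genes)
            if start is None:
                raise ConfigurationError(
                    f"{genome_id}: replicon of {n_genes} genes too small for "
                    f"template {tpl.template_id}"
                )
            gap_pos = int(rng.integers(1, span)) if insert_gap else -1
            cas_indices = []
            offset = 0
            for j, fam in enumerate(tpl.gene_family_list):
                if j == gap_pos:
                    offset += 1  # one background gene inside the locus
                idx = start + j + offset
                family_at[idx] = fam
                cas_indices.append(idx)
            occupied[start : start + width] = True
            loci.append(_PlantedLocus(template=tpl, cas_indices=cas_indices))

    cas_positions = sorted(i for lc in loci for i in lc.cas_indices)

    def near_cas(idx: int) -> bool:
        return any(abs(idx - c) <= k for c in cas_positions)

    carf_near = bool(loci) and bool(rng.random() < config.carf_near_cas_prob)
    if carf_near:
        carf_index = _place_near(rng, occupied, loci, k, n_genes)
        if carf_index is None:
            raise ConfigurationError(f"{genome_id}: no free slot near a locus for the query gene")
    else:
        carf_index = _place_where(rng, occupied, lambda i: not near_cas(i))
        if carf_index is None:
            raise ConfigurationError(f"{genome_id}: no cas-free slot for the query gene")
    occupied[carf_index] = True
    family_at[carf_index] = QUERY_FAMILY

    wyl_near = bool(rng.random() < config.wyl_near_carf_prob)
    if wyl_near:
        wyl_index = _place_where(
            rng, occupied, lambda i: 1 <= abs(i - carf_index) <= k
        )
        if wyl_index is None:
            raise ConfigurationError(f"{genome_id}: no free slot near the query gene")
    else:
        wyl_index = _place_where(rng, occupied, lambda i: abs(i - carf_index) > k)
        if wyl_index is None:
            raise ConfigurationError(f"{genome_id}: no slot away from the query gene")
    occupied[wyl_index] = True
    family_at[wyl_index] = PARTNER_FAMILY

    effector_at: dict[int, str] = {}
    if rng.random() < config.carf_effector_prob:
        effector_at[carf_index] = "HEPN"

    return _GenomeLayout(
        family_at=family_at,
        effector_at=effector_at,
        loci=loci,
        carf_index=carf_index,
        wyl_index=wyl_index,
        carf_near_intent=carf_near,
        wyl_near_intent=wyl_near,
    )


def _find_run(rng, occupied, width, gap_guard, n_genes):
    """A random free run of ``width`` slots, gap_guard slots clear of other loci."""
    candidates = []
    for start in range(0, n_genes - width + 1):
        lo = max(0, start - gap_guard)
        hi = min(n_genes, start + width + gap_guard)
        if not occupied[lo:hi].any():
            candidates.append(start)
    if not candidates:
        return None
    return int(candidates[int(rng.integers(len(candidates)))])


def _place_where(rng, occupied, pred):
    candidates = [i for i in range(len(occupied)) if not occupied[i] and pred(i)]
    if not candidates:
        return None
    return int(candidates[int(rng.integers(len(candidates)))])


def _place_near(rng, occupied, loci, k, n_genes):
    """A free slot within k gene indices of a randomly chosen locus."""
    lc = loci[int(rng.integers(len(loci)))]
    lo, hi = lc.cas_indices[0], lc.cas_indices[-1]
    candidates = [
        i
        for i in range(max(0, lo - k), min(n_genes, hi + k + 1))
        if not occupied[i]
    ]
    if not candidates:
        # fall back to any locus
        candidates = [
            i
            for other in loci
            for i in range(
                max(0, other.cas_indices[0] - k),
                min(n_genes, other.cas_indices[-1] + k + 1),
            )
            if not occupied[i]
        ]
    if not candidates:
        return None
    return int(candidates[int(rng.integers(len(candidates)))])


def _derive_event(gid: str, layout: _GenomeLayout, pid_at: dict[int, str], k: int) -> dict:
    """Association facts for the planted query gene, derived from the layout."""
    ci = layout.carf_index
    window = set(range(ci - k, ci + k + 1))
    overlapping = [
        lc for lc in layout.loci if any(i in window for i in range(lc.cas_indices[0], lc.cas_indices[-1] + 1))
    ]
    near_cas = bool(overlapping)
    nearest_type = "-"
    if overlapping:
        def dist(lc):
            lo, hi = lc.cas_indices[0], lc.cas_indices[-1]
            return 0 if lo <= ci <= hi else min(abs(ci - lo), abs(ci - hi))

        dmin = min(dist(lc) for lc in overlapping)
        nearest = sorted(
            {lc.template.true_type for lc in overlapping if dist(lc) == dmin}
        )
        nearest_type = ",".join(nearest)
    return {
        "genome_id": gid,
        "carf_protein_id": pid_at[ci],
        "carf_index": ci,
        "near_cas": int(near_cas),
        "nearest_type": nearest_type,
        "wyl_protein_id": pid_at[layout.wyl_index],
        "wyl_same_window": int(abs(layout.wyl_index - ci) <= k),
        "carf_with_effector": int(ci in layout.effector_at),
    }
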