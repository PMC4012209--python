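"""End-to-end orchestration: parse -> filter -> windows -> cluster -> annotate
-> associate -> report.

The pipeline consumes a collection directory as produced by
:mod:`caslink.synthetic` (or assembled by hand from real annotations):

    genomes/<genome_id>.gbk            or  .ptt + .faa pairs
    hits.tsv                           domain-hit table
    signature.tsv                      cas family -> role table
    taxa.tsv                           genome_id, genus, species, size_bp

Every stage writes its intermediate TSV into the output directory so any
stage can be audited or re-run independently; the run report echoes all
parameters and the counts at every stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation_io as aio
from .architecture import (
    Architecture,
    EffectorConfig,
    classify_effector,
    hits_from_frame,
    resolve_overlaps,
)
from .cluster import ClusteringParams, write_blastclust
from .crispr import (
    AssociationTable,
    CasSignatureTable,
    CrisprLocusCall,
    build_inventory,
    call_loci,
    family_type_association,
    genome_cooccurrence,
    presence_summary,
)
from .neighborhood import (
    CoOccurrenceTable,
    FamilyAnnotation,
    NeighborhoodParams,
    NeighborhoodWindow,
    annotate_clusters,
    cooccurrence,
    extract_window,
    format_linkage,
    pool_and_cluster,
    protein_families,
    read_hits,
    reverse_cas_linkage,
)
from .representatives import SelectionOverrides, select_representatives

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and parameters for one end-to-end run."""

    input_dir: str | Path
    output_dir: str | Path
    query_family: str = "CARF"
    partner_families: tuple[str, ...] = ("WYL",)
    annotation_format: str = "genbank"  # or "ptt"
    neighborhood: NeighborhoodParams = field(default_factory=NeighborhoodParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    effector: EffectorConfig = field(default_factory=EffectorConfig)
    overrides: SelectionOverrides = field(default_factory=SelectionOverrides)
    evalue_cutoff: float = 0.01
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.annotation_format not in ("genbank", "ptt"):
            raise ValueError("annotation_format must be 'genbank' or 'ptt'")


@dataclass
class RunReport:
    """Stage counts and result tables of one pipeline run."""

    params: dict
    n_genomes: int = 0
    n_replicons: int = 0
    n_genes: int = 0
    n_complete_proteins: int = 0
    n_removed_incomplete: int = 0
    n_query_genes: int = 0
    n_windows: int = 0
    n_pooled_proteins: int = 0
    n_clusters: int = 0
    n_loci: int = 0
    n_representative_genomes: int = 0
    cooccurrence: CoOccurrenceTable | None = None
    reverse_linkage: dict[str, tuple[int, int]] = field(default_factory=dict)
    association: AssociationTable | None = None
    genome_partition: pd.DataFrame | None = None
    presence: tuple[int, int] = (0, 0)

    def summary_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_genomes",
                "n_replicons",
                "n_genes",
                "n_complete_proteins",
                "n_removed_incomplete",
                "n_query_genes",
                "n_windows",
                "n_pooled_proteins",
                "n_clusters",
                "n_loci",
                "n_representative_genomes",
            )
        }
        d["reverse_linkage"] = {
            fam: format_linkage(t, l) for fam, (t, l) in self.reverse_linkage.items()
        }
        d["presence"] = {
            "genomes_with_query_family": self.presence[0],
            "lacking_cas1_and_cas10": self.presence[1],
        }
        d["params"] = self.params
        return d

    def summary(self) -> str:
        lines = ["caslink run report", "=" * 19]
        d = self.summary_dict()
        for k in (
            "n_genomes",
            "n_replicons",
            "n_genes",
            "n_complete_proteins",
            "n_removed_incomplete",
            "n_query_genes",
            "n_windows",
            "n_pooled_proteins",
            "n_clusters",
            "n_loci",
            "n_representative_genomes",
        ):
            lines.append(f"{k:28s} {d[k]}")
        for fam, s in d["reverse_linkage"].items():
            lines.append(f"reverse cas linkage {fam:8s} {s}")
        lines.append(
            "genomes with query family    "
            f"{self.presence[0]} (lacking cas1/cas10: {self.presence[1]})"
        )
        lines.append(f"parameters: {json.dumps(d['params'], sort_keys=True)}")
        return "\n".join(lines) + "\n"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def load_genomes(config: PipelineConfig) -> list[aio.Replicon]:
    gdir = Path(config.input_dir) / "genomes"
    if not gdir.is_dir():
        raise PipelineError("parse", f"no genomes/ directory under {config.input_dir}")
    replicons: list[aio.Replicon] = []
    if config.annotation_format == "genbank":
        for path in sorted(gdir.glob("*.gbk")):
            replicons.extend(aio.read_genbank(path, genome_id=path.stem))
    else:
        for path in sorted(gdir.glob("*.ptt")):
            faa = path.with_suffix(".faa")
            replicons.append(aio.read_ptt(path, faa, genome_id=path.stem))
    if not replicons:
        raise PipelineError("parse", f"no annotation files in {gdir}")
    return replicons


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order and write TSVs plus the run report."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {
        "query_family": config.query_family,
        "partner_families": list(config.partner_families),
        "annotation_format": config.annotation_format,
        "window_k": config.neighborhood.window_k,
        "length_coverage": config.clustering.length_coverage,
        "score_density": config.clustering.score_density,
        "evalue_cutoff": config.evalue_cutoff,
    }
    report = RunReport(params=params)

    def stage(name):
        logger.info("stage %-22s %6.1fs", name, time.time() - t0)

    # parse ----------------------------------------------------------------
    replicons = load_genomes(config)
    genomes = sorted({r.genome_id for r in replicons})
    report.n_genomes = len(genomes)
    report.n_replicons = len(replicons)
    report.n_genes = sum(len(r) for r in replicons)
    stage("parse")

    # completeness filter ---------------------------------------------------
    complete: dict[str, str] = {}
    n_removed = 0
    for rep in replicons:
        kept, frep = aio.filter_incomplete(list(rep.genes))
        n_removed += frep.n_removed
        for g in kept:
            if g.protein_id:
                complete[g.protein_id] = g.protein_seq
    report.n_complete_proteins = len(complete)
    report.n_removed_incomplete = n_removed
    stage("filter")

    # hits + per-protein families ------------------------------------------
    hits_path = Path(config.input_dir) / "hits.tsv"
    try:
        hits = read_hits(hits_path, config.evalue_cutoff)
    except FileNotFoundError as exc:
        raise PipelineError("annotate", str(exc)) from exc
    family_of = protein_families(hits, config.evalue_cutoff)
    sig_path = Path(config.input_dir) / "signature.tsv"
    sig = CasSignatureTable.from_tsv(sig_path) if sig_path.exists() else CasSignatureTable()

    # query windows ---------------------------------------------------------
    query_windows: list[NeighborhoodWindow] = []
    partner_windows: dict[str, list[NeighborhoodWindow]] = {
        fam: [] for fam in config.partner_families
    }
    for rep in replicons:
        for g in rep.genes:
            if g.protein_id is None or g.is_partial or g.is_pseudo:
                continue
            fam = family_of.get(g.protein_id)
            if fam == config.query_family:
                query_windows.append(extract_window(rep, g.index, config.neighborhood))
            elif fam in partner_windows:
                partner_windows[fam].append(
                    extract_window(rep, g.index, config.neighborhood)
                )
    report.n_query_genes = len(query_windows)
    report.n_windows = len(query_windows)
    _write_windows(query_windows, out / "windows.tsv")
    stage("windows")

    if not query_windows:
        logger.warning("no query genes of family %s found", config.query_family)
        report.cooccurrence = CoOccurrenceTable(counts={}, total_queries=0)
        report.genome_partition = pd.DataFrame()
        _finalize(report, out)
        return report

    # pool + cluster + annotate --------------------------------------------
    clusters = pool_and_cluster(query_windows, config.clustering)
    report.n_pooled_proteins = len(clusters.partition)
    report.n_clusters = clusters.n_clusters
    with open(out / "clusters.txt", "w") as fh:
        write_blastclust(clusters, fh)
    annotation = annotate_clusters(clusters, hits, config.evalue_cutoff)
    pd.DataFrame(
        sorted(annotation.labels.items()), columns=["cluster_id", "family"]
    ).to_csv(out / "cluster_annotation.tsv", sep="\t", index=False)
    stage("cluster")

    # co-occurrence histogram + reverse linkage ----------------------------
    cooc = cooccurrence(query_windows, clusters, annotation)
    report.cooccurrence = cooc
    cooc.to_frame().to_csv(out / "cooccurrence.tsv", sep="\t", index=False)
    cas_labels = sig.cas_families
    report.reverse_linkage[config.query_family] = reverse_cas_linkage(
        query_windows, family_of, cas_labels
    )
    for fam, wins in partner_windows.items():
        if wins:
            report.reverse_linkage[fam] = reverse_cas_linkage(wins, family_of, cas_labels)
    pd.DataFrame(
        [
            {"family": fam, "total": t, "cas_linked": l, "display": format_linkage(t, l)}
            for fam, (t, l) in report.reverse_linkage.items()
        ]
    ).to_csv(out / "reverse_linkage.tsv", sep="\t", index=False)
    stage("cooccurrence")

    # loci + typing ---------------------------------------------------------
    loci: list[CrisprLocusCall] = []
    for rep in replicons:
        loci.extend(call_loci(rep, family_of, sig))
    report.n_loci = len(loci)
    pd.DataFrame(
        [
            {
                "genome_id": lc.genome_id,
                "replicon_id": lc.replicon_id,
                "start_index": lc.start_index,
                "end_index": lc.end_index,
                "assigned_type": lc.assigned_type,
                "all_types": ",".join(lc.all_types),
                "composite": int(lc.composite),
                "members": ",".join(lc.member_families),
            }
            for lc in loci
        ],
        columns=[
            "genome_id",
            "replicon_id",
            "start_index",
            "end_index",
            "assigned_type",
            "all_types",
            "composite",
            "members",
        ],
    ).to_csv(out / "loci.tsv", sep="\t", index=False)
    stage("loci")

    # family/type association ----------------------------------------------
    assoc_windows = {config.query_family: query_windows}
    for fam, wins in partner_windows.items():
        if wins:
            assoc_windows[fam] = wins
    assoc = family_type_association(assoc_windows, loci)
    report.association = assoc
    assoc.to_frame().to_csv(out / "association.tsv", sep="\t", index=False)
    stage("association")

    # architectures + effector classes --------------------------------------
    effector_proteins: set[str] = set()
    query_pids = [pid for pid, fam in family_of.items() if fam == config.query_family]
    archs: list[Architecture] = []
    for pid in sorted(query_pids):
        ph = hits_from_frame(hits, pid)
        if not ph:
            continue
        arch = resolve_overlaps(ph, config.evalue_cutoff)
        archs.append(arch)
        if classify_effector(arch, config.effector) == "effector_bearing":
            effector_proteins.add(pid)
    pd.DataFrame(
        [
            {
                "protein_id": a.protein_id,
                "architecture": str(a),
                "effector_class": classify_effector(a, config.effector),
            }
            for a in archs
        ]
    ).to_csv(out / "architectures.tsv", sep="\t", index=False)
    stage("architecture")

    # genome inventories, representatives, genome-level stats ---------------
    taxa_path = Path(config.input_dir) / "taxa.tsv"
    taxa = aio.read_taxa(taxa_path) if taxa_path.exists() else []
    if taxa:
        rep_ids = select_representatives(taxa, config.overrides)
    else:
        rep_ids = genomes
    report.n_representative_genomes = len(rep_ids)
    loci_by_genome: dict[str, list[CrisprLocusCall]] = {}
    for lc in loci:
        loci_by_genome.setdefault(lc.genome_id, []).append(lc)
    pids_by_genome: dict[str, list[str]] = {}
    for rep in replicons:
        pids_by_genome.setdefault(rep.genome_id, []).extend(
            g.protein_id for g in rep.genes if g.protein_id
        )
    inventories = [
        build_inventory(
            gid,
            loci_by_genome.get(gid, []),
            family_of,
            pids_by_genome.get(gid, []),
            carf_families=[config.query_family],
            effector_proteins=effector_proteins,
        )
        for gid in sorted(rep_ids)
    ]
    partition = genome_cooccurrence(inventories)
    report.genome_partition = partition
    partition.to_csv(out / "genome_cooccurrence.tsv", sep="\t", index=False)
    report.presence = presence_summary(inventories)
    stage("inventory")

    _finalize(report, out)
    return report


def _write_windows(windows: list[NeighborhoodWindow], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "genome_id": w.genome_id,
                "replicon_id": w.replicon_id,
                "query_protein_id": w.query.protein_id,
                "query_index": w.query.index,
                "n_members": len(w.members),
                "member_indices": ",".join(map(str, w.member_indices)),
            }
            for w in windows
        ],
        columns=[
            "genome_id",
            "replicon_id",
            "query_protein_id",
            "query_index",
            "n_members",
            "member_indices",
        ],
    ).to_csv(path, sep="\t", index=False)


def _finalize(report: RunReport, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report.summary_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "report.txt", "w") as fh:
        fh.write(report.summary())


def make_demo(seed: int, out_dir, n_genera: int = 6) -> tuple["object", RunReport]:
    """Generate a small default collection and run the pipeline on it.

    The quickstart entry point: returns (ground truth, run report); the
    collection lands in ``<out_dir>/collection`` and the analysis in
    ``<out_dir>/analysis``.
    """
    from .synthetic import SimulationConfig, generate_collection

    out = Path(out_dir)
    cfg = SimulationConfig(seed=seed, n_genera=n_genera)
    gt = generate_collection(cfg, out / "collection")
    pconfig = PipelineConfig(
        input_dir=out / "collection",
        output_dir=out / "analysis",
        neighborhood=NeighborhoodParams(window_k=cfg.window_k),
    )
    report = run_pipeline(pconfig)
    return gt, report
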