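"""Validation scenarios with planted truth, and brute-force reference oracles.

Every function here builds a self-contained scenario from a seed, runs
the package's own code path on it, and measures recovery against either
an exhaustive independent reference implementation or the generator's
ground truth:

* :func:`alignment_oracle_check` — Smith-Waterman scores vs exhaustive
  enumeration of all local alignments (monotone matchings) on short
  sequences;
* :func:`clustering_oracle_check` — single-linkage partitions vs an
  all-pairs transitive-closure reference built directly on Biopython's
  aligner;
* :func:`planted_family_check` — dereplication of generator families at
  controlled identity (exact representative count, adjusted Rand index);
* :func:`association_check` / :func:`reverse_linkage_check` — the
  co-occurrence histogram and reverse cas-linkage vs planted events;
* :func:`typing_check`, :func:`presence_check`, :func:`selection_check`,
  :func:`determinism_check` — locus typing, the genome-level summaries,
  representative selection, and byte determinism / format round-trips.

The reference implementations are deliberately independent of the
production code paths they check: the alignment oracle enumerates
alignments combinatorially, and the clustering oracle re-derives the
linked relation from a fresh ``PairwiseAligner`` and finds components by
breadth-first search rather than union-find.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import annotation_io as aio
from .architecture import classify_effector, hits_from_frame, resolve_overlaps
from .cluster import ClusteringParams, dereplicate, single_linkage
from .crispr import (
    CasSignatureTable,
    build_inventory,
    call_loci,
    family_type_association,
    genome_category,
    genome_cooccurrence,
    presence_summary,
)
from .neighborhood import (
    NeighborhoodParams,
    annotate_clusters,
    cooccurrence,
    extract_window,
    pool_and_cluster,
    protein_families,
    read_hits,
    reverse_cas_linkage,
)
from .representatives import SelectionOverrides, select_representatives
from .similarity import ScoringParams, local_align
from .synthetic import (
    FamilySpec,
    SimulationConfig,
    generate_collection,
    generate_family,
    random_protein,
)

# ---------------------------------------------------------------------------
# Brute-force oracles


def oracle_local_score(a: str, b: str, params: ScoringParams | None = None) -> int:
    """Exhaustive optimal local-alignment score for short sequences.

    Enumerates every monotone matching between positions of ``a`` and
    ``b`` (the matched columns of a local alignment determine its gap
    runs, and grouping indels between two matched columns into one run
    per sequence is always optimal under affine costs), scoring each
    with the substitution matrix and the gap cost open + len * extend.
    The empty alignment scores 0.  Exponential in sequence length; keep
    lengths <= 10.
    """
    p = params or ScoringParams()
    M = p.matrix
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        for ai in itertools.combinations(range(len(a)), k):
            base = None
            for bi in itertools.combinations(range(len(b)), k):
                s = 0
                for t in range(k):
                    s += int(M[a[ai[t]], b[bi[t]]])
                    if t:
                        ga = ai[t] - ai[t - 1] - 1
                        gb = bi[t] - bi[t - 1] - 1
                        if ga:
                            s -= p.gap_open + ga * p.gap_extend
                        if gb:
                            s -= p.gap_open + gb * p.gap_extend
                if s > best:
                    best = s
    return best


def oracle_partition(
    seqs: dict[str, str], params: ClusteringParams | None = None
) -> set[frozenset[str]]:
    """Transitive closure of the linked relation, re-derived from scratch.

    Evaluates every pair with a fresh Biopython local aligner, applies
    the coverage and score-density thresholds directly, and collects
    connected components by breadth-first search.
    """
    p = params or ClusteringParams()
    aligner = p.scoring.aligner()
    ln2 = math.log(2)
    ids = list(seqs)
    adj: dict[str, set[str]] = {i: set() for i in ids}
    for x, y in itertools.combinations(ids, 2):
        a, b = seqs[x], seqs[y]
        alns = aligner.align(a, b)
        try:
            aln = alns[0]
        except IndexError:
            continue
        blocks_a, blocks_b = aln.aligned
        if len(blocks_a) == 0:
            continue
        cov_a = (blocks_a[-1][1] - blocks_a[0][0]) / len(a)
        cov_b = (blocks_b[-1][1] - blocks_b[0][0]) / len(b)
        bits = (p.scoring.karlin_lambda * aln.score - math.log(p.scoring.karlin_k)) / ln2
        if (
            cov_a >= p.length_coverage
            and cov_b >= p.length_coverage
            and bits / aln.length >= p.score_density
        ):
            adj[x].add(y)
            adj[y].add(x)
    seen: set[str] = set()
    comps: set[frozenset[str]] = set()
    for i in ids:
        if i in seen:
            continue
        comp, queue = {i}, [i]
        while queue:
            for nb in adj[queue.pop()]:
                if nb not in comp:
                    comp.add(nb)
                    queue.append(nb)
        seen |= comp
        comps.add(frozenset(comp))
    return comps


# ---------------------------------------------------------------------------
# Scenario checks


def alignment_oracle_check(seed: int, n_pairs: int = 200, max_len: int = 8) -> dict:
    """Smith-Waterman scores vs exhaustive enumeration on random short pairs."""
    rng = np.random.default_rng(seed)
    params = ScoringParams()
    agree = 0
    for _ in range(n_pairs):
        a = random_protein(rng, int(rng.integers(1, max_len + 1)))
        b = random_protein(rng, int(rng.integers(1, max_len + 1)))
        if local_align(a, b, params).raw_score == oracle_local_score(a, b, params):
            agree += 1
    return {"n_pairs": n_pairs, "n_agree": agree, "agreement_pct": 100.0 * agree / n_pairs}


def _random_instance(rng: np.random.Generator, max_seqs: int) -> dict[str, str]:
    """A clustering instance mixing related families and random singletons."""
    seqs: dict[str, str] = {}
    n_target = int(rng.integers(5, max_seqs + 1))
    counter = 0
    n_fams = int(rng.integers(1, 4))
    for f in range(n_fams):
        spec = FamilySpec(
            family_id=f"F{f}",
            n_members=int(rng.integers(2, 6)),
            within_identity=float(rng.uniform(0.55, 0.95)),
            seed_length=int(rng.integers(30, 80)),
        )
        for seq in generate_family(spec, rng):
            if len(seqs) >= n_target:
                break
            counter += 1
            seqs[f"S{counter:03d}"] = seq
    while len(seqs) < n_target:
        counter += 1
        seqs[f"S{counter:03d}"] = random_protein(rng, int(rng.integers(30, 80)))
    return seqs


def clustering_oracle_check(seed: int, n_instances: int = 50, max_seqs: int = 25) -> dict:
    """single_linkage partitions vs the transitive-closure reference."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        seqs = _random_instance(rng, max_seqs)
        ours = set(frozenset(ms) for ms in single_linkage(seqs).clusters().values())
        ref = oracle_partition(seqs)
        if ours == ref:
            agree += 1
    return {
        "n_instances": n_instances,
        "n_agree": agree,
        "agreement_pct": 100.0 * agree / n_instances,
    }


def planted_family_check(
    seed: int,
    n_families: int = 10,
    n_members: int = 20,
    within_identity: float = 0.75,
    seed_length: int = 200,
    n_backgrounds: int = 30,
) -> dict:
    """Dereplication of planted families at controlled identity.

    Families are generated from independent seeds; the clustering must
    recover exactly one representative per family (adjusted Rand index
    1.0 against the planted labels), and unique random background
    proteins must all stay singletons.
    """
    root = np.random.SeedSequence(seed)
    fam_ss, bg_ss = root.spawn(2)
    seqs: dict[str, str] = {}
    labels: dict[str, int] = {}
    for f, child in enumerate(fam_ss.spawn(n_families)):
        rng = np.random.default_rng(child)
        spec = FamilySpec(
            family_id=f"F{f}",
            n_members=n_members,
            within_identity=within_identity,
            seed_length=seed_length,
        )
        for m, seq in enumerate(generate_family(spec, rng)):
            pid = f"F{f:02d}M{m:02d}"
            seqs[pid] = seq
            labels[pid] = f
    clusters = single_linkage(seqs)
    ids = sorted(seqs)
    ari = adjusted_rand_score(
        [labels[i] for i in ids], [clusters.partition[i] for i in ids]
    )
    reps = dereplicate(seqs)
    bg_rng = np.random.default_rng(bg_ss)
    bg = {
        f"B{i:03d}": random_protein(bg_rng, 150) for i in range(n_backgrounds)
    }
    bg_reps = dereplicate(bg)
    return {
        "n_input": len(seqs),
        "n_representatives": len(reps),
        "adjusted_rand_index": float(ari),
        "n_backgrounds": n_backgrounds,
        "n_background_singletons": len(bg_reps),
    }


def _association_config(seed: int, **overrides) -> SimulationConfig:
    """The neighborhood-recovery study condition: 200 single-query genomes.

    Genomes are kept deliberately small (one query gene each, short
    background proteins, window of 5 genes per side — the lower end of
    the screening window range) so the all-pairs clustering of ~2000
    pooled neighbor proteins stays tractable on one CPU.
    """
    base = dict(
        seed=seed,
        n_genera=100,
        species_per_genus=(2, 2),
        genes_per_replicon=(22, 30),
        protein_length=(80, 150),
        window_k=5,
        wyl_near_carf_prob=0.8,
        carf_near_cas_prob=0.9,
        template_prob=0.4,
        cas_free_fraction=0.1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def _windows_and_families(collection_dir, window_k: int):
    replicons = []
    gdir = Path(collection_dir) / "genomes"
    for path in sorted(gdir.glob("*.gbk")):
        replicons.extend(aio.read_genbank(path, genome_id=path.stem))
    hits = read_hits(Path(collection_dir) / "hits.tsv")
    family_of = protein_families(hits)
    params = NeighborhoodParams(window_k=window_k)
    windows = []
    for rep in replicons:
        for g in rep.genes:
            if g.protein_id and family_of.get(g.protein_id) == "CARF":
                windows.append(extract_window(rep, g.index, params))
    return replicons, hits, family_of, windows


def association_check(seed: int, work_dir) -> dict:
    """Window-level WYL co-occurrence vs planted events, with binomial bounds."""
    cfg = _association_config(seed)
    gt = generate_collection(cfg, work_dir)
    _, hits, _, windows = _windows_and_families(work_dir, cfg.window_k)
    clusters = pool_and_cluster(windows)
    annotation = annotate_clusters(clusters, hits)
    cooc = cooccurrence(windows, clusters, annotation)
    wyl_count = cooc.counts.get("WYL", 0)
    gt_count = int(gt.events["wyl_same_window"].sum())
    n = len(windows)
    p = cfg.wyl_near_carf_prob
    se = math.sqrt(n * p * (1 - p))
    return {
        "n_windows": n,
        "wyl_count": wyl_count,
        "gt_count": gt_count,
        "exact_match": int(wyl_count == gt_count),
        "expected": n * p,
        "binomial_3se": 3 * se,
        "within_3se": int(abs(wyl_count - n * p) <= 3 * se),
        "n_pooled": len(clusters.partition),
        "n_clusters": clusters.n_clusters,
    }


def reverse_linkage_check(seed: int, work_dir, carf_near_cas_prob: float) -> dict:
    """Reverse cas-linkage at planted probability 0 or 1 (no clustering needed)."""
    cfg = _association_config(
        seed,
        n_genera=25,
        carf_near_cas_prob=carf_near_cas_prob,
        cas_free_fraction=0.0,
    )
    gt = generate_collection(cfg, work_dir)
    _, _, family_of, windows = _windows_and_families(work_dir, cfg.window_k)
    sig = CasSignatureTable()
    total, linked = reverse_cas_linkage(windows, family_of, sig.cas_families)
    gt_linked = int(gt.events["near_cas"].sum())
    return {
        "n_windows": total,
        "cas_linked": linked,
        "gt_linked": gt_linked,
        "linked_pct": 100.0 * linked / total if total else 0.0,
    }


def typing_check(seed: int, work_dir) -> dict:
    """Locus typing, association table and genome partition vs ground truth."""
    cfg = SimulationConfig(seed=seed)
    gt = generate_collection(cfg, work_dir)
    replicons, hits, family_of, windows = _windows_and_families(work_dir, cfg.window_k)
    sig = CasSignatureTable()
    loci = []
    for rep in replicons:
        loci.extend(call_loci(rep, family_of, sig))
    called = {
        (lc.genome_id, lc.replicon_id, lc.start_index, lc.end_index): lc.assigned_type
        for lc in loci
    }
    n_correct = 0
    for row in gt.loci.itertuples():
        key = (row.genome_id, row.replicon_id, row.start_index, row.end_index)
        if called.get(key) == row.true_type:
            n_correct += 1
    spans_match = int(len(called) == len(gt.loci))

    assoc = family_type_association({"CARF": windows}, loci)
    carf = assoc.rows["CARF"]
    ev = gt.events
    gt_near = int(ev["near_cas"].sum())
    gt_per_type: dict[str, int] = {}
    for types in ev.loc[ev["near_cas"] == 1, "nearest_type"]:
        for t in str(types).split(","):
            gt_per_type[t] = gt_per_type.get(t, 0) + 1
    assoc_match = int(
        carf.total == len(ev)
        and carf.near_cas == gt_near
        and {t: c for t, c in carf.per_type.items() if c} == gt_per_type
    )

    # genome-level partition vs planted templates
    effector_proteins = set()
    for pid in sorted(p for p, f in family_of.items() if f == "CARF"):
        arch = resolve_overlaps(hits_from_frame(hits, pid))
        if classify_effector(arch) == "effector_bearing":
            effector_proteins.add(pid)
    pids_by_genome: dict[str, list[str]] = {}
    loci_by_genome: dict[str, list] = {}
    for rep in replicons:
        pids_by_genome.setdefault(rep.genome_id, []).extend(
            g.protein_id for g in rep.genes if g.protein_id
        )
    for lc in loci:
        loci_by_genome.setdefault(lc.genome_id, []).append(lc)
    inventories = [
        build_inventory(
            gid, loci_by_genome.get(gid, []), family_of, pids, ["CARF"], effector_proteins
        )
        for gid, pids in sorted(pids_by_genome.items())
    ]
    partition = genome_cooccurrence(inventories)
    gt_partition = _gt_partition(gt)
    cells = partition.set_index("category")[["carf_with_effector", "carf_without_effector"]]
    partition_match = int(cells.equals(gt_partition))
    return {
        "n_loci": len(gt.loci),
        "n_typed_correctly": n_correct,
        "typing_accuracy_pct": 100.0 * n_correct / len(gt.loci) if len(gt.loci) else 100.0,
        "spans_match": spans_match,
        "association_match": assoc_match,
        "partition_match": partition_match,
    }


def _gt_partition(gt):
    """The genome partition implied by planted loci and effector flags."""
    import pandas as pd

    from .crispr import GENOME_CATEGORIES

    types_by_genome: dict[str, set[str]] = {g: set() for g in gt.taxa["genome_id"]}
    for row in gt.loci.itertuples():
        types_by_genome[row.genome_id].add(row.true_type)
    eff = dict(zip(gt.events["genome_id"], gt.events["carf_with_effector"]))
    counts = {c: [0, 0] for c in GENOME_CATEGORIES}
    for gid, types in types_by_genome.items():
        has_iii = any(t.startswith("III") for t in types)
        has_i, has_ii = "I" in types, "II" in types
        if has_iii and (has_i or has_ii):
            cat = "III_cooccurring"
        elif has_iii:
            cat = "III_sole"
        elif has_i:
            cat = "I_only"
        elif has_ii:
            cat = "II_only"
        else:
            cat = "none"
        if eff.get(gid):
            counts[cat][0] += 1
        else:
            counts[cat][1] += 1
    frame = pd.DataFrame(
        [
            {
                "category": c,
                "carf_with_effector": counts[c][0],
                "carf_without_effector": counts[c][1],
            }
            for c in GENOME_CATEGORIES
        ]
    ).set_index("category")
    return frame


def presence_check(seed: int, work_dir) -> dict:
    """cas1/cas10 presence summary on a 40-genome, 10% cas-free collection."""
    cfg = SimulationConfig(
        seed=seed,
        n_genera=20,
        species_per_genus=(2, 2),
        genes_per_replicon=(40, 55),
        protein_length=(80, 150),
        carf_near_cas_prob=1.0,
        cas_free_fraction=0.1,
    )
    gt = generate_collection(cfg, work_dir)
    replicons, _, family_of, _ = _windows_and_families(work_dir, cfg.window_k)
    sig = CasSignatureTable()
    loci_by_genome: dict[str, list] = {}
    pids_by_genome: dict[str, list[str]] = {}
    for rep in replicons:
        loci_by_genome.setdefault(rep.genome_id, []).extend(call_loci(rep, family_of, sig))
        pids_by_genome.setdefault(rep.genome_id, []).extend(
            g.protein_id for g in rep.genes if g.protein_id
        )
    inventories = [
        build_inventory(gid, loci_by_genome.get(gid, []), family_of, pids, ["CARF"])
        for gid, pids in sorted(pids_by_genome.items())
    ]
    n_with, n_lacking = presence_summary(inventories)
    gt_cas_free = int((gt.loci.groupby("genome_id").size().reindex(
        gt.taxa["genome_id"], fill_value=0) == 0).sum())
    return {
        "n_genomes": len(gt.taxa),
        "genomes_with_query_family": n_with,
        "lacking_cas1_cas10": n_lacking,
        "gt_cas_free": gt_cas_free,
    }


def selection_check(seed: int) -> dict:
    """Representative selection: max-size rule, overrides, idempotence."""
    rng = np.random.default_rng(seed)
    taxa = []
    for gi in range(5):
        genus = f"Genus{gi:02d}"
        for sj in range(int(rng.integers(1, 4))):
            taxa.append(
                aio.TaxonInfo(
                    f"R{gi}{sj}", genus, f"{genus} sp{sj}", int(rng.integers(2, 8)) * 10**6
                )
            )
    taxa.append(aio.TaxonInfo("BSU", "Bacillus", "Bacillus subtilis 168", 4_215_606))
    taxa.append(aio.TaxonInfo("BME", "Bacillus", "Bacillus megaterium big", 5_900_000))
    taxa.append(
        aio.TaxonInfo("ECO", "Escherichia", "Escherichia coli K12 substr. MG1655", 4_641_652)
    )
    taxa.append(aio.TaxonInfo("ECX", "Escherichia", "Escherichia coli O157", 5_500_000))
    chosen = select_representatives(taxa, SelectionOverrides())
    n_genera = len({t.genus for t in taxa})
    overrides_honored = int("BSU" in chosen and "ECO" in chosen)
    selected_taxa = [t for t in taxa if t.genome_id in chosen]
    reselected = select_representatives(selected_taxa, SelectionOverrides())
    idempotent = int(set(reselected) == set(chosen))
    return {
        "n_genera": n_genera,
        "n_selected": len(chosen),
        "one_per_genus": int(len(chosen) == n_genera),
        "overrides_honored": overrides_honored,
        "idempotent": idempotent,
    }


def _tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for path in sorted(Path(root).rglob("*")):
        if path.is_file():
            h.update(str(path.relative_to(root)).encode())
            h.update(path.read_bytes())
    return h.hexdigest()


def determinism_check(seed: int, work_dir) -> dict:
    """Byte determinism of the generator and GenBank<->PTT round-trip equality."""
    work = Path(work_dir)
    cfg = SimulationConfig(
        seed=seed, n_genera=3, genes_per_replicon=(50, 70), protein_length=(80, 150)
    )
    generate_collection(cfg, work / "run1")
    generate_collection(cfg, work / "run2")
    identical = int(_tree_digest(work / "run1") == _tree_digest(work / "run2"))
    gdir = work / "run1" / "genomes"
    n_equal = 0
    gbks = sorted(gdir.glob("*.gbk"))
    for gbk in gbks:
        via_gbk = aio.read_genbank(gbk, genome_id=gbk.stem)[0]
        via_ptt = aio.read_ptt(
            gbk.with_suffix(".ptt"), gbk.with_suffix(".faa"), genome_id=gbk.stem
        )
        if via_gbk == via_ptt:
            n_equal += 1
    return {
        "byte_identical": identical,
        "n_genomes": len(gbks),
        "n_roundtrip_equal": n_equal,
    }
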