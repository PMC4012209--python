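from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from caslink.annotation_io import GeneRecord, Replicon, read_genbank
from caslink.cluster import ClusterSet
from caslink.neighborhood import (
    FamilyAnnotation,
    NeighborhoodParams,
    annotate_clusters,
    cooccurrence,
    extract_window,
    format_linkage,
    pool_and_cluster,
    protein_families,
    read_hits,
    reverse_cas_linkage,
)
from caslink.synthetic import random_protein


def make_replicon(n_genes, topology="linear", genome_id="G", seqs=None):
    rng = np.random.default_rng(99)
    genes = []
    for i in range(n_genes):
        start = 10 + i * 200
        genes.append(
            GeneRecord(
                locus_tag=f"l{i:03d}",
                protein_id=f"p{i:03d}",
                start=start,
                end=start + 150,
                strand="+",
                product="x",
                protein_seq=(seqs or {}).get(i, random_protein(rng, 50)),
                index=i,
            )
        )
    return Replicon(genome_id, "chr", n_genes * 200 + 100, topology, tuple(genes))


class TestExtractWindow:
    def test_interior_query_gets_full_window(self):
        rep = make_replicon(40)
        w = extract_window(rep, 20, NeighborhoodParams(window_k=10))
        assert len(w.members) == 21
        assert w.member_indices == tuple(range(10, 31))
        assert w.query.index == 20

    def test_linear_start_truncates(self):
        rep = make_replicon(40)
        w = extract_window(rep, 0, NeighborhoodParams(window_k=5))
        assert len(w.members) == 6
        assert w.member_indices == tuple(range(0, 6))

    def test_circular_wrap_without_duplicates(self):
        rep = make_replicon(8, topology="circular")
        w = extract_window(rep, 2, NeighborhoodParams(window_k=5))
        assert len(w.members) == 8
        assert sorted(w.member_indices) == list(range(8))

    def test_circular_partial_wrap(self):
        rep = make_replicon(30, topology="circular")
        w = extract_window(rep, 1, NeighborhoodParams(window_k=3))
        assert sorted(w.member_indices) == [0, 1, 2, 3, 4, 28, 29]

    def test_out_of_range_index(self):
        rep = make_replicon(5)
        with pytest.raises(IndexError):
            extract_window(rep, 5)

    def test_window_size_bound_property(self):
        rep = make_replicon(60)
        for k in (1, 5, 10):
            for qi in (0, 3, 30, 59):
                w = extract_window(rep, qi, NeighborhoodParams(window_k=k))
                assert len(w.members) <= 2 * k + 1


class TestPoolAndCluster:
    def test_shared_gene_pooled_once_and_queries_excluded(self):
        rep = make_replicon(12)
        w1 = extract_window(rep, 4, NeighborhoodParams(window_k=3))
        w2 = extract_window(rep, 6, NeighborhoodParams(window_k=3))
        cs = pool_and_cluster([w1, w2])
        # union of indices 1..9 minus the two queries
        assert set(cs.partition) == {f"p{i:03d}" for i in range(1, 10)} - {"p004", "p006"}

    def test_unique_backgrounds_all_singletons(self):
        rep = make_replicon(15)
        w = extract_window(rep, 7, NeighborhoodParams(window_k=5))
        cs = pool_and_cluster([w])
        assert cs.n_clusters == len(cs.partition) == 10

    def test_planted_family_recovered_in_pool(self, small_collection, small_config):
        cdir, gt = small_collection
        hits = read_hits(Path(cdir) / "hits.tsv")
        family_of = protein_families(hits)
        params = NeighborhoodParams(window_k=small_config.window_k)
        windows = []
        for gbk in sorted(Path(cdir, "genomes").glob("*.gbk")):
            (rep,) = read_genbank(gbk, genome_id=gbk.stem)
            for g in rep.genes:
                if g.protein_id and family_of.get(g.protein_id) == "CARF":
                    windows.append(extract_window(rep, g.index, params))
        cs = pool_and_cluster(windows)
        wyl_in_pool = {
            p for p in cs.partition
            if family_of.get(p) == "WYL"
        }
        # planted WYL neighbors form exactly one cluster
        wyl_clusters = {cs.partition[p] for p in wyl_in_pool}
        assert len(wyl_clusters) == 1
        members = set(cs.members(next(iter(wyl_clusters))))
        assert members == wyl_in_pool


class TestAnnotateClusters:
    def _clusters(self):
        return ClusterSet(
            partition={"a": "C1", "b": "C1", "c": "C1", "d": "C2"},
            representatives={"C1": "a", "C2": "d"},
        )

    def test_majority_label(self):
        hits = pd.DataFrame(
            [
                {"protein_id": p, "family": "WYL", "start": 1, "end": 50,
                 "evalue": 1e-20, "score": 80.0}
                for p in ("a", "b")
            ]
            + [{"protein_id": "c", "family": "HTH", "start": 1, "end": 50,
                "evalue": 1e-30, "score": 90.0}]
        )
        ann = annotate_clusters(self._clusters(), hits)
        assert ann.label("C1") == "WYL"
        assert ann.label("C2") == "unknown"

    def test_tie_broken_by_best_evalue(self):
        hits = pd.DataFrame(
            [
                {"protein_id": "a", "family": "WYL", "start": 1, "end": 50,
                 "evalue": 1e-40, "score": 80.0},
                {"protein_id": "b", "family": "HTH", "start": 1, "end": 50,
                 "evalue": 1e-10, "score": 80.0},
            ]
        )
        ann = annotate_clusters(self._clusters(), hits)
        assert ann.label("C1") == "WYL"

    def test_evalue_filter_applied(self):
        hits = pd.DataFrame(
            [{"protein_id": "a", "family": "WYL", "start": 1, "end": 50,
              "evalue": 0.5, "score": 10.0}]
        )
        ann = annotate_clusters(self._clusters(), hits)
        assert ann.label("C1") == "unknown"

    def test_ground_truth_labels_recovered(self, pipeline_run):
        config, report, gt = pipeline_run
        ann = pd.read_csv(Path(config.output_dir) / "cluster_annotation.tsv", sep="\t")
        labels = set(ann["family"])
        assert "WYL" in labels
        # every non-unknown label is a planted family
        planted = set(gt.genes["family"]) - {"background"}
        assert labels - {"unknown"} <= planted | {"wHTH", "HEPN"}


class TestCoOccurrence:
    def test_probability_one_counts_every_window(self, tmp_path):
        from caslink.synthetic import SimulationConfig, generate_collection

        cfg = SimulationConfig(
            seed=5, n_genera=3, wyl_near_carf_prob=1.0,
            genes_per_replicon=(60, 80), protein_length=(80, 120),
        )
        gt = generate_collection(cfg, tmp_path)
        hits = read_hits(tmp_path / "hits.tsv")
        family_of = protein_families(hits)
        params = NeighborhoodParams(window_k=cfg.window_k)
        windows = []
        for gbk in sorted(Path(tmp_path, "genomes").glob("*.gbk")):
            (rep,) = read_genbank(gbk, genome_id=gbk.stem)
            for g in rep.genes:
                if g.protein_id and family_of.get(g.protein_id) == "CARF":
                    windows.append(extract_window(rep, g.index, params))
        cs = pool_and_cluster(windows)
        ann = annotate_clusters(cs, hits)
        table = cooccurrence(windows, cs, ann)
        assert table.counts["WYL"] == table.total_queries == len(gt.events)

    def test_counts_nondecreasing_in_window_k(self, small_collection, small_config):
        cdir, _ = small_collection
        hits = read_hits(Path(cdir) / "hits.tsv")
        family_of = protein_families(hits)
        counts = []
        for k in (3, 6, 10):
            windows = []
            for gbk in sorted(Path(cdir, "genomes").glob("*.gbk")):
                (rep,) = read_genbank(gbk, genome_id=gbk.stem)
                for g in rep.genes:
                    if g.protein_id and family_of.get(g.protein_id) == "CARF":
                        windows.append(extract_window(rep, g.index, NeighborhoodParams(window_k=k)))
            cs = pool_and_cluster(windows)
            ann = annotate_clusters(cs, hits)
            counts.append(cooccurrence(windows, cs, ann).counts.get("WYL", 0))
        assert counts == sorted(counts)


class TestReverseCasLinkage:
    def test_linked_bounded_by_total(self, pipeline_run):
        _, report, _ = pipeline_run
        for total, linked in report.reverse_linkage.values():
            assert 0 <= linked <= total

    def test_ground_truth_counts_match(self, pipeline_run):
        _, report, gt = pipeline_run
        total, linked = report.reverse_linkage["CARF"]
        assert total == len(gt.events)
        assert linked == int(gt.events["near_cas"].sum())

    def test_display_convention(self):
        assert format_linkage(186, 178) == "186 (178)"
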