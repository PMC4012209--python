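import math
from pathlib import Path

import numpy as np
import pytest

from caslink.synthetic import (
    ConfigurationError,
    FamilySpec,
    LocusTemplate,
    SimulationConfig,
    generate_collection,
    generate_family,
    mutate,
    pairwise_identity,
    random_protein,
)


class TestGenerateFamily:
    def test_full_identity_gives_identical_members(self):
        rng = np.random.default_rng(0)
        spec = FamilySpec("F", n_members=5, within_identity=1.0, seed_length=100)
        members = generate_family(spec, rng)
        assert len(set(members)) == 1

    def test_pairwise_identity_matches_substitution_model(self):
        # two members mutated independently at rate 1-w agree at a position
        # iff both kept it (w^2) or both mutated to the same residue
        rng = np.random.default_rng(1)
        w, L = 0.75, 200
        expect = w * w + (1 - w * w) / 19
        spec = FamilySpec("F", n_members=20, within_identity=w, seed_length=L)
        members = generate_family(spec, rng)
        idents = [
            pairwise_identity(members[i], members[j])
            for i in range(10)
            for j in range(i + 1, 20)
        ]
        sd = math.sqrt(expect * (1 - expect) / L)  # per-pair SD
        assert abs(np.mean(idents) - expect) < 3 * sd

    def test_distinct_families_are_background_similar(self):
        rng = np.random.default_rng(2)
        fam_a = generate_family(FamilySpec("A", 5, 0.75, 200), rng)
        fam_b = generate_family(FamilySpec("B", 5, 0.75, 200), rng)
        cross = [pairwise_identity(a, b) for a in fam_a for b in fam_b]
        assert np.mean(cross) < 0.15

    def test_mutation_count_is_exact(self):
        rng = np.random.default_rng(3)
        seed = random_protein(rng, 200)
        m = mutate(seed, 0.75, rng)
        assert sum(a != b for a, b in zip(seed, m)) == 50


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(carf_near_cas_prob=1.5)

    def test_template_requires_signature(self):
        with pytest.raises(ValueError, match="requires"):
            LocusTemplate("bad", "III-A", ("cas10", "cas1"))

    def test_replicon_too_small_is_configuration_error(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_genera=1, genes_per_replicon=(4, 4))
        with pytest.raises(ConfigurationError):
            generate_collection(cfg, tmp_path)

    def test_yaml_roundtrip(self, tmp_path, small_config):
        small_config.to_yaml(tmp_path / "c.yaml")
        assert SimulationConfig.from_yaml(tmp_path / "c.yaml") == small_config


class TestGenerateCollection:
    def test_emits_all_files(self, small_collection):
        cdir, gt = small_collection
        assert (Path(cdir) / "hits.tsv").exists()
        assert (Path(cdir) / "signature.tsv").exists()
        assert (Path(cdir) / "taxa.tsv").exists()
        assert (Path(cdir) / "config.yaml").exists()
        n_genomes = len(gt.taxa)
        assert len(list(Path(cdir, "genomes").glob("*.gbk"))) == n_genomes
        assert len(list(Path(cdir, "genomes").glob("*.ptt"))) == n_genomes

    def test_one_query_and_partner_gene_per_genome(self, small_collection):
        _, gt = small_collection
        per_genome = gt.genes.groupby("genome_id")["family"].value_counts().unstack(fill_value=0)
        assert (per_genome["CARF"] == 1).all()
        assert (per_genome["WYL"] == 1).all()

    def test_planted_loci_contain_their_template_genes(self, small_collection):
        _, gt = small_collection
        for row in gt.loci.itertuples():
            members = row.members.split(",")
            span = row.end_index - row.start_index + 1
            assert span >= len(members)
            if row.true_type == "III-A":
                assert "cas10" in members and "csm2" in members

    def test_events_consistent_with_gene_table(self, small_collection):
        _, gt = small_collection
        genes = gt.genes.set_index("protein_id")
        k = gt.config.window_k
        for ev in gt.events.itertuples():
            carf_idx = genes.loc[ev.carf_protein_id, "index"]
            assert genes.loc[ev.carf_protein_id, "family"] == "CARF"
            wyl_idx = genes.loc[ev.wyl_protein_id, "index"]
            assert bool(ev.wyl_same_window) == (abs(wyl_idx - carf_idx) <= k)
            g_loci = gt.loci[gt.loci.genome_id == ev.genome_id]
            overlaps = (
                (g_loci.start_index <= carf_idx + k) & (g_loci.end_index >= carf_idx - k)
            ).any()
            assert bool(ev.near_cas) == bool(overlaps)

    def test_near_cas_probability_zero_means_no_events(self, tmp_path):
        cfg = SimulationConfig(
            seed=11, n_genera=3, carf_near_cas_prob=0.0,
            genes_per_replicon=(70, 90), protein_length=(80, 120),
        )
        gt = generate_collection(cfg, tmp_path)
        assert gt.events["near_cas"].sum() == 0

    def test_near_cas_probability_one_means_all_events(self, tmp_path):
        cfg = SimulationConfig(
            seed=12, n_genera=3, carf_near_cas_prob=1.0, cas_free_fraction=0.0,
            genes_per_replicon=(70, 90), protein_length=(80, 120),
        )
        gt = generate_collection(cfg, tmp_path)
        assert (gt.events["near_cas"] == 1).all()

    def test_within_family_identity_control(self, small_collection):
        _, gt = small_collection
        w = 0.75
        assert (gt.identities["identity_to_seed"] >= w - 0.10).all()

    def test_taxa_sizes_match_replicon_lengths(self, small_collection):
        cdir, gt = small_collection
        from caslink.annotation_io import read_genbank

        for row in gt.taxa.itertuples():
            (rep,) = read_genbank(Path(cdir, "genomes", f"{row.genome_id}.gbk"),
                                  genome_id=row.genome_id)
            assert rep.length_bp == row.size_bp
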