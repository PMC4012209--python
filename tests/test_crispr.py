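import pytest

from caslink.crispr import (
    CasSignatureTable,
    CrisprLocusCall,
    GenomeInventory,
    assign_type,
    build_inventory,
    call_loci,
    family_type_association,
    genome_category,
    genome_cooccurrence,
    presence_summary,
)
from caslink.neighborhood import NeighborhoodParams, extract_window

from test_neighborhood import make_replicon

SIG = CasSignatureTable()


def annotated_replicon(families):
    """Replicon whose gene i is annotated with families[i] (None = background)."""
    rep = make_replicon(len(families))
    family_of = {
        f"p{i:03d}": fam for i, fam in enumerate(families) if fam is not None
    }
    return rep, family_of


class TestCallLoci:
    def test_contiguous_run_is_one_locus(self):
        rep, fam = annotated_replicon([None, "cas1", "cas2", "cas10", "csm2", None])
        loci = call_loci(rep, fam, SIG)
        assert len(loci) == 1
        assert (loci[0].start_index, loci[0].end_index) == (1, 4)
        assert loci[0].member_families == ("cas1", "cas2", "cas10", "csm2")

    def test_gap_above_tolerance_splits_locus(self):
        rep, fam = annotated_replicon(
            ["cas1", "cas2", None, None, None, "cas10", None]
        )
        loci = call_loci(rep, fam, SIG)
        assert len(loci) == 2

    def test_gap_within_tolerance_merges(self):
        rep, fam = annotated_replicon(["cas1", "cas2", None, None, "cas10"])
        loci = call_loci(rep, fam, SIG)
        assert len(loci) == 1

    def test_idempotent_and_order_independent(self):
        rep, fam = annotated_replicon(["cas1", None, "cas2", None, None, None, "cas9"])
        first = call_loci(rep, fam, SIG)
        assert call_loci(rep, fam, SIG) == first


class TestAssignType:
    def _locus(self, fams):
        return CrisprLocusCall(
            genome_id="G", replicon_id="r", start_index=0,
            end_index=len(fams) - 1, member_families=tuple(fams),
        )

    @pytest.mark.parametrize(
        "fams,expected",
        [
            (("cas10", "csm2", "cas1"), "III-A"),
            (("cas10", "cmr5"), "III-B"),
            (("cas3", "cas1", "cas2"), "I"),
            (("cas9", "cas1", "cas2"), "II"),
            (("cas10", "cas1"), "III-unspecified"),
            (("cas1", "cas2"), "unknown"),
        ],
    )
    def test_signature_rules(self, fams, expected):
        assert assign_type(self._locus(fams), SIG).assigned_type == expected

    def test_conflicting_signatures_flag_composite(self):
        lc = assign_type(self._locus(("cas3", "cas9", "cas1")), SIG)
        assert lc.composite
        assert set(lc.all_types) == {"I", "II"}


class TestFamilyTypeAssociation:
    def test_single_gene_next_to_locus(self):
        fams = [None] * 12
        fams[2:6] = ["cas10", "csm2", "cas1", "cas2"]
        rep, fam = annotated_replicon(fams)
        loci = call_loci(rep, fam, SIG)
        w = extract_window(rep, 8, NeighborhoodParams(window_k=5))
        table = family_type_association({"CARF": [w]}, loci)
        row = table.rows["CARF"]
        assert (row.total, row.near_cas) == (1, 1)
        assert row.per_type == {"III-A": 1}

    def test_window_missing_locus_not_near(self):
        fams = [None] * 30
        fams[0] = "cas9"
        rep, fam = annotated_replicon(fams)
        loci = call_loci(rep, fam, SIG)
        w = extract_window(rep, 20, NeighborhoodParams(window_k=5))
        row = family_type_association({"CARF": [w]}, loci).rows["CARF"]
        assert (row.total, row.near_cas) == (1, 0)
        assert row.per_type == {}

    def test_nearest_locus_wins(self):
        fams = [None] * 30
        fams[0:3] = ["cas3", "cas1", "cas2"]  # type I at 0-2
        fams[10:13] = ["cas10", "cmr5", "cas2"]  # III-B at 10-12
        rep, fam = annotated_replicon(fams)
        loci = call_loci(rep, fam, SIG)
        w = extract_window(rep, 8, NeighborhoodParams(window_k=7))
        row = family_type_association({"CARF": [w]}, loci).rows["CARF"]
        assert row.per_type == {"III-B": 1}

    def test_per_type_counts_bounded_by_near_cas(self, pipeline_run):
        _, report, _ = pipeline_run
        for row in report.association.rows.values():
            assert row.near_cas <= row.total
            # ties may double-count a gene across types, never within one
            for count in row.per_type.values():
                assert count <= row.near_cas


class TestGenomeLevel:
    def _inv(self, types, eff=False, carf=True, cas1=True, cas10=False):
        return GenomeInventory(
            genome_id="G",
            types_present=frozenset(types),
            has_cas1=cas1,
            has_cas10=cas10,
            carf_families=frozenset({"CARF"} if carf else set()),
            carf_with_effector=eff,
        )

    @pytest.mark.parametrize(
        "types,expected",
        [
            ({"III-B", "I"}, "III_cooccurring"),
            ({"III-A"}, "III_sole"),
            ({"I"}, "I_only"),
            ({"II"}, "II_only"),
            (set(), "none"),
            ({"III-unspecified", "II"}, "III_cooccurring"),
        ],
    )
    def test_genome_partition_categories(self, types, expected):
        assert genome_category(self._inv(types)) == expected

    def test_cooccurrence_table_is_a_partition(self):
        invs = [
            self._inv({"III-A", "I"}, eff=True),
            self._inv({"III-B"}),
            self._inv({"I"}),
            self._inv(set(), carf=False),
        ]
        table = genome_cooccurrence(invs)
        assert table["n_genomes"].sum() == len(invs)
        assert (
            table["carf_with_effector"] + table["carf_without_effector"]
        ).equals(table["n_genomes"])

    def test_presence_summary_counts(self):
        invs = [
            self._inv({"III-A"}, cas1=True),
            self._inv({"I"}, cas1=False, cas10=True),
            self._inv(set(), cas1=False, cas10=False),
            self._inv(set(), carf=False, cas1=False, cas10=False),
        ]
        assert presence_summary(invs) == (3, 1)

    def test_presence_summary_empty_case(self):
        invs = [self._inv(set(), carf=False)]
        assert presence_summary(invs) == (0, 0)

    def test_build_inventory_from_annotations(self):
        fams = [None] * 10
        fams[0:3] = ["cas10", "csm2", "cas1"]
        rep, fam = annotated_replicon(fams)
        fam["p008"] = "CARF"
        loci = call_loci(rep, fam, SIG)
        inv = build_inventory(
            "G", loci, fam, [f"p{i:03d}" for i in range(10)], ["CARF"], {"p008"}
        )
        assert inv.types_present == frozenset({"III-A"})
        assert inv.has_cas1 and inv.has_cas10
        assert inv.has_carf and inv.carf_with_effector


class TestSignatureTable:
    def test_tsv_roundtrip(self, tmp_path):
        SIG.to_tsv(tmp_path / "sig.tsv")
        back = CasSignatureTable.from_tsv(tmp_path / "sig.tsv")
        assert back.roles == SIG.roles

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            CasSignatureTable(roles={"casX": "not_a_role"})
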