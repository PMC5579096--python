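"""Taxonomy map parsing and the clade/monophyly machinery."""

import numpy as np
import pytest

from nematax import (
    Lineage,
    SupportTree,
    TaxonMap,
    TaxonomyError,
    build_family_clade_index,
    read_taxon_map,
    smallest_supported_clade,
)
from nematax.taxonomy import TRIVIAL, lineage_lca

from oracles import (
    oracle_is_monophyletic,
    oracle_smallest_supported_clade,
    random_topology,
    to_newick,
    with_random_supports,
)


class TestLineage:
    def test_semicolon_path_parses_to_family(self):
        lin = Lineage.from_path("Nematoda;Enoplea;Enoplida;Oncholaimidae;Viscosia")
        assert lin.family == "Oncholaimidae"
        assert lin.get("genus") == "Viscosia"

    def test_rank_order_enforced(self):
        with pytest.raises(TaxonomyError):
            Lineage.from_pairs([("family", "F"), ("phylum", "Nematoda")])
        with pytest.raises(TaxonomyError):
            Lineage.from_pairs([("family", "F"), ("family", "G")])

    @pytest.mark.parametrize(
        "paths, expected",
        [
            # same family, different genera -> LCA at family
            (["Nematoda;Enoplea;Enoplida;FamX;GenA", "Nematoda;Enoplea;Enoplida;FamX;GenB"],
             ("family", "FamX")),
            # different families within one order -> LCA at order
            (["Nematoda;Enoplea;Enoplida;FamX", "Nematoda;Enoplea;Enoplida;FamY"],
             ("order", "Enoplida")),
            # disagreement at phylum -> no LCA
            (["Nematoda;Enoplea", "Arthropoda;Maxillopoda"], (None, None)),
        ],
    )
    def test_lca_walks_shared_prefix(self, paths, expected):
        assert lineage_lca([Lineage.from_path(p) for p in paths]) == expected


class TestTaxonMap:
    def test_read_rank_columns(self, tmp_path):
        p = tmp_path / "taxa.tsv"
        p.write_text(
            "label\tphylum\tclass\torder\tfamily\tgenus\tspecies\n"
            "AY123\tNematoda\t\tEnoplida\tOncholaimidae\tViscosia\t\n"
            "uncultured eukaryote clone X\tNematoda\t\t\tFamZ\t\t\n"
        )
        taxa = read_taxon_map(p)
        assert taxa.family("AY123") == "Oncholaimidae"
        assert not taxa.is_non_voucher("AY123")
        assert taxa.is_non_voucher("uncultured eukaryote clone X")

    def test_read_semicolon_path_column(self, tmp_path):
        p = tmp_path / "taxa.tsv"
        p.write_text(
            "label\tlineage\nAY123\tNematoda;Enoplea;Enoplida;Oncholaimidae;Viscosia\n"
        )
        assert read_taxon_map(p).family("AY123") == "Oncholaimidae"

    def test_duplicate_label_is_error(self, tmp_path):
        p = tmp_path / "taxa.tsv"
        p.write_text("label\tlineage\nX\tNematoda;;;FamA\nX\tNematoda;;;FamB\n")
        with pytest.raises(TaxonomyError, match="duplicate"):
            read_taxon_map(p)

    def test_missing_family_lists_offenders(self, tmp_path):
        p = tmp_path / "taxa.tsv"
        p.write_text("label\tlineage\nGOOD\tNematoda;Enoplea;Enoplida;FamA\nBAD\tNematoda\n")
        with pytest.raises(TaxonomyError, match="BAD"):
            read_taxon_map(p)

    def test_unknown_label_lookup_raises(self, two_family_taxa):
        with pytest.raises(TaxonomyError):
            two_family_taxa.lineage("nope")

    def test_marker_matching_is_case_insensitive(self):
        taxa = TaxonMap({"Uncultured clone": Lineage.from_path("Nematoda;;;FamA")})
        assert taxa.is_non_voucher("Uncultured clone")


class TestSupportTree:
    def test_supports_read_from_internal_labels(self, two_family_tree):
        sups = sorted(two_family_tree.supports.values())
        assert sups == [95.0, 99.0]

    def test_fractional_supports_scaled(self):
        st = SupportTree.from_newick("((A1:1,A2:1)0.95:1,(B1:1,B2:1)0.99:1);")
        assert sorted(st.supports.values()) == [95.0, 99.0]

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TaxonomyError):
            SupportTree.from_newick("((A:1,A:1)90:1,B:1);")

    def test_outgroup_rerooting_moves_root(self):
        st = SupportTree.from_newick("(((A:1,B:1)90:1,C:1)80:1,OG:1);")
        st.reroot(["OG"])
        root_children_tips = [st.leaves_under(c) for c in st.root.child_nodes()]
        assert {"OG"} in root_children_tips


class TestFamilyCladeIndex:
    def test_perfect_two_family_structure(self, two_family_tree, two_family_taxa):
        idx = build_family_clade_index(two_family_tree, two_family_taxa)
        assert idx["FamA"].monophyletic and idx["FamA"].support == 95.0
        assert idx["FamB"].monophyletic and idx["FamB"].support == 99.0

    def test_interleaved_families_not_monophyletic(
        self, interleaved_tree, two_family_taxa
    ):
        idx = build_family_clade_index(interleaved_tree, two_family_taxa)
        assert not idx["FamA"].monophyletic
        assert not idx["FamB"].monophyletic

    def test_query_tip_inside_clade_is_transparent(self, two_family_taxa):
        st = SupportTree.from_newick("((A1:1,(q7:1,A2:1)70:1)88:1,B1:1);")
        idx = build_family_clade_index(st, two_family_taxa, query_tips={"q7"})
        assert idx["FamA"].monophyletic
        assert idx["FamA"].support == 88.0
        q7 = st.find_tip("q7")
        assert q7 in idx["FamA"].spanning_nodes

    def test_single_tip_family_trivially_monophyletic(self, two_family_taxa):
        st = SupportTree.from_newick("((A1:1,A2:1)95:1,B1:1);")
        idx = build_family_clade_index(st, two_family_taxa)
        assert idx["FamB"].monophyletic
        assert idx["FamB"].support == TRIVIAL
        assert idx["FamB"].trivial

    def test_unknown_tip_is_error(self, two_family_taxa):
        st = SupportTree.from_newick("((A1:1,MYSTERY:1)95:1,B1:1);")
        with pytest.raises(TaxonomyError, match="MYSTERY"):
            build_family_clade_index(st, two_family_taxa)

    def test_edge_ownership_is_a_partition(self, two_family_tree, two_family_taxa):
        idx = build_family_clade_index(two_family_tree, two_family_taxa)
        owned = list(idx.edge_owner)
        assert len(owned) == len(set(owned))
        n_edges = sum(1 for nd in two_family_tree.tree.preorder_node_iter()
                      if nd.parent_node is not None)
        per_family = sum(
            len(idx[f].spanning_nodes) for f in idx.families() if idx[f].monophyletic
        )
        assert per_family <= n_edges


class TestSmallestSupportedClade:
    def test_immediate_cherry(self, two_family_taxa):
        st = SupportTree.from_newick("(((q:1,A1:1)100:1,A2:1)90:1,B1:1);")
        clade = smallest_supported_clade(st, "q", 70, query_tips={"q"})
        assert st.leaves_under(clade) == {"q", "A1"}

    def test_all_supports_below_floor_gives_none(self):
        st = SupportTree.from_newick("(((q:1,A1:1)60:1,A2:1)50:1,B1:1);")
        assert smallest_supported_clade(st, "q", 70, query_tips={"q"}) is None

    def test_boundary_support_is_inclusive(self):
        st = SupportTree.from_newick("(((q:1,A1:1)70:1,A2:1)50:1,B1:1);")
        clade = smallest_supported_clade(st, "q", 70, query_tips={"q"})
        assert st.leaves_under(clade) == {"q", "A1"}

    def test_clade_must_hold_a_reference_tip(self):
        # the 100-support cherry holds only query tips; ascent continues
        st = SupportTree.from_newick("(((q:1,q2:1)100:1,A2:1)90:1,B1:1);")
        clade = smallest_supported_clade(st, "q", 70, query_tips={"q", "q2"})
        assert st.leaves_under(clade) == {"q", "q2", "A2"}

    def test_missing_tip_raises(self, two_family_tree):
        with pytest.raises(TaxonomyError):
            smallest_supported_clade(two_family_tree, "nope", 70)


class TestOracleAgreement:
    """Implementation vs exhaustive clade enumeration on random trees."""

    @pytest.mark.parametrize("n_tips", [4, 7, 12])
    def test_smallest_clade_matches_enumeration(self, n_tips):
        rng = np.random.default_rng(42 + n_tips)
        labels = [f"t{i}" for i in range(n_tips)]
        for _ in range(60):
            t = with_random_supports(random_topology(labels, rng), rng)
            st = SupportTree.from_newick(to_newick(t))
            queries = {lab for lab in labels if rng.random() < 0.3}
            for tip in labels:
                expected = oracle_smallest_supported_clade(t, tip, 70, queries - {tip})
                got = smallest_supported_clade(st, tip, 70, queries - {tip})
                got_tips = None if got is None else frozenset(st.leaves_under(got))
                assert got_tips == expected, (t, tip, queries)

    def test_monophyly_matches_enumeration(self):
        rng = np.random.default_rng(7)
        labels = [f"t{i}" for i in range(10)]
        fams = {lab: f"Fam{i % 3}" for i, lab in enumerate(labels)}
        for _ in range(80):
            t = with_random_supports(random_topology(labels, rng), rng)
            st = SupportTree.from_newick(to_newick(t))
            queries = {lab for lab in labels if rng.random() < 0.2}
            taxa = TaxonMap(
                {
                    lab: Lineage.from_pairs([("phylum", "N"), ("family", fams[lab])])
                    for lab in labels
                    if lab not in queries
                }
            )
            idx = build_family_clade_index(st, taxa, query_tips=queries)
            for fam in idx.families():
                expected = oracle_is_monophyletic(t, idx[fam].tips, queries)
                assert idx[fam].monophyletic == expected, (t, fam, queries)

    def test_query_transparency(self):
        """Grafting query tips anywhere never flips a monophyly verdict."""
        rng = np.random.default_rng(11)
        labels = [f"t{i}" for i in range(8)]
        fams = {lab: f"Fam{i % 2}" for i, lab in enumerate(labels)}
        taxa = TaxonMap(
            {
                lab: Lineage.from_pairs([("phylum", "N"), ("family", fams[lab])])
                for lab in labels
            }
        )
        for _ in range(40):
            t = with_random_supports(random_topology(labels, rng), rng)
            st0 = SupportTree.from_newick(to_newick(t))
            idx0 = build_family_clade_index(st0, taxa)
            verdicts0 = {f: idx0[f].monophyletic for f in idx0.families()}
            # graft queries next to random tips, preserving reference structure
            t_aug = t
            for q in ["q1", "q2", "q3"]:
                host = labels[int(rng.integers(len(labels)))]
                t_aug = _replace_tip(t_aug, host, ((host, q), 50))
            st = SupportTree.from_newick(to_newick(t_aug))
            idx = build_family_clade_index(st, taxa, query_tips={"q1", "q2", "q3"})
            assert {f: idx[f].monophyletic for f in idx.families()} == verdicts0


def _replace_tip(t, tip, replacement):
    if isinstance(t, str):
        return replacement if t == tip else t
    children, support = t
    return (tuple(_replace_tip(c, tip, replacement) for c in children), support)
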