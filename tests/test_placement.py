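"""jplace I/O and the single/cumulative likelihood-weight classifier."""

import json

import pytest

from nematax import (
    Placement,
    PlacementAssignConfig,
    PlacementSet,
    Status,
    SupportTree,
    TaxonomyError,
    assign_by_placement,
    build_family_clade_index,
    placement_summary,
    read_jplace,
    write_jplace,
)
from nematax.assignments import count_by_status
from test_tree_assign import taxa_for

# Two clean family clades; edge ids assigned postorder by the {N} tokens.
JPLACE_TREE = "(((A1:1{0},A2:1{1})90:1{2},A3:1{3})95:1{4},(B1:1{5},B2:1{6})99:1{7}):0;"


def minimal_jplace(tmp_path, placements, fields=None, version=3):
    doc = {
        "version": version,
        "tree": JPLACE_TREE,
        "fields": fields or ["edge_num", "likelihood", "like_weight_ratio"],
        "placements": placements,
        "metadata": {},
    }
    p = tmp_path / "x.jplace"
    p.write_text(json.dumps(doc))
    return p


@pytest.fixture
def two_family_index():
    st = SupportTree.from_newick(JPLACE_TREE)
    taxa = taxa_for(
        {"A1": "FamA", "A2": "FamA", "A3": "FamA", "B1": "FamB", "B2": "FamB"}
    )
    return build_family_clade_index(st, taxa)


def pset(d):
    return PlacementSet(
        {q: [Placement(e, -100.0, w) for e, w in ps] for q, ps in d.items()}
    )


class TestJplaceIO:
    def test_minimal_single_placement_file(self, tmp_path):
        p = minimal_jplace(tmp_path, [{"p": [[0, -1234.5, 1.0]], "n": ["q1"]}])
        tree, ps = read_jplace(p)
        assert len(ps) == 1
        (pl,) = ps.placements_for("q1")
        assert pl.edge_id == 0 and pl.lwr == 1.0
        assert set(tree.edge_ids.values()) == set(range(8))

    def test_lwr_sum_invariant_enforced(self, tmp_path):
        p = minimal_jplace(
            tmp_path, [{"p": [[0, -1.0, 0.6], [1, -1.0, 0.5]], "n": ["q1"]}]
        )
        with pytest.raises(TaxonomyError, match="sum"):
            read_jplace(p)

    def test_missing_fields_rejected(self, tmp_path):
        p = minimal_jplace(
            tmp_path,
            [{"p": [[0, 1.0]], "n": ["q1"]}],
            fields=["edge_num", "likelihood"],
        )
        with pytest.raises(TaxonomyError, match="fields"):
            read_jplace(p)

    def test_unknown_version_rejected(self, tmp_path):
        p = minimal_jplace(tmp_path, [], version=9)
        with pytest.raises(TaxonomyError, match="version"):
            read_jplace(p)

    def test_edge_num_outside_tree_rejected(self, tmp_path):
        p = minimal_jplace(tmp_path, [{"p": [[42, -1.0, 1.0]], "n": ["q1"]}])
        with pytest.raises(TaxonomyError, match="42"):
            read_jplace(p)

    def test_round_trip_preserves_edges_and_lwrs(self, tmp_path):
        p = minimal_jplace(
            tmp_path,
            [
                {"p": [[0, -10.0, 0.625], [3, -11.0, 0.25]], "n": ["q1"]},
                {"p": [[7, -9.0, 1.0]], "nm": [["q2", 13]]},
            ],
        )
        tree, ps = read_jplace(p)
        out = tmp_path / "rt.jplace"
        write_jplace(tree, ps, out)
        tree2, ps2 = read_jplace(out)
        assert tree2.edge_ids.values() != {}
        for q in ps.queries():
            a = [(x.edge_id, x.lwr) for x in ps.placements_for(q)]
            b = [(x.edge_id, x.lwr) for x in ps2.placements_for(q)]
            assert a == b
        # tip-to-edge-id mapping identical after the round trip
        def tip_edges(t):
            return {
                nd.taxon.label: eid
                for nd, eid in t.edge_ids.items()
                if nd.is_leaf()
            }
        assert tip_edges(tree) == tip_edges(tree2)


class TestAssignByPlacement:
    def test_single_certain_placement(self, two_family_index):
        out = assign_by_placement(pset({"q": [(0, 1.0)]}), two_family_index)
        (a,) = out
        assert a.status == Status.ASSIGNED and a.family == "FamA"
        assert a.evidence["rule"] == "single"
        assert a.evidence["best_lwr"] == 1.0

    def test_cumulative_rule_forced(self, two_family_index):
        # 0.50 + 0.30 + 0.17 spread over FamA's three in-clade edges
        out = assign_by_placement(
            pset({"q": [(0, 0.50), (1, 0.30), (3, 0.17)]}), two_family_index
        )
        (a,) = out
        assert a.status == Status.ASSIGNED and a.family == "FamA"
        assert a.evidence["rule"] == "cumulative"
        assert a.evidence["cum_lwr"] == pytest.approx(0.97)

    def test_single_rule_evidence_preferred_when_both_apply(self, two_family_index):
        out = assign_by_placement(
            pset({"q": [(0, 0.96), (1, 0.04)]}), two_family_index
        )
        (a,) = out
        assert a.evidence["rule"] == "single"

    def test_split_below_threshold_unassigned(self, two_family_index):
        out = assign_by_placement(
            pset({"q": [(0, 0.5), (5, 0.3)]}), two_family_index
        )
        (a,) = out
        assert a.status == Status.UNASSIGNED

    def test_sister_family_split_at_threshold_is_ambiguous(self, two_family_index):
        # FamA and FamB are sisters: a 0.5/0.5 split reaches the joint
        # threshold without either side sufficing alone
        out = assign_by_placement(
            pset({"q": [(0, 0.5), (5, 0.5)]}), two_family_index
        )
        (a,) = out
        assert a.status == Status.AMBIGUOUS
        assert set(a.candidates) == {"FamA", "FamB"}

    def test_mrca_subtending_edge_is_outside_clade(self, two_family_index):
        # edge 4 subtends FamA's MRCA: mass there supports neither family
        out = assign_by_placement(pset({"q": [(4, 1.0)]}), two_family_index)
        (a,) = out
        assert a.status == Status.UNASSIGNED

    def test_support_floor_gates_eligibility(self):
        st = SupportTree.from_newick("((A1:1{0},A2:1{1})60:1{2},(B1:1{3},B2:1{4})99:1{5}):0;")
        taxa = taxa_for({"A1": "FamA", "A2": "FamA", "B1": "FamB", "B2": "FamB"})
        idx = build_family_clade_index(st, taxa)
        out = assign_by_placement(pset({"q": [(0, 1.0)]}), idx)
        assert out[0].status == Status.UNASSIGNED
        relaxed = assign_by_placement(
            pset({"q": [(0, 1.0)]}),
            idx,
            PlacementAssignConfig(min_clade_support=50),
        )
        assert relaxed[0].status == Status.ASSIGNED

    def test_single_tip_family_pendant_edge_counts_inside(self):
        st = SupportTree.from_newick("((A1:1{0},A2:1{1})95:1{2},B1:1{3}):0;")
        taxa = taxa_for({"A1": "FamA", "A2": "FamA", "B1": "FamB"})
        idx = build_family_clade_index(st, taxa)
        out = assign_by_placement(pset({"q": [(3, 0.97)]}), idx)
        (a,) = out
        assert a.status == Status.ASSIGNED and a.family == "FamB"

    def test_nested_clade_in_assemblage_ambiguous(self):
        # FamP's references (P1, P2) straddle nested monophyletic FamN:
        # a paraphyletic assemblage with FamN inside its spanning clade.
        st = SupportTree.from_newick(
            "((P1:1{0},((N1:1{1},N2:1{2})98:1{3},P2:1{4})90:1{5})85:1{6},Z1:1{7}):0;"
        )
        taxa = taxa_for(
            {"P1": "FamP", "P2": "FamP", "N1": "FamN", "N2": "FamN", "Z1": "FamZ"}
        )
        idx = build_family_clade_index(st, taxa)
        assert not idx["FamP"].monophyletic
        assert idx["FamN"].monophyletic
        # 0.55 on assemblage-only edges, 0.42 inside the nested clade
        out = assign_by_placement(
            pset({"q": [(0, 0.30), (4, 0.25), (1, 0.42)]}), idx
        )
        (a,) = out
        assert a.status == Status.AMBIGUOUS
        assert set(a.candidates) == {"FamN", "FamP"}
        assert a.evidence["pair_lwr"] == pytest.approx(0.97)

    def test_distant_families_never_pair(self):
        # FamA and FamC share no clade boundary (neither nested nor
        # sister): their joint mass may cross the bar but stays unassigned
        st = SupportTree.from_newick(
            "(((A1:1{0},A2:1{1})95:1{2},(B1:1{3},B2:1{4})99:1{5})90:1{6},"
            "(C1:1{7},C2:1{8})98:1{9}):0;"
        )
        taxa = taxa_for(
            {"A1": "FamA", "A2": "FamA", "B1": "FamB",
             "B2": "FamB", "C1": "FamC", "C2": "FamC"}
        )
        idx = build_family_clade_index(st, taxa)
        out = assign_by_placement(pset({"q": [(0, 0.5), (7, 0.45)]}), idx)
        assert out[0].status == Status.UNASSIGNED

    def test_threshold_monotonicity(self, two_family_index):
        queries = {
            "q1": [(0, 0.8), (1, 0.15)],
            "q2": [(0, 0.5), (5, 0.4)],
            "q3": [(5, 0.99)],
            "q4": [(0, 0.4), (1, 0.3), (2, 0.3)],
        }
        counts = []
        for thr in (0.5, 0.7, 0.9, 0.95, 1.0):
            out = assign_by_placement(
                pset(queries),
                two_family_index,
                PlacementAssignConfig(likelihood_threshold=thr),
            )
            counts.append(sum(a.assigned for a in out))
        assert counts == sorted(counts, reverse=True)

    def test_renormalization_restores_truncated_mass(self, two_family_index):
        truncated = pset({"q": [(0, 0.6), (1, 0.2)]})  # 0.2 mass lost
        strict = assign_by_placement(truncated, two_family_index)
        assert strict[0].status == Status.UNASSIGNED
        renorm = assign_by_placement(
            truncated,
            two_family_index,
            PlacementAssignConfig(renormalize=True),
        )
        assert renorm[0].status == Status.ASSIGNED and renorm[0].family == "FamA"


class TestPlacementSummary:
    def test_statuses_partition_queries(self, two_family_index):
        out = assign_by_placement(
            pset(
                {
                    "q1": [(0, 1.0)],
                    "q2": [(0, 0.5), (5, 0.5)],
                    "q3": [(5, 0.96)],
                }
            ),
            two_family_index,
        )
        counts = count_by_status(out)
        assert counts["total"] == 3
        assert sum(v for k, v in counts.items() if k != "total") == 3
        table = placement_summary(out)
        assert int(table.loc[table.status == "total", "count"].iloc[0]) == 3

    def test_empty_input_all_zero(self):
        table = placement_summary([])
        assert (table["count"] == 0).all()
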