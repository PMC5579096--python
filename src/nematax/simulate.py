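"""Synthetic reference trees, taxonomies, placements, hit tables and
morphospecies lists with known ground truth.

The generator emulates the data a family-level metabarcoding study feeds
the three classifiers: a reference phylogeny in which families form
clades with controllable bootstrap support and a controllable fraction of
broken (paraphyletic) families; per-query placement distributions whose
likelihood weight concentrates inside the true family's clade to a
controllable degree; similarity-hit tables with identity decay across
taxonomic distance, score ties, and "uncultured"-style contaminant top
hits; and a morphology-side species list produced by binomial thinning of
the true per-family richness.

Everything is a pure function of (config, seed): the same seed always
reproduces the same fixture. Branch lengths are arbitrary positive values
(no classifier in this package consumes them); difficulty is modelled at
the tree/placement/hit level, not at the sequence level.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .placement import Placement, PlacementSet, write_jplace
from .alignment import HitRecord, HitTable
from .taxonomy import (
    RANKS,
    FamilyCladeIndex,
    Lineage,
    SupportTree,
    TaxonMap,
    TaxonomyError,
    build_family_clade_index,
)


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the scale of a marine-nematode metabarcoding survey:
    a ~300-tip reference tree spanning a few dozen families, 139 query
    OTUs, mostly well-supported family clades with a minority broken by
    paraphyly, placements that usually but not always concentrate inside
    the true clade, and a ~90-99% identity band for within-family hits.
    """

    n_families: int = 30
    tips_per_family: tuple[int, int] = (2, 18)  # inclusive range
    n_queries: int = 139
    support_mean: float = 85.0
    support_sd: float = 15.0
    paraphyly_fraction: float = 0.1
    placement_concentration: float = 2000.0
    #: symmetric Dirichlet base weight per edge; small values make the
    #: likelihood-weight vectors sparse, as placement tools emit
    placement_base_alpha: float = 0.05
    identity_decay: float = 6.0  # identity % lost per rank of distance
    contamination_rate: float = 0.1
    off_reference_fraction: float = 0.1
    #: bootstrap-support penalty (percentage points off the mean) for the
    #: joint reference+query tree: co-inferring short query sequences
    #: erodes clade support relative to the reference-only inference
    query_support_penalty: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("paraphyly_fraction", "contamination_rate", "off_reference_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0,1]: {v}")
        if self.placement_concentration < 0:
            raise ValueError("placement_concentration must be >= 0")
        if self.placement_base_alpha <= 0:
            raise ValueError("placement_base_alpha must be > 0")
        if self.n_families < 2:
            raise ValueError("need at least 2 families")
        lo, hi = self.tips_per_family
        if not 1 <= lo <= hi:
            raise ValueError(f"bad tips_per_family range: {self.tips_per_family}")


#: difficulty tags carried in the truth table
CLEAN = "clean"
PARAPHYLETIC = "paraphyletic-target"
OFF_REFERENCE = "off-reference"


def _draw_support(rng: np.random.Generator, mean: float, sd: float) -> int:
    if sd <= 0:
        return int(round(min(100.0, max(0.0, mean))))
    a, b = (0 - mean) / sd, (100 - mean) / sd
    v = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
    return int(round(v))


def _grow_random_tree(
    rng: np.random.Generator,
    taxon_namespace: dendropy.TaxonNamespace,
    labels: Sequence[str],
) -> dendropy.Node:
    """Random binary subtree over the labels (sequential leaf splitting)."""
    root = dendropy.Node()
    root.edge.length = float(rng.exponential(0.1))
    leaves = [root]
    while len(leaves) < len(labels):
        target = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = float(rng.exponential(0.1))
            target.add_child(child)
            leaves.append(child)
    for node, label in zip(leaves, labels):
        node.taxon = taxon_namespace.require_taxon(label=label)
    return root


def simulate_reference(cfg: SimConfig) -> tuple[SupportTree, TaxonMap, pd.DataFrame]:
    """Reference tree + taxonomy map + query truth table.

    Family clades are grown on a random backbone; supports are drawn from
    a truncated normal on [0, 100]; with probability
    ``paraphyly_fraction`` a multi-tip family is broken by regrafting one
    member outside its clade (next to another family's clade, which that
    family's monophyly survives). The taxonomy map also carries a few
    non-voucher ("uncultured ...") labels used as contaminant hit
    subjects; they are not tree tips.
    """
    rng = np.random.default_rng(cfg.seed)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)

    fam_names = [f"Fam{i:02d}" for i in range(1, cfg.n_families + 1)]
    lo, hi = cfg.tips_per_family
    fam_sizes = {f: int(rng.integers(lo, hi + 1)) for f in fam_names}
    fam_tips = {
        f: [f"{f}_t{j}" for j in range(1, fam_sizes[f] + 1)] for f in fam_names
    }

    # backbone over families, then per-family expansion
    backbone_root = _grow_random_tree(rng, dendropy.TaxonNamespace(), fam_names)
    backbone_root.edge.length = None
    tree.seed_node = backbone_root
    for leaf in list(tree.leaf_node_iter()):
        fam = leaf.taxon.label
        leaf.taxon = None
        sub = _grow_random_tree(rng, ns, fam_tips[fam])
        if sub.is_leaf():
            leaf.taxon = sub.taxon
        else:
            for child in sub.child_nodes():
                leaf.add_child(child)
    tree.update_taxon_namespace()

    supports: dict = {}
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf():
            supports[nd] = float(
                _draw_support(rng, cfg.support_mean, cfg.support_sd)
            )
    st = SupportTree(tree, supports=supports)

    # taxonomy: families grouped into orders (5 per order), orders into
    # classes (3 per order-group), one phylum
    entries: dict[str, Lineage] = {}
    for i, fam in enumerate(fam_names):
        order = f"Ord{i // 5 + 1:02d}"
        klass = f"Cla{i // 15 + 1:02d}"
        for j, tip in enumerate(fam_tips[fam], start=1):
            entries[tip] = Lineage.from_pairs(
                [
                    ("phylum", "Nematoda"),
                    ("class", klass),
                    ("order", order),
                    ("family", fam),
                    ("genus", f"Gen_{fam}_{j}"),
                    ("species", f"Gen_{fam}_{j} sp{j}"),
                ]
            )

    # break some families (regraft one member next to another family)
    broken: set[str] = set()
    multi = [f for f in fam_names if fam_sizes[f] >= 2]
    for fam in multi:
        if rng.random() < cfg.paraphyly_fraction:
            broken.add(fam)
    if broken:
        for fam in sorted(broken):
            # re-index per regraft: earlier moves reshape the tree
            idx0 = build_family_clade_index(st, TaxonMap(entries), query_tips=())
            mover = st.find_tip(fam_tips[fam][0])
            # host must hang below the root so its subtending edge exists,
            # and must survive the pruning of the mover's unary parent
            others = [
                f
                for f in fam_names
                if f != fam
                and idx0[f].mrca.parent_node is not None
                and idx0[f].mrca is not mover.parent_node
            ]
            if others:
                host = others[int(rng.integers(len(others)))]
                host_mrca = idx0[host].mrca
            else:
                # heavily broken trees: fall back to any surviving edge
                # outside the mover's own family
                own = set(fam_tips[fam])
                pool = sorted(
                    (
                        nd
                        for nd in st.tree.preorder_node_iter()
                        if nd.parent_node is not None
                        and nd is not mover.parent_node
                        and nd is not mover
                        and not (st.leaves_under(nd) & own)
                    ),
                    key=lambda nd: min(st.leaves_under(nd)),
                )
                host_mrca = pool[int(rng.integers(len(pool)))]
            _prune_leaf(tree, mover)
            _attach_at_edge(
                st,
                host_mrca,
                mover,
                support=_draw_support(rng, cfg.support_mean, cfg.support_sd),
                rng=rng,
            )
        tree.update_taxon_namespace()

    # contaminant (non-voucher) hit subjects, never tree tips
    n_contam = max(3, cfg.n_families // 5)
    for c in range(1, n_contam + 1):
        fam = fam_names[int(rng.integers(len(fam_names)))]
        entries[f"uncultured eukaryote clone U{c}"] = entries[fam_tips[fam][0]]

    taxa = TaxonMap(entries)
    _assign_edge_ids(st)

    # query truth
    rows = []
    for k in range(1, cfg.n_queries + 1):
        qid = f"OTU{k:04d}"
        if rng.random() < cfg.off_reference_fraction:
            rows.append((qid, f"OffFam{k:02d}", OFF_REFERENCE))
        else:
            fam = fam_names[int(rng.integers(len(fam_names)))]
            tag = PARAPHYLETIC if fam in broken else CLEAN
            rows.append((qid, fam, tag))
    truth = pd.DataFrame(rows, columns=["query_id", "true_family", "difficulty"])
    return st, taxa, truth


def _prune_leaf(tree: dendropy.Tree, leaf: dendropy.Node) -> None:
    parent = leaf.parent_node
    parent.remove_child(leaf)
    # suppress the now-unary parent
    if parent.num_child_nodes() == 1 and parent.parent_node is not None:
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        grand.remove_child(parent)
        grand.add_child(only)


def _attach_at_edge(
    st: SupportTree,
    at_node: dendropy.Node,
    new_leaf: dendropy.Node,
    support: float,
    rng: np.random.Generator,
) -> None:
    """Split the edge above ``at_node`` and hang ``new_leaf`` there."""
    parent = at_node.parent_node
    if parent is None:
        raise TaxonomyError("cannot attach above the root")
    parent.remove_child(at_node)
    joint = dendropy.Node()
    joint.edge.length = float(rng.exponential(0.1))
    parent.add_child(joint)
    joint.add_child(at_node)
    joint.add_child(new_leaf)
    st.supports[joint] = float(support)


def _assign_edge_ids(st: SupportTree) -> None:
    """Number edges 0..E-1 in postorder (jplace style)."""
    st.edge_ids.clear()
    nodes = list(st.tree.postorder_node_iter())[:-1]  # root edge unnumbered
    for i, nd in enumerate(nodes):
        st.edge_ids[nd] = i


def attach_queries(
    ref_newick: str,
    taxa: TaxonMap,
    truth: pd.DataFrame,
    cfg: SimConfig,
) -> SupportTree:
    """Reference+query tree for the tree-based classifier.

    Clean and paraphyletic-target queries attach on an edge inside their
    true family's (MRCA-spanning) clade; off-reference queries attach on
    an arbitrary edge outside every family clade when one exists, else
    anywhere. All supports — existing internal nodes and the joints the
    attachments create — are re-drawn with the mean lowered by
    ``query_support_penalty``, since the joint tree is a fresh inference
    whose supports suffer from the added short query sequences.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    st = SupportTree.from_newick(ref_newick)
    joint_mean = cfg.support_mean - cfg.query_support_penalty
    for nd in st.tree.preorder_node_iter():
        if not nd.is_leaf():
            st.supports[nd] = float(
                _draw_support(rng, joint_mean, cfg.support_sd)
            )
    idx = build_family_clade_index(st, taxa, query_tips=())
    in_any_clade = set()
    for fam in idx.families():
        in_any_clade |= idx[fam].spanning_nodes
        in_any_clade.add(idx[fam].mrca)  # splitting the subtending edge
        # would create a clade that looks like the family plus the query

    for row in truth.to_dict("records"):
        qid, fam, tag = row["query_id"], row["true_family"], row["difficulty"]
        if tag == OFF_REFERENCE:
            pool = [
                nd
                for nd in st.tree.preorder_node_iter()
                if nd.parent_node is not None and nd not in in_any_clade
            ]
            if not pool:
                pool = [
                    nd
                    for nd in st.tree.preorder_node_iter()
                    if nd.parent_node is not None
                ]
        else:
            if fam not in idx:
                raise TaxonomyError(f"true family {fam!r} not in reference")
            pool = sorted(
                (nd for nd in idx[fam].spanning_nodes if nd.parent_node is not None),
                key=lambda nd: min(st.leaves_under(nd)),
            )
        at = pool[int(rng.integers(len(pool)))]
        leaf = dendropy.Node()
        leaf.taxon = st.tree.taxon_namespace.require_taxon(label=qid)
        leaf.edge.length = float(rng.exponential(0.1))
        _attach_at_edge(
            st, at, leaf, support=_draw_support(rng, joint_mean, cfg.support_sd), rng=rng
        )
        # keep the family clade index in sync with the growing tree: the
        # new joint node lies inside whatever spanning sets 'at' was in
        for fam2 in idx.families():
            if at in idx[fam2].spanning_nodes:
                idx.clades[fam2] = dataclasses.replace(
                    idx.clades[fam2],
                    spanning_nodes=idx.clades[fam2].spanning_nodes
                    | {leaf.parent_node, leaf},
                )
                if at in in_any_clade:
                    in_any_clade |= {leaf.parent_node, leaf}
    st.tree.update_taxon_namespace()
    return st


def simulate_placements(
    ref: SupportTree,
    idx: FamilyCladeIndex,
    truth: pd.DataFrame,
    cfg: SimConfig,
) -> PlacementSet:
    """Dirichlet likelihood-weight vectors over the reference edges.

    For a query with true family F the Dirichlet gets ``1 + c`` pseudo-
    mass on one randomly chosen edge inside F's clade and 1 elsewhere
    (c = ``placement_concentration``): c → ∞ concentrates all weight on
    a single in-clade edge, c = 0 is the symmetric Dirichlet over every
    edge. Off-reference queries always draw from the symmetric Dirichlet.
    The per-query weights sum to 1 exactly (nothing is truncated).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    nodes = [nd for nd in ref.tree.postorder_node_iter() if nd in ref.edge_ids]
    if not nodes:
        raise TaxonomyError("reference tree has no edge ids")
    edge_ids = np.array([ref.edge_ids[nd] for nd in nodes])
    n_edges = len(nodes)

    placements: dict[str, list[Placement]] = {}
    for row in truth.to_dict("records"):
        qid, fam, tag = row["query_id"], row["true_family"], row["difficulty"]
        alpha = np.full(n_edges, cfg.placement_base_alpha)
        if tag != OFF_REFERENCE:
            if fam not in idx:
                raise TaxonomyError(f"true family {fam!r} not in clade index")
            inside = [
                i for i, nd in enumerate(nodes) if nd in idx[fam].spanning_nodes
            ]
            if not inside:
                raise TaxonomyError(f"family {fam!r} has no in-clade edges")
            target = inside[int(rng.integers(len(inside)))]
            if np.isinf(cfg.placement_concentration):
                lwr = np.zeros(n_edges)
                lwr[target] = 1.0
                placements[qid] = _to_placements(edge_ids, lwr, rng)
                continue
            alpha[target] += cfg.placement_concentration
        lwr = rng.dirichlet(alpha)
        placements[qid] = _to_placements(edge_ids, lwr, rng)
    return PlacementSet(placements)


def _to_placements(
    edge_ids: np.ndarray, lwr: np.ndarray, rng: np.random.Generator
) -> list[Placement]:
    base_ll = -3000.0 + float(rng.normal(0, 10))
    out = []
    for eid, w in zip(edge_ids, lwr):
        if w <= 0:
            continue
        out.append(
            Placement(
                edge_id=int(eid),
                log_likelihood=base_ll + float(np.log(max(w, 1e-300))),
                lwr=float(w),
            )
        )
    return out


def simulate_hits(
    taxa: TaxonMap,
    truth: pd.DataFrame,
    cfg: SimConfig,
) -> HitTable:
    """BLAST-like hit tables with identity decay and contaminant top hits.

    True-family subjects score in the 90-99% family band; decoy subjects
    lose ``identity_decay`` percent per rank of taxonomic distance (same
    order, then different order). Bit score is a fixed monotone function
    of identity. With probability ``contamination_rate`` a non-voucher
    subject is injected above the best true hit. Off-reference queries
    only receive decoy-band hits (below the family floor).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    by_family: dict[str, list[str]] = {}
    order_of: dict[str, str] = {}
    contaminants: list[str] = []
    for label in taxa.labels():
        if taxa.is_non_voucher(label):
            contaminants.append(label)
            continue
        lin = taxa.lineage(label)
        by_family.setdefault(lin.family, []).append(label)
        order_of[lin.family] = lin.get("order") or ""
    families = sorted(by_family)

    def bit_score(identity: float) -> float:
        return round(identity * 6.0, 1)

    records: list[HitRecord] = []
    for row in truth.to_dict("records"):
        qid, fam, tag = row["query_id"], row["true_family"], row["difficulty"]
        if tag == OFF_REFERENCE:
            top_identity = 0.0
            for other in rng.choice(families, size=min(5, len(families)), replace=False):
                for subj in by_family[other][:2]:
                    ident = float(rng.uniform(75, 85))
                    top_identity = max(top_identity, ident)
                    records.append(
                        HitRecord(qid, subj, round(ident, 1), 100.0, bit_score(ident))
                    )
        else:
            members = by_family[fam]
            n_true = min(len(members), 5)
            # sparser reference families sit farther from any query: the
            # identity band shifts down as coverage thins out, dipping
            # below the 90% family floor when only a member or two exist
            band_lo = 80.0 + 2.5 * min(len(members), 5)
            band_hi = min(band_lo + 10.0, 99.5)
            idents = np.sort(rng.uniform(band_lo, band_hi, size=n_true))[::-1]
            top_identity = float(idents[0])
            for subj, ident in zip(members, idents):
                records.append(
                    HitRecord(qid, subj, round(float(ident), 1), 100.0, bit_score(float(ident)))
                )
            for other in families:
                if other == fam:
                    continue
                dist = 1.0 if order_of[other] == order_of[fam] else 2.0
                ident = top_identity - cfg.identity_decay * dist - float(
                    rng.uniform(0, 2)
                )
                if ident < 50:
                    continue
                records.append(
                    HitRecord(
                        qid,
                        by_family[other][0],
                        round(max(ident, 0.0), 1),
                        100.0,
                        bit_score(max(ident, 0.0)),
                    )
                )
        if contaminants and rng.random() < cfg.contamination_rate:
            subj = contaminants[int(rng.integers(len(contaminants)))]
            ident = min(100.0, top_identity + 0.3)
            records.append(
                HitRecord(qid, subj, round(ident, 1), 100.0, bit_score(ident) + 1.0)
            )
    return HitTable(records)


def simulate_morpho(
    truth: pd.DataFrame,
    detection_prob: Union[float, Mapping[str, float]] = 0.8,
    seed: int = 0,
    sample: str = "S1",
) -> pd.DataFrame:
    """Morphology-side per-family counts by binomial thinning.

    True richness per family is the number of queries carrying it
    (off-reference families included: morphology can see families the
    reference database lacks). ``detection_prob`` may be one probability
    or a per-family mapping; a family with probability 0 models taxa a
    morphological survey systematically misses (endoparasites) or,
    inverted, taxa only morphology finds.
    """
    rng = np.random.default_rng(seed)
    richness = truth.groupby("true_family").size().sort_index()
    rows = []
    for fam, n in richness.items():
        p = (
            detection_prob.get(fam, 0.8)
            if isinstance(detection_prob, Mapping)
            else float(detection_prob)
        )
        if not 0 <= p <= 1:
            raise ValueError(f"detection probability outside [0,1] for {fam}: {p}")
        rows.append((fam, sample, int(rng.binomial(int(n), p))))
    return pd.DataFrame(rows, columns=["family", "sample", "morphospecies_count"])


# ---------------------------------------------------------------------------
# fixture directory
# ---------------------------------------------------------------------------

def write_taxon_map(taxa: TaxonMap, path: Union[str, Path]) -> None:
    rows = []
    for label in taxa.labels():
        lin = taxa.lineage(label)
        rows.append([label] + [lin.get(r) or "" for r in RANKS])
    pd.DataFrame(rows, columns=["label", *RANKS]).to_csv(path, sep="\t", index=False)


def simulate_all(cfg: SimConfig, outdir: Union[str, Path]) -> dict[str, Path]:
    """Emit a complete fixture directory for the whole pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, taxa, truth = simulate_reference(cfg)
    idx = build_family_clade_index(ref, taxa, query_tips=())
    ps = simulate_placements(ref, idx, truth, cfg)
    hits = simulate_hits(taxa, truth, cfg)
    qtree = attach_queries(ref.to_newick(), taxa, truth, cfg)
    morpho = simulate_morpho(truth, seed=cfg.seed + 4)

    paths = {
        "reference": outdir / "reference.nwk",
        "query_tree": outdir / "query_tree.nwk",
        "taxa": outdir / "taxa.tsv",
        "jplace": outdir / "queries.jplace",
        "hits": outdir / "hits.tsv",
        "morpho": outdir / "morpho.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.json",
    }
    paths["reference"].write_text(ref.to_newick() + "\n")
    paths["query_tree"].write_text(qtree.to_newick() + "\n")
    write_taxon_map(taxa, paths["taxa"])
    write_jplace(ref, ps, paths["jplace"])
    hits.to_frame().rename(
        columns={
            "query_id": "qseqid",
            "subject_id": "sseqid",
            "identity": "pident",
            "coverage": "qcovs",
            "bit_score": "bitscore",
        }
    ).to_csv(paths["hits"], sep="\t", index=False)
    morpho.to_csv(paths["morpho"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["config"].write_text(json.dumps(dataclasses.asdict(cfg), indent=1))
    return paths
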