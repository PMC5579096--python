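"""Shared domain types for family-level taxonomy assignment.

This module holds the ranked-lineage model, the taxonomy map (sequence
label -> lineage, with flags for non-voucher GenBank-style labels such as
"uncultured eukaryote clone ..."), the support-annotated reference tree,
and the clade machinery every classifier builds on: per-family monophyly,
MRCA clades with bootstrap support, and the ascent to the smallest
supported clade above a query tip.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy

logger = logging.getLogger(__name__)

#: Canonical rank order, highest first. Family is the pivotal rank: every
#: reference record used by a classifier must carry one.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")

FAMILY_INDEX = RANKS.index("family")

#: Label substrings marking sequences without a vouchered, identified source.
DEFAULT_NON_VOUCHER_MARKERS: tuple[str, ...] = (
    "uncultured",
    "unidentified",
    "environmental",
)

#: Sentinel support value for single-tip families, whose "clade" is the
#: pendant edge and has no bootstrap value of its own.
TRIVIAL = "trivial"


class TaxonomyError(ValueError):
    """Raised for malformed or inconsistent taxonomy inputs."""


@dataclass(frozen=True)
class Lineage:
    """A ranked taxon path from phylum down to species.

    Ranks may be missing from the bottom up (e.g. a record identified only
    to family), but the order is fixed and no rank repeats.
    """

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [r for r, _ in self.ranks]
        if len(set(names)) != len(names):
            raise TaxonomyError(f"duplicate rank in lineage: {names}")
        order = [RANKS.index(r) for r in names]  # raises on unknown rank
        if order != sorted(order):
            raise TaxonomyError(f"ranks out of order: {names}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Lineage":
        return cls(tuple((r.lower(), t) for r, t in pairs if t))

    @classmethod
    def from_path(cls, path: str, sep: str = ";") -> "Lineage":
        """Build from a semicolon path assumed to start at phylum."""
        parts = [p.strip() for p in path.split(sep) if p.strip()]
        if len(parts) > len(RANKS):
            raise TaxonomyError(f"path longer than {len(RANKS)} ranks: {path!r}")
        return cls(tuple(zip(RANKS, parts)))

    def get(self, rank: str) -> Optional[str]:
        for r, t in self.ranks:
            if r == rank:
                return t
        return None

    @property
    def family(self) -> Optional[str]:
        return self.get("family")

    def taxon_at_depth(self, depth: int) -> Optional[str]:
        """Taxon at RANKS[depth], or None if absent."""
        return self.get(RANKS[depth])


def lineage_lca(lineages: Sequence[Lineage]) -> tuple[Optional[str], Optional[str]]:
    """Lowest common ancestor of several lineages.

    Walks the fixed rank order from phylum downwards while every lineage
    names the same taxon at that rank. Returns ``(rank, taxon)`` of the
    deepest shared level, or ``(None, None)`` if the lineages disagree
    already at phylum (or the input is empty).
    """
    if not lineages:
        return None, None
    best: tuple[Optional[str], Optional[str]] = (None, None)
    for depth, rank in enumerate(RANKS):
        taxa = {ln.taxon_at_depth(depth) for ln in lineages}
        if taxa == {None}:
            continue  # rank absent everywhere: transparent, keep walking
        if len(taxa) != 1:
            break
        best = (rank, taxa.pop())
    return best


class TaxonMap:
    """Mapping from sequence/tip label to :class:`Lineage`.

    Labels are unique; lookup of an unknown label raises (silent misses
    hide data errors). Each label carries a "non-voucher" flag set when it
    contains one of the configured marker substrings (case-insensitive).
    """

    def __init__(
        self,
        entries: Mapping[str, Lineage],
        markers: Sequence[str] = DEFAULT_NON_VOUCHER_MARKERS,
    ) -> None:
        self._entries = dict(entries)
        self._markers = tuple(m.lower() for m in markers)
        self._flags = {
            label: any(m in label.lower() for m in self._markers)
            for label in self._entries
        }

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, label: str) -> bool:
        return label in self._entries

    def __iter__(self):
        return iter(self._entries)

    def lineage(self, label: str) -> Lineage:
        try:
            return self._entries[label]
        except KeyError:
            raise TaxonomyError(f"label not in taxonomy map: {label!r}") from None

    def family(self, label: str) -> Optional[str]:
        return self.lineage(label).family

    def is_non_voucher(self, label: str) -> bool:
        if label not in self._flags:
            raise TaxonomyError(f"label not in taxonomy map: {label!r}")
        return self._flags[label]

    def labels(self) -> list[str]:
        return list(self._entries)

    def with_entries(self, extra: Mapping[str, Lineage]) -> "TaxonMap":
        """New map with additional entries (duplicates are an error)."""
        dup = set(extra) & set(self._entries)
        if dup:
            raise TaxonomyError(f"duplicate labels: {sorted(dup)}")
        merged = dict(self._entries)
        merged.update(extra)
        return TaxonMap(merged, self._markers)


def read_taxon_map(
    path: Union[str, Path],
    markers: Sequence[str] = DEFAULT_NON_VOUCHER_MARKERS,
    require_family: bool = True,
) -> TaxonMap:
    """Read a TSV taxonomy map.

    Two layouts are accepted, detected from the header:

    * ``label`` plus per-rank columns (``phylum`` ... ``species``);
    * ``label`` plus a single ``lineage`` column holding a semicolon path
      starting at phylum.

    ``require_family=True`` enforces that every record resolves a family,
    the rank all classifiers in this package target; offending labels are
    listed in the error.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = [h.strip().lower() for h in header_line.split("\t")]
        if "label" not in header:
            raise TaxonomyError(f"{path}: header must contain a 'label' column")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise TaxonomyError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            rows.append(dict(zip(header, cells)))

    entries: dict[str, Lineage] = {}
    missing_family: list[str] = []
    for row in rows:
        label = row["label"].strip()
        if label in entries:
            raise TaxonomyError(f"{path}: duplicate label {label!r}")
        if "lineage" in row:
            lin = Lineage.from_path(row["lineage"])
        else:
            lin = Lineage.from_pairs((r, row.get(r, "").strip()) for r in RANKS)
        if require_family and lin.family is None:
            missing_family.append(label)
        entries[label] = lin
    if missing_family:
        raise TaxonomyError(
            f"{path}: records lacking a family: {sorted(missing_family)}"
        )
    return TaxonMap(entries, markers)


# ---------------------------------------------------------------------------
# Support-annotated trees
# ---------------------------------------------------------------------------

_EDGE_NUM_RE = re.compile(r"\{(\d+)\}")


class SupportTree:
    """A rooted tree with optional bootstrap supports and jplace edge ids.

    Thin wrapper over a :class:`dendropy.Tree`. Supports are integers in
    [0, 100] read from internal node labels; newick exports using the
    [0, 1] dialect are auto-scaled with a warning. Edge ids come from the
    ``{N}`` tokens of jplace tree strings and, when present, are unique
    and cover every edge.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        supports: Optional[dict] = None,
        edge_ids: Optional[dict] = None,
    ) -> None:
        self.tree = tree
        # clade semantics are rooted throughout; "as read" means the seed
        # node of the newick string acts as the root
        self.tree.is_rooted = True
        #: node -> support percent (internal nodes only)
        self.supports: dict = supports if supports is not None else {}
        #: node -> integer edge id of the edge subtending the node
        self.edge_ids: dict = edge_ids if edge_ids is not None else {}
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise TaxonomyError("tip labels are not unique")
        if self.edge_ids:
            ids = list(self.edge_ids.values())
            if len(set(ids)) != len(ids):
                raise TaxonomyError("edge ids are not unique")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        newick: str,
        outgroup: Optional[Sequence[str]] = None,
    ) -> "SupportTree":
        """Parse a newick string with node-label supports.

        ``{N}`` edge-number tokens (jplace dialect) are accepted anywhere a
        branch annotation may appear; they are mapped to edges by the order
        in which node descriptions complete, which is postorder.

        ``outgroup`` re-roots the tree above the MRCA of the named tips;
        without it the tree is used as written.
        """
        edge_nums = [int(m) for m in _EDGE_NUM_RE.findall(newick)]
        stripped = _EDGE_NUM_RE.sub("", newick)
        try:
            tree = dendropy.Tree.get(
                data=stripped,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except (dendropy.utility.error.DataParseError, ValueError) as e:
            raise TaxonomyError(f"newick parse failed: {e}") from e
        edge_ids: dict = {}
        if edge_nums:
            nodes = list(tree.postorder_node_iter())
            if len(edge_nums) == len(nodes) - 1:
                nodes = nodes[:-1]  # rootmost edge carries no number
            if len(edge_nums) != len(nodes):
                raise TaxonomyError(
                    f"{len(edge_nums)} edge numbers for {len(nodes)} edges"
                )
            edge_ids = dict(zip(nodes, edge_nums))

        st = cls(tree, edge_ids=edge_ids)
        st._read_supports()
        if outgroup:
            st.reroot(outgroup)
        return st

    @classmethod
    def read(cls, path: Union[str, Path], outgroup: Optional[Sequence[str]] = None) -> "SupportTree":
        return cls.from_newick(Path(path).read_text(), outgroup=outgroup)

    def _read_supports(self) -> None:
        raw: dict = {}
        for nd in self.tree.preorder_node_iter():
            if nd.is_leaf() or nd.label is None:
                continue
            try:
                val = float(nd.label)
            except ValueError:
                continue
            raw[nd] = val
        if raw and max(raw.values()) <= 1.0:
            logger.warning("supports look like fractions in [0,1]; scaling by 100")
            raw = {nd: v * 100 for nd, v in raw.items()}
        for nd, v in raw.items():
            if not 0 <= v <= 100:
                raise TaxonomyError(f"support {v} outside [0,100]")
            self.supports[nd] = v

    # -- basic accessors ----------------------------------------------------

    @property
    def root(self):
        return self.tree.seed_node

    def tip_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    def find_tip(self, label: str):
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == label:
                return lf
        raise TaxonomyError(f"tip not in tree: {label!r}")

    def support_of(self, node) -> Optional[float]:
        return self.supports.get(node)

    def node_for_edge_id(self, edge_id: int):
        for nd, eid in self.edge_ids.items():
            if eid == edge_id:
                return nd
        raise TaxonomyError(f"edge id {edge_id} not in tree")

    def leaves_under(self, node) -> set[str]:
        return {lf.taxon.label for lf in node.leaf_iter()}

    def mrca_of(self, labels: Iterable[str]):
        """MRCA by direct traversal.

        Deliberately avoids dendropy's bipartition-backed ``mrca``, whose
        encoding caches go stale when the topology is edited in place
        (query attachment, regrafting).
        """
        targets = set(labels)
        if not targets:
            raise TaxonomyError("mrca of an empty label set")
        missing = targets - self.tip_labels()
        if missing:
            raise TaxonomyError(f"tips not in tree: {sorted(missing)}")
        for nd in self.tree.postorder_node_iter():
            if targets <= self.leaves_under(nd):
                return nd  # postorder: first superset is the smallest
        raise TaxonomyError("no common ancestor found")  # pragma: no cover

    def reroot(self, outgroup: Sequence[str]) -> None:
        """Re-root above the outgroup MRCA (single tip: above that tip)."""
        if len(outgroup) == 1:
            node = self.find_tip(outgroup[0])
        else:
            node = self.mrca_of(outgroup)
        if node is self.root:
            raise TaxonomyError(
                f"outgroup {list(outgroup)} spans the root; cannot re-root"
            )
        self.tree.reroot_at_edge(node.edge, update_bipartitions=False)

    def to_newick(self, edge_numbers: bool = False) -> str:
        """Newick string with supports as internal labels.

        With ``edge_numbers=True``, jplace ``{N}`` tokens are re-attached
        after each edge's branch length.
        """
        for nd in self.tree.preorder_node_iter():
            if not nd.is_leaf() and nd in self.supports:
                v = self.supports[nd]
                nd.label = str(int(v)) if float(v).is_integer() else str(v)
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        if not edge_numbers:
            return s
        if not self.edge_ids:
            raise TaxonomyError("tree has no edge ids to serialize")
        # Re-parse order trick: rebuild by walking our own postorder and
        # splicing {N} after each node's closing token is fragile with
        # string surgery; instead serialize via recursion.
        return self._newick_with_edge_numbers() + ";"

    def _newick_with_edge_numbers(self) -> str:
        def fmt(nd) -> str:
            if nd.is_leaf():
                core = nd.taxon.label
            else:
                children = ",".join(fmt(c) for c in nd.child_nodes())
                label = ""
                if nd in self.supports:
                    v = self.supports[nd]
                    label = str(int(v)) if float(v).is_integer() else str(v)
                core = f"({children}){label}"
            if nd.edge.length is not None:
                core += f":{nd.edge.length:g}"
            if nd in self.edge_ids:
                core += f"{{{self.edge_ids[nd]}}}"
            return core

        return fmt(self.root)


# ---------------------------------------------------------------------------
# Family clades
# ---------------------------------------------------------------------------

@dataclass
class FamilyClade:
    """One family's standing in the reference tree."""

    family: str
    tips: frozenset[str]  # reference tip labels
    monophyletic: bool
    mrca: object  # dendropy node (MRCA of the reference tips)
    #: bootstrap percent, TRIVIAL for single-tip families, or None
    support: Union[float, str, None]
    #: nodes whose subtending edge lies strictly inside the MRCA subtree
    #: (pendant edges included, the MRCA's own subtending edge excluded)
    spanning_nodes: frozenset = field(repr=False, default=frozenset())

    @property
    def trivial(self) -> bool:
        return self.support == TRIVIAL

    def eligible(self, min_support: float) -> bool:
        """Usable as an assignment target at the given support floor."""
        if not self.monophyletic:
            return False
        if self.trivial:
            return True
        return self.support is not None and self.support >= min_support


class FamilyCladeIndex:
    """Per-family monophyly, MRCA clades, and the edge -> family map.

    Edge ownership is restricted to monophyletic families so that every
    edge has at most one owner; non-monophyletic families still record
    their MRCA-spanning edge set, which the placement classifier uses to
    recognize paraphyletic-assemblage ambiguity.
    """

    def __init__(self, tree: SupportTree, clades: dict[str, FamilyClade]) -> None:
        self.tree = tree
        self.clades = clades
        #: node -> family owning the node's subtending edge
        self.edge_owner: dict = {}
        for fam, clade in clades.items():
            if clade.monophyletic:
                for nd in clade.spanning_nodes:
                    if nd in self.edge_owner:  # pragma: no cover - guarded by build
                        raise TaxonomyError(
                            f"edge owned by both {self.edge_owner[nd]} and {fam}"
                        )
                    self.edge_owner[nd] = fam

    def families(self) -> list[str]:
        return sorted(self.clades)

    def __getitem__(self, family: str) -> FamilyClade:
        return self.clades[family]

    def __contains__(self, family: str) -> bool:
        return family in self.clades

    def owner_of_node(self, node) -> Optional[str]:
        return self.edge_owner.get(node)

    def eligible_families(self, min_support: float) -> list[str]:
        return sorted(
            f for f, c in self.clades.items() if c.eligible(min_support)
        )


def build_family_clade_index(
    tree: SupportTree,
    taxa: TaxonMap,
    query_tips: Iterable[str] = (),
) -> FamilyCladeIndex:
    """Judge monophyly and locate the MRCA clade of every reference family.

    Query tips are transparent: a clade holding family-F references plus
    any number of query tips still counts as F's clade. Monophyly is
    therefore judged on reference tips only. Single-tip families are
    monophyletic by convention with support :data:`TRIVIAL` (their clade
    is the pendant edge).
    """
    query_tips = set(query_tips)
    fam_tips: dict[str, set[str]] = {}
    for label in sorted(tree.tip_labels()):
        if label in query_tips:
            continue
        if label not in taxa:
            raise TaxonomyError(
                f"tip {label!r} neither a query tip nor in the taxonomy map"
            )
        fam = taxa.family(label)
        if fam is not None:
            fam_tips.setdefault(fam, set()).add(label)

    clades: dict[str, FamilyClade] = {}
    for fam, tips in fam_tips.items():
        if len(tips) == 1:
            tip_node = tree.find_tip(next(iter(tips)))
            clades[fam] = FamilyClade(
                family=fam,
                tips=frozenset(tips),
                monophyletic=True,
                mrca=tip_node,
                support=TRIVIAL,
                spanning_nodes=frozenset([tip_node]),
            )
            continue
        mrca = tree.mrca_of(tips)
        under = tree.leaves_under(mrca)
        ref_under = under - query_tips
        mono = ref_under == tips
        spanning = frozenset(
            nd for nd in mrca.preorder_iter() if nd is not mrca
        )
        clades[fam] = FamilyClade(
            family=fam,
            tips=frozenset(tips),
            monophyletic=mono,
            mrca=mrca,
            support=tree.support_of(mrca),
            spanning_nodes=spanning,
        )
    return FamilyCladeIndex(tree, clades)


def smallest_supported_clade(
    tree: SupportTree,
    tip: str,
    min_support: float,
    query_tips: Iterable[str] = (),
):
    """Smallest ancestor clade of ``tip`` passing the support floor.

    Ascends node by node from the tip; the first ancestor whose support is
    >= ``min_support`` and whose clade contains at least one reference tip
    (a tip outside ``query_tips``) is returned. The root qualifies only if
    it carries a support value. Returns ``None`` when no ancestor
    qualifies.
    """
    query_tips = set(query_tips)
    node = tree.find_tip(tip)
    anc = node.parent_node
    while anc is not None:
        sup = tree.support_of(anc)
        if sup is not None and sup >= min_support:
            leaves = tree.leaves_under(anc)
            if leaves - query_tips - {tip}:
                return anc
        anc = anc.parent_node
    return None
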