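"""Family assignment from phylogenetic placements (jplace files).

A placement run assigns each query a distribution of likelihood weight
ratios (LWR) over the edges of a fixed, edge-numbered reference tree.
The classifier assigns a family when either

(a) the single best placement carries LWR >= the likelihood threshold
    (0.95 by default) and its edge lies inside an eligible family clade
    (monophyletic, bootstrap support >= the floor, or a single-tip
    family); or
(b) the LWR accumulated over all placements inside exactly one eligible
    family's clade reaches the threshold.

When neither family alone reaches the threshold but two families that
share a clade boundary — one nested in the other (the nested-clade-in-
paraphyletic-assemblage situation) or sisters — do so jointly, the query
is reported ambiguous-between the two. Everything else is unassigned.
Placements on edges owned by no family clade support no candidate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .assignments import Assignment, Status, count_by_status
from .taxonomy import FamilyCladeIndex, SupportTree, TaxonomyError

LWR_SUM_TOL = 1e-6


@dataclass(frozen=True)
class Placement:
    edge_id: int
    log_likelihood: float
    lwr: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.lwr) or not 0 <= self.lwr <= 1:
            raise ValueError(f"likelihood weight ratio outside [0,1]: {self.lwr}")


class PlacementSet:
    """Per-query placements, sorted by descending LWR.

    Invariants: no duplicate edge per query; per-query LWR sums to at
    most 1 (within :data:`LWR_SUM_TOL`).
    """

    def __init__(self, placements: Mapping[str, Sequence[Placement]]) -> None:
        self._by_query: dict[str, list[Placement]] = {}
        for q, ps in placements.items():
            ps = sorted(ps, key=lambda p: (-p.lwr, p.edge_id))
            edges = [p.edge_id for p in ps]
            if len(set(edges)) != len(edges):
                raise TaxonomyError(f"query {q!r}: duplicate placement edges")
            total = sum(p.lwr for p in ps)
            if total > 1 + LWR_SUM_TOL:
                raise TaxonomyError(
                    f"query {q!r}: likelihood weight ratios sum to {total:.6f} > 1"
                )
            self._by_query[q] = ps

    def queries(self) -> list[str]:
        return sorted(self._by_query)

    def placements_for(self, query_id: str) -> list[Placement]:
        return list(self._by_query[query_id])

    def __len__(self) -> int:
        return len(self._by_query)


@dataclass
class PlacementAssignConfig:
    likelihood_threshold: float = 0.95
    min_clade_support: float = 70.0
    #: renormalize truncated per-query LWR vectors to sum 1 before the
    #: rules run; off by default so missing mass counts against assignment
    renormalize: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.likelihood_threshold <= 1:
            raise ValueError(
                f"likelihood_threshold outside (0,1]: {self.likelihood_threshold}"
            )
        if not 0 <= self.min_clade_support <= 100:
            raise ValueError(
                f"min_clade_support outside [0,100]: {self.min_clade_support}"
            )


# ---------------------------------------------------------------------------
# jplace I/O
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("edge_num", "like_weight_ratio")


def read_jplace(path: Union[str, Path]) -> tuple[SupportTree, PlacementSet]:
    """Read a jplace (version 3) file.

    The edge numbering of the ``{N}`` tokens in the tree string is
    preserved exactly; multiplexed name arrays keep their first name as
    the query id.
    """
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("version")
    if version not in (1, 2, 3, "1", "2", "3"):
        raise TaxonomyError(f"{path}: unsupported jplace version {version!r}")
    fields = doc.get("fields")
    if not fields or any(f not in fields for f in _REQUIRED_FIELDS):
        raise TaxonomyError(
            f"{path}: 'fields' must include {list(_REQUIRED_FIELDS)}; got {fields}"
        )
    tree = SupportTree.from_newick(doc["tree"])
    if not tree.edge_ids:
        raise TaxonomyError(f"{path}: tree string carries no {{N}} edge numbers")
    known_edges = set(tree.edge_ids.values())

    idx = {f: i for i, f in enumerate(fields)}
    ll_idx = idx.get("likelihood")
    placements: dict[str, list[Placement]] = {}
    for pq in doc.get("placements", []):
        if "n" in pq:
            name = pq["n"][0]
        elif "nm" in pq:
            name = pq["nm"][0][0]
        else:
            raise TaxonomyError(f"{path}: placement without 'n' or 'nm'")
        plist = []
        for row in pq["p"]:
            edge = int(row[idx["edge_num"]])
            if edge not in known_edges:
                raise TaxonomyError(f"{path}: edge_num {edge} not in tree")
            ll = float(row[ll_idx]) if ll_idx is not None else float("nan")
            plist.append(
                Placement(edge_id=edge, log_likelihood=ll, lwr=float(row[idx["like_weight_ratio"]]))
            )
        if name in placements:
            raise TaxonomyError(f"{path}: duplicate query name {name!r}")
        placements[name] = plist
    return tree, PlacementSet(placements)


def write_jplace(
    tree: SupportTree,
    ps: PlacementSet,
    path: Union[str, Path],
    metadata: Optional[dict] = None,
) -> None:
    """Write a version-3 jplace file (round-trips with :func:`read_jplace`)."""
    doc = {
        "version": 3,
        "tree": tree.to_newick(edge_numbers=True),
        "fields": ["edge_num", "likelihood", "like_weight_ratio"],
        "placements": [
            {
                "p": [
                    [p.edge_id, p.log_likelihood, p.lwr]
                    for p in ps.placements_for(q)
                ],
                "n": [q],
            }
            for q in ps.queries()
        ],
        "metadata": metadata or {"invocation": "nematax"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------

def _adjacent(idx: FamilyCladeIndex, fam_a: str, fam_b: str) -> bool:
    """True when the two family clades share an edge boundary.

    Nested: one family's spanning edge set contains the other's (a
    monophyletic clade inside a paraphyletic assemblage). Sister: the two
    MRCAs hang off the same parent node.
    """
    a, b = idx[fam_a], idx[fam_b]
    if a.spanning_nodes >= b.spanning_nodes or b.spanning_nodes >= a.spanning_nodes:
        return True
    pa = a.mrca.parent_node
    pb = b.mrca.parent_node
    return pa is not None and pa is pb


def assign_by_placement(
    ps: PlacementSet,
    idx: FamilyCladeIndex,
    cfg: PlacementAssignConfig = PlacementAssignConfig(),
) -> list[Assignment]:
    """Apply the single / cumulative likelihood-weight rules per query."""
    tree = idx.tree
    known_edges = set(tree.edge_ids.values())
    if not known_edges:
        raise TaxonomyError("clade index tree carries no edge ids")

    eligible = set(idx.eligible_families(cfg.min_clade_support))
    # node -> eligible owner family (rules a and b)
    owner_of = {
        nd: fam for nd, fam in idx.edge_owner.items() if fam in eligible
    }

    out: list[Assignment] = []
    for q in ps.queries():
        placements = ps.placements_for(q)
        for p in placements:
            if p.edge_id not in known_edges:
                raise TaxonomyError(
                    f"query {q!r}: placement edge {p.edge_id} not in index tree"
                )
        if cfg.renormalize and placements:
            total = sum(p.lwr for p in placements)
            if total > 0:
                placements = [
                    Placement(p.edge_id, p.log_likelihood, p.lwr / total)
                    for p in placements
                ]

        nodes = {p.edge_id: tree.node_for_edge_id(p.edge_id) for p in placements}

        # (a) single strong placement inside an eligible clade
        if placements:
            best = placements[0]
            fam = owner_of.get(nodes[best.edge_id])
            if best.lwr >= cfg.likelihood_threshold and fam is not None:
                out.append(
                    Assignment(
                        q,
                        Status.ASSIGNED,
                        family=fam,
                        method="placement",
                        evidence={"best_lwr": best.lwr, "rule": "single"},
                    )
                )
                continue

        # (b) cumulative LWR per eligible family
        cum: dict[str, float] = {}
        for p in placements:
            fam = owner_of.get(nodes[p.edge_id])
            if fam is not None:
                cum[fam] = cum.get(fam, 0.0) + p.lwr
        winners = sorted(f for f, v in cum.items() if v >= cfg.likelihood_threshold)
        if len(winners) == 1:
            f = winners[0]
            out.append(
                Assignment(
                    q,
                    Status.ASSIGNED,
                    family=f,
                    method="placement",
                    evidence={"cum_lwr": cum[f], "rule": "cumulative"},
                )
            )
            continue

        # (c) boundary-sharing family pair reaching the threshold jointly
        pair = _ambiguous_pair(placements, nodes, idx, cfg)
        if pair is not None:
            fams, mass = pair
            out.append(
                Assignment(
                    q,
                    Status.AMBIGUOUS,
                    candidates=fams,
                    method="placement",
                    evidence={"pair_lwr": mass, "rule": "pair"},
                )
            )
            continue

        # (d) unassigned, with the per-family mass seen as diagnostics
        out.append(
            Assignment(
                q,
                Status.UNASSIGNED,
                method="placement",
                evidence={
                    "cum_lwr": max(cum.values()) if cum else 0.0,
                    "family_mass": {f: round(v, 6) for f, v in sorted(cum.items())},
                },
            )
        )
    return out


def _ambiguous_pair(
    placements: Sequence[Placement],
    nodes: Mapping[int, object],
    idx: FamilyCladeIndex,
    cfg: PlacementAssignConfig,
) -> Optional[tuple[tuple[str, str], float]]:
    """Best boundary-sharing family pair whose joint mass passes the bar.

    Mass per family is taken over the family's MRCA-spanning edges minus
    edges owned by any other family, so a paraphyletic assemblage (which
    owns no edges) can still act as one side of the pair.
    """
    # spanning-based mass per family (paraphyletic assemblages included)
    span_mass: dict[str, float] = {}
    for fam in idx.families():
        clade = idx[fam]
        m = 0.0
        for p in placements:
            nd = nodes[p.edge_id]
            if nd in clade.spanning_nodes:
                owner = idx.owner_of_node(nd)
                if owner is None or owner == fam:
                    m += p.lwr
        if m > 0:
            span_mass[fam] = m

    candidates = sorted(span_mass)
    best: Optional[tuple[tuple[str, str], float]] = None
    for i, fa in enumerate(candidates):
        for fb in candidates[i + 1 :]:
            if not _adjacent(idx, fa, fb):
                continue
            if (
                span_mass[fa] >= cfg.likelihood_threshold
                or span_mass[fb] >= cfg.likelihood_threshold
            ):
                continue  # one side suffices alone; not a joint ambiguity
            joint = span_mass[fa] + span_mass[fb]
            if joint >= cfg.likelihood_threshold:
                if best is None or joint > best[1]:
                    best = ((fa, fb), joint)
    return best


def placement_summary(assignments: Sequence[Assignment]) -> pd.DataFrame:
    """Counts by status; statuses always partition the query set."""
    counts = count_by_status(assignments)
    return pd.DataFrame(
        [(k, counts[k]) for k in [s.value for s in Status] + ["total"]],
        columns=["status", "count"],
    )
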