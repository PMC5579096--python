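"""Tree-based family assignment from a joint reference+query phylogeny.

Each query tip is walked rootwards to the smallest clade whose bootstrap
support reaches the floor (70% by default) and which contains at least
one reference tip. If that clade's reference composition is a single
family — other query tips being transparent — the query is assigned that
family with the clade support as evidence; mixed composition or no
qualifying clade leaves it unassigned.

Two run modes mirror common practice: a cumulative run (all queries in
one tree) and a partitioned run (queries split across several trees each
holding the full reference set), with a stability report comparing the
two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .assignments import Assignment, Status
from .taxonomy import (
    SupportTree,
    TaxonMap,
    TaxonomyError,
    smallest_supported_clade,
)


@dataclass
class TreeAssignConfig:
    min_support: float = 70.0
    #: outgroup tip labels for re-rooting, or None to use the tree as read
    outgroup: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if not 0 <= self.min_support <= 100:
            raise ValueError(f"min_support outside [0,100]: {self.min_support}")


def assign_by_tree(
    tree: SupportTree,
    taxa: TaxonMap,
    query_tips: Iterable[str],
    cfg: TreeAssignConfig = TreeAssignConfig(),
) -> list[Assignment]:
    """Assign each query tip from its smallest supported clade.

    The ascent stops at the first (smallest) ancestor clade meeting the
    support floor and containing a reference tip; no larger clade is
    considered even if its composition would be cleaner.
    """
    query_tips = set(query_tips)
    tips = tree.tip_labels()
    missing = query_tips - tips
    if missing:
        raise TaxonomyError(f"query tips absent from tree: {sorted(missing)}")
    if cfg.outgroup:
        tree.reroot(cfg.outgroup)

    out: list[Assignment] = []
    for q in sorted(query_tips):
        clade = smallest_supported_clade(tree, q, cfg.min_support, query_tips)
        if clade is None:
            out.append(Assignment(q, Status.UNASSIGNED, method="tree"))
            continue
        refs = tree.leaves_under(clade) - query_tips
        families = sorted({taxa.family(t) for t in refs})
        support = tree.support_of(clade)
        if len(families) == 1:
            out.append(
                Assignment(
                    q,
                    Status.ASSIGNED,
                    family=families[0],
                    method="tree",
                    evidence={"support": support, "clade_size": len(refs)},
                )
            )
        else:
            out.append(
                Assignment(
                    q,
                    Status.UNASSIGNED,
                    candidates=tuple(families),
                    method="tree",
                    evidence={"support": support, "clade_size": len(refs)},
                )
            )
    return out


@dataclass
class StabilityReport:
    """Cumulative-vs-partitioned comparison of positive assignments."""

    matched: int = 0  # assigned in both modes, same family
    differing: int = 0  # assigned in both modes, different family
    new: int = 0  # assigned only in the partitioned run
    lost: int = 0  # assigned only in the cumulative run
    both_unassigned: int = 0
    details: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.details,
            columns=["query_id", "cumulative_family", "partitioned_family", "verdict"],
        )


def stability_report(
    cumulative: Sequence[Assignment],
    partitioned: Sequence[Assignment],
) -> StabilityReport:
    cum = {a.query_id: a for a in cumulative}
    par = {a.query_id: a for a in partitioned}
    if set(cum) != set(par):
        raise TaxonomyError(
            "cumulative and partitioned runs cover different query sets"
        )
    rep = StabilityReport()
    for q in sorted(cum):
        cf = cum[q].family if cum[q].assigned else None
        pf = par[q].family if par[q].assigned else None
        if cf and pf:
            verdict = "matched" if cf == pf else "differing"
        elif pf:
            verdict = "new"
        elif cf:
            verdict = "lost"
        else:
            verdict = "both_unassigned"
        setattr(rep, verdict, getattr(rep, verdict) + 1)
        rep.details.append((q, cf or "", pf or "", verdict))
    return rep


def partitioned_run(
    trees: Sequence[SupportTree],
    taxa: TaxonMap,
    partitions: Sequence[Iterable[str]],
    cfg: TreeAssignConfig = TreeAssignConfig(),
    cumulative: Optional[Sequence[Assignment]] = None,
) -> tuple[list[Assignment], Optional[StabilityReport]]:
    """Run the tree rule per partition and merge the verdicts.

    Each tree must contain exactly its partition's query tips on top of
    the shared reference set; a query appearing in two partitions is an
    error. When a cumulative-run assignment list is supplied, a
    :class:`StabilityReport` against it is returned as well.
    """
    if len(trees) != len(partitions):
        raise TaxonomyError(
            f"{len(trees)} trees for {len(partitions)} partitions"
        )
    seen: set[str] = set()
    merged: list[Assignment] = []
    for tree, part in zip(trees, partitions):
        part = set(part)
        dup = part & seen
        if dup:
            raise TaxonomyError(f"queries in multiple partitions: {sorted(dup)}")
        seen |= part
        missing = part - tree.tip_labels()
        if missing:
            raise TaxonomyError(
                f"partition queries absent from their tree: {sorted(missing)}"
            )
        merged.extend(assign_by_tree(tree, taxa, part, cfg))
    merged.sort(key=lambda a: a.query_id)
    report = stability_report(cumulative, merged) if cumulative is not None else None
    return merged, report
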