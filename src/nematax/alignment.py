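"""Alignment-based family assignment from tabular similarity hits.

Two classifiers operate on BLAST-style tabular hit files:

* the strict top-hit rule — assign the top bit-score hit's family when it
  reaches the identity and coverage floors and all score-tied top hits
  agree on the family (ties across families are an explicit conflict);
* an LCA classifier with a relative bit-score range — retain every hit
  within ``relative_range`` percent of the best bit-score and assign the
  lowest common ancestor of the retained lineages, reported only when the
  LCA sits at or below the family rank.

Hits against non-voucher subjects ("uncultured", "unidentified",
"environmental" labels) are dropped before either rule, and the next best
match is evaluated in their place.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .assignments import Assignment, Status
from .taxonomy import TaxonMap, TaxonomyError, lineage_lca, RANKS, FAMILY_INDEX

#: Identity ladder for optional calls below family (single-linkage 18S
#: thresholds: 99% species, 96.5% genus, 90% family, 84% order).
IDENTITY_LADDER: dict[str, float] = {
    "species": 99.0,
    "genus": 96.5,
    "family": 90.0,
    "order": 84.0,
}

#: Default column mapping for BLAST outfmt-6-style files.
DEFAULT_COLUMNS: dict[str, str] = {
    "query_id": "qseqid",
    "subject_id": "sseqid",
    "identity": "pident",
    "coverage": "qcovs",
    "bit_score": "bitscore",
}


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    identity: float  # percent in [0, 100]
    coverage: float  # percent in [0, 100]
    bit_score: float

    def __post_init__(self) -> None:
        for name in ("identity", "coverage", "bit_score"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} not finite: {v}")
        if not 0 <= self.identity <= 100:
            raise ValueError(f"identity outside [0,100]: {self.identity}")
        if not 0 <= self.coverage <= 100:
            raise ValueError(f"coverage outside [0,100]: {self.coverage}")
        if self.bit_score < 0:
            raise ValueError(f"negative bit score: {self.bit_score}")


def _sort_key(r: HitRecord):
    # total, deterministic order: score desc, identity desc, subject asc
    return (-r.bit_score, -r.identity, r.subject_id)


class HitTable:
    """Hit records grouped by query, canonically sorted within each query.

    ``queries`` can name queries with no (remaining) records, so a query
    whose hits were all filtered away still flows through the
    classifiers and comes out unassigned rather than vanishing.
    """

    def __init__(
        self,
        records: Sequence[HitRecord],
        queries: Optional[Sequence[str]] = None,
    ) -> None:
        self._by_query: dict[str, list[HitRecord]] = {
            q: [] for q in (queries or [])
        }
        for r in records:
            self._by_query.setdefault(r.query_id, []).append(r)
        for q in self._by_query:
            self._by_query[q].sort(key=_sort_key)

    def queries(self) -> list[str]:
        return sorted(self._by_query)

    def hits_for(self, query_id: str) -> list[HitRecord]:
        return list(self._by_query.get(query_id, []))

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_query.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.query_id, r.subject_id, r.identity, r.coverage, r.bit_score)
            for q in self.queries()
            for r in self._by_query[q]
        ]
        return pd.DataFrame(
            rows, columns=["query_id", "subject_id", "identity", "coverage", "bit_score"]
        )


def read_hits(
    path: Union[str, Path],
    columns: Optional[dict[str, str]] = None,
) -> HitTable:
    """Read a BLAST outfmt-6-style TSV into a :class:`HitTable`.

    ``columns`` remaps the logical fields (query_id, subject_id, identity,
    coverage, bit_score) onto the file's column names; headerless files
    with exactly the five default columns in order are also accepted.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        # headerless fallback: assume the five logical columns in order
        df = pd.read_csv(path, sep="\t", header=None)
        if df.shape[1] < 5:
            raise TaxonomyError(f"{path}: cannot locate hit columns {missing}")
        df.columns = list(colmap.values()) + [
            f"extra{i}" for i in range(df.shape[1] - 5)
        ]
    records = [
        HitRecord(
            query_id=str(row[colmap["query_id"]]),
            subject_id=str(row[colmap["subject_id"]]),
            identity=float(row[colmap["identity"]]),
            coverage=float(row[colmap["coverage"]]),
            bit_score=float(row[colmap["bit_score"]]),
        )
        for row in df.to_dict("records")
    ]
    return HitTable(records)


def filter_non_voucher(hits: HitTable, taxa: TaxonMap) -> HitTable:
    """Drop hits whose subject label is flagged non-voucher.

    Every subject must resolve in the taxonomy map; an unknown subject is
    an error naming the label, never a silent miss.
    """
    kept: list[HitRecord] = []
    for q in hits.queries():
        for r in hits.hits_for(q):
            if r.subject_id not in taxa:
                raise TaxonomyError(
                    f"subject {r.subject_id!r} not resolvable in taxonomy map"
                )
            if not taxa.is_non_voucher(r.subject_id):
                kept.append(r)
    return HitTable(kept, queries=hits.queries())


def top_hit_assign(
    hits: HitTable,
    taxa: TaxonMap,
    min_identity: float = 90.0,
    min_coverage: float = 100.0,
    consistency_k: int = 1,
) -> list[Assignment]:
    """Strict top-hit rule.

    A query is assigned family F iff its best bit-score hit passes the
    identity and coverage floors and every hit in the consistency window
    maps to F. The window is the exact bit-score tie at the top
    (``consistency_k=1``); ``consistency_k>1`` widens it to the top-k
    hits. Tied top hits in different families yield a conflict (counted
    as unassigned downstream); queries with no hits are unassigned.
    """
    out: list[Assignment] = []
    for q in hits.queries():
        recs = hits.hits_for(q)
        if not recs:
            out.append(Assignment(q, Status.UNASSIGNED, method="top_hit"))
            continue
        best = recs[0]
        if best.identity < min_identity or best.coverage < min_coverage:
            out.append(
                Assignment(
                    q,
                    Status.UNASSIGNED,
                    method="top_hit",
                    evidence={"identity": best.identity, "coverage": best.coverage},
                )
            )
            continue
        if consistency_k <= 1:
            window = [r for r in recs if r.bit_score == best.bit_score]
        else:
            window = recs[:consistency_k]
        families = sorted({taxa.family(r.subject_id) for r in window})
        if len(families) == 1:
            out.append(
                Assignment(
                    q,
                    Status.ASSIGNED,
                    family=families[0],
                    method="top_hit",
                    evidence={
                        "identity": best.identity,
                        "coverage": best.coverage,
                        "bit_score": best.bit_score,
                    },
                )
            )
        else:
            out.append(
                Assignment(
                    q,
                    Status.CONFLICT,
                    candidates=tuple(families),
                    method="top_hit",
                    evidence={"identity": best.identity, "bit_score": best.bit_score},
                )
            )
    return out


def lca_assign(
    hits: HitTable,
    taxa: TaxonMap,
    relative_range: float = 2.0,
) -> list[Assignment]:
    """LCA rule with a relative bit-score range.

    Hits scoring at least ``(1 - relative_range/100)`` of the best bit
    score are retained; the query is assigned the family of the retained
    lineages' lowest common ancestor when that ancestor sits at or below
    the family rank. An LCA above family leaves the query unassigned,
    with the LCA taxon recorded as evidence.
    """
    out: list[Assignment] = []
    cutoff_factor = 1.0 - relative_range / 100.0
    for q in hits.queries():
        recs = hits.hits_for(q)
        if not recs:
            out.append(Assignment(q, Status.UNASSIGNED, method="lca"))
            continue
        best = recs[0].bit_score
        retained = [r for r in recs if r.bit_score >= cutoff_factor * best]
        lineages = [taxa.lineage(r.subject_id) for r in retained]
        rank, taxon = lineage_lca(lineages)
        fam = lineages[0].family if lineages else None
        if rank is not None and RANKS.index(rank) >= FAMILY_INDEX and fam is not None:
            out.append(
                Assignment(
                    q,
                    Status.ASSIGNED,
                    family=fam,
                    method="lca",
                    evidence={
                        "lca_rank": rank,
                        "lca_taxon": taxon,
                        "n_retained": len(retained),
                    },
                )
            )
        else:
            out.append(
                Assignment(
                    q,
                    Status.UNASSIGNED,
                    method="lca",
                    evidence={
                        "lca_rank": rank,
                        "lca_taxon": taxon,
                        "n_retained": len(retained),
                    },
                )
            )
    return out
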