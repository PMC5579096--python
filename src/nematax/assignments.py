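"""The per-query assignment record shared by all classifiers."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd


class Status(str, Enum):
    ASSIGNED = "assigned"
    UNASSIGNED = "unassigned"
    CONFLICT = "conflict"
    AMBIGUOUS = "ambiguous-between"


@dataclass(frozen=True)
class Assignment:
    """Outcome of one classifier for one query.

    ``status == ASSIGNED`` iff exactly one family is set; conflict and
    ambiguous outcomes carry the candidate families instead. ``evidence``
    holds the method-appropriate scores (identity %, clade support %,
    single or cumulative likelihood weight ratio, ...).
    """

    query_id: str
    status: Status
    family: Optional[str] = None
    candidates: tuple[str, ...] = ()
    method: str = ""
    evidence: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.status == Status.ASSIGNED) != (self.family is not None):
            raise ValueError(
                f"{self.query_id}: status {self.status.value} inconsistent "
                f"with family={self.family!r}"
            )
        if self.status in (Status.CONFLICT, Status.AMBIGUOUS) and len(self.candidates) < 2:
            raise ValueError(
                f"{self.query_id}: {self.status.value} requires >=2 candidate families"
            )

    @property
    def assigned(self) -> bool:
        return self.status == Status.ASSIGNED


def assignments_to_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append(
            {
                "query_id": a.query_id,
                "method": a.method,
                "status": a.status.value,
                "family": a.family or "",
                "candidates": ";".join(a.candidates),
                "evidence": json.dumps(dict(a.evidence), sort_keys=True, default=float),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["query_id", "method", "status", "family", "candidates", "evidence"],
    )


def write_assignments(assignments: Sequence[Assignment], path: Union[str, Path]) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False)


def read_assignments(path: Union[str, Path]) -> list[Assignment]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.to_dict("records"):
        out.append(
            Assignment(
                query_id=str(row["query_id"]),
                status=Status(row["status"]),
                family=row["family"] or None,
                candidates=tuple(c for c in str(row["candidates"]).split(";") if c),
                method=str(row.get("method", "")),
                evidence=json.loads(row["evidence"]) if row.get("evidence") else {},
            )
        )
    return out


def count_by_status(assignments: Sequence[Assignment]) -> dict[str, int]:
    counts = {s.value: 0 for s in Status}
    for a in assignments:
        counts[a.status.value] += 1
    counts["total"] = len(assignments)
    return counts
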