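"""Cross-method congruence, exclusion bookkeeping, and the per-family
OTU-versus-morphospecies comparison.

The congruence analysis lines up the per-query verdicts of several
classifiers: queries whose positively-assigning methods all name the same
family are congruent (a single positive assignment cannot disagree with
anything and also counts as congruent); two or more methods naming
different families is a conflict, and the conflict record lists the
per-method families.

The OTU/morphospecies comparison tallies assigned OTUs and identified
morphospecies per (family, sample) and correlates the paired counts with
the Pearson product-moment coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .assignments import Assignment
from .taxonomy import TaxonMap, TaxonomyError


# ---------------------------------------------------------------------------
# Exclusion-filter bookkeeping
# ---------------------------------------------------------------------------

def apply_exclusions(
    otu_ids: Sequence[str],
    exclusions: Sequence[tuple[str, str]],
) -> tuple[list[str], pd.DataFrame]:
    """Remove listed OTU ids, keeping an audit log of each removal.

    Every excluded id must be present in the input and each appears once;
    the survivors keep their input order, and
    ``len(survivors) == len(otu_ids) - len(exclusions)`` always holds.
    """
    ids = list(otu_ids)
    excl_ids = [e for e, _ in exclusions]
    if len(set(excl_ids)) != len(excl_ids):
        raise TaxonomyError("duplicate ids in exclusion list")
    missing = [e for e in excl_ids if e not in ids]
    if missing:
        raise TaxonomyError(f"exclusion ids not in input: {missing}")
    excl_set = set(excl_ids)
    survivors = [i for i in ids if i not in excl_set]
    audit = pd.DataFrame(exclusions, columns=["otu_id", "reason"])
    return survivors, audit


# ---------------------------------------------------------------------------
# Method congruence
# ---------------------------------------------------------------------------

class MethodMatrix:
    """Per-query × per-method assignment matrix.

    All methods must cover the same query set; one row per query.
    """

    def __init__(self, per_method: Mapping[str, Sequence[Assignment]]) -> None:
        if len(per_method) < 2:
            raise TaxonomyError("congruence needs at least two methods")
        self.methods = list(per_method)
        self._cells: dict[str, dict[str, Assignment]] = {}
        query_sets = {}
        for m, assignments in per_method.items():
            d = {a.query_id: a for a in assignments}
            if len(d) != len(assignments):
                raise TaxonomyError(f"method {m!r}: duplicate query ids")
            query_sets[m] = set(d)
            self._cells[m] = d
        ref = next(iter(query_sets.values()))
        for m, qs in query_sets.items():
            if qs != ref:
                raise TaxonomyError(
                    f"method {m!r} covers a different query set"
                )
        self.queries = sorted(ref)

    def family_of(self, query_id: str, method: str) -> Optional[str]:
        a = self._cells[method][query_id]
        return a.family if a.assigned else None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for q in self.queries:
            row: dict[str, object] = {"query_id": q}
            for m in self.methods:
                a = self._cells[m][q]
                row[m] = a.family if a.assigned else a.status.value
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class CongruenceSummary:
    congruent: int = 0  # >=1 positive assignment, all agreeing
    partially_assigned: int = 0  # no positive assignment at all
    conflicting: int = 0  # >=2 positive assignments, differing
    conflicts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["query_id", "method", "family"]
        )
    )


def congruence(mm: MethodMatrix) -> CongruenceSummary:
    """Bucket every query as congruent / partially-assigned / conflicting.

    The three buckets partition the query set. Conflict records list the
    family each positively-assigning method chose.
    """
    summary = CongruenceSummary()
    conflict_rows = []
    for q in mm.queries:
        fams = {m: mm.family_of(q, m) for m in mm.methods}
        positive = {m: f for m, f in fams.items() if f is not None}
        distinct = set(positive.values())
        if not positive:
            summary.partially_assigned += 1
        elif len(distinct) == 1:
            summary.congruent += 1
        else:
            summary.conflicting += 1
            for m, f in sorted(positive.items()):
                conflict_rows.append((q, m, f))
    if conflict_rows:
        summary.conflicts = pd.DataFrame(
            conflict_rows, columns=["query_id", "method", "family"]
        )
    return summary


# ---------------------------------------------------------------------------
# Family count table and correlation
# ---------------------------------------------------------------------------

def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two paired count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise TaxonomyError("need two equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise TaxonomyError("Pearson correlation undefined for zero variance")
    return float(stats.pearsonr(x, y).statistic)


def family_count_table(
    assignments_per_sample: Mapping[str, Sequence[Assignment]],
    morpho: pd.DataFrame,
    taxa: Optional[TaxonMap] = None,
    synonyms: Optional[Mapping[str, str]] = None,
    exclude_unreferenced: bool = False,
) -> pd.DataFrame:
    """Aligned per-(family, sample) OTU and morphospecies counts.

    ``morpho`` needs columns family, sample, morphospecies_count.
    Family names are harmonized through ``synonyms`` (database name →
    accepted name); with a ``taxa`` map supplied, any harmonized family
    unknown to the map is an error listing the offenders. Families seen
    only on the morphology side keep a row with ``otu_count = 0`` (and
    vice versa). ``exclude_unreferenced`` drops families absent from the
    taxonomy map instead of failing — the "no reference sequence data"
    situation.
    """
    synonyms = dict(synonyms or {})

    def harmonize(fam: str) -> str:
        return synonyms.get(fam, fam)

    required = {"family", "sample", "morphospecies_count"}
    if not required <= set(morpho.columns):
        raise TaxonomyError(f"morpho table must have columns {sorted(required)}")

    otu_counts: dict[tuple[str, str], int] = {}
    for sample, assignments in assignments_per_sample.items():
        for a in assignments:
            if a.assigned:
                key = (harmonize(a.family), sample)
                otu_counts[key] = otu_counts.get(key, 0) + 1

    morpho_counts: dict[tuple[str, str], int] = {}
    for row in morpho.to_dict("records"):
        key = (harmonize(str(row["family"])), str(row["sample"]))
        morpho_counts[key] = morpho_counts.get(key, 0) + int(row["morphospecies_count"])

    keys = sorted(set(otu_counts) | set(morpho_counts))
    if taxa is not None:
        ref_families = {
            taxa.family(lbl) for lbl in taxa.labels() if not taxa.is_non_voucher(lbl)
        }
        unknown = sorted({f for f, _ in keys} - ref_families)
        if unknown:
            if exclude_unreferenced:
                keys = [k for k in keys if k[0] not in unknown]
            else:
                raise TaxonomyError(
                    f"families not harmonizable against the taxonomy map: {unknown}"
                )
    rows = [
        (f, s, otu_counts.get((f, s), 0), morpho_counts.get((f, s), 0))
        for f, s in keys
    ]
    return pd.DataFrame(
        rows, columns=["family", "sample", "otu_count", "morphospecies_count"]
    )


def correlate_counts(table: pd.DataFrame, drop_all_zero: bool = True) -> float:
    """Pearson correlation of otu_count vs morphospecies_count rows."""
    df = table
    if drop_all_zero:
        df = df[(df["otu_count"] > 0) | (df["morphospecies_count"] > 0)]
    return pearson_correlation(df["otu_count"], df["morphospecies_count"])


# ---------------------------------------------------------------------------
# Supplementary-style table loaders
# ---------------------------------------------------------------------------

def load_family_counts(path: Union[str, Path]) -> pd.DataFrame:
    """Load a per-(family, sample) count TSV.

    Expected columns: ``family``, ``sample`` (site/extraction label),
    ``otu_count``, ``morphospecies_count``. This is the layout of a
    published per-family OTU/morphospecies comparison table exported to
    TSV.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"family", "sample", "otu_count", "morphospecies_count"}
    missing = required - set(df.columns)
    if missing:
        raise TaxonomyError(f"{path}: missing columns {sorted(missing)}")
    if (df[["otu_count", "morphospecies_count"]] < 0).any().any():
        raise TaxonomyError(f"{path}: negative counts")
    return df


@dataclass
class MorphoInventory:
    """Species/genus/family tallies of a morphology-based faunal list."""

    n_species: int
    n_genera: int
    n_families: int
    table: pd.DataFrame


def load_morpho_species_list(
    path: Union[str, Path],
    site: Optional[str] = None,
) -> MorphoInventory:
    """Load a morphospecies list TSV and tally distinct taxa.

    Expected columns: ``species``, ``genus``, ``family`` and optionally
    ``site``; when ``site`` is given, rows are filtered to it first.
    Counts are of distinct names per rank.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"species", "genus", "family"}
    missing = required - set(df.columns)
    if missing:
        raise TaxonomyError(f"{path}: missing columns {sorted(missing)}")
    if site is not None:
        if "site" not in df.columns:
            raise TaxonomyError(f"{path}: no 'site' column to filter on")
        df = df[df["site"] == site]
    return MorphoInventory(
        n_species=df["species"].nunique(),
        n_genera=df["genus"].nunique(),
        n_families=df["family"].nunique(),
        table=df.reset_index(drop=True),
    )
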