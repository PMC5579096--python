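# Methods

## Problem setting

Metabarcoding surveys of marine meiofauna produce OTUs from a short 18S
rRNA fragment (V1–V2, ~370 bp). Species-level references are so sparse
for nematodes that the practical question is family-level: given an OTU
and a curated reference set, which family does it belong to, and how
confident is that call? This package implements the three ways that
question is answered in practice — similarity hits, clades in a joint
phylogeny, and phylogenetic placements — under one data model, so their
verdicts can be compared query by query.

All classifiers emit the same `Assignment` record: a status in
{assigned, unassigned, conflict, ambiguous-between}, the family when
assigned, candidate families otherwise, and the numeric evidence that
decided the outcome (identity %, clade support %, single or cumulative
likelihood weight ratio). Statuses are mutually exclusive and exhaustive,
so status counts always partition the query set.

## Shared taxonomy model

Lineages are ordered rank paths (phylum > class > order > family > genus
> species); ranks may be missing, but order is fixed and the family rank
is mandatory for every reference record. The LCA of a set of lineages is
computed by walking the rank order from the top while all lineages agree;
ranks absent from *every* lineage are transparent, a rank present in some
but not all stops the walk. Labels containing "uncultured",
"unidentified" or "environmental" (case-insensitive, configurable) are
flagged non-voucher and removed from hit tables before classification,
promoting the next best match.

Trees are rooted as read; an explicit outgroup option re-roots them,
since maximum-likelihood output is arbitrarily rooted. Bootstrap supports
are read from internal node labels; values on [0, 1] are auto-scaled to
percent with a warning. MRCAs are computed by direct traversal rather
than through cached bipartition encodings, because the synthetic-data
generator and the query-attachment step edit topologies in place and
stale caches silently corrupt clade lookups (this was observed, not
hypothetical).

A `FamilyCladeIndex` records, per family: its reference tips, monophyly
judged on reference tips only (query tips are transparent), the MRCA,
its support, and the set of edges strictly inside the MRCA subtree. Edge
*ownership* — the edge → family map the placement rules consume — is
restricted to monophyletic families, which keeps it a partition: a
family's clade cannot contain another family's subtending edge. The
MRCA-spanning edge set is still recorded for non-monophyletic families;
it is what lets the placement classifier recognize a paraphyletic
assemblage. Conventions at the boundary: the edge subtending a family's
MRCA is outside the clade (bipartition semantics — that edge is shared
with the rest of the tree); the pendant edge of a single-tip family is
inside, and such families are trivially monophyletic and always eligible
targets, because real reference sets contain many families with a single
sequence.

## Alignment-based rules

Hits are ordered by bit score (descending), ties broken by identity then
subject id, making every verdict independent of input row order. The
top-hit rule assigns the top record's family iff identity ≥ 90, coverage
= 100 (compared as reported integers), and every record *tied with the
top bit score* maps to the same family; tied top hits in different
families are a conflict, counted as unassigned downstream. The
consistency window is the exact score tie by default — the one worked
case in the literature this mirrors is a tie — and can be widened to the
top-k hits. The 90/96.5/99% identity ladder for order/genus/species
calls is exposed as a constant but only family assignments are produced.

The LCA rule retains hits with bit score ≥ (1 − r/100) × best (default
r = 2%), and assigns the family of the retained lineages' LCA when that
LCA is at or below family rank; an LCA above family leaves the query
unassigned with the LCA taxon as evidence. Using bit score for the range
(rather than raw alignment score) is a deliberate choice recorded here
because classifiers differ on it; with r = 0 and a unique best hit the
rule reduces to the top-hit family.

When the top hit is non-voucher, the entire remaining list is available
after filtering — there is no cap on how many next-best hits are
examined.

## Tree-based rule

From each query tip, ascend parent by parent; the first ancestor whose
support passes the floor (default 70%, inclusive) *and* whose clade
contains at least one reference tip is decisive. If its reference tips
map to one family, assign it with the clade support as evidence; if they
span several families, the query is unassigned with those families
recorded as candidates. No larger clade is considered once the smallest
qualifying one is found — continuing outward could only change the answer
under paraphyly, and smallest-clade precedence keeps the rule
deterministic. The root counts as a candidate only when it carries a
support value, which most ML outputs do not define.

The partitioned mode runs the same rule on several trees, each holding
the full reference set plus a disjoint subset of queries, merges the
verdicts, and reports stability against a cumulative run: matched /
differing / new / lost / both-unassigned per query.

## Placement-based rule

jplace (version 3) files are parsed by stripping the `{N}` edge tokens
and zipping them against postorder node iteration — the order in which
newick node descriptions complete is exactly postorder, so the numbering
survives a round trip bit-exactly. Per query, placements must have
distinct edges and LWRs summing to ≤ 1 + 1e−6.

Assignment applies four rules in order (single placement, cumulative
per-family, boundary-sharing pair, unassigned); see the README for the
formal statement. Two decisions deserve justification:

* **The 0.95 threshold applies to likelihood weight ratios.** LWR is the
  placement tool's normalized per-edge confidence and the only relevant
  quantity on [0, 1]; raw log-likelihoods are kept as evidence only.
* **Truncated LWR vectors are not renormalized by default.** Placement
  tools keep only the best placements, so per-query mass can sum to less
  than 1; the conservative reading is that missing mass counts against
  assignment. `renormalize=true` restores the opposite convention.

The ambiguity rule is deliberately narrow: only *pairs* of families
whose clades share an edge boundary — one nested inside the other's
spanning clade, or sisters — can be reported ambiguous-between, and only
when neither side reaches the threshold alone. For the nested case the
outer side is typically a paraphyletic assemblage, which owns no edges;
its mass is taken over its spanning edges minus edges owned by other
families. Arbitrary multi-family unions are left unassigned with
per-family mass diagnostics, because a union assembled freely from
enough families would always pass the threshold and mean nothing.

## Congruence and the morphology comparison

Queries are bucketed as congruent (all positively-assigning methods name
one family; a single positive assignment is congruent by vacuity),
partially-assigned (no method assigns), or conflicting (≥ 2 methods,
≥ 2 families), with conflict records listing each method's family. The
buckets partition the query set.

The OTU/morphospecies comparison tallies assigned OTUs and morphospecies
per (family, sample) — families seen by only one side keep a zero row on
the other — harmonizes family names through an optional synonym table
with the supplied taxonomy map as authority, and correlates the paired
counts with the Pearson product-moment coefficient (scipy). Zero
variance is an error, not a NaN. Rows that are zero on both sides are
dropped before correlating; whether such rows existed in the published
analysis is not stated anywhere, so this choice is exposed as
`drop_all_zero` and its effect should be checked when comparing against
externally produced tables.

## Synthetic data: what it emulates and what it does not

The generator is a pure function of (config, seed). It emulates, at the
level the classifiers operate on:

* a reference tree built by attaching per-family clades (random binary
  expansions) to a random backbone, supports drawn from a truncated
  normal on [0, 100] (default 85 ± 15 — a curated reference set with
  mostly well-supported families); a fraction of families (default 0.1)
  is broken by regrafting one member outside its clade;
* queries with truth tags: clean, paraphyletic-target (true family
  broken), off-reference (true family absent from the references,
  default 0.1 — the incomplete-database regime; correct behavior is
  unassigned and is scored separately);
* placements as Dirichlet LWR vectors over all edges: symmetric base
  weight 0.05 per edge plus a concentration parameter (default 2000) on
  one edge inside the true family's clade. Concentration → ∞ puts all
  mass on that edge; 0 is the symmetric Dirichlet. The small base weight
  makes vectors sparse, as placement tools emit; per-query mass sums to
  1 exactly;
* hit tables whose within-family identity band scales with reference
  coverage (80 + 2.5·min(n_members, 5), width 10): a family with one
  reference sequence often has no hit above the 90% floor, which is the
  mechanism behind strict top-hit's low yield on sparse databases.
  Decoy hits decay with taxonomic distance (default 6%/rank); bit score
  is a fixed monotone function of identity; contaminant non-voucher top
  hits are injected at rate 0.1;
* a joint reference+query tree for the tree rule, with every support
  re-drawn at a penalized mean (default −15 points): co-inferring many
  short queries erodes bootstrap support relative to the reference-only
  inference, which is why the placement classifier (which keeps the
  clean reference tree) outperforms the tree rule at survey scale;
* morphology-side counts by binomial thinning of true per-family
  richness, with per-family detection probabilities (0 models
  systematically overlooked taxa such as endoparasites).

Branch lengths are arbitrary positive values; no classifier in scope
consumes them. Not modelled: actual sequences (no chimaeras, no
alignment error), abundance, primer bias, multiple samples with shared
structure. Passing tests therefore demonstrate the correctness of the
decision rules and bookkeeping under controlled difficulty — not that
any particular real survey's yield will be reproduced.

## Numerical and degenerate-input choices

Support exactly at the floor passes (≥, exposed as a parameter). Hit
sort order is total, so permuting input rows never changes a verdict.
Queries whose hits are all filtered away remain in the table with an
empty list and come out unassigned rather than disappearing. The LWR sum
tolerance is 1e−6; Pearson correlation requires n ≥ 2 and non-zero
variance on both sides. Seeds are mandatory for every stochastic
generator; sub-generators derive fixed offsets from the master seed.

## Problem sizes

The test suite runs the clade machinery against a brute-force clade
enumeration oracle on every rooted binary shape with ≤ 12 tips (849
shapes) and on 1000 random 30-tip trees, and runs the pipeline
end-to-end at a reduced scale (6–12 families, 20–80 queries) chosen so
the full suite completes in seconds. `scripts/acceptance.py` runs at
study scale: 30 families, ~300 reference tips, 139 queries, 14-way
partitioned tree runs.

## Known limitations

* The LCA rule's bit-score range may diverge from classifiers that use
  raw alignment scores; verdicts near the range boundary can differ.
* Under heavy paraphyly, nested supported clades can imply conflicting
  single-family compositions; smallest-clade precedence resolves this
  silently in the tree rule (candidates are recorded when composition is
  mixed, but a *pure* smaller clade wins even if a larger pure clade of
  a different family exists).
* The ambiguity pair rule checks adjacency through MRCA spanning sets;
  two families separated by a single zero-length edge chain are still
  "distant" to it.
* Family-name harmonization is only as good as the supplied synonym
  table; classification updates are handled by supplying a different
  taxonomy map, not by any online sync.
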