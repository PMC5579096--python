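"""Independent brute-force oracles over nested-tuple tree structures.

A tree is either a tip label (``str``) or a pair ``(children, support)``
where ``children`` is a tuple of subtrees and ``support`` is a number in
[0, 100] or ``None``. The oracles enumerate every clade explicitly and
never touch the package's tree machinery, so they can arbitrate the
clade-finding, monophyly and tree-assignment code.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

Node = Union[str, tuple]


def to_newick(t: Node) -> str:
    def fmt(n: Node) -> str:
        if isinstance(n, str):
            return n + ":1"
        children, support = n
        lab = "" if support is None else str(support)
        return "(" + ",".join(fmt(c) for c in children) + f"){lab}:1"
    children, support = t
    lab = "" if support is None else str(support)
    return "(" + ",".join(fmt(c) for c in children) + f"){lab};"


def tips_of(t: Node) -> frozenset[str]:
    if isinstance(t, str):
        return frozenset([t])
    return frozenset().union(*(tips_of(c) for c in t[0]))


def enumerate_clades(t: Node) -> list[tuple[frozenset[str], Optional[float], bool]]:
    """All internal clades as (tip set, support, is_root) triples."""
    out: list[tuple[frozenset[str], Optional[float], bool]] = []

    def walk(n: Node, is_root: bool) -> frozenset[str]:
        if isinstance(n, str):
            return frozenset([n])
        children, support = n
        tips = frozenset().union(*(walk(c, False) for c in children))
        out.append((tips, support, is_root))
        return tips

    walk(t, True)
    return out


def oracle_smallest_supported_clade(
    t: Node,
    tip: str,
    min_support: float,
    query_tips: Sequence[str] = (),
) -> Optional[frozenset[str]]:
    """Tip set of the smallest qualifying clade containing ``tip``.

    Qualifying: support present and >= ``min_support`` (the root clade
    needs an explicit support value like any other) and at least one
    reference tip besides ``tip`` itself.
    """
    qs = set(query_tips)
    best: Optional[frozenset[str]] = None
    for tips, support, _is_root in enumerate_clades(t):
        if tip not in tips or support is None or support < min_support:
            continue
        if not (tips - qs - {tip}):
            continue
        if best is None or len(tips) < len(best):
            best = tips
    return best


def oracle_is_monophyletic(
    t: Node,
    fam_tips: frozenset[str],
    query_tips: Sequence[str] = (),
) -> bool:
    """Monophyly on reference tips, query tips transparent.

    The family's MRCA clade is the smallest enumerated clade containing
    all its tips (the whole tree counts as a clade for this purpose);
    monophyletic iff that clade adds no other reference tips.
    """
    if len(fam_tips) == 1:
        return True
    qs = set(query_tips)
    all_clades = enumerate_clades(t) + [(tips_of(t), None, True)]
    containing = [tips for tips, _s, _r in all_clades if fam_tips <= tips]
    mrca_tips = min(containing, key=len)
    return (mrca_tips - qs) == fam_tips


def oracle_tree_verdict(
    t: Node,
    tip: str,
    min_support: float,
    query_tips: Sequence[str],
    family_of: dict[str, str],
) -> tuple[str, Optional[str]]:
    """Tree-rule verdict: ('assigned', family) or ('unassigned', None)."""
    clade = oracle_smallest_supported_clade(t, tip, min_support, query_tips)
    if clade is None:
        return "unassigned", None
    refs = clade - set(query_tips) - {tip}
    families = {family_of[r] for r in refs}
    if len(families) == 1:
        return "assigned", families.pop()
    return "unassigned", None


# ---------------------------------------------------------------------------
# topology generators
# ---------------------------------------------------------------------------

def all_shapes(n: int) -> list:
    """All rooted binary tree shapes with ``n`` unlabeled tips.

    Shapes are nested tuples with ``None`` leaves; counts follow the
    Wedderburn–Etherington numbers (1, 1, 1, 2, 3, 6, 11, 23, ...).
    """
    memo: dict[int, list] = {1: [None]}

    def gen(k: int) -> list:
        if k in memo:
            return memo[k]
        out = []
        for left in range(1, k // 2 + 1):
            right = k - left
            ls, rs = gen(left), gen(right)
            for i, a in enumerate(ls):
                bs = rs if left != right else ls[i:]
                for b in bs:
                    out.append((a, b))
        memo[k] = out
        return out

    return gen(n)


def label_shape(shape, labels: list[str]) -> Node:
    """Attach labels left-to-right; supports filled in later."""
    it = iter(labels)

    def walk(s):
        if s is None:
            return next(it)
        return ((walk(s[0]), walk(s[1])), None)

    return walk(shape)


def with_random_supports(t: Node, rng, p_none: float = 0.2) -> Node:
    """Copy of the tree with supports drawn in {None} ∪ [0, 100]."""
    def walk(n: Node) -> Node:
        if isinstance(n, str):
            return n
        children, _ = n
        support = None if rng.random() < p_none else int(rng.integers(0, 101))
        return (tuple(walk(c) for c in children), support)

    return walk(t)


def random_topology(labels: list[str], rng) -> Node:
    """Random rooted binary topology by random pairwise joins."""
    subtrees: list[Node] = list(labels)
    while len(subtrees) > 1:
        i = int(rng.integers(len(subtrees)))
        a = subtrees.pop(i)
        j = int(rng.integers(len(subtrees)))
        b = subtrees.pop(j)
        subtrees.append(((a, b), None))
    return subtrees[0]
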