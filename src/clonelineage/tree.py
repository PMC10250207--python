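"""Lineage-tree construction from mosaic-variant carrier sets.

Variants sharing an identical carrier set mark the same cell division, so
they are merged into one branch group.  A collection of groups is a
perfect phylogeny iff every two carrier sets are nested or disjoint (a
laminar family); the groups then arrange themselves into a rooted tree by
the strict-superset partial order, with the zygote as an implicit root
carrying all units.  Incompatible groups are data, not errors: a minimal
number of them is removed (ties broken towards groups supported by fewer
variants, since a branch witnessed by many independent mutations is more
credible than one witnessed by a single call) and reported in the
conflict list.  Sibling order is meaningless, so unresolved branching is
emitted as a multifurcation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_model import GenomicSite

#: Above this many mutually conflicting groups the exact minimum-removal
#: search is replaced by the greedy drop-fewest-variants rule.
_EXACT_CONFLICT_LIMIT = 20


@dataclass(frozen=True)
class BranchGroup:
    """Variants with an identical carrier set: one (candidate) branch."""

    carriers: frozenset[str]
    variants: tuple[GenomicSite, ...]

    def __post_init__(self) -> None:
        if not self.carriers:
            raise ValueError("branch group needs a non-empty carrier set")
        if not self.variants:
            raise ValueError("branch group needs at least one variant")

    @property
    def size(self) -> int:
        return len(self.carriers)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class TreeNode:
    carriers: frozenset[str]
    variants: tuple[GenomicSite, ...] = ()
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class LineageTree:
    """Rooted tree over units; edges (into nodes) carry branch groups."""

    root: TreeNode
    units: list[str]
    conflicts: list[BranchGroup] = field(default_factory=list)

    def internal_clades(self) -> set[frozenset[str]]:
        """Carrier sets of non-trivial internal edges (1 < |c| < n)."""
        n = len(self.units)
        out: set[frozenset[str]] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if 1 < len(node.carriers) < n:
                out.add(node.carriers)
            stack.extend(node.children)
        return out

    def validate_nesting(self) -> None:
        """Check the structural invariants of a perfect phylogeny."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            child_union: set[str] = set()
            for ch in node.children:
                if not ch.carriers < node.carriers:
                    raise AssertionError(
                        f"child carriers {sorted(ch.carriers)} do not strictly "
                        f"nest in parent {sorted(node.carriers)}"
                    )
                if child_union & ch.carriers:
                    raise AssertionError("sibling carrier sets overlap")
                child_union |= ch.carriers
                stack.append(ch)


def group_by_carriers(
    sharing: Mapping[GenomicSite, frozenset[str] | set[str]]
) -> list[BranchGroup]:
    """Merge variants with identical carrier sets into branch groups,
    sorted by (size desc, lexicographic carriers)."""
    if not sharing:
        raise ValueError("empty sharing map")
    by_set: dict[frozenset[str], list[GenomicSite]] = {}
    for site, carriers in sharing.items():
        by_set.setdefault(frozenset(carriers), []).append(site)
    groups = [
        BranchGroup(carriers=c, variants=tuple(sorted(v))) for c, v in by_set.items()
    ]
    groups.sort(key=lambda g: (-g.size, sorted(g.carriers)))
    return groups


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def _drop_priority(g: BranchGroup) -> tuple:
    return (g.n_variants, g.size, sorted(g.carriers))


def _resolve_conflicts(
    groups: Sequence[BranchGroup],
) -> tuple[list[BranchGroup], list[BranchGroup]]:
    """Remove groups of minimal total variant support so the rest is laminar.

    Compatibility is pairwise, so conflicts form a graph and any valid
    removal set is a vertex cover over the conflicted groups.  The cover
    minimizes the total number of member variants dropped (a branch
    witnessed by many independent mutations outweighs several
    single-variant artifacts), with ties broken towards fewer groups and
    then the drop-priority order.  Exact branch-and-bound up to
    ``_EXACT_CONFLICT_LIMIT`` conflicted groups, greedy beyond.
    """
    edges = [
        (i, j)
        for i, j in itertools.combinations(range(len(groups)), 2)
        if not _compatible(groups[i].carriers, groups[j].carriers)
    ]
    if not edges:
        return list(groups), []
    conflicted = {i for e in edges for i in e}

    def removal_key(cset: set[int]) -> tuple:
        return (
            sum(groups[i].n_variants for i in cset),
            len(cset),
            sorted(_drop_priority(groups[i]) for i in cset),
        )

    dropped_idx: set[int] | None = None
    if len(conflicted) <= _EXACT_CONFLICT_LIMIT:
        best: list = [None, None]  # key, cover

        def bnb(cset: set[int], live: list[tuple[int, int]]) -> None:
            key = removal_key(cset)
            if best[0] is not None and key >= best[0]:
                return
            if not live:
                best[0], best[1] = key, set(cset)
                return
            u, v = live[0]
            for w in sorted((u, v), key=lambda i: _drop_priority(groups[i])):
                bnb(cset | {w}, [e for e in live if w not in e])

        bnb(set(), edges)
        dropped_idx = best[1]
    if dropped_idx is None:  # greedy fallback on large conflict sets
        dropped_idx = set()
        live = edges
        while live:
            worst = min({i for e in live for i in e} - dropped_idx,
                        key=lambda i: _drop_priority(groups[i]))
            dropped_idx.add(worst)
            live = [e for e in live if worst not in e]
    kept = [g for i, g in enumerate(groups) if i not in dropped_idx]
    dropped = sorted(
        (groups[i] for i in dropped_idx), key=_drop_priority
    )
    return kept, dropped


def build_tree(groups: Sequence[BranchGroup], units: Sequence[str]) -> LineageTree:
    """Arrange compatible branch groups into a rooted lineage tree.

    The root carries all units (the zygote is implicit even if no variant
    is shared by everyone).  Each kept group becomes the edge into an
    internal node; leaves are the units themselves.  Incompatible groups
    are minimally removed and recorded in ``tree.conflicts``.
    """
    units = sorted(units)
    unit_set = frozenset(units)
    for g in groups:
        if not g.carriers <= unit_set:
            raise ValueError(f"group carriers {sorted(g.carriers)} outside unit set")
    kept, dropped = _resolve_conflicts(list(groups))

    # Merge variant lists of kept groups by carrier set (root-size groups
    # annotate the root edge).
    merged: dict[frozenset[str], list[GenomicSite]] = {}
    for g in kept:
        merged.setdefault(g.carriers, []).extend(g.variants)

    root = TreeNode(carriers=unit_set, variants=tuple(sorted(merged.pop(unit_set, ()))))
    # Insert internal nodes largest-first: the parent of a set is the
    # smallest already-inserted strict superset.
    nodes = [root]
    for carriers in sorted(merged, key=lambda c: (-len(c), sorted(c))):
        parent = root
        while True:
            nxt = next(
                (ch for ch in parent.children if carriers < ch.carriers), None
            )
            if nxt is None:
                break
            parent = nxt
        node = TreeNode(carriers=carriers, variants=tuple(sorted(merged[carriers])))
        # Reparent any existing children now strictly inside the new node.
        inside = [ch for ch in parent.children if ch.carriers < carriers]
        for ch in inside:
            parent.children.remove(ch)
        node.children.extend(inside)
        parent.children.append(node)
        nodes.append(node)

    # Attach unit leaves under the smallest node containing each unit.
    for unit in units:
        parent = root
        while True:
            nxt = next(
                (ch for ch in parent.children
                 if unit in ch.carriers and len(ch.carriers) > 1),
                None,
            )
            if nxt is None:
                break
            parent = nxt
        if len(parent.carriers) == 1:
            continue  # parent already is this unit's singleton node
        singleton = next(
            (ch for ch in parent.children if ch.carriers == frozenset({unit})), None
        )
        if singleton is None:
            parent.children.append(TreeNode(carriers=frozenset({unit})))

    tree = LineageTree(root=root, units=units, conflicts=dropped)
    tree.validate_nesting()
    return tree


def compare_trees(tree: LineageTree, truth: LineageTree) -> dict[str, float]:
    """Clade-level agreement between a reconstructed and a true tree.

    Returns the fraction of true non-trivial internal edges recovered, the
    fraction of reconstructed edges that are true, and the Robinson-Foulds
    distance (size of the symmetric difference of clade sets).
    """
    if sorted(tree.units) != sorted(truth.units):
        raise ValueError("trees have different leaf sets")
    rec = tree.internal_clades()
    tru = truth.internal_clades()
    shared = rec & tru
    return {
        "recovered": len(shared) / len(tru) if tru else 1.0,
        "precision": len(shared) / len(rec) if rec else 1.0,
        "rf_distance": float(len(rec ^ tru)),
    }


def to_newick(tree: LineageTree) -> str:
    """Newick string; internal labels carry the edge's variant count.

    Multifurcations are preserved.  Exported through dendropy so the text
    is guaranteed parseable by standard tools.
    """
    import dendropy

    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def convert(node: TreeNode, dnode) -> None:
        for ch in node.children:
            dch = dnode.new_child()
            if ch.is_leaf and len(ch.carriers) == 1:
                (unit,) = ch.carriers
                dch.taxon = taxa.require_taxon(label=unit)
            else:
                dch.label = str(len(ch.variants))
            convert(ch, dch)

    dtree.seed_node.label = str(len(tree.root.variants))
    convert(tree.root, dtree.seed_node)
    return dtree.as_string(schema="newick", suppress_rooting=True).strip()


def write_branch_table(tree: LineageTree, path) -> None:
    with open(path, "w") as fh:
        fh.write("#edge_id\tcarriers\tn_variants\tvariant_list\n")
        idx = 0
        stack = [tree.root]
        while stack:
            node = stack.pop()
            if node.variants or node is tree.root:
                vlist = ";".join(f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}" for v in node.variants)
                fh.write(f"e{idx}\t{','.join(sorted(node.carriers))}"
                         f"\t{len(node.variants)}\t{vlist}\n")
                idx += 1
            stack.extend(node.children)


def write_conflicts(tree: LineageTree, path) -> None:
    with open(path, "w") as fh:
        fh.write("#carriers\tn_variants\tvariant_list\n")
        for g in tree.conflicts:
            vlist = ";".join(f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}" for v in g.variants)
            fh.write(f"{','.join(sorted(g.carriers))}\t{g.n_variants}\t{vlist}\n")
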