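"""Fitch parsimony mapping of substitutions onto a given tree.

Synonymous substitutions observed among alleles are placed on the branches
of a supplied (ML) tree by Fitch parsimony, per-branch change counts are
tallied, and the number of synonymous substitutions separating two alleles
(KS) is re-counted as the sum of mapped changes along the tree path between
them.  Path counting recovers parallel and back substitutions that pairwise
difference counting collapses, so ``KS_max`` can exceed the largest raw
pairwise difference count; ``KS_max / LS`` feeds the clock-based TMRCA.

Trees come in as newick; unrooted trees are accepted and rooted on a named
outgroup.  Among equally parsimonious reconstructions only the per-site
change totals (and hence path sums on homoplasy-free data) are unique;
branch attribution uses the classic second-pass rule with a deterministic
lexicographic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import dendropy
import numpy as np

from .alleles_io import AlleleSet
from .codon_evol import NUCS


class LeafMismatchError(ValueError):
    pass


@dataclass
class Phylogeny:
    """Rooted tree whose leaves are (a subset of) allele names."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(
        cls, newick: str, outgroup: "str | None" = None
    ) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        if outgroup is not None:
            node = None
            for leaf in tree.leaf_node_iter():
                if leaf.taxon is not None and leaf.taxon.label == outgroup:
                    node = leaf
                    break
            if node is None:
                raise LeafMismatchError(f"outgroup {outgroup!r} not in tree")
            tree.to_outgroup_position(node, update_bipartitions=False)
        return cls(tree=tree)

    @classmethod
    def from_file(
        cls, path, outgroup: "str | None" = None
    ) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read(), outgroup=outgroup)

    def leaf_names(self) -> list[str]:
        return [
            l.taxon.label for l in self.tree.leaf_node_iter() if l.taxon
        ]

    def edge_keys(self) -> list[str]:
        """Stable branch identifiers (child-node key) for non-root nodes."""
        self._label_internals()
        return [
            _node_key(n)
            for n in self.tree.preorder_node_iter()
            if n.parent_node is not None
        ]

    def _label_internals(self) -> None:
        i = 0
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node.label is None:
                node.label = f"node{i}"
            i += 1

    def newick(self) -> str:
        out = StringIO()
        self.tree.write(file=out, schema="newick", suppress_rooting=True)
        return out.getvalue().strip()


def _node_key(node: dendropy.Node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return node.taxon.label
    return node.label or f"id{id(node)}"


@dataclass
class BranchChangeMap:
    """Per-branch and per-site counts of parsimony-placed changes."""

    branch_counts: dict[str, int]
    per_site_counts: dict[int, int]  # 0-based column -> Fitch minimum
    sites: list[int]

    @property
    def total_changes(self) -> int:
        return sum(self.per_site_counts.values())


def _fitch_site(
    t: dendropy.Tree, states: dict[str, str]
) -> tuple[int, dict[int, str]]:
    """One-site Fitch: (minimum change count, node -> assigned state).

    Sequences with a gap/ambiguity at the site get the full state set (they
    constrain nothing).  Second pass assigns the parent's state when it is
    in the child's preliminary set, otherwise the lexicographically smallest
    member of the child's set (a change on that branch).
    """
    prelim: dict[int, frozenset] = {}
    count = 0
    for node in t.postorder_node_iter():
        if node.is_leaf():
            s = states.get(node.taxon.label if node.taxon else "", "")
            prelim[id(node)] = (
                frozenset(s) if s in NUCS else frozenset(NUCS)
            )
        else:
            sets = [prelim[id(c)] for c in node.child_nodes()]
            inter = frozenset.intersection(*sets)
            if inter:
                prelim[id(node)] = inter
            else:
                # polytomy-safe: sequential pairwise Fitch over children
                acc = sets[0]
                for s in sets[1:]:
                    both = acc & s
                    if both:
                        acc = both
                    else:
                        acc = acc | s
                        count += 1
                prelim[id(node)] = acc

    assigned: dict[int, str] = {}
    for node in t.preorder_node_iter():
        opts = prelim[id(node)]
        if node.parent_node is None:
            assigned[id(node)] = min(opts)
        else:
            p = assigned[id(node.parent_node)]
            assigned[id(node)] = p if p in opts else min(opts)
    return count, assigned


def fitch_map(
    t: Phylogeny,
    a: AlleleSet,
    sites: "list[int] | None" = None,
    tie_break: str = "lex",
) -> BranchChangeMap:
    """Map per-column changes onto branches by Fitch parsimony.

    ``sites`` are 0-based alignment columns (default: all variable columns).
    Raises :class:`LeafMismatchError` if tree leaves are missing from the
    allele set.  ``tie_break`` is reserved for alternative placements of
    ambiguous changes; per-site totals are identical for all settings.
    """
    if tie_break not in ("lex",):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    leaf_names = t.leaf_names()
    name_to_idx = {n.raw: i for i, n in enumerate(a.names)}
    missing = [n for n in leaf_names if n not in name_to_idx]
    if missing:
        raise LeafMismatchError(f"tree leaves missing from alleles: {missing}")

    if sites is None:
        sites = [
            col
            for col in range(a.alignment_length)
            if len(
                {
                    a.sequences[name_to_idx[n]][col]
                    for n in leaf_names
                    if a.sequences[name_to_idx[n]][col] in NUCS
                }
            )
            > 1
        ]

    t._label_internals()
    branch_counts: dict[str, int] = {k: 0 for k in t.edge_keys()}
    per_site: dict[int, int] = {}
    for col in sites:
        states = {
            n: a.sequences[name_to_idx[n]][col] for n in leaf_names
        }
        count, assigned = _fitch_site(t.tree, states)
        per_site[col] = count
        for node in t.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if assigned[id(node)] != assigned[id(node.parent_node)]:
                branch_counts[_node_key(node)] += 1
    return BranchChangeMap(
        branch_counts=branch_counts, per_site_counts=per_site, sites=list(sites)
    )


def _path_edges(
    t: Phylogeny, leaf1: str, leaf2: str
) -> list[str]:
    nodes = {}
    for leaf in t.tree.leaf_node_iter():
        if leaf.taxon is not None:
            nodes[leaf.taxon.label] = leaf
    for name in (leaf1, leaf2):
        if name not in nodes:
            raise LeafMismatchError(f"unknown leaf {name!r}")
    if leaf1 == leaf2:
        return []
    anc1 = []
    n = nodes[leaf1]
    while n is not None:
        anc1.append(n)
        n = n.parent_node
    anc1_ids = {id(x): i for i, x in enumerate(anc1)}
    path2 = []
    n = nodes[leaf2]
    while id(n) not in anc1_ids:
        path2.append(n)
        n = n.parent_node
    mrca_pos = anc1_ids[id(n)]
    edges = [_node_key(x) for x in anc1[:mrca_pos]]
    edges += [_node_key(x) for x in path2]
    return edges


def path_ks(
    m: BranchChangeMap, t: Phylogeny, leaf1: str, leaf2: str
) -> int:
    """Sum of mapped changes along the unique path between two leaves."""
    return sum(m.branch_counts.get(e, 0) for e in _path_edges(t, leaf1, leaf2))


@dataclass
class KsMatrix:
    names: list[str]
    matrix: np.ndarray
    ks_max: int


def ks_matrix(m: BranchChangeMap, t: Phylogeny) -> KsMatrix:
    """All-pairs path sums of mapped changes and their maximum (KS_max)."""
    names = t.leaf_names()
    n = len(names)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            v = path_ks(m, t, names[i], names[j])
            mat[i, j] = mat[j, i] = v
    return KsMatrix(
        names=names, matrix=mat, ks_max=int(mat.max()) if n > 1 else 0
    )
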