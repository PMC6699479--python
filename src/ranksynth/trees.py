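"""Rooted, branch-length-free trees: newick I/O and cluster/MRCA primitives.

Trees here are purely topological.  Input phylogenies are read as rooted as
drawn, branch lengths are parsed and discarded, and multifurcations are legal
everywhere (a polytomy signals absent information, not simultaneous
divergence).  Children are kept in a canonical order — sorted by the
lexicographically smallest descendant leaf label — so serialization is
deterministic and topology equality is string equality of canonical newick.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "TreeNode",
    "Tree",
    "TreeError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "map_tips",
    "nontrivial_clusters",
    "restrict",
    "mrca",
    "TipMapReport",
]


class TreeError(ValueError):
    """Malformed newick or violated tree invariants."""


class TreeNode:
    __slots__ = ("label", "children", "parent", "_min_leaf")

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self._min_leaf: str = ""

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def iter_preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def iter_postorder(self) -> Iterator["TreeNode"]:
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.iter_preorder() if n.is_leaf]


class Tree:
    """Rooted tree with unique leaf labels and canonical child order."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._canonicalize()
        labels = self.leaf_labels()
        dupes = {l for l in labels if labels.count(l) > 1}
        if any(l is None for l in labels):
            raise TreeError("unlabeled leaf")
        if dupes:
            raise TreeError(f"duplicate leaf label {sorted(dupes)[0]!r}")
        self._leaf_index: dict[str, TreeNode] = {
            n.label: n for n in self.root.iter_preorder() if n.is_leaf
        }

    def _canonicalize(self) -> None:
        for node in self.root.iter_postorder():
            if node.is_leaf:
                node._min_leaf = node.label or ""
            else:
                node.children.sort(key=lambda c: c._min_leaf)
                node._min_leaf = node.children[0]._min_leaf

    # -- queries -----------------------------------------------------------

    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()

    @property
    def leaf_set(self) -> frozenset[str]:
        return frozenset(self._leaf_index)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_index)

    def internal_nodes(self, include_root: bool = True) -> list[TreeNode]:
        out = [n for n in self.root.iter_preorder() if not n.is_leaf]
        if not include_root and out and out[0] is self.root:
            out = out[1:]
        return out

    def leaf_node(self, label: str) -> TreeNode:
        try:
            return self._leaf_index[label]
        except KeyError:
            raise TreeError(f"unknown leaf id {label!r}") from None

    def cluster_of(self, node: TreeNode) -> frozenset[str]:
        return frozenset(n.label for n in node.iter_preorder() if n.is_leaf)

    def copy(self) -> "Tree":
        def dup(n: TreeNode) -> TreeNode:
            m = TreeNode(label=n.label)
            for c in n.children:
                m.add_child(dup(c))
            return m

        return Tree(dup(self.root))

    def relabel(self, mapping: dict[str, str]) -> "Tree":
        t = self.copy()
        for leaf in t._leaf_index.values():
            leaf.label = mapping.get(leaf.label, leaf.label)
        return Tree(t.root)

    def __eq__(self, other) -> bool:  # canonical-form equality
        return isinstance(other, Tree) and write_newick(self) == write_newick(other)

    def __hash__(self) -> int:
        return hash(write_newick(self))


# -- newick I/O ------------------------------------------------------------


def parse_newick(text: str, underscores_are_spaces: bool = False) -> Tree:
    """Parse one rooted newick statement; branch lengths are discarded.

    Quoted labels follow newick conventions; by default underscores are kept
    verbatim (``underscores_are_spaces=True`` enables the classic dialect).
    """
    if not text or not text.strip():
        raise TreeError("empty newick text")
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=not underscores_are_spaces,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise TreeError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = TreeNode(label=label)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dt.seed_node)
    if root.is_leaf and root.label is None:
        raise TreeError("empty tree")
    return Tree(root)


_QUOTE_NEEDED = re.compile(r"[\s(),:;\[\]']")


def _format_label(label: str) -> str:
    if _QUOTE_NEEDED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, internal_labels: bool = False) -> str:
    """Serialize in canonical child order; ``parse_newick`` round-trips."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return _format_label(node.label)
        inner = ",".join(fmt(c) for c in node.children)
        lab = (
            _format_label(node.label)
            if internal_labels and node.label
            else ""
        )
        return f"({inner}){lab}"

    return fmt(tree.root) + ";"


def read_newick(path: str | Path, **kw) -> Tree:
    return parse_newick(Path(path).read_text(encoding="utf-8"), **kw)


# -- cluster / restriction / mrca primitives -------------------------------


def nontrivial_clusters(tree: Tree) -> set[frozenset[str]]:
    """Leaf sets of internal non-root nodes, singletons excluded."""
    out: set[frozenset[str]] = set()
    clusters: dict[int, set[str]] = {}
    for node in tree.root.iter_postorder():
        if node.is_leaf:
            clusters[id(node)] = {node.label}
        else:
            s: set[str] = set()
            for c in node.children:
                s |= clusters.pop(id(c))
            clusters[id(node)] = s
            if node is not tree.root and len(s) >= 2:
                out.add(frozenset(s))
    return out


def restrict(tree: Tree, keep: Iterable[str]) -> Tree:
    """Induced topology on ``keep`` ∩ leaves; unary nodes suppressed."""
    keep = frozenset(keep)
    if not keep & tree.leaf_set:
        raise TreeError("restriction leaf set does not intersect the tree")

    def prune(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            return TreeNode(label=node.label) if node.label in keep else None
        kids = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        new = TreeNode(label=node.label)
        for k in kids:
            new.add_child(k)
        return new

    return Tree(prune(tree.root))


def mrca(tree: Tree, leaf_ids: Iterable[str]) -> TreeNode:
    """Deepest node whose leaf set contains all of ``leaf_ids``."""
    ids = list(leaf_ids)
    if not ids:
        raise TreeError("mrca of empty set")
    nodes = [tree.leaf_node(l) for l in ids]
    current = nodes[0]
    seen_depth: dict[int, int] = {}
    # ancestors of the running mrca, with depths
    def ancestors(n: TreeNode) -> dict[int, TreeNode]:
        out = {}
        while n is not None:
            out[id(n)] = n
            n = n.parent
        return out

    anc = ancestors(current)
    for n in nodes[1:]:
        walker = n
        while id(walker) not in anc:
            walker = walker.parent
        current = walker
        anc = ancestors(current)
    return current


# -- tip mapping -----------------------------------------------------------


@dataclass
class TipMapReport:
    """Per-leaf outcome of mapping a source tree onto the taxonomy."""

    matches: list = field(default_factory=list)  # NameMatchResult per input leaf
    pruned: list[tuple[str, str]] = field(default_factory=list)  # (label, reason)

    @property
    def n_pruned(self) -> int:
        return len(self.pruned)


def map_tips(
    tree: Tree,
    taxonomy,
    fuzzy_threshold: int = 2,
    allow_genus_tips: bool = True,
) -> tuple[Tree, TipMapReport]:
    """Relabel leaves to taxon ids; prune unmatched and duplicate-mapping
    leaves (first in canonical order wins); suppress resulting unary nodes."""
    report = TipMapReport()
    labels = tree.leaf_labels()  # canonical order
    mapping: dict[str, str] = {}
    seen_ids: set[str] = set()
    drop: set[str] = set()
    for lab in labels:
        res = taxonomy.resolve_label(
            lab, fuzzy_threshold=fuzzy_threshold, allow_genus_tips=allow_genus_tips
        )
        report.matches.append(res)
        if res.matched_id is None:
            drop.add(lab)
            report.pruned.append((lab, "unmatched"))
        elif res.matched_id in seen_ids:
            drop.add(lab)
            report.pruned.append((lab, f"duplicate of {res.matched_id}"))
        else:
            seen_ids.add(res.matched_id)
            mapping[lab] = res.matched_id
    kept = [l for l in labels if l not in drop]
    if len(kept) < 2:
        raise TreeError("fewer than 2 mapped leaves remain after pruning")
    mapped = restrict(tree, kept).relabel(mapping)
    return mapped, report
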