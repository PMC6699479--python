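"""Ranked supertree synthesis over rooted triples.

The engine expresses every internal node (cluster) of a source tree as the
set of rooted triples it implies — (a,b|c) for each pair a,b inside the
cluster and each leaf c of the same source outside it — and accepts clusters
greedily in rank order: a cluster is kept iff its triples are jointly
consistent with everything accepted so far (the classic BUILD test of Aho et
al.).  Because acceptance is atomic per cluster and sources are visited in
rank order, the first-ranked tree always has all its groupings displayed,
later trees keep whatever does not contradict earlier ones, and the taxonomy
— ranked last — only fills gaps.  The final tree is the minimally resolved
(BUILD) tree of the accepted constraints: where no source says anything, the
result is a polytomy.

Internally a cluster constraint is carried as (ingroup, outgroup) rather than
an enumerated triple set; the two forms induce identical BUILD components, so
explicit-triple operations and cluster-level synthesis share one engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .trees import Tree, TreeNode, nontrivial_clusters

__all__ = [
    "RootedTriple",
    "ConstraintSet",
    "SourceClusters",
    "SynthesisResult",
    "InconsistentConstraints",
    "cluster_triples",
    "is_consistent",
    "build_tree",
    "synthesize",
    "source_from_tree",
    "source_from_taxonomy",
]


class InconsistentConstraints(ValueError):
    """build_tree called on a constraint set with no displaying tree."""


@dataclass(frozen=True, order=True)
class RootedTriple:
    """ab|c — a and b are closer to each other than either is to c."""

    a: str
    b: str
    c: str

    def __post_init__(self):
        if len({self.a, self.b, self.c}) != 3:
            raise ValueError("triple members must be distinct")
        if self.a > self.b:
            object.__setattr__(self, "a", self.b)
            object.__setattr__(self, "b", self.a)

    @classmethod
    def of(cls, a: str, b: str, c: str) -> "RootedTriple":
        return cls(min(a, b), max(a, b), c)


@dataclass(frozen=True)
class ConstraintSet:
    triples: frozenset[RootedTriple]
    universe: frozenset[str]

    def __post_init__(self):
        for t in self.triples:
            if not {t.a, t.b, t.c} <= self.universe:
                raise ValueError(f"triple {t} outside universe")


def cluster_triples(cluster: Iterable[str], source_leaves: Iterable[str]) -> set[RootedTriple]:
    """All triples implied by a cluster within its source leaf set."""
    C = frozenset(cluster)
    L = frozenset(source_leaves)
    if len(C) < 2:
        raise ValueError("cluster must have ≥2 members")
    if not C < L:
        raise ValueError("cluster must be a proper subset of the source leaves")
    out: set[RootedTriple] = set()
    members = sorted(C)
    outgroup = L - C
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            for c in outgroup:
                out.add(RootedTriple(a, b, c))
    return out


# -- BUILD core ------------------------------------------------------------
#
# A constraint is (ingroup frozenset, outgroup frozenset): within a current
# leaf set X it glues ingroup∩X into one BUILD component iff |ingroup∩X| ≥ 2
# and outgroup∩X is non-empty (i.e. some triple still has its outgroup in X).


def _partition(
    X: frozenset[str], constraints: list[tuple[frozenset[str], frozenset[str]]]
) -> list[frozenset[str]]:
    parent: dict[str, str] = {x: x for x in X}

    def find(x: str) -> str:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for ing, out in constraints:
        it = iter(ing)
        first = find(next(it))
        for other in it:
            r = find(other)
            if r != first:
                parent[r] = first
    comps: dict[str, set[str]] = {}
    for x in X:
        comps.setdefault(find(x), set()).add(x)
    return [frozenset(c) for c in comps.values()]


def _sub_constraints(
    comps: list[frozenset[str]],
    constraints: list[tuple[frozenset[str], frozenset[str]]],
) -> list[list[tuple[frozenset[str], frozenset[str]]]]:
    index = {x: i for i, comp in enumerate(comps) for x in comp}
    buckets: list[list[tuple[frozenset[str], frozenset[str]]]] = [[] for _ in comps]
    for ing, out in constraints:
        # an active constraint's ingroup lies in exactly one component
        i = index[next(iter(ing))]
        sub_out = out & comps[i]
        if sub_out:
            buckets[i].append((ing, sub_out))
    return buckets


def _consistent(
    X: frozenset[str], constraints: list[tuple[frozenset[str], frozenset[str]]]
) -> bool:
    stack = [(X, constraints)]
    while stack:
        X, constraints = stack.pop()
        if len(X) <= 2:
            continue
        comps = _partition(X, constraints)
        if len(comps) == 1:
            return False
        for comp, sub in zip(comps, _sub_constraints(comps, constraints)):
            if len(comp) > 2 and sub:
                stack.append((comp, sub))
    return True


def _build(
    X: frozenset[str], constraints: list[tuple[frozenset[str], frozenset[str]]]
) -> TreeNode:
    if len(X) == 1:
        return TreeNode(label=next(iter(X)))
    comps = _partition(X, constraints)
    if len(comps) == 1 and len(X) >= 2:
        raise InconsistentConstraints(f"no tree displays the constraints on {sorted(X)[:6]}…")
    node = TreeNode()
    for comp, sub in zip(comps, _sub_constraints(comps, constraints)):
        node.add_child(_build(comp, sub))
    return node


def _restricted(
    constraints: Iterable[tuple[frozenset[str], frozenset[str]]],
    X: frozenset[str],
) -> list[tuple[frozenset[str], frozenset[str]]]:
    out = []
    for ing, og in constraints:
        ing2, og2 = ing & X, og & X
        if len(ing2) >= 2 and og2:
            out.append((ing2, og2))
    return out


def _triples_as_constraints(
    triples: Iterable[RootedTriple],
) -> list[tuple[frozenset[str], frozenset[str]]]:
    return [(frozenset((t.a, t.b)), frozenset((t.c,))) for t in triples]


def is_consistent(S: ConstraintSet) -> bool:
    """True iff some rooted tree on the universe displays every triple."""
    return _consistent(S.universe, _restricted(_triples_as_constraints(S.triples), S.universe))


def build_tree(S: ConstraintSet) -> Tree:
    """Minimally resolved (BUILD) tree displaying every triple of ``S``."""
    root = _build(
        S.universe, _restricted(_triples_as_constraints(S.triples), S.universe)
    )
    return Tree(root)


# -- ranked synthesis ------------------------------------------------------


@dataclass(frozen=True)
class SourceClusters:
    """One ranked source: its leaf set and its nontrivial clusters."""

    source_id: str
    leaf_set: frozenset[str]
    clusters: tuple[frozenset[str], ...]

    def __post_init__(self):
        for c in self.clusters:
            if not c <= self.leaf_set:
                raise ValueError(
                    f"source {self.source_id}: cluster outside its leaf set"
                )


def source_from_tree(source_id: str, tree: Tree) -> SourceClusters:
    return SourceClusters(
        source_id=source_id,
        leaf_set=tree.leaf_set,
        clusters=tuple(sorted(nontrivial_clusters(tree), key=lambda c: (-len(c), min(c)))),
    )


def source_from_taxonomy(taxonomy, source_id: str = "taxonomy") -> SourceClusters:
    clusters = tuple(sp for _, sp in taxonomy.clusters())
    return SourceClusters(
        source_id=source_id,
        leaf_set=taxonomy.species_under(taxonomy.root_id),
        clusters=clusters,
    )


@dataclass
class SynthesisResult:
    tree: Tree
    ledger: dict[str, dict[str, list[frozenset[str]]]]  # source -> accepted/rejected
    provenance: dict[frozenset[str], str] = field(default_factory=dict)

    def accepted(self, source_id: str) -> list[frozenset[str]]:
        return self.ledger[source_id]["accepted"]

    def rejected(self, source_id: str) -> list[frozenset[str]]:
        return self.ledger[source_id]["rejected"]


def synthesize(
    ranked_sources: Sequence[SourceClusters],
    universe: Iterable[str],
) -> SynthesisResult:
    """Greedy ranked atomic acceptance of source clusters.

    Sources are visited in rank order (taxonomy last by convention of the
    caller); each source's clusters are offered largest-first (ties by
    lexicographically smallest leaf) and accepted iff their implied triples
    are consistent with everything accepted before.  The returned tree spans
    the whole universe; leaves named by no accepted cluster sit at the root.
    """
    U = frozenset(universe)
    if not U:
        raise ValueError("universe is empty")
    for src in ranked_sources:
        if not src.leaf_set <= U:
            extra = sorted(src.leaf_set - U)[:3]
            raise ValueError(
                f"source {src.source_id} references leaves outside the universe: {extra}"
            )
    accepted: list[tuple[frozenset[str], frozenset[str]]] = []
    ledger: dict[str, dict[str, list[frozenset[str]]]] = {}
    provenance: dict[frozenset[str], str] = {}
    for src in ranked_sources:
        entry = {"accepted": [], "rejected": []}
        ledger[src.source_id] = entry
        for C in sorted(src.clusters, key=lambda c: (-len(c), min(c))):
            constraint = (C, src.leaf_set - C)
            if not constraint[1]:
                # cluster equals the source's whole leaf set: no triples
                entry["accepted"].append(C)
                provenance.setdefault(C, src.source_id)
                continue
            if _consistent(U, accepted + [constraint]):
                accepted.append(constraint)
                entry["accepted"].append(C)
                provenance.setdefault(C, src.source_id)
            else:
                entry["rejected"].append(C)
    tree = Tree(_build(U, accepted))
    return SynthesisResult(tree=tree, ledger=ledger, provenance=provenance)


def write_ledger_tsv(result: SynthesisResult, path) -> None:
    """Per-source accepted/rejected clusters, members semicolon-joined."""
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source_id", "cluster", "status"])
        for source_id, entry in result.ledger.items():
            for status in ("accepted", "rejected"):
                for C in entry[status]:
                    w.writerow([source_id, ";".join(sorted(C)), status])
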