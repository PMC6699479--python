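"""Support/conflict annotation of synthesis-tree branches.

For every internal non-root node of the synthesis tree and every input tree,
the node's leaf set is restricted to the input's leaves.  If the restriction
is empty, a singleton, or the whole input, the input says nothing (neutral).
If it equals one of the input's own clusters the input *supports* the branch;
if it properly overlaps some input cluster (splitting it) the input
*conflicts*; a restriction that is merely compatible — e.g. resolvable inside
a polytomy — is neutral.  Exported annotation files carry one
"support/conflict" label per branch, keyed by a canonical node id (a short
hash of the sorted leaf ids), in the drag-and-drop text style interactive
tree viewers accept.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .trees import Tree, nontrivial_clusters

__all__ = [
    "SUPPORTS",
    "CONFLICTS",
    "NEUTRAL",
    "NodeAnnotation",
    "AnnotationTable",
    "node_status",
    "annotate_tree",
    "export_annotations",
    "read_branch_labels",
    "canonical_node_id",
]

SUPPORTS = "supports"
CONFLICTS = "conflicts"
NEUTRAL = "neutral"


def canonical_node_id(cluster: frozenset[str]) -> str:
    digest = hashlib.sha1(";".join(sorted(cluster)).encode("utf-8")).hexdigest()
    return digest[:12]


def node_status(
    cluster: frozenset[str],
    source: Tree,
    source_clusters: set[frozenset[str]] | None = None,
) -> str:
    """Status of one synthesis cluster against one source tree."""
    L = source.leaf_set
    restricted = cluster & L
    if len(restricted) <= 1 or restricted == L:
        return NEUTRAL
    if source_clusters is None:
        source_clusters = nontrivial_clusters(source)
    if restricted in source_clusters:
        return SUPPORTS
    for D in source_clusters:
        if restricted & D and restricted - D and D - restricted:
            return CONFLICTS
    return NEUTRAL


@dataclass
class NodeAnnotation:
    node_id: str
    cluster: frozenset[str]
    supporting: tuple[str, ...] = ()
    conflicting: tuple[str, ...] = ()

    @property
    def support_count(self) -> int:
        return len(self.supporting)

    @property
    def conflict_count(self) -> int:
        return len(self.conflicting)

    @property
    def informed(self) -> bool:
        return self.support_count + self.conflict_count >= 1

    @property
    def label(self) -> str:
        return f"{self.support_count}/{self.conflict_count}"


@dataclass
class AnnotationTable:
    rows: dict[str, NodeAnnotation] = field(default_factory=dict)
    n_sources: int = 0

    @property
    def informed_nodes(self) -> list[NodeAnnotation]:
        return [r for r in self.rows.values() if r.informed]

    def summary(self) -> dict[str, int]:
        """Partition of informed nodes by support vs conflict balance."""
        more_support = more_conflict = equal = 0
        for r in self.informed_nodes:
            if r.support_count > r.conflict_count:
                more_support += 1
            elif r.conflict_count > r.support_count:
                more_conflict += 1
            else:
                equal += 1
        return {
            "informed": more_support + more_conflict + equal,
            "more_support": more_support,
            "more_conflict": more_conflict,
            "equal": equal,
        }


def annotate_tree(
    synthesis: Tree, sources: Sequence[tuple[str, Tree]]
) -> AnnotationTable:
    """Evaluate node_status for every internal non-root node × source."""
    table = AnnotationTable(n_sources=len(sources))
    cached = [
        (sid, tree, nontrivial_clusters(tree)) for sid, tree in sources
    ]
    for node in synthesis.internal_nodes(include_root=False):
        cluster = synthesis.cluster_of(node)
        if len(cluster) < 2:
            continue
        supporting, conflicting = [], []
        for sid, tree, clus in cached:
            st = node_status(cluster, tree, clus)
            if st == SUPPORTS:
                supporting.append(sid)
            elif st == CONFLICTS:
                conflicting.append(sid)
        nid = canonical_node_id(cluster)
        table.rows[nid] = NodeAnnotation(
            node_id=nid,
            cluster=cluster,
            supporting=tuple(supporting),
            conflicting=tuple(conflicting),
        )
    return table


def export_annotations(
    table: AnnotationTable, tree: Tree, out_dir: str | Path
) -> dict[str, Path]:
    """Write branch-label TSV and a per-node JSON-lines dump; deterministic
    order (by sorted cluster)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree_ids = {
        canonical_node_id(tree.cluster_of(n))
        for n in tree.internal_nodes(include_root=False)
    }
    unknown = set(table.rows) - tree_ids
    if unknown:
        raise ValueError(f"annotation refers to nodes not in the tree: {sorted(unknown)[:3]}")
    ordered = sorted(table.rows.values(), key=lambda r: sorted(r.cluster))
    labels_path = out_dir / "branch_labels.txt"
    with open(labels_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["node_id", "support_conflict"])
        for r in ordered:
            w.writerow([r.node_id, r.label])
    jsonl_path = out_dir / "nodes.jsonl"
    with open(jsonl_path, "w", encoding="utf-8") as fh:
        for r in ordered:
            fh.write(
                json.dumps(
                    {
                        "node_id": r.node_id,
                        "support_count": r.support_count,
                        "conflict_count": r.conflict_count,
                        "supporting": list(r.supporting),
                        "conflicting": list(r.conflicting),
                    },
                    sort_keys=True,
                )
                + "\n"
            )
    return {"branch_labels": labels_path, "nodes": jsonl_path}


def read_branch_labels(path: str | Path) -> dict[str, tuple[int, int]]:
    """Round-trip reader for the branch-label file: node_id → (support, conflict)."""
    out: dict[str, tuple[int, int]] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # header
        for nid, label in reader:
            s, c = label.split("/")
            out[nid] = (int(s), int(c))
    return out
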