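"""Resolution, coverage, and monophyly reports over a synthesis tree.

Resolution counts bifurcating internal nodes against an expected count for a
fully resolved tree (by default n_tips − 1, the internal-node count of a
rooted binary tree; the expectation is an explicit parameter because
published figures sometimes use a different basis).  Coverage tabulates, per
taxon of a chosen rank, how many species carry phylogenetic and/or
geographic information.  Monophyly asks, for each named taxon with at least
two sampled members on the tree, whether those members form a clade; the
eligible leaf set defaults to species with actual phylogenetic data, since
taxonomy-placed leaves would trivially vote for their own hierarchy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

from .taxonomy import Taxonomy
from .trees import Tree, mrca

__all__ = [
    "ResolutionStats",
    "CoverageRow",
    "MonophylyRow",
    "resolution_stats",
    "coverage_by_rank",
    "assess_monophyly",
    "display_round",
    "percentage",
    "write_resolution_csv",
    "write_coverage_csv",
    "write_monophyly_csv",
]


def display_round(x: float, places: int = 1) -> float:
    """Round half away from zero to ``places`` decimals (display convention)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(part: int, whole: int) -> float:
    """100·part/whole, display-rounded to one decimal."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return display_round(100.0 * part / whole)


@dataclass(frozen=True)
class ResolutionStats:
    n_tips: int
    n_internal: int
    n_bifurcating: int
    expected_resolved: int

    @property
    def pct_unresolved(self) -> float:
        return display_round(100.0 * (1.0 - self.n_bifurcating / self.expected_resolved))

    @classmethod
    def from_counts(
        cls, n_bifurcating: int, expected_resolved: int, n_tips: int = 0, n_internal: int = 0
    ) -> "ResolutionStats":
        if expected_resolved < n_bifurcating:
            raise ValueError("expected_resolved below observed bifurcating count")
        return cls(n_tips, n_internal, n_bifurcating, expected_resolved)


def resolution_stats(tree: Tree, expected_resolved: int | None = None) -> ResolutionStats:
    internal = tree.internal_nodes(include_root=True)
    n_bif = sum(1 for n in internal if len(n.children) == 2)
    n_tips = tree.n_leaves
    if expected_resolved is None:
        expected_resolved = max(n_tips - 1, 1)
    if expected_resolved < n_bif:
        raise ValueError(
            f"expected_resolved ({expected_resolved}) below bifurcating count ({n_bif})"
        )
    return ResolutionStats(
        n_tips=n_tips,
        n_internal=len(internal),
        n_bifurcating=n_bif,
        expected_resolved=expected_resolved,
    )


@dataclass(frozen=True)
class CoverageRow:
    taxon_id: str
    name: str
    rank: str
    n_species_total: int
    n_with_phylo: int
    n_with_geo: int
    n_with_both: int

    @property
    def pct_phylo(self) -> float:
        return percentage(self.n_with_phylo, self.n_species_total)


def coverage_by_rank(
    taxonomy: Taxonomy,
    phylo_sampled: Iterable[str],
    geo_sampled: Iterable[str],
    rank: str,
) -> list[CoverageRow]:
    """One row per accepted taxon of ``rank``, counting its species with
    phylogenetic / geographic / both kinds of information."""
    phylo = frozenset(phylo_sampled)
    geo = frozenset(geo_sampled)
    rows = []
    for tid in taxonomy.accepted_ids(rank=rank):
        sp = taxonomy.species_under(tid)
        if not sp:
            continue
        rows.append(
            CoverageRow(
                taxon_id=tid,
                name=taxonomy.name_of(tid),
                rank=rank,
                n_species_total=len(sp),
                n_with_phylo=len(sp & phylo),
                n_with_geo=len(sp & geo),
                n_with_both=len(sp & phylo & geo),
            )
        )
    rows.sort(key=lambda r: r.name)
    return rows


@dataclass(frozen=True)
class MonophylyRow:
    taxon_id: str
    name: str
    n_species_sampled: int
    assessable: bool
    monophyletic: bool | None
    n_intruders: int


def assess_monophyly(
    tree: Tree,
    taxonomy: Taxonomy,
    rank: str,
    eligible: Iterable[str] | None = None,
) -> list[MonophylyRow]:
    """Monophyly of each taxon of ``rank`` with ≥2 eligible members on the
    tree; intruders are eligible non-member leaves under the members' MRCA.
    Taxa with fewer than two eligible members are reported not assessable."""
    leaves = tree.leaf_set
    elig = frozenset(eligible) if eligible is not None else leaves
    elig &= leaves
    rows = []
    for tid in taxonomy.accepted_ids(rank=rank):
        members_all = taxonomy.species_under(tid)
        members = members_all & elig
        if len(members) < 2:
            rows.append(
                MonophylyRow(
                    taxon_id=tid,
                    name=taxonomy.name_of(tid),
                    n_species_sampled=len(members),
                    assessable=False,
                    monophyletic=None,
                    n_intruders=0,
                )
            )
            continue
        node = mrca(tree, members)
        under = tree.cluster_of(node)
        intruders = (under & elig) - members_all
        rows.append(
            MonophylyRow(
                taxon_id=tid,
                name=taxonomy.name_of(tid),
                n_species_sampled=len(members),
                assessable=True,
                monophyletic=not intruders,
                n_intruders=len(intruders),
            )
        )
    rows.sort(key=lambda r: r.name)
    return rows


# -- CSV writers -----------------------------------------------------------


def write_resolution_csv(stats: ResolutionStats, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(
            ["n_tips", "n_internal", "n_bifurcating", "expected_resolved", "pct_unresolved"]
        )
        w.writerow(
            [
                stats.n_tips,
                stats.n_internal,
                stats.n_bifurcating,
                stats.expected_resolved,
                stats.pct_unresolved,
            ]
        )


def write_coverage_csv(rows: Sequence[CoverageRow], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(
            [
                "taxon_id",
                "name",
                "rank",
                "n_species_total",
                "n_with_phylo",
                "n_with_geo",
                "n_with_both",
                "pct_phylo",
            ]
        )
        for r in rows:
            w.writerow(
                [
                    r.taxon_id,
                    r.name,
                    r.rank,
                    r.n_species_total,
                    r.n_with_phylo,
                    r.n_with_geo,
                    r.n_with_both,
                    r.pct_phylo,
                ]
            )


def write_monophyly_csv(rows: Sequence[MonophylyRow], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(
            ["taxon_id", "name", "n_species_sampled", "assessable", "monophyletic", "n_intruders"]
        )
        for r in rows:
            w.writerow(
                [
                    r.taxon_id,
                    r.name,
                    r.n_species_sampled,
                    int(r.assessable),
                    "" if r.monophyletic is None else int(r.monophyletic),
                    r.n_intruders,
                ]
            )
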