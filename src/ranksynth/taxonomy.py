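"""Hierarchical reference taxonomy: storage, validation, and tip-name resolution.

The taxonomy is the lowest-priority source of groupings in a synthesis run and
the authority against which tip labels of input phylogenies are resolved.  It
is a single rooted hierarchy of accepted taxa over an ordered rank vocabulary
(subclass down to subspecies), plus flat synonym records pointing at accepted
targets.  Tips that can only be identified to genus level ("Chthamalus sp. A")
are kept, modelled as pseudo-species records parented at their genus.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import edlib

__all__ = [
    "RANK_ORDER",
    "TaxonRecord",
    "Taxonomy",
    "NameMatchResult",
    "TaxonomyError",
    "load_taxonomy",
    "read_taxonomy_tsv",
    "write_taxonomy_tsv",
    "validate_names",
    "write_name_report",
]

#: Rank vocabulary, coarse to fine.  Ordinals index this list.
RANK_ORDER: tuple[str, ...] = (
    "subclass",
    "infraclass",
    "superorder",
    "order",
    "suborder",
    "superfamily",
    "family",
    "subfamily",
    "genus",
    "species",
    "subspecies",
)

_RANK_ORDINAL = {r: i for i, r in enumerate(RANK_ORDER)}

ACCEPTED = "accepted"
SYNONYM = "synonym"

_GENUS_ONLY_RE = re.compile(r"^(\S+)\s+sp\.(?:\s+(\S.*))?$")


class TaxonomyError(ValueError):
    """Raised when a taxonomy table violates the hierarchy invariants."""


def rank_ordinal(rank: str) -> int:
    try:
        return _RANK_ORDINAL[rank]
    except KeyError:
        raise TaxonomyError(f"unknown rank string: {rank!r}") from None


@dataclass(frozen=True)
class TaxonRecord:
    """One row of the reference taxonomy.

    ``status`` is ``"accepted"`` or ``"synonym"``; synonyms carry the id of
    their accepted target in ``synonym_of`` and take no part in the hierarchy.
    ``pseudo`` marks genus-only pseudo-species registered at validation time.
    """

    taxon_id: str
    name: str
    rank: str
    parent_id: str | None = None
    status: str = ACCEPTED
    synonym_of: str | None = None
    pseudo: bool = False

    @property
    def is_accepted(self) -> bool:
        return self.status == ACCEPTED


@dataclass(frozen=True)
class NameMatchResult:
    """Outcome of resolving one tip label against the taxonomy."""

    query_label: str
    matched_id: str | None
    match_kind: str  # exact | synonym | normalized | fuzzy | genus_only | unmatched
    edit_distance: int = 0


def _normalize(name: str) -> str:
    return " ".join(name.split()).casefold()


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


class Taxonomy:
    """A validated rooted hierarchy of taxon records.

    Mutable only through :meth:`register_genus_tip`, which adds pseudo-species
    for genus-only tip labels; everything else is read-only queries.
    """

    def __init__(self, records: Iterable[TaxonRecord]):
        self._records: dict[str, TaxonRecord] = {}
        self._children: dict[str, list[str]] = {}
        self.root_id: str = ""
        for rec in records:
            self._add(rec)
        self._validate()

    # -- construction -----------------------------------------------------

    def _add(self, rec: TaxonRecord) -> None:
        if rec.taxon_id in self._records:
            raise TaxonomyError(f"duplicate taxon_id {rec.taxon_id!r}")
        rank_ordinal(rec.rank)  # reject unknown rank strings
        self._records[rec.taxon_id] = rec
        if rec.is_accepted and rec.parent_id is not None:
            self._children.setdefault(rec.parent_id, []).append(rec.taxon_id)

    def _validate(self) -> None:
        roots = [
            r.taxon_id
            for r in self._records.values()
            if r.is_accepted and r.parent_id is None
        ]
        if not roots:
            raise TaxonomyError("no root record (cycle detected or empty table)")
        if len(roots) > 1:
            raise TaxonomyError(f"multiple roots: {sorted(roots)}")
        self.root_id = roots[0]
        for rec in self._records.values():
            if rec.status == SYNONYM:
                tgt = rec.synonym_of
                if tgt is None or tgt not in self._records:
                    raise TaxonomyError(
                        f"synonym {rec.taxon_id!r} has dangling target {tgt!r}"
                    )
                if not self._records[tgt].is_accepted:
                    raise TaxonomyError(
                        f"synonym {rec.taxon_id!r} points to synonym {tgt!r}"
                    )
            elif rec.parent_id is not None:
                parent = self._records.get(rec.parent_id)
                if parent is None:
                    raise TaxonomyError(
                        f"dangling parent_id {rec.parent_id!r} of {rec.taxon_id!r}"
                    )
                if not parent.is_accepted:
                    raise TaxonomyError(
                        f"accepted record {rec.taxon_id!r} has synonym parent"
                    )
                if rank_ordinal(rec.rank) <= rank_ordinal(parent.rank):
                    raise TaxonomyError(
                        f"rank of {rec.taxon_id!r} ({rec.rank}) not finer than "
                        f"parent rank ({parent.rank})"
                    )
        # reachability from the root detects cycles / disconnected components
        seen: set[str] = set()
        stack = [self.root_id]
        while stack:
            tid = stack.pop()
            if tid in seen:
                raise TaxonomyError("cycle detected in parent links")
            seen.add(tid)
            stack.extend(self._children.get(tid, ()))
        accepted = {t for t, r in self._records.items() if r.is_accepted}
        if seen != accepted:
            missing = sorted(accepted - seen)[:5]
            raise TaxonomyError(f"cycle detected: unreachable records {missing}")
        self._rebuild_indexes()

    def _rebuild_indexes(self) -> None:
        self._name_to_accepted: dict[str, list[str]] = {}
        self._name_to_synonym: dict[str, list[str]] = {}
        self._norm_accepted: dict[str, list[str]] = {}
        self._norm_synonym: dict[str, list[str]] = {}
        for tid, rec in self._records.items():
            if rec.is_accepted:
                self._name_to_accepted.setdefault(rec.name, []).append(tid)
                self._norm_accepted.setdefault(_normalize(rec.name), []).append(tid)
            else:
                self._name_to_synonym.setdefault(rec.name, []).append(tid)
                self._norm_synonym.setdefault(_normalize(rec.name), []).append(tid)
        for idx in (
            self._name_to_accepted,
            self._name_to_synonym,
            self._norm_accepted,
            self._norm_synonym,
        ):
            for ids in idx.values():
                ids.sort()

    # -- basic queries -----------------------------------------------------

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._records

    def __len__(self) -> int:
        return len(self._records)

    def record(self, taxon_id: str) -> TaxonRecord:
        try:
            return self._records[taxon_id]
        except KeyError:
            raise TaxonomyError(f"unknown taxon_id {taxon_id!r}") from None

    def records(self) -> list[TaxonRecord]:
        return list(self._records.values())

    def children(self, taxon_id: str) -> list[str]:
        return list(self._children.get(taxon_id, ()))

    def name_of(self, taxon_id: str) -> str:
        return self.record(taxon_id).name

    def accepted_ids(self, rank: str | None = None) -> list[str]:
        rank_ordinal(rank) if rank is not None else None
        return sorted(
            t
            for t, r in self._records.items()
            if r.is_accepted and (rank is None or r.rank == rank)
        )

    def is_leaf_taxon(self, taxon_id: str) -> bool:
        """True for accepted species/subspecies (or pseudo-tips) with no
        accepted children — the units that become tree tips."""
        rec = self.record(taxon_id)
        return (
            rec.is_accepted
            and rec.rank in ("species", "subspecies")
            and not self._children.get(taxon_id)
        )

    def species_under(self, taxon_id: str) -> frozenset[str]:
        """All leaf taxa (species/subspecies/registered genus-only tips)
        descending from ``taxon_id``; a leaf taxon returns itself."""
        rec = self.record(taxon_id)
        if not rec.is_accepted:
            raise TaxonomyError(f"{taxon_id!r} is a synonym, not accepted")
        out: set[str] = set()
        stack = [taxon_id]
        while stack:
            tid = stack.pop()
            kids = self._children.get(tid)
            if kids:
                stack.extend(kids)
            elif self.is_leaf_taxon(tid):
                out.add(tid)
        return frozenset(out)

    def ancestors(self, taxon_id: str) -> list[str]:
        """Parent chain from the taxon's parent up to the root."""
        out = []
        rec = self.record(taxon_id)
        while rec.parent_id is not None:
            out.append(rec.parent_id)
            rec = self.record(rec.parent_id)
        return out

    # -- genus-only pseudo-tips -------------------------------------------

    def register_genus_tip(self, genus_id: str, label: str) -> str:
        """Register (or fetch) the pseudo-species for a genus-only label.

        The pseudo id is deterministic in (genus, normalized label) so that
        re-validation is idempotent.
        """
        rec = self.record(genus_id)
        if rec.rank != "genus" or not rec.is_accepted:
            raise TaxonomyError(f"{genus_id!r} is not an accepted genus")
        pid = f"{genus_id}!{_normalize(label)}"
        if pid in self._records:
            return pid
        tip = TaxonRecord(
            taxon_id=pid,
            name=label,
            rank="species",
            parent_id=genus_id,
            status=ACCEPTED,
            pseudo=True,
        )
        self._records[pid] = tip
        self._children.setdefault(genus_id, []).append(pid)
        self._name_to_accepted.setdefault(label, []).append(pid)
        self._norm_accepted.setdefault(_normalize(label), []).append(pid)
        return pid

    # -- restriction -------------------------------------------------------

    def restrict_to(self, root_taxon_id: str) -> "Taxonomy":
        """Sub-taxonomy rooted at ``root_taxon_id`` (the root-taxon setting of
        a synthesis run); keeps synonyms whose targets survive."""
        rec = self.record(root_taxon_id)
        if not rec.is_accepted:
            raise TaxonomyError("root taxon must be accepted")
        keep: set[str] = set()
        stack = [root_taxon_id]
        while stack:
            tid = stack.pop()
            keep.add(tid)
            stack.extend(self._children.get(tid, ()))
        recs = [
            replace(self._records[root_taxon_id], parent_id=None)
        ] + [self._records[t] for t in sorted(keep) if t != root_taxon_id]
        recs += [
            r
            for r in self._records.values()
            if r.status == SYNONYM and r.synonym_of in keep
        ]
        return Taxonomy(recs)

    # -- cluster / tree views ---------------------------------------------

    def clusters(self) -> list[tuple[str, frozenset[str]]]:
        """Taxonomy's contribution to synthesis: one (taxon_id, leaf set) per
        accepted internal taxon with ≥2 leaf descendants, largest first; ties
        broken coarse-rank-first then by name; the root's full set excluded."""
        rows = []
        for tid in self.accepted_ids():
            if tid == self.root_id or self.is_leaf_taxon(tid):
                continue
            sp = self.species_under(tid)
            if len(sp) >= 2:
                rec = self.record(tid)
                rows.append((tid, sp, rank_ordinal(rec.rank), rec.name))
        rows.sort(key=lambda r: (-len(r[1]), r[2], r[3]))
        return [(tid, sp) for tid, sp, _, _ in rows]

    def to_tree(self):
        """Taxonomy rendered as a tree over its leaf taxa, unary chains
        suppressed; leaf labels are taxon ids."""
        from .trees import Tree, TreeNode

        def grow(tid: str) -> TreeNode | None:
            if self.is_leaf_taxon(tid):
                return TreeNode(label=tid)
            kids = [grow(k) for k in self._children.get(tid, ())]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            node = TreeNode(label=None)
            for k in kids:
                node.add_child(k)
            return node

        root = grow(self.root_id)
        if root is None:
            raise TaxonomyError("taxonomy has zero species")
        return Tree(root)

    # -- name resolution ---------------------------------------------------

    def _fuzzy_candidates(self, genus_word: str, budget: int) -> list[tuple[str, str, bool]]:
        """Accepted species names grouped by genus-word agreement: exact
        genus-word matches are flagged True; names whose genus word is itself
        within ``budget`` edits are flagged False (fallback tier)."""
        out = []
        for name, ids in self._name_to_accepted.items():
            cand_genus = _normalize(name).split(" ", 1)[0]
            if cand_genus == genus_word:
                tier = True
            elif budget > 0 and _edit_distance(cand_genus, genus_word) <= budget:
                tier = False
            else:
                continue
            for tid in ids:
                rec = self._records[tid]
                if rec.rank in ("species", "subspecies") and not rec.pseudo:
                    out.append((name, tid, tier))
        return out

    def resolve_label(
        self,
        label: str,
        fuzzy_threshold: int = 2,
        allow_genus_tips: bool = True,
    ) -> NameMatchResult:
        """Resolve one label: exact → synonym → normalized → fuzzy →
        genus-only → unmatched.  Fuzzy matching requires a unique minimum
        edit distance ≤ threshold and an exactly matching genus word."""
        if fuzzy_threshold < 0:
            raise ValueError("fuzzy_threshold must be ≥ 0")
        ids = self._name_to_accepted.get(label)
        if ids:
            return NameMatchResult(label, ids[0], "exact", 0)
        ids = self._name_to_synonym.get(label)
        if ids:
            target = self._records[ids[0]].synonym_of
            return NameMatchResult(label, target, "synonym", 0)
        norm = _normalize(label)
        ids = self._norm_accepted.get(norm)
        if ids:
            return NameMatchResult(label, ids[0], "normalized", 0)
        ids = self._norm_synonym.get(norm)
        if ids:
            target = self._records[ids[0]].synonym_of
            return NameMatchResult(label, target, "normalized", 0)
        genus_word = norm.split(" ", 1)[0]
        if fuzzy_threshold > 0 and genus_word:
            # two tiers: names in the same genus word first; only if none is
            # within the budget do genus-word misspellings compete
            for tier in (True, False):
                best: list[str] = []
                best_d = fuzzy_threshold + 1
                for name, tid, t in self._fuzzy_candidates(genus_word, fuzzy_threshold):
                    if t is not tier:
                        continue
                    d = _edit_distance(norm, _normalize(name))
                    if d < best_d:
                        best_d, best = d, [tid]
                    elif d == best_d:
                        best.append(tid)
                if best_d <= fuzzy_threshold:
                    if len(best) == 1:
                        return NameMatchResult(label, best[0], "fuzzy", best_d)
                    break  # ambiguous within the preferred tier: never guess
        if allow_genus_tips:
            m = _GENUS_ONLY_RE.match(" ".join(label.split()))
            if m:
                gname = m.group(1)
                gids = [
                    t
                    for t in self._name_to_accepted.get(gname, ())
                    if self._records[t].rank == "genus"
                ]
                if gids:
                    pid = self.register_genus_tip(gids[0], " ".join(label.split()))
                    return NameMatchResult(label, pid, "genus_only", 0)
        return NameMatchResult(label, None, "unmatched", 0)


# -- module-level operations ----------------------------------------------


def load_taxonomy(
    rows: Iterable[dict | Sequence[str]],
) -> Taxonomy:
    """Build a validated Taxonomy from (id, parent_id, name, rank, status,
    synonym_target) rows; dict rows use those keys (uid/parent_uid/synonym_of
    aliases accepted)."""
    records = []
    for row in rows:
        if isinstance(row, dict):
            tid = str(row.get("id", row.get("uid", ""))).strip()
            parent = str(row.get("parent_id", row.get("parent_uid", "")) or "").strip()
            name = str(row["name"]).strip()
            rank = str(row["rank"]).strip()
            status = str(row.get("status", "") or ACCEPTED).strip() or ACCEPTED
            target = str(
                row.get("synonym_target", row.get("synonym_of", "")) or ""
            ).strip()
        else:
            tid, parent, name, rank, status, target = (
                list(str(x).strip() for x in row) + ["", ""]
            )[:6]
            status = status or ACCEPTED
        records.append(
            TaxonRecord(
                taxon_id=tid,
                name=name,
                rank=rank,
                parent_id=parent or None,
                status=SYNONYM if status.startswith("synonym") else ACCEPTED,
                synonym_of=target or None,
            )
        )
    if not records:
        raise TaxonomyError("empty taxonomy table")
    return Taxonomy(records)


_TSV_COLS = ["uid", "parent_uid", "name", "rank", "status", "synonym_of"]


def read_taxonomy_tsv(path: str | Path, ott_dialect: bool = False) -> Taxonomy:
    """Read a taxonomy table: tab-separated with a header row, or the
    OTT-style pipe-separated dialect (``uid | parent_uid | name | ...``)."""
    text = Path(path).read_text(encoding="utf-8")
    rows: list[dict] = []
    if ott_dialect:
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = [h.strip() for h in lines[0].split("|")]
        for ln in lines[1:]:
            vals = [v.strip() for v in ln.split("|")]
            rows.append(dict(zip(header, vals)))
    else:
        reader = csv.DictReader(io.StringIO(text), delimiter="\t")
        rows = list(reader)
    return load_taxonomy(rows)


def write_taxonomy_tsv(taxonomy: Taxonomy, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLS)
        for rec in sorted(taxonomy.records(), key=lambda r: r.taxon_id):
            if rec.pseudo:
                continue
            w.writerow(
                [
                    rec.taxon_id,
                    rec.parent_id or "",
                    rec.name,
                    rec.rank,
                    rec.status,
                    rec.synonym_of or "",
                ]
            )


def validate_names(
    labels: Sequence[str],
    taxonomy: Taxonomy,
    fuzzy_threshold: int = 2,
    allow_genus_tips: bool = True,
) -> list[NameMatchResult]:
    """Resolve each label against the taxonomy, in input order."""
    return [
        taxonomy.resolve_label(
            lab, fuzzy_threshold=fuzzy_threshold, allow_genus_tips=allow_genus_tips
        )
        for lab in labels
    ]


def write_name_report(results: Sequence[NameMatchResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["label", "matched_id", "match_kind", "edit_distance"])
        for r in results:
            w.writerow([r.query_label, r.matched_id or "", r.match_kind, r.edit_distance])
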