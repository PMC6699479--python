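"""Ranking of input studies for synthesis.

Studies are ordered by three criteria: (1) narrower taxonomic scope first;
(2) among studies aiming at the same focal taxon, more molecular markers
first (a morphological character set counts as one marker unit); (3) then
more genera, then more species.  Everything else keeps input order (the sort
is stable), and the taxonomy is always ranked last, so published phylogenies
win every conflict against it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

__all__ = [
    "StudyMetadata",
    "SCOPE_ORDER",
    "TAXONOMY_SOURCE_ID",
    "scope_ordinal",
    "rank_studies",
    "read_studies_tsv",
    "write_ranked_ids",
    "read_ranked_ids",
]

#: Scope vocabulary, narrowest first; ordinals start at 1.
SCOPE_ORDER: tuple[str, ...] = (
    "genus",
    "subfamily",
    "family",
    "superfamily",
    "suborder",
    "order",
    "superorder",
    "subclass",
)

#: Reserved source id for the taxonomy, appended after all studies.
TAXONOMY_SOURCE_ID = "taxonomy"


def scope_ordinal(scope_rank: str) -> int:
    """genus=1 … subclass=8; unknown scope strings are an error."""
    try:
        return SCOPE_ORDER.index(scope_rank) + 1
    except ValueError:
        raise ValueError(f"unknown scope rank {scope_rank!r}") from None


@dataclass(frozen=True)
class StudyMetadata:
    study_id: str
    focal_taxon_id: str
    scope_rank: str
    marker_count: int
    n_species: int
    n_genera: int

    def __post_init__(self):
        scope_ordinal(self.scope_rank)
        if self.marker_count < 1 or self.n_species < 1 or self.n_genera < 1:
            raise ValueError(f"study {self.study_id}: counts must be positive")
        if self.n_genera > self.n_species:
            raise ValueError(
                f"study {self.study_id}: n_genera exceeds n_species"
            )


def rank_studies(studies: Sequence[StudyMetadata]) -> list[str]:
    """Ordered study ids, taxonomy appended last.

    The marker/taxon tie-breaks apply only inside a (scope, focal taxon)
    group; groups of equal scope stay in input order, keyed by their first
    appearance.
    """
    ids = [s.study_id for s in studies]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})[0]
        raise ValueError(f"duplicate study_id {dup!r}")
    group_first: dict[tuple[int, str], int] = {}
    for idx, s in enumerate(studies):
        key = (scope_ordinal(s.scope_rank), s.focal_taxon_id)
        group_first.setdefault(key, idx)
    order = sorted(
        range(len(studies)),
        key=lambda i: (
            scope_ordinal(studies[i].scope_rank),
            group_first[(scope_ordinal(studies[i].scope_rank), studies[i].focal_taxon_id)],
            -studies[i].marker_count,
            -studies[i].n_genera,
            -studies[i].n_species,
            i,
        ),
    )
    return [studies[i].study_id for i in order] + [TAXONOMY_SOURCE_ID]


def read_studies_tsv(path: str | Path) -> list[StudyMetadata]:
    """Study metadata TSV: study_id, focal_taxon, scope, markers (semicolon
    separated, token ``morphology`` allowed and counted as one), n_species,
    n_genera."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            markers = [m.strip() for m in row["markers"].split(";") if m.strip()]
            out.append(
                StudyMetadata(
                    study_id=row["study_id"].strip(),
                    focal_taxon_id=row["focal_taxon"].strip(),
                    scope_rank=row["scope"].strip().lower(),
                    marker_count=len(markers),
                    n_species=int(row["n_species"]),
                    n_genera=int(row["n_genera"]),
                )
            )
    return out


def write_ranked_ids(ranked: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(ranked) + "\n", encoding="utf-8")


def read_ranked_ids(path: str | Path) -> list[str]:
    return [
        ln.strip()
        for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if ln.strip()
    ]
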