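"""Occurrence ingestion and geographic-vs-phylogenetic coverage reports.

Occurrence tables are Darwin-Core-like CSVs (scientificName,
decimalLatitude, decimalLongitude; column names matched case-insensitively).
Rows with unparseable or out-of-bounds coordinates are dropped and counted.
Names resolve through the same taxonomy machinery as tree tips, so records
filed under synonyms count toward their accepted species; genus-only labels
are left unresolved here (an occurrence cannot be tied to a particular
unidentified tip).  Reports: a per-order cross-tabulation of species with
geographic/phylogenetic/both/neither information, the "well-recorded but
unsequenced" table, and an equal-angle grid of record densities.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .taxonomy import Taxonomy

__all__ = [
    "OccurrenceRecord",
    "LoadedOccurrences",
    "GeoSummary",
    "load_occurrences",
    "resolve_occurrence_names",
    "species_with_geo",
    "coverage_crosstab",
    "top_georeferenced_unsampled",
    "grid_density",
]

_NAME_COLS = ("scientificname",)
_LAT_COLS = ("decimallatitude",)
_LON_COLS = ("decimallongitude",)


@dataclass(frozen=True)
class OccurrenceRecord:
    verbatim_name: str
    latitude: float
    longitude: float
    record_id: str
    resolved_id: str | None = None


@dataclass
class LoadedOccurrences:
    records: list[OccurrenceRecord]
    n_rejected: int

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _find_col(columns: Sequence[str], wanted: Sequence[str], what: str) -> str:
    lowered = {c.lower().strip(): c for c in columns}
    for w in wanted:
        if w in lowered:
            return lowered[w]
    raise ValueError(f"missing required column for {what} (looked for {wanted})")


def load_occurrences(source: str | Path | pd.DataFrame) -> LoadedOccurrences:
    """Read an occurrence CSV (or DataFrame); invalid-coordinate rows are
    dropped and counted in ``n_rejected``."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    name_c = _find_col(df.columns, _NAME_COLS, "scientific name")
    lat_c = _find_col(df.columns, _LAT_COLS, "decimal latitude")
    lon_c = _find_col(df.columns, _LON_COLS, "decimal longitude")
    records: list[OccurrenceRecord] = []
    rejected = 0
    triples = zip(df[name_c].tolist(), df[lat_c].tolist(), df[lon_c].tolist())
    for i, (name, lat_s, lon_s) in enumerate(triples):
        name = str(name).strip()
        try:
            lat = float(lat_s)
            lon = float(lon_s)
        except (TypeError, ValueError):
            rejected += 1
            continue
        if not (math.isfinite(lat) and math.isfinite(lon)):
            rejected += 1
            continue
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            rejected += 1
            continue
        records.append(
            OccurrenceRecord(
                verbatim_name=name, latitude=lat, longitude=lon, record_id=str(i)
            )
        )
    return LoadedOccurrences(records=records, n_rejected=rejected)


def resolve_occurrence_names(
    records: Iterable[OccurrenceRecord],
    taxonomy: Taxonomy,
    fuzzy_threshold: int = 2,
) -> list[OccurrenceRecord]:
    """Fill ``resolved_id`` via the taxonomy's label resolution (synonyms map
    to their accepted target); each distinct name is resolved once."""
    records = list(records)
    cache: dict[str, str | None] = {}
    out = []
    for rec in records:
        if rec.verbatim_name not in cache:
            res = taxonomy.resolve_label(
                rec.verbatim_name,
                fuzzy_threshold=fuzzy_threshold,
                allow_genus_tips=False,
            )
            cache[rec.verbatim_name] = res.matched_id
        out.append(replace(rec, resolved_id=cache[rec.verbatim_name]))
    return out


def species_with_geo(records: Iterable[OccurrenceRecord]) -> frozenset[str]:
    return frozenset(r.resolved_id for r in records if r.resolved_id is not None)


def per_species_counts(records: Iterable[OccurrenceRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in records:
        if r.resolved_id is not None:
            counts[r.resolved_id] = counts.get(r.resolved_id, 0) + 1
    return counts


def coverage_crosstab(
    taxonomy: Taxonomy,
    phylo_sampled: Iterable[str],
    records: Iterable[OccurrenceRecord],
    rank: str = "order",
) -> pd.DataFrame:
    """Per-taxon (of ``rank``) counts of species in the four exclusive
    categories both / phylo_only / geo_only / neither; rows sum to totals."""
    phylo = frozenset(phylo_sampled)
    geo = species_with_geo(records)
    rows = []
    for tid in taxonomy.accepted_ids(rank=rank):
        sp = taxonomy.species_under(tid)
        if not sp:
            continue
        both = len(sp & phylo & geo)
        p_only = len(sp & phylo) - both
        g_only = len(sp & geo) - both
        rows.append(
            {
                "taxon_id": tid,
                "name": taxonomy.name_of(tid),
                "n_species_total": len(sp),
                "both": both,
                "phylo_only": p_only,
                "geo_only": g_only,
                "neither": len(sp) - both - p_only - g_only,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "taxon_id",
            "name",
            "n_species_total",
            "both",
            "phylo_only",
            "geo_only",
            "neither",
        ],
    ).sort_values("name", ignore_index=True)


def top_georeferenced_unsampled(
    records: Iterable[OccurrenceRecord],
    phylo_sampled: Iterable[str],
    min_records: int = 30,
    taxonomy: Taxonomy | None = None,
) -> pd.DataFrame:
    """Species with strictly more than ``min_records`` occurrence records and
    no phylogenetic data, most-recorded first (ties by name)."""
    phylo = frozenset(phylo_sampled)
    counts = per_species_counts(records)
    rows = []
    for tid, n in counts.items():
        if n > min_records and tid not in phylo:
            name = taxonomy.name_of(tid) if taxonomy is not None else tid
            rows.append({"taxon_id": tid, "name": name, "n_records": n})
    df = pd.DataFrame(rows, columns=["taxon_id", "name", "n_records"])
    return df.sort_values(
        ["n_records", "name"], ascending=[False, True], ignore_index=True
    )


@dataclass
class GeoSummary:
    species_counts: dict[str, int]
    grid: dict[tuple[int, int], int]
    cell_degrees: float

    @property
    def n_resolved_records(self) -> int:
        return sum(self.species_counts.values())

    @property
    def n_gridded_records(self) -> int:
        return sum(self.grid.values())


def grid_density(
    records: Iterable[OccurrenceRecord], cell_degrees: float
) -> GeoSummary:
    """Bin records into an equal-angle grid: cell indices are
    floor((lat+90)/cell) and floor((lon+180)/cell); the topmost/rightmost
    boundary is closed so lat=90 / lon=180 land in the last cell."""
    if cell_degrees <= 0:
        raise ValueError("cell size must be positive")
    records = list(records)
    top_row = math.ceil(180.0 / cell_degrees) - 1
    top_col = math.ceil(360.0 / cell_degrees) - 1
    grid: dict[tuple[int, int], int] = {}
    for r in records:
        row = min(int(math.floor((r.latitude + 90.0) / cell_degrees)), top_row)
        col = min(int(math.floor((r.longitude + 180.0) / cell_degrees)), top_col)
        grid[(row, col)] = grid.get((row, col), 0) + 1
    return GeoSummary(
        species_counts=per_species_counts(records),
        grid=grid,
        cell_degrees=cell_degrees,
    )


def write_species_counts_csv(records, path, taxonomy: Taxonomy | None = None) -> None:
    counts = per_species_counts(records)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["taxon_id", "name", "n_records"])
        for tid in sorted(counts):
            name = taxonomy.name_of(tid) if taxonomy is not None else tid
            w.writerow([tid, name, counts[tid]])


def write_grid_csv(summary: GeoSummary, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["row", "col", "lat_low", "lon_low", "count"])
        for (row, col) in sorted(summary.grid):
            w.writerow(
                [
                    row,
                    col,
                    row * summary.cell_degrees - 90.0,
                    col * summary.cell_degrees - 180.0,
                    summary.grid[(row, col)],
                ]
            )
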