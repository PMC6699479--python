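"""End-to-end orchestration: validate → map → rank → synthesize → annotate →
report → geo, from a single YAML configuration, with a machine-readable
manifest and deterministic outputs (reruns on identical inputs are
byte-identical)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from . import annotation as ann
from . import geo as geomod
from . import reports as rep
from .ranking import (
    TAXONOMY_SOURCE_ID,
    rank_studies,
    read_studies_tsv,
    write_ranked_ids,
)
from .synthesis import (
    source_from_taxonomy,
    source_from_tree,
    synthesize,
    write_ledger_tsv,
)
from .taxonomy import Taxonomy, read_taxonomy_tsv, write_name_report
from .trees import map_tips, read_newick, write_newick

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("ranksynth")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"[{stage}] {cause}")


@dataclass
class PipelineConfig:
    taxonomy: str
    trees_dir: str
    studies: str
    out_dir: str
    occurrences: str | None = None
    root_taxon_id: str | None = None
    fuzzy_threshold: int = 2
    expected_resolved: int | None = None
    min_records: int = 30
    grid_cell_degrees: float = 5.0
    coverage_ranks: tuple[str, ...] = ("order", "family")
    monophyly_ranks: tuple[str, ...] = ("family", "genus")
    geo_enabled: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("coverage_ranks", "monophyly_ranks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage; outputs land under ``cfg.out_dir``.  Any stage error
    aborts with the stage name; files written so far are removed."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path, writer) -> None:
        writer(path)
        written.append(path)

    manifest: dict = {"config": asdict(cfg), "inputs": {}, "stages": {}}
    try:
        result = _run_stages(cfg, out, emit, manifest)
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:  # pragma: no cover - safety net
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError("internal", exc) from exc
    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return out


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kw):
            log.info("[%s] start", name)
            try:
                return fn(*args, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def _run_stages(cfg: PipelineConfig, out: Path, emit, manifest: dict):
    # ---- load inputs -----------------------------------------------------
    @_stage("load")
    def load():
        taxonomy = read_taxonomy_tsv(cfg.taxonomy)
        if cfg.root_taxon_id:
            taxonomy = taxonomy.restrict_to(cfg.root_taxon_id)
        studies = read_studies_tsv(cfg.studies)
        trees = {}
        for meta in studies:
            path = Path(cfg.trees_dir) / f"{meta.study_id}.nwk"
            if not path.exists():
                raise FileNotFoundError(f"missing tree file {path}")
            trees[meta.study_id] = read_newick(path)
            manifest["inputs"][str(path)] = _sha256(path)
        manifest["inputs"][str(Path(cfg.taxonomy))] = _sha256(Path(cfg.taxonomy))
        manifest["inputs"][str(Path(cfg.studies))] = _sha256(Path(cfg.studies))
        return taxonomy, studies, trees

    taxonomy, studies, trees = load()

    # ---- validate + map tips --------------------------------------------
    @_stage("map_tips")
    def do_map():
        mapped = {}
        all_matches = []
        n_pruned = 0
        for sid in sorted(trees):
            mtree, report = map_tips(
                trees[sid], taxonomy, fuzzy_threshold=cfg.fuzzy_threshold
            )
            mapped[sid] = mtree
            all_matches.extend(report.matches)
            n_pruned += report.n_pruned
        emit(out / "name_report.tsv", lambda p: write_name_report(all_matches, p))
        manifest["stages"]["map_tips"] = {
            "n_labels": len(all_matches),
            "n_pruned": n_pruned,
        }
        return mapped

    mapped = do_map()

    # ---- rank ------------------------------------------------------------
    @_stage("rank")
    def do_rank():
        ranked = rank_studies(studies)
        emit(out / "ranked_ids.txt", lambda p: write_ranked_ids(ranked, p))
        manifest["stages"]["rank"] = {"order": ranked}
        return ranked

    ranked = do_rank()

    # ---- synthesize ------------------------------------------------------
    @_stage("synthesize")
    def do_synth():
        sources = []
        for sid in ranked:
            if sid == TAXONOMY_SOURCE_ID:
                sources.append(source_from_taxonomy(taxonomy, TAXONOMY_SOURCE_ID))
            else:
                sources.append(source_from_tree(sid, mapped[sid]))
        universe = taxonomy.species_under(taxonomy.root_id)
        result = synthesize(sources, universe)
        display = result.tree.relabel(_display_map(taxonomy, result.tree.leaf_set))
        emit(
            out / "synthesis.nwk",
            lambda p: p.write_text(write_newick(display) + "\n", encoding="utf-8"),
        )
        emit(out / "ledger.tsv", lambda p: write_ledger_tsv(result, p))
        manifest["stages"]["synthesize"] = {
            "n_tips": result.tree.n_leaves,
            "accepted": sum(len(e["accepted"]) for e in result.ledger.values()),
            "rejected": sum(len(e["rejected"]) for e in result.ledger.values()),
        }
        return result

    synth = do_synth()

    # ---- annotate --------------------------------------------------------
    @_stage("annotate")
    def do_annotate():
        sources = [(sid, mapped[sid]) for sid in ranked if sid != TAXONOMY_SOURCE_ID]
        table = ann.annotate_tree(synth.tree, sources)
        files = ann.export_annotations(table, synth.tree, out / "annotations")
        for p in files.values():
            emit(p, lambda _: None)
        manifest["stages"]["annotate"] = table.summary()
        return table

    table = do_annotate()

    # ---- reports ---------------------------------------------------------
    @_stage("report")
    def do_report():
        phylo_sampled = frozenset().union(
            *(t.leaf_set for t in mapped.values())
        ) if mapped else frozenset()
        geo_sampled: frozenset[str] = frozenset()
        records = None
        if cfg.geo_enabled and cfg.occurrences and Path(cfg.occurrences).exists():
            # a missing occurrence file is the geo stage's error, not ours
            loaded = geomod.load_occurrences(cfg.occurrences)
            records = geomod.resolve_occurrence_names(
                loaded.records, taxonomy, fuzzy_threshold=cfg.fuzzy_threshold
            )
            geo_sampled = geomod.species_with_geo(records)
        stats = rep.resolution_stats(synth.tree, cfg.expected_resolved)
        rdir = out / "reports"
        rdir.mkdir(exist_ok=True)
        emit(rdir / "resolution.csv", lambda p: rep.write_resolution_csv(stats, p))
        for rank in cfg.coverage_ranks:
            rows = rep.coverage_by_rank(taxonomy, phylo_sampled, geo_sampled, rank)
            emit(
                rdir / f"coverage_{rank}.csv",
                lambda p, rows=rows: rep.write_coverage_csv(rows, p),
            )
        for rank in cfg.monophyly_ranks:
            rows = rep.assess_monophyly(
                synth.tree, taxonomy, rank, eligible=phylo_sampled
            )
            emit(
                rdir / f"monophyly_{rank}.csv",
                lambda p, rows=rows: rep.write_monophyly_csv(rows, p),
            )
        manifest["stages"]["report"] = {
            "n_tips": stats.n_tips,
            "n_bifurcating": stats.n_bifurcating,
            "pct_unresolved": stats.pct_unresolved,
            "n_phylo_sampled": len(phylo_sampled),
        }
        return phylo_sampled, records

    phylo_sampled, records = do_report()

    # ---- geo -------------------------------------------------------------
    if cfg.geo_enabled and cfg.occurrences:

        @_stage("geo")
        def do_geo():
            gdir = out / "geo"
            gdir.mkdir(exist_ok=True)
            loaded = geomod.load_occurrences(cfg.occurrences)
            manifest["inputs"][str(Path(cfg.occurrences))] = _sha256(
                Path(cfg.occurrences)
            )
            recs = geomod.resolve_occurrence_names(
                loaded.records, taxonomy, fuzzy_threshold=cfg.fuzzy_threshold
            )
            emit(
                gdir / "species_counts.csv",
                lambda p: geomod.write_species_counts_csv(recs, p, taxonomy),
            )
            crosstab = geomod.coverage_crosstab(taxonomy, phylo_sampled, recs)
            emit(
                gdir / "crosstab.csv",
                lambda p: crosstab.to_csv(p, index=False),
            )
            top = geomod.top_georeferenced_unsampled(
                recs, phylo_sampled, min_records=cfg.min_records, taxonomy=taxonomy
            )
            emit(gdir / "top_unsampled.csv", lambda p: top.to_csv(p, index=False))
            summary = geomod.grid_density(recs, cfg.grid_cell_degrees)
            emit(gdir / "grid.csv", lambda p: geomod.write_grid_csv(summary, p))
            manifest["stages"]["geo"] = {
                "n_records": len(loaded.records),
                "n_rejected": loaded.n_rejected,
                "n_species_with_geo": len(geomod.species_with_geo(recs)),
            }

        do_geo()
    elif cfg.geo_enabled and not cfg.occurrences:
        manifest["stages"]["geo"] = {"skipped": "no occurrence file configured"}

    return synth


def _display_map(taxonomy: Taxonomy, tids) -> dict[str, str]:
    """Leaf-id → scientific-name map; homonyms get the id appended so tree
    leaf labels stay unique."""
    names: dict[str, list[str]] = {}
    for tid in tids:
        names.setdefault(taxonomy.name_of(tid), []).append(tid)
    out = {}
    for name, ids in names.items():
        if len(ids) == 1:
            out[ids[0]] = name
        else:
            for tid in ids:
                out[tid] = f"{name} [{tid}]"
    return out
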