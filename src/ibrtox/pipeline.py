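"""Pipeline orchestration: overlap -> enrichment -> IBR, with a manifest.

A :class:`PipelineConfig` (usually loaded from YAML) names the inputs and
options; :func:`run_pipeline` executes the requested stages in order and
writes every output plus a ``manifest.json`` listing inputs, options and
the SHA-256 checksum of each output.  Re-running with identical config and
inputs reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import load_gmt, run_ora, write_enrichment_table
from .genesets import GeneSet, compare_sets, intersect, read_gene_list, write_overlap_table
from .ibr import (
    build_panel,
    compute_ibr,
    infer_directions,
    read_directions,
    read_replicate_table,
    write_scores_long,
)
from .plotting import radar_chart

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("ibrtox")

STAGES = ("overlap", "enrich", "ibr")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Paths are resolved relative to ``base_dir`` (the config file's
    directory when loaded from YAML).  ``query_list`` defaults to the
    intersection computed by the overlap stage; ``directions_file`` may be
    omitted when ``control_group`` is set, in which case directions are
    inferred from the panel means.
    """

    out_dir: Path
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    gene_list_a: Path | None = None
    gene_list_b: Path | None = None
    universe_size: int | None = None
    gmt: Path | None = None
    query_list: Path | None = None
    biomarker_table: Path | None = None
    directions_file: Path | None = None
    control_group: str | None = None
    sd_mode: str = "sample"
    min_scope: str = "per_biomarker"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        base = path.parent
        def p(key):
            return (base / raw[key]) if key in raw and raw[key] else None
        cfg = cls(
            out_dir=base / raw.get("out_dir", "results"),
            seed=int(raw.get("seed", 0)),
            stages=list(raw.get("stages", STAGES)),
            gene_list_a=p("gene_list_a"),
            gene_list_b=p("gene_list_b"),
            universe_size=raw.get("universe_size"),
            gmt=p("gmt"),
            query_list=p("query_list"),
            biomarker_table=p("biomarker_table"),
            directions_file=p("directions_file"),
            control_group=raw.get("control_group"),
            sd_mode=raw.get("sd_mode", "sample"),
            min_scope=raw.get("min_scope", "per_biomarker"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        """Check stage names, enumerations and referenced paths before running."""
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise PipelineError(f"config: unknown stages {unknown}; valid: {STAGES}")
        if self.sd_mode not in ("sample", "population"):
            raise PipelineError(f"config: sd_mode must be sample|population, got {self.sd_mode!r}")
        if self.min_scope not in ("per_biomarker", "global"):
            raise PipelineError(
                f"config: min_scope must be per_biomarker|global, got {self.min_scope!r}"
            )
        needed: list[tuple[str, Path | None]] = []
        if "overlap" in self.stages:
            needed += [("gene_list_a", self.gene_list_a), ("gene_list_b", self.gene_list_b)]
            if self.universe_size is None or self.universe_size < 1:
                raise PipelineError("config: overlap stage needs a positive universe_size")
        if "enrich" in self.stages:
            needed += [("gmt", self.gmt)]
            if "overlap" not in self.stages and self.query_list is None:
                raise PipelineError(
                    "config: enrich stage needs query_list when overlap stage is not run"
                )
        if "ibr" in self.stages:
            needed += [("biomarker_table", self.biomarker_table)]
            if self.directions_file is None and self.control_group is None:
                raise PipelineError(
                    "config: ibr stage needs directions_file or control_group"
                )
            if self.directions_file is not None:
                needed.append(("directions_file", self.directions_file))
        if self.query_list is not None:
            needed.append(("query_list", self.query_list))
        for name, pth in needed:
            if pth is None:
                raise PipelineError(f"config: {name} is required for the selected stages")
            if not Path(pth).exists():
                raise PipelineError(f"config: {name} path does not exist: {pth}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest.

    Stages run in the fixed order overlap -> enrich -> ibr.  Any stage
    failure raises :class:`PipelineError` naming the stage.  The manifest
    (also written to ``<out_dir>/manifest.json``) records inputs, options,
    seed and a SHA-256 checksum per output file.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    query: GeneSet | None = None

    if "overlap" in config.stages:
        try:
            log.info("[overlap] comparing %s vs %s", config.gene_list_a, config.gene_list_b)
            a = read_gene_list(config.gene_list_a)
            b = read_gene_list(config.gene_list_b)
            record = compare_sets(a, b, n_universe=int(config.universe_size))
            write_overlap_table([record], out / "overlap.tsv", out / "overlap.json")
            query = intersect(a, b)
            (out / "intersection.txt").write_text(
                "\n".join(sorted(query.symbols)) + "\n", encoding="utf-8"
            )
            outputs["overlap.tsv"] = out / "overlap.tsv"
            outputs["overlap.json"] = out / "overlap.json"
            outputs["intersection.txt"] = out / "intersection.txt"
            log.info("[overlap] |A|=%d |B|=%d both=%d p=%.3g",
                     len(a), len(b), record["both"], record["p_value"])
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'overlap' failed: {exc}") from exc

    if "enrich" in config.stages:
        try:
            annotation = load_gmt(config.gmt)
            if config.query_list is not None:
                query = read_gene_list(config.query_list)
            if query is None:
                raise ValueError("no query available (run overlap or set query_list)")
            log.info("[enrich] %d terms, query %s (%d genes)",
                     len(annotation), query.name, len(query))
            result = run_ora(query, annotation)
            write_enrichment_table(result, out / "enrichment.tsv")
            outputs["enrichment.tsv"] = out / "enrichment.tsv"
            log.info("[enrich] top term %s (q=%.3g), query coverage %.1f%%",
                     result.rows[0].term_id, result.rows[0].q_value,
                     100 * result.coverage)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'enrich' failed: {exc}") from exc

    if "ibr" in config.stages:
        try:
            table = read_replicate_table(config.biomarker_table)
            if config.directions_file is not None:
                directions = read_directions(config.directions_file)
            else:
                means = table.groupby(["group", "biomarker"])["value"].mean().unstack()
                directions = infer_directions(means, config.control_group)
            panel = build_panel(table, directions)
            ibr = compute_ibr(panel, sd_mode=config.sd_mode, min_scope=config.min_scope)
            write_scores_long(ibr, out / "ibr_scores.tsv")
            (out / "ibr_index.json").write_text(
                json.dumps(
                    {g: round(v, 10) for g, v in ibr.ibr_index.items()},
                    indent=2, sort_keys=True,
                )
                + "\n",
                encoding="utf-8",
            )
            radar_chart(ibr, out / "radar.svg")
            outputs["ibr_scores.tsv"] = out / "ibr_scores.tsv"
            outputs["ibr_index.json"] = out / "ibr_index.json"
            outputs["radar.svg"] = out / "radar.svg"
            log.info("[ibr] indices: %s",
                     {g: round(v, 3) for g, v in ibr.ibr_index.items()})
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'ibr' failed: {exc}") from exc

    manifest = {
        "tool": "ibrtox",
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "options": {"sd_mode": config.sd_mode, "min_scope": config.min_scope},
        "inputs": {
            k: str(v)
            for k, v in (
                ("gene_list_a", config.gene_list_a),
                ("gene_list_b", config.gene_list_b),
                ("gmt", config.gmt),
                ("query_list", config.query_list),
                ("biomarker_table", config.biomarker_table),
                ("directions_file", config.directions_file),
            )
            if v is not None
        },
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
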