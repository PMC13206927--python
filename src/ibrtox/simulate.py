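"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators, all pure functions of their spec (seed included):

* replicate-level biomarker panels for a control / toxicant / pretreated
  design, with per-biomarker response direction, multiplicative effect
  sizes and Gaussian replicate noise;
* gene universes with a planted exact overlap between two sets;
* GMT-style term annotations with planted enriched terms over a query.

Defaults mirror a cytotoxicity study contrasting a full-dose toxicant
group against a protective-pretreatment group over a biomarker battery
spanning mitochondrial apoptosis, mitochondrial metabolism, mitophagy and
general apoptosis, with n = 4 replicates per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import Term, TermAnnotation
from .genesets import GeneSet
from .ibr import Direction

__all__ = [
    "GroupSpec",
    "BiomarkerSpec",
    "PanelSpec",
    "OverlapSpec",
    "default_panel_spec",
    "generate_panel",
    "generate_overlap_sets",
    "generate_annotation",
    "write_gene_list",
    "write_gmt",
    "write_fixture_workspace",
    "DEFAULT_PLANTED_OVERLAP",
]

# default planted-term signal: overlap of the planted term with the query
DEFAULT_PLANTED_OVERLAP = 150


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group: label and effect multiplier (0 = untreated)."""

    label: str
    effect_multiplier: float = 1.0


@dataclass(frozen=True)
class BiomarkerSpec:
    """One biomarker: response direction, baseline level, effect magnitude."""

    label: str
    direction: Direction
    baseline: float = 1.0
    effect_size: float = 0.5  # relative effect (fraction of baseline) at multiplier 1

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass(frozen=True)
class PanelSpec:
    groups: tuple[GroupSpec, ...]
    biomarkers: tuple[BiomarkerSpec, ...]
    n_replicates: int = 4
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class OverlapSpec:
    n_universe: int
    n_a: int
    n_b: int
    k_overlap: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_overlap > min(self.n_a, self.n_b):
            raise ValueError("k_overlap cannot exceed min(n_a, n_b)")
        if self.n_a + self.n_b - self.k_overlap > self.n_universe:
            raise ValueError(
                "universe too small: n_a + n_b - k_overlap exceeds n_universe"
            )


# Biomarker battery emulating a mitochondrial-toxicity panel: apoptosis
# effectors rise on exposure, metabolic and mitophagy markers fall.
_DEFAULT_BIOMARKERS: tuple[BiomarkerSpec, ...] = (
    # mitochondrial apoptosis
    BiomarkerSpec("AIF", "up"),
    BiomarkerSpec("PARP1", "up"),
    # mitochondrial metabolism
    BiomarkerSpec("ROS", "up"),
    BiomarkerSpec("ATP", "down"),
    BiomarkerSpec("NAK_ATPASE", "down"),
    BiomarkerSpec("MMP", "down"),
    # mitophagy
    BiomarkerSpec("PINK1", "down"),
    BiomarkerSpec("PARKIN", "down"),
    BiomarkerSpec("LC3B", "down"),
    BiomarkerSpec("TOM20", "down"),
    # general apoptosis / neuronal identity
    BiomarkerSpec("TUNEL", "up"),
    BiomarkerSpec("TH", "down"),
)


def default_panel_spec(seed: int = 0) -> PanelSpec:
    """Study-shaped default: control, full-dose toxicant, pretreated+toxicant.

    The pretreated group sees a reduced effective dose (multiplier 0.6),
    so its expected IBR index falls between control and toxicant.
    """
    return PanelSpec(
        groups=(
            GroupSpec("control", 0.0),
            GroupSpec("toxicant", 1.0),
            GroupSpec("pretreated+toxicant", 0.6),
        ),
        biomarkers=_DEFAULT_BIOMARKERS,
        n_replicates=4,
        noise_sd=0.1,
        seed=seed,
    )


def generate_panel(spec: PanelSpec) -> tuple[pd.DataFrame, dict[str, Direction]]:
    """Simulate a replicate-level biomarker table.

    Each replicate value is ``baseline * (1 + sign * effect_size *
    group_multiplier) + N(0, noise_sd)`` with sign +1 for "up" biomarkers
    and -1 for "down".  Returns the long table (group, replicate,
    biomarker, value) and the true direction flags.  Deterministic for a
    given spec.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for g in spec.groups:
        for b in spec.biomarkers:
            sign = 1.0 if b.direction == "up" else -1.0
            mean = b.baseline * (1.0 + sign * b.effect_size * g.effect_multiplier)
            noise = rng.normal(0.0, spec.noise_sd, size=spec.n_replicates)
            for r in range(spec.n_replicates):
                rows.append(
                    {
                        "group": g.label,
                        "replicate": r + 1,
                        "biomarker": b.label,
                        "value": mean + noise[r],
                    }
                )
    directions = {b.label: b.direction for b in spec.biomarkers}
    return pd.DataFrame(rows), directions


def generate_overlap_sets(spec: OverlapSpec) -> tuple[GeneSet, GeneSet, GeneSet]:
    """Universe plus two sets with an exact planted overlap.

    Symbols are synthetic, zero-padded (``G000001`` ...) so lexicographic
    order equals numeric order.  Returns (universe, A, B) with
    ``|A ∩ B| == k_overlap`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    symbols = [f"G{i + 1:06d}" for i in range(spec.n_universe)]
    n_needed = spec.n_a + spec.n_b - spec.k_overlap
    picked = rng.choice(spec.n_universe, size=n_needed, replace=False)
    both = picked[: spec.k_overlap]
    a_only = picked[spec.k_overlap : spec.n_a]
    b_only = picked[spec.n_a :]
    universe = GeneSet("universe", frozenset(symbols))
    set_a = GeneSet("set_a", frozenset(symbols[i] for i in np.concatenate([both, a_only])))
    set_b = GeneSet("set_b", frozenset(symbols[i] for i in np.concatenate([both, b_only])))
    return universe, set_a, set_b


def generate_annotation(
    universe: GeneSet | None = None,
    n_terms: int = 1000,
    term_size_range: tuple[int, int] = (200, 800),
    planted_terms: list[tuple[str, int]] | None = None,
    query_size: int = 600,
    seed: int = 0,
    query: GeneSet | None = None,
) -> tuple[TermAnnotation, GeneSet]:
    """Term annotation with optional planted query enrichment.

    Background terms sample genes uniformly from the universe, so under
    the null their overlap with the query is exactly hypergeometric.  Each
    planted term ``(term_id, overlap)`` contains exactly ``overlap`` query
    genes, the rest drawn from outside the query; its size is sampled from
    ``term_size_range`` (clipped to be >= overlap).  Defaults describe a
    4000-gene universe with terms large enough that the discrete null
    p-value distribution is close to uniform.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    if universe is None:
        universe = GeneSet("universe", frozenset(f"G{i + 1:06d}" for i in range(4000)))
    lo, hi = term_size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError(f"bad term_size_range {term_size_range} for universe of {len(universe)}")
    uni_sorted = sorted(universe.symbols)
    if query is None:
        if not (1 <= query_size <= len(universe)):
            raise ValueError("query_size must be within the universe size")
        q_idx = rng.choice(len(uni_sorted), size=query_size, replace=False)
        query = GeneSet("query", frozenset(uni_sorted[i] for i in q_idx))
    elif not query.symbols <= universe.symbols:
        raise ValueError("explicit query must be a subset of the universe")
    q_sorted = sorted(query.symbols)
    bg_sorted = sorted(universe.symbols - query.symbols)

    terms: dict[str, Term] = {}
    for tid, overlap in planted_terms or []:
        if overlap > len(q_sorted):
            raise ValueError(f"planted overlap {overlap} exceeds query size {len(q_sorted)}")
        size = int(rng.integers(lo, hi + 1))
        size = max(size, overlap)
        n_bg = size - overlap
        if n_bg > len(bg_sorted):
            raise ValueError(f"planted term {tid!r} too large for the non-query pool")
        in_q = rng.choice(len(q_sorted), size=overlap, replace=False)
        out_q = rng.choice(len(bg_sorted), size=n_bg, replace=False)
        genes = frozenset(
            [q_sorted[i] for i in in_q] + [bg_sorted[i] for i in out_q]
        )
        terms[tid] = Term(tid, f"planted term (query overlap {overlap})", genes)
    width = len(str(n_terms))
    for j in range(n_terms):
        tid = f"BG{j + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(uni_sorted), size=size, replace=False)
        terms[tid] = Term(tid, "background term", frozenset(uni_sorted[i] for i in idx))
    return TermAnnotation(terms=terms, universe=universe), query


def write_gene_list(geneset: GeneSet, path: str | Path) -> None:
    """Write a gene set as a one-symbol-per-line list (sorted)."""
    Path(path).write_text("\n".join(sorted(geneset.symbols)) + "\n", encoding="utf-8")


def write_gmt(annotation: TermAnnotation, path: str | Path) -> None:
    """Write an annotation as GMT (term, description, genes...), sorted for determinism."""
    lines = []
    for tid in sorted(annotation.terms):
        t = annotation.terms[tid]
        lines.append("\t".join([t.term_id, t.description, *sorted(t.genes)]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_fixture_workspace(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Materialize a complete demo workspace the pipeline can run end to end.

    Writes gene lists with a planted 21-gene overlap (set sizes 164 and
    865 in a 2000-gene universe), a small GMT with two terms enriched in
    that overlap, a replicate biomarker table with directions, and a
    pipeline config.  Returns the mapping of logical names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    universe, set_a, set_b = generate_overlap_sets(
        OverlapSpec(n_universe=2000, n_a=164, n_b=865, k_overlap=21, seed=sub())
    )
    from .genesets import intersect

    query = intersect(set_a, set_b)
    annotation, _ = generate_annotation(
        universe=universe,
        n_terms=40,
        term_size_range=(20, 60),
        planted_terms=[("PLANTED_A", 10), ("PLANTED_B", 8)],
        seed=sub(),
        query=query,
    )
    table, directions = generate_panel(default_panel_spec(seed=sub()))

    paths = {
        "targets_a": out / "targets_toxicant.txt",
        "targets_b": out / "targets_disease.txt",
        "gmt": out / "annotation.gmt",
        "panel": out / "biomarkers.tsv",
        "directions": out / "directions.tsv",
        "config": out / "config.yaml",
    }
    write_gene_list(set_a, paths["targets_a"])
    write_gene_list(set_b, paths["targets_b"])
    write_gmt(annotation, paths["gmt"])
    table.to_csv(paths["panel"], sep="\t", index=False, float_format="%.10g")
    dir_lines = ["biomarker\tdirection"] + [
        f"{b}\t{d}" for b, d in directions.items()
    ]
    paths["directions"].write_text("\n".join(dir_lines) + "\n", encoding="utf-8")
    config = "\n".join(
        [
            f"gene_list_a: {paths['targets_a'].name}",
            f"gene_list_b: {paths['targets_b'].name}",
            "universe_size: 2000",
            f"gmt: {paths['gmt'].name}",
            f"biomarker_table: {paths['panel'].name}",
            f"directions_file: {paths['directions'].name}",
            "sd_mode: sample",
            "min_scope: per_biomarker",
            "out_dir: results",
            f"seed: {seed}",
            "stages: [overlap, enrich, ibr]",
            "",
        ]
    )
    paths["config"].write_text(config, encoding="utf-8")
    return paths
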