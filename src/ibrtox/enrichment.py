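"""Local over-representation analysis (ORA).

A self-contained replacement for web enrichment services: GMT-backed term
annotations, exact hypergeometric upper-tail p-values and Benjamini–Hochberg
FDR adjustment.  One-sided (enrichment only); no GO-graph propagation or
term-redundancy trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet, normalize_symbols

__all__ = [
    "Term",
    "TermAnnotation",
    "EnrichmentRow",
    "ORAResult",
    "GmtParseError",
    "load_gmt",
    "run_ora",
    "bh_adjust",
    "write_enrichment_table",
]


class GmtParseError(ValueError):
    """Raised for a malformed GMT line; message names the 1-based line number."""


@dataclass(frozen=True)
class Term:
    term_id: str
    description: str
    genes: frozenset[str]


@dataclass
class TermAnnotation:
    """A collection of gene-set terms over a shared universe.

    Every term's gene set is a subset of the universe; terms left with no
    genes after restriction are dropped.
    """

    terms: dict[str, Term]
    universe: GeneSet

    def __post_init__(self) -> None:
        restricted = {}
        for tid, term in self.terms.items():
            genes = term.genes & self.universe.symbols
            if genes:
                restricted[tid] = Term(term.term_id, term.description, frozenset(genes))
        self.terms = restricted

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's ORA result.

    k = |query ∩ term|, K = term size, n = query size within the universe,
    N = universe size; ``p_value`` is the exact hypergeometric upper tail
    P(X >= k), ``q_value`` its Benjamini–Hochberg adjustment across the
    annotation's terms.
    """

    term_id: str
    description: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float


@dataclass
class ORAResult:
    """ORA rows (sorted by ascending p, then term_id) plus query coverage.

    ``query_size_input`` counts the query genes supplied; ``query_size_used``
    those found in the universe.  Genes missing from the universe are dropped
    from the test but kept visible through this coverage pair.
    """

    rows: list[EnrichmentRow]
    query_size_input: int
    query_size_used: int

    @property
    def coverage(self) -> float:
        if self.query_size_input == 0:
            return 0.0
        return self.query_size_used / self.query_size_input

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def load_gmt(path: str | Path, universe: GeneSet | None = None) -> TermAnnotation:
    """Parse a GMT file (term<TAB>description<TAB>gene...).

    Gene symbols are normalized (uppercase/trim) and deduplicated within a
    term.  A line with fewer than three tab-separated fields raises
    :class:`GmtParseError` naming the line number.  Unless ``universe`` is
    given, the universe defaults to the union of all term genes.
    """
    path = Path(path)
    terms: dict[str, Term] = {}
    all_genes: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected at least 3 tab-separated "
                    f"fields (term, description, genes...), got {len(fields)}"
                )
            tid, desc = fields[0].strip(), fields[1].strip()
            genes = normalize_symbols(fields[2:], name=tid).symbols
            if not genes:
                continue
            terms[tid] = Term(tid, desc, genes)
            all_genes |= genes
    if universe is None:
        universe = GeneSet(name="gmt_union", symbols=frozenset(all_genes))
    return TermAnnotation(terms=terms, universe=universe)


def run_ora(query: GeneSet, annotation: TermAnnotation) -> ORAResult:
    """Hypergeometric over-representation of ``query`` in every term.

    The query is restricted to the annotation universe first; an empty
    restricted query raises ``ValueError`` (nothing is testable).  Rows are
    sorted by ascending p-value with ties broken by term_id, and q-values
    are Benjamini–Hochberg across all returned terms.
    """
    used = query.symbols & annotation.universe.symbols
    if not used:
        raise ValueError(
            f"query {query.name!r} shares no genes with the annotation universe"
        )
    n, N = len(used), len(annotation.universe)
    order = sorted(annotation.terms)
    ks = np.array([len(annotation.terms[t].genes & used) for t in order])
    Ks = np.array([len(annotation.terms[t].genes) for t in order])
    ps = np.clip(hypergeom.sf(ks - 1, N, Ks, n), 5e-324, 1.0)
    qs = bh_adjust(list(ps)) if order else []
    rows = [
        EnrichmentRow(
            term_id=t,
            description=annotation.terms[t].description,
            k=int(k),
            K=int(K),
            n=n,
            N=N,
            p_value=float(p),
            q_value=float(q),
        )
        for t, k, K, p, q in zip(order, ks, Ks, ps, qs)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return ORAResult(rows=rows, query_size_input=len(query), query_size_used=n)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Input order is preserved in the output.  Raises ``ValueError`` for any
    p outside (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def write_enrichment_table(result: ORAResult, path: str | Path) -> None:
    """Write ORA rows as TSV in the fixed column order."""
    cols = ["term_id", "description", "k", "K", "n", "N", "p_value", "q_value"]
    lines = ["\t".join(cols)]
    for r in result.rows:
        lines.append(
            "\t".join(
                [
                    r.term_id,
                    r.description,
                    str(r.k),
                    str(r.K),
                    str(r.n),
                    str(r.N),
                    format(r.p_value, ".6g"),
                    format(r.q_value, ".6g"),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
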