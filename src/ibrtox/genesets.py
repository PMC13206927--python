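"""Gene-symbol set handling.

Ingests plain-text gene lists (one symbol per line), normalizes symbols,
computes pairwise intersections and Venn partitions, and attaches a
hypergeometric upper-tail p-value to an observed overlap.  This is the
set logic behind compound-target vs. disease-gene comparisons in network
toxicology / network pharmacology workflows.

Normalization is deliberately minimal — uppercase and trim — because alias
or identifier mapping would require an external database.  The background
(universe) size for significance testing must always be supplied by the
caller; no genome-wide default is assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from scipy.stats import hypergeom

__all__ = [
    "GeneSet",
    "VennPartition",
    "OverlapTest",
    "normalize_symbols",
    "read_gene_list",
    "intersect",
    "venn_counts",
    "overlap_significance",
    "compare_sets",
    "write_overlap_table",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of normalized (uppercase, trimmed) gene symbols."""

    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        for s in self.symbols:
            if not s or s != s.strip() or s != s.upper():
                raise ValueError(f"unnormalized symbol in GeneSet {self.name!r}: {s!r}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.symbols))


@dataclass(frozen=True)
class VennPartition:
    """Counts of the three regions of a two-set Venn diagram."""

    only_a: int
    only_b: int
    both: int

    def __post_init__(self) -> None:
        if min(self.only_a, self.only_b, self.both) < 0:
            raise ValueError("Venn partition counts must be non-negative")

    @property
    def size_a(self) -> int:
        return self.only_a + self.both

    @property
    def size_b(self) -> int:
        return self.only_b + self.both


@dataclass(frozen=True)
class OverlapTest:
    """Hypergeometric upper-tail test of an observed set overlap.

    ``p_value`` is P(X >= k) where X is the overlap of a uniformly random
    size-``n_b`` draw from a universe of ``n_universe`` genes of which
    ``n_a`` belong to set A.  One-sided: only excess overlap is tested.
    """

    k: int
    n_a: int
    n_b: int
    n_universe: int
    p_value: float


def normalize_symbols(raw_lines: Iterable[str], name: str = "geneset") -> GeneSet:
    """Build a :class:`GeneSet` from raw text lines.

    Symbols are trimmed and uppercased; duplicates collapse; blank lines and
    lines starting with ``#`` are dropped.  Empty input yields an empty set.
    """
    symbols = set()
    for line in raw_lines:
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        symbols.add(token.upper())
    return GeneSet(name=name, symbols=frozenset(symbols))


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line UTF-8 gene list file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    return normalize_symbols(text.splitlines(), name=name or path.stem)


def intersect(a: GeneSet, b: GeneSet) -> GeneSet:
    """Shared symbols of two normalized sets (commutative)."""
    return GeneSet(name=f"{a.name}&{b.name}", symbols=a.symbols & b.symbols)


def venn_counts(a: GeneSet, b: GeneSet) -> VennPartition:
    """Two-set Venn partition counts."""
    both = len(a.symbols & b.symbols)
    return VennPartition(only_a=len(a) - both, only_b=len(b) - both, both=both)


def overlap_significance(k: int, n_a: int, n_b: int, n_universe: int) -> OverlapTest:
    """Upper-tail hypergeometric probability of an overlap of at least ``k``.

    Raises ``ValueError`` when the counts are not a feasible configuration
    (overlap larger than either set, or a set larger than the universe).
    """
    if k < 0:
        raise ValueError(f"overlap k={k} must be non-negative")
    if k > min(n_a, n_b):
        raise ValueError(f"overlap k={k} exceeds min(|A|, |B|) = {min(n_a, n_b)}")
    if max(n_a, n_b) > n_universe:
        raise ValueError(
            f"set sizes ({n_a}, {n_b}) cannot exceed universe size {n_universe}"
        )
    # sf(k-1) = P(X >= k); X ~ Hypergeom(N=n_universe, K=n_a, n=n_b)
    p = float(hypergeom.sf(k - 1, n_universe, n_a, n_b))
    p = min(max(p, 0.0), 1.0) or 5e-324  # clamp; keep p strictly positive
    return OverlapTest(k=k, n_a=n_a, n_b=n_b, n_universe=n_universe, p_value=p)


def compare_sets(a: GeneSet, b: GeneSet, n_universe: int) -> dict:
    """Venn partition plus overlap significance for two sets, as one record."""
    part = venn_counts(a, b)
    test = overlap_significance(part.both, len(a), len(b), n_universe)
    return {
        "set_a": a.name,
        "set_b": b.name,
        "only_a": part.only_a,
        "only_b": part.only_b,
        "both": part.both,
        "universe": n_universe,
        "p_value": test.p_value,
    }


def write_overlap_table(records: list[dict], tsv_path: str | Path,
                        json_path: str | Path | None = None) -> None:
    """Write overlap records as TSV and (optionally) a JSON mirror."""
    cols = ["set_a", "set_b", "only_a", "only_b", "both", "universe", "p_value"]
    lines = ["\t".join(cols)]
    for rec in records:
        lines.append("\t".join(_fmt(rec[c]) for c in cols))
    Path(tsv_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(records, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def _fmt(value) -> str:
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)
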