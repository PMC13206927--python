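"""Independent brute-force / closed-form oracles used by the test suite.

These deliberately avoid the library's own code paths: set enumeration via
itertools, explicit step-up FDR, plain-Python standardization and a
Cartesian shoelace polygon area.
"""

from __future__ import annotations

import itertools
import math
import statistics


def enumerate_overlap_pvalue(k: int, n_a: int, n_b: int, n_universe: int) -> float:
    """P(|A ∩ B| >= k) by enumerating every size-n_b subset of the universe.

    A is fixed to the first n_a elements; B ranges over all C(N, n_b)
    subsets, each equally likely.
    """
    universe = range(n_universe)
    a = set(range(n_a))
    hits = 0
    total = 0
    for b in itertools.combinations(universe, n_b):
        total += 1
        if len(a.intersection(b)) >= k:
            hits += 1
    return hits / total


def stepup_bh(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up, written directly from the definition.

    q_(i) = min over j >= i of p_(j) * m / j (sorted order), clipped at 1,
    then mapped back to the input order.
    """
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        q_sorted[rank - 1] = running
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = min(q_sorted[rank], 1.0)
    return q


def shoelace_star_area(radii: list[float]) -> float:
    """Area of the radar polygon via the Cartesian shoelace formula.

    Vertex i is at angle 2*pi*i/k, radius radii[i].
    """
    k = len(radii)
    pts = [
        (r * math.cos(2 * math.pi * i / k), r * math.sin(2 * math.pi * i / k))
        for i, r in enumerate(radii)
    ]
    acc = 0.0
    for i in range(k):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % k]
        acc += x1 * y2 - x2 * y1
    return abs(acc) / 2.0


def ibr_chain_oracle(
    X: list[list[float]], directions: list[str], sd_mode: str = "sample"
) -> list[float]:
    """Step-by-step IBR indices per group, spreadsheet style.

    Explicit per-biomarker mean/SD, sign flip for "down" markers, shift by
    the absolute per-biomarker minimum, then shoelace area per group.
    """
    n_groups, n_bio = len(X), len(X[0])
    Z = [[0.0] * n_bio for _ in range(n_groups)]
    for j in range(n_bio):
        col = [X[g][j] for g in range(n_groups)]
        m = statistics.fmean(col)
        if sd_mode == "sample":
            s = statistics.stdev(col)
        else:
            s = statistics.pstdev(col)
        for g in range(n_groups):
            y = (X[g][j] - m) / s if s > 0 else 0.0
            Z[g][j] = y if directions[j] == "up" else -y
    S = [[0.0] * n_bio for _ in range(n_groups)]
    for j in range(n_bio):
        shift = abs(min(Z[g][j] for g in range(n_groups)))
        for g in range(n_groups):
            S[g][j] = Z[g][j] + shift
    return [shoelace_star_area(S[g]) for g in range(n_groups)]
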