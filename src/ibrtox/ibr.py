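"""Integrated Biomarker Response (IBR) index.

The IBR condenses a battery of biomarker responses measured across
treatment groups into one dimensionless number per group, via:

1. standardization: Y = (X - m) / s per biomarker, where X is the group
   mean, m and s the overall mean and SD of that biomarker across groups;
2. direction alignment: Z = Y for biomarkers that rise upon treatment,
   Z = -Y for those that fall, so larger Z always means a larger response;
3. translation: S = Z + |min(Z)|, the minimum taken per biomarker across
   groups, giving non-negative radar radii with the least-responsive group
   pinned at zero;
4. area: the group's IBR index is the area of the star polygon whose i-th
   vertex sits at angle 2*pi*(i-1)/k and radius S_i, i.e. the sum of
   adjacent-spoke triangle areas S_i * S_{i+1} * sin(2*pi/k) / 2.

Higher IBR indicates a greater overall response (in toxicology, more
severe damage).  The index depends on the biomarker axis order; this is
surfaced explicitly through :func:`order_sensitivity` rather than hidden.

Also houses 2^-ddCt relative quantification, the usual preprocessing step
turning qPCR cycle thresholds into the fold changes that populate a panel.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BiomarkerPanel",
    "IBRResult",
    "ddct_fold_change",
    "build_panel",
    "panel_from_means",
    "standardize",
    "apply_direction",
    "translate_scores",
    "star_area",
    "compute_ibr",
    "order_sensitivity",
    "infer_directions",
    "read_replicate_table",
    "read_directions",
    "write_scores_long",
]

Direction = Literal["up", "down"]
SdMode = Literal["sample", "population"]
MinScope = Literal["per_biomarker", "global"]


@dataclass
class BiomarkerPanel:
    """Group-by-biomarker matrix of mean assay values with response directions.

    ``X[g, b]`` is the mean value of biomarker ``biomarkers[b]`` in group
    ``groups[g]`` (arbitrary assay units; each biomarker may use its own).
    ``directions[b]`` says whether the biomarker goes up or down upon
    treatment.  ``replicates``, when present, is the long-format source
    table (group, replicate, biomarker, value).
    """

    groups: list[str]
    biomarkers: list[str]
    directions: dict[str, Direction]
    X: np.ndarray
    replicates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if len(self.groups) < 2:
            raise ValueError("a panel needs at least 2 groups")
        if len(self.biomarkers) < 2:
            raise ValueError("a panel needs at least 2 biomarkers")
        if self.X.shape != (len(self.groups), len(self.biomarkers)):
            raise ValueError(
                f"X shape {self.X.shape} does not match "
                f"({len(self.groups)} groups, {len(self.biomarkers)} biomarkers)"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X must be finite everywhere")
        missing = [b for b in self.biomarkers if b not in self.directions]
        if missing:
            raise ValueError(f"missing direction flags for: {missing}")
        bad = {b: d for b, d in self.directions.items() if d not in ("up", "down")}
        if bad:
            raise ValueError(f"direction flags must be 'up' or 'down', got {bad}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarkers)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.groups, columns=self.biomarkers)


@dataclass
class IBRResult:
    """Full output of the IBR chain for one panel.

    ``Y``, ``Z``, ``S`` are group-by-biomarker DataFrames; ``m`` and ``s``
    per-biomarker overall means and SDs; ``star_coordinates`` maps each
    group to its ordered (angle, radius) vertices; ``ibr_index`` maps each
    group to its star area.
    """

    Y: pd.DataFrame
    Z: pd.DataFrame
    S: pd.DataFrame
    m: pd.Series
    s: pd.Series
    star_coordinates: dict[str, list[tuple[float, float]]]
    ibr_index: dict[str, float]
    sd_mode: SdMode = "sample"
    min_scope: MinScope = "per_biomarker"


def ddct_fold_change(
    ct_target_treated: float,
    ct_reference_treated: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_control;
    the fold change is 2**(-ddCt).  A fold change of 1 means no change
    relative to the control after reference-gene normalization.
    """
    cts = (ct_target_treated, ct_reference_treated, ct_target_control, ct_reference_control)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError(f"Ct values must be finite, got {cts}")
    ddct = (ct_target_treated - ct_reference_treated) - (
        ct_target_control - ct_reference_control
    )
    return float(2.0 ** (-ddct))


def build_panel(
    replicate_table: pd.DataFrame,
    directions: Mapping[str, Direction],
    group_order: Sequence[str] | None = None,
    biomarker_order: Sequence[str] | None = None,
) -> BiomarkerPanel:
    """Build a panel from a long replicate table (group, replicate, biomarker, value).

    Each group-by-biomarker cell becomes the arithmetic mean of its
    replicates; a cell with no replicates is an error naming the absent
    combinations.  Orders default to first appearance in the table.
    """
    required = {"group", "biomarker", "value"}
    if not required.issubset(replicate_table.columns):
        raise ValueError(
            f"replicate table needs columns {sorted(required)}, "
            f"got {list(replicate_table.columns)}"
        )
    groups = list(group_order) if group_order else list(
        dict.fromkeys(replicate_table["group"])
    )
    biomarkers = list(biomarker_order) if biomarker_order else list(
        dict.fromkeys(replicate_table["biomarker"])
    )
    means = replicate_table.groupby(["group", "biomarker"])["value"].mean()
    missing = [
        (g, b) for g in groups for b in biomarkers if (g, b) not in means.index
    ]
    if missing:
        raise ValueError(f"replicate table has no values for cells: {missing}")
    X = np.array([[means[(g, b)] for b in biomarkers] for g in groups])
    return BiomarkerPanel(
        groups=groups,
        biomarkers=biomarkers,
        directions={b: directions[b] for b in biomarkers},
        X=X,
        replicates=replicate_table,
    )


def panel_from_means(
    means: pd.DataFrame, directions: Mapping[str, Direction]
) -> BiomarkerPanel:
    """Build a panel from a group-by-biomarker matrix of means."""
    return BiomarkerPanel(
        groups=list(means.index),
        biomarkers=list(means.columns),
        directions=dict(directions),
        X=means.to_numpy(dtype=float),
    )


def standardize(
    panel: BiomarkerPanel, sd_mode: SdMode = "sample"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize each biomarker across groups: Y = (X - m) / s.

    ``m`` and ``s`` are computed over the panel's groups per biomarker.
    ``sd_mode`` selects the SD flavor: "sample" (ddof=1, default) or
    "population" (ddof=0).  A constant biomarker (s = 0) gets a Y column
    of zeros with a warning instead of failing.
    """
    if sd_mode not in ("sample", "population"):
        raise ValueError(f"sd_mode must be 'sample' or 'population', got {sd_mode!r}")
    ddof = 1 if sd_mode == "sample" else 0
    m = panel.X.mean(axis=0)
    s = panel.X.std(axis=0, ddof=ddof)
    Y = np.zeros_like(panel.X)
    for j, b in enumerate(panel.biomarkers):
        if s[j] == 0.0:
            warnings.warn(
                f"biomarker {b!r} is constant across groups; standardized "
                "scores set to 0",
                stacklevel=2,
            )
            continue
        Y[:, j] = (panel.X[:, j] - m[j]) / s[j]
    return Y, m, s


def apply_direction(
    Y: np.ndarray, directions: Sequence[Direction]
) -> np.ndarray:
    """Sign-align standardized scores: Z = Y for "up", Z = -Y for "down"."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape[1] != len(directions):
        raise ValueError("one direction flag per biomarker column is required")
    signs = []
    for d in directions:
        if d == "up":
            signs.append(1.0)
        elif d == "down":
            signs.append(-1.0)
        else:
            raise ValueError(f"unknown direction label {d!r}")
    return Y * np.asarray(signs)


def translate_scores(
    Z: np.ndarray, min_scope: MinScope = "per_biomarker"
) -> np.ndarray:
    """Translate to non-negative radar radii: S = Z + |min(Z)|.

    The minimum is taken per biomarker across groups (default) or over the
    whole matrix ("global").  The |.| is applied literally, so when
    min(Z) > 0 the shift still adds |min(Z)|; with centered Y and >= 2
    groups the per-biomarker min is always <= 0 and the minimizing group
    lands exactly at S = 0.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z must be finite")
    if min_scope == "per_biomarker":
        shift = np.abs(Z.min(axis=0))
    elif min_scope == "global":
        shift = np.abs(Z.min())
    else:
        raise ValueError(f"min_scope must be 'per_biomarker' or 'global', got {min_scope!r}")
    return Z + shift


def star_area(s_row: Sequence[float]) -> float:
    """Area of the radar (star) polygon for one group's ordered scores.

    With k >= 2 equally spaced axes, the polygon vertex for score S_i sits
    at angle 2*pi*(i-1)/k and radius S_i; the enclosed area is the sum of
    adjacent-spoke triangles, sum_i S_i * S_{i+1} * sin(2*pi/k) / 2 with
    wraparound S_{k+1} = S_1.
    """
    s = np.asarray(s_row, dtype=float)
    k = s.size
    if k < 2:
        raise ValueError("star area needs at least 2 biomarkers")
    return float(np.sum(s * np.roll(s, -1)) * math.sin(2.0 * math.pi / k) / 2.0)


def compute_ibr(
    panel: BiomarkerPanel,
    sd_mode: SdMode = "sample",
    min_scope: MinScope = "per_biomarker",
) -> IBRResult:
    """Run the full IBR chain on a panel.

    Chains standardization, direction alignment, translation and star area,
    and assembles the radar coordinates used for plotting.
    """
    Y, m, s = standardize(panel, sd_mode=sd_mode)
    Z = apply_direction(Y, [panel.directions[b] for b in panel.biomarkers])
    S = translate_scores(Z, min_scope=min_scope)
    k = panel.n_biomarkers
    angles = [2.0 * math.pi * i / k for i in range(k)]
    coords = {
        g: [(angles[j], float(S[i, j])) for j in range(k)]
        for i, g in enumerate(panel.groups)
    }
    index = {g: star_area(S[i, :]) for i, g in enumerate(panel.groups)}
    gi, bi = panel.groups, panel.biomarkers
    return IBRResult(
        Y=pd.DataFrame(Y, index=gi, columns=bi),
        Z=pd.DataFrame(Z, index=gi, columns=bi),
        S=pd.DataFrame(S, index=gi, columns=bi),
        m=pd.Series(m, index=bi),
        s=pd.Series(s, index=bi),
        star_coordinates=coords,
        ibr_index=index,
        sd_mode=sd_mode,
        min_scope=min_scope,
    )


def order_sensitivity(
    result: IBRResult, n_permutations: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Distribution of the IBR index over biomarker axis orderings.

    The index depends on which biomarkers are adjacent on the radar; this
    reports min/median/max per group over orderings — exhaustive for
    k <= 6 axes, otherwise ``n_permutations`` orderings sampled with the
    given seed (deterministic).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    S = result.S.to_numpy()
    k = S.shape[1]
    if k <= 6:
        orders = list(itertools.permutations(range(k)))
    else:
        rng = np.random.default_rng(seed)
        orders = [tuple(rng.permutation(k)) for _ in range(n_permutations)]
    rows = []
    for i, g in enumerate(result.S.index):
        vals = np.array([star_area(S[i, list(o)]) for o in orders])
        rows.append(
            {
                "group": g,
                "n_orderings": len(orders),
                "min": float(vals.min()),
                "median": float(np.median(vals)),
                "max": float(vals.max()),
                "observed": result.ibr_index[g],
            }
        )
    return pd.DataFrame(rows).set_index("group")


def infer_directions(
    panel_means: pd.DataFrame, control_group: str
) -> dict[str, Direction]:
    """Infer direction flags as sign(mean of treated groups - control mean).

    A biomarker whose treated mean is below the control mean is "down",
    otherwise "up" (ties count as "up").  The inference is logged so the
    caller can audit it.
    """
    if control_group not in panel_means.index:
        raise ValueError(f"control group {control_group!r} not in panel")
    treated = panel_means.drop(index=control_group).mean(axis=0)
    control = panel_means.loc[control_group]
    out: dict[str, Direction] = {}
    for b in panel_means.columns:
        out[b] = "down" if treated[b] < control[b] else "up"
        warnings.warn(
            f"auto direction for {b!r}: {out[b]} "
            f"(treated mean {treated[b]:.4g} vs control {control[b]:.4g})",
            stacklevel=2,
        )
    return out


def read_replicate_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format TSV with columns group, replicate, biomarker, value."""
    df = pd.read_csv(path, sep="\t", dtype={"group": str, "biomarker": str})
    return df


def read_directions(path: str | Path) -> dict[str, Direction]:
    """Read a two-column TSV (biomarker, up|down); a header row is optional."""
    out: dict[str, Direction] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"directions file line {lineno}: expected 2 columns")
        b, d = parts[0].strip(), parts[1].strip().lower()
        if (b, d) == ("biomarker", "direction"):
            continue
        if d not in ("up", "down"):
            raise ValueError(f"directions file line {lineno}: unknown direction {d!r}")
        out[b] = d  # type: ignore[assignment]
    return out


def write_scores_long(result: IBRResult, path: str | Path) -> None:
    """Write Y/Z/S in long format (group, biomarker, Y, Z, S) as TSV."""
    rows = []
    for g in result.Y.index:
        for b in result.Y.columns:
            rows.append(
                {
                    "group": g,
                    "biomarker": b,
                    "Y": result.Y.loc[g, b],
                    "Z": result.Z.loc[g, b],
                    "S": result.S.loc[g, b],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
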