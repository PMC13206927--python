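# Methods

## Scope and model

`ibrtox` implements three connected analyses used in network-toxicology /
network-pharmacology studies of a toxicant and a candidate protective
compound:

1. **Gene-set overlap.** Target and disease gene lists are plain text,
   one symbol per line. Normalization is uppercase-and-trim only; alias or
   identifier mapping is deliberately out of scope because it would
   require an external database, and silent alias expansion changes set
   sizes in ways the user cannot audit. Overlap significance is the exact
   hypergeometric upper tail `P(X ≥ k)` for drawing one set's size from a
   finite universe containing the other set. The universe size must be
   supplied by the caller: published studies of this kind routinely omit
   their background, and defaulting to a genome size would manufacture
   significance. The test is one-sided (excess overlap only), since the
   scientific question is whether the compound's targets concentrate in
   the disease gene set.

2. **Over-representation analysis (ORA).** A local, self-contained
   replacement for web enrichment services: GMT term collections, exact
   hypergeometric p-values, Benjamini–Hochberg q-values across all terms
   of one collection. The universe defaults to the union of all term
   genes unless overridden. Query genes absent from the universe are
   dropped from the test but surfaced as a coverage fraction, mirroring
   how enrichment services treat unmapped symbols without hiding the
   discrepancy. No GO-graph propagation, term-redundancy trimming or
   ranked-list (GSEA-style) statistics: those are different methods, not
   optional features of this one.

3. **Integrated biomarker response (IBR).** Per biomarker, group means
   are standardized across groups (`Y = (X − m)/s`), sign-aligned with the
   biomarker's known response direction (`Z = ±Y`), and translated by the
   absolute per-biomarker minimum (`S = Z + |min Z|`). Each group's index
   is the area of the radar polygon with radii `S` on equally spaced
   axes: `Σ S_i S_{i+1} sin(2π/k)/2`, which equals the shoelace area of
   the polygon vertices. Higher index = larger overall response.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `sd_mode` | `sample` (ddof=1) | SD flavor in standardization. The common choice in the IBR literature; it changes every value, so it is explicit and switchable to `population`. |
| `min_scope` | `per_biomarker` | Scope of `min(Z)` in the translation. Per-biomarker follows the original IBR construction (each axis gets its own baseline); a `global` option exists for sensitivity analysis. |
| direction flags | caller-supplied | One `up`/`down` per biomarker. An auto mode infers them from `sign(treated mean − control mean)` given a designated control group, and warns for each inference so it can be audited. |
| axis order | input order | The index depends on which biomarkers are adjacent. Rather than silently fixing an order, `order_sensitivity` reports min/median/max of the index over orderings (exhaustive for k ≤ 6, seeded sampling above). At k = 3 every ordering gives the same index; at k = 4 there are at most 3 distinct values (circular orders up to rotation/reflection). |
| universe size (overlap test) | none — required | See above; no genome-size default. |

Notable literal readings, chosen to follow the defining formula exactly:
`S = Z + |min(Z)|` adds `|min|` even if `min(Z) > 0`. With centered `Y`
and ≥ 2 groups the per-biomarker minimum is always ≤ 0, so in practice the
minimizing group lands at `S = 0`; the literal form only differs under the
non-default `global` scope.

Degenerate inputs: a biomarker constant across groups has `s = 0`; its
`Y` column is set to 0 with a warning instead of failing, so a panel with
one flat marker remains computable. Two-group panels are inherently
degenerate under sample SD: every non-constant biomarker standardizes to
`|Y| = √2/2`, so the index then reflects only directions, not magnitudes —
use three or more groups when magnitudes matter.

## qPCR preprocessing

`ddct_fold_change` converts cycle thresholds to relative expression by
the 2^−ΔΔCt method, with
ΔΔCt = (Ct_target − Ct_reference)_treated − (Ct_target − Ct_reference)_control.
Fold changes (dimensionless, control ≈ 1) are a natural unit for panel
biomarkers; the IBR chain is invariant to per-biomarker positive affine
rescaling anyway, so mixing assay units across biomarkers is safe.

## Synthetic data generator

The generator produces inputs with exactly the statistical structure the
analyses assume; all generators are pure functions of their spec
including the seed.

**Panels.** Replicate values are
`baseline · (1 + sign · δ · group_multiplier) + N(0, noise_sd)`, sign +1
for `up` biomarkers and −1 for `down`. The default design mirrors a
protective-pretreatment cytotoxicity study: groups `control`
(multiplier 0), `toxicant` (1.0) and `pretreated+toxicant` (0.6 —
pretreatment attenuates the effective insult), 12 biomarkers spanning
mitochondrial apoptosis (AIF, PARP1 up), mitochondrial metabolism (ROS
up; ATP, Na⁺/K⁺-ATPase, membrane potential down), mitophagy (PINK1,
Parkin, LC3B, TOM20 down) and general apoptosis / neuronal identity
(TUNEL up, TH down). Defaults: baseline 1.0 (fold-of-control units),
effect size δ = 0.5 (a 50% change at full dose — a typical
strongly-significant assay response), Gaussian replicate noise
sd = 0.1 (10% of baseline, consistent with tight mean ± SEM error bars at
n = 4), and n = 4 replicates per cell. Gaussian noise keeps closed-form
expectations; effects are multiplicative so directions and magnitudes
compose.

**Overlap sets.** Two sets with an exactly planted intersection inside a
synthetic universe (`G000001`, ... — zero-padded so lexicographic order is
numeric order, making deterministic tie-breaks easy to eyeball). The demo
workspace plants a 21-gene overlap between sets of 164 and 865 in a
2000-gene universe; note 164 + 865 − 21 = 1008 genes, so a universe of at
least that size is required.

**Annotations.** Background terms sample genes uniformly from the
universe, so under the null the query–term overlap is exactly
hypergeometric and the ORA p-values are calibrated by construction.
Defaults — universe 4000, query 600, term sizes 200–800 — were chosen so
the discrete null p-value distribution is close to uniform: with small
terms the hypergeometric tail is coarsely discrete and the realized
fraction of p < 0.05 falls well below its nominal level, which would make
null calibration untestable rather than wrong. Planted terms contain a
stated number of query genes exactly (default 150, ~2.5× the null
expectation for a 600-gene term), the rest drawn from outside the query.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: correlated biomarkers (real mitochondrial
markers co-vary strongly), non-Gaussian or heteroscedastic assay noise,
dose–response curve shapes, gene-symbol aliasing, and the dependency
structure of real GO/KEGG annotations (nested terms, hub genes). Results
on real studies additionally depend on choices the synthetic world fixes
by construction, above all the enrichment background.

## Numerical choices

- Hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, N, K, n)`;
  p-values clamped into `(0, 1]` (a tail of exactly 0 is rounded to the
  smallest positive double so downstream log-scale displays stay finite).
- BH adjustment delegates to `statsmodels` (`fdr_bh`); ORA rows are
  sorted by ascending p with ties broken lexicographically by term id,
  making output order deterministic.
- The star-area sum over adjacent spokes is used rather than a generic
  polygon routine; it equals the shoelace area for axes in angular order
  and is exact for k = 2 (zero area, the two axes being collinear).
- The radar SVG is byte-deterministic (fixed hash salt, no embedded
  timestamp) so pipeline output checksums reproduce across runs; the
  dashed zero-reference line marks, per axis, the radius where the
  direction-aligned score Z crosses 0.
- All pipeline randomness flows from one config seed; derived sub-seeds
  are drawn below 2³¹ via `numpy` seed sequences.

## Problem sizes used in the test suite

Oracle-equivalence checks run on ~60 random panels of 2–6 groups ×
2–8 biomarkers against a step-by-step plain-Python reimplementation
(tolerance 1e−10 relative). Exhaustive hypergeometric enumeration covers
universes up to N = 12. Statistical properties use 100 simulation seeds
(planted-term recovery, group-ordering recovery) or 3 × 1000 null terms
(type-I calibration); these sizes give the binomial success criteria
comfortable margins while keeping the default suite fast.

## Known limitations

- The IBR index is order-dependent for k ≥ 4; report `order_sensitivity`
  alongside the index, or fix a biologically motivated axis order and
  state it.
- No inferential statistics on IBR differences (no bootstrap CIs over
  replicates); the index is descriptive here, as it is in the literature
  that uses it.
- Two-group panels lose magnitude information (see above).
- ORA validity rests entirely on the chosen universe; with real
  annotations the default union-of-terms universe can differ materially
  from an experiment-specific background.
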