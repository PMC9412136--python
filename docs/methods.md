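# Methods

`karstdiv` analyses staged vegetation surveys — communities sampled at
several points along a successional or restoration gradient — and asks
how species diversity, the functional structure of the community, and
community stability move together. This note records the statistical
model, the choices that were genuinely open, and what the synthetic
studies do and do not demonstrate.

## The diversity decomposition

For a plot with `S` species, `N_i` individuals of species `i`
(`N = Σ N_i`), and relative densities `p_i`:

- **Species diversity** is the finite-sample Simpson index
  `SD = 1 − Σ N_i(N_i − 1) / [N(N − 1)]` — the probability that two
  individuals drawn *without replacement* belong to different species.
  It is computed from raw pooled counts and is undefined for `N < 2`.
- **Functional diversity** is Rao's quadratic entropy
  `FD = Σ_i Σ_j d_ij p_i p_j` — the expected trait dissimilarity of two
  randomly drawn individuals — computed from relative densities and a
  species dissimilarity matrix with `d_ij ∈ [0, 1]`.
- **Functional redundancy** is the difference `FR = SD − FD` (the
  de Bello decomposition): the share of species diversity carried by
  functionally similar species.

SD uses the count-based estimator while FD uses relative densities.
The two estimators are deliberately not harmonized: the decomposition
is kept exactly as conventionally printed. Because
`FD ≤ 1 − Σ p_i² ≤ SD` whenever `d_ij ≤ 1` and `p` is derived from the
same counts, `FR ≥ 0` holds analytically in that case; with per-layer
density weighting the two vectors can differ slightly, and the code
asserts only `FR ≥ −1e-9` on tested inputs.

**Stability** is the inverse coefficient of variation of the
per-species densities present in a plot, `STB = μ/σ` with σ the sample
(n − 1) standard deviation over species with density > 0. Structural
zeros from the study-wide species axis are excluded — including them
would make a plot's stability depend on which other plots were
surveyed. A plot with one species, or with all present densities
identical, returns an infinite-stability sentinel rather than raising.

## Trait distances

Six quantitative traits are used: plant height (PLH, m), leaf thickness
(LT, mm), chlorophyll content (CHL, SPAD), leaf dry matter content
(LDMC, g/g), leaf area (LA, cm²), and specific leaf area (SLA, cm²/g).
Each trait column is range-standardized to [0, 1] over the *whole*
species pool (not per stage), so distances are comparable across stages
and bounded. Two dissimilarities are offered:

- **Gower** (default): the mean absolute trait difference. This is the
  natural reading of a [0, 1]-bounded trait distance for purely
  quantitative traits.
- **Scaled Euclidean**: the Euclidean distance divided by `√T`, kept as
  a config switch because "Euclidean distance" is the other common
  convention; on standardized traits it also lies in [0, 1].

Neither is claimed to reproduce any particular published matrix: the
standardization underlying a bounded "Euclidean" distance is usually
left unstated in field studies, so both defensible readings ship.
Missing trait cells are a hard error — imputation would silently change
`d_ij`.

A consequence worth knowing: the mean pairwise distance of points in
the unit trait cube has a practical ceiling near 0.5 (attained by a
balanced two-cluster arrangement at opposite ends of every trait).
Rao's FD is therefore bounded by roughly half the Gini–Simpson index.
Published FD values above that ratio imply an unstandardized or
otherwise differently scaled distance; this package's values are
internally consistent but can sit lower than such published numbers.

## Data model and density normalization

Surveys use nested layer subplots of very different areas (four
subplots per layer; 10 × 10 m tree, 4 × 4 m shrub, 1 × 1 m herb).
Counts from different layers are therefore never compared directly:
per plot and layer, counts are summed over the layer's subplots and
divided by the layer's total sampled area, giving densities in
individuals/m²; a species recorded in two layers gets the sum of its
layer densities (documented behavior, never an error). Raw counts are
pooled across layers for the Simpson index. How field studies combine
layers into one per-plot vector is rarely stated; the per-layer-area
rule is the only internally consistent density and is this package's
documented choice.

## Stage-wise inference

- **Normality gate.** Shapiro–Wilk per stage; the one-way ANOVA
  proceeds only when every group passes at α = 0.05 (by default a
  failing gate logs a warning rather than aborting; `hard=True`
  raises). With 3 replicates per stage the test is nearly powerless —
  it is implemented as specified but should be read as a formality at
  that sample size.
- **ANOVA and letters.** One-way ANOVA across stages; pairwise
  comparisons by Tukey HSD (default) or Fisher LSD (config switch,
  since "multiple comparison tests" in SPSS-based workflows is
  ambiguous). The compact letter display uses the insert-and-absorb
  algorithm; letters are ordered from the highest group mean, and
  letter sharing exactly mirrors the pairwise non-significance relation
  at α = 0.05.
- **Correlations.** Pearson r with two-sided t-distribution p values,
  starred at p < .05 / .01 / .001. Plot-level trait values are the
  unweighted mean trait of the species present in the plot
  (abundance-weighted community means are deliberately out of scope).
  Per-stage correlations at n = 3 are reported but carry almost no
  inferential weight.
- **Stepwise regression.** Stability on functional diversity (x1) and
  functional redundancy (x2); forward entry at p < .05, backward
  removal at p > .10 (SPSS conventions). A candidate may enter only
  while a residual degree of freedom remains, and entry stops once the
  model fits perfectly, where partial tests are meaningless. Raw and
  standardized coefficients (`b·SD(x)/SD(y)`) are both reported because
  "biased/standardized partial regression coefficient" usage varies.
  With 3 plots per stage, a per-stage model can retain at most one
  predictor; the pooled 15-plot regression is reported alongside,
  clearly labeled.

## Saturation analysis

Functional diversity (`y1`) and functional redundancy (`y2`) are fitted
as polynomials in species diversity — quadratics by default, the
minimal family producing a rise-then-fall FD and two crossings; the
degree is configurable and R² is always reported since the fit family
behind published versions of this analysis is typically unstated.
Intersections come from polynomial root-finding (imaginary tolerance
1e-9, deduplication at 1e-6, so a tangency counts once). With exactly
two crossings `a` and `b` in [0, 1]:

- `b` is the **saturation point** of functional diversity;
- `c = (1, y2(1))` and `d = (1, y1(1))` are the curve values at maximal
  species diversity (an extrapolation beyond the observed SD range,
  always flagged as such);
- `S1 = ∫_a^b (y1 − y2) dx` is the net FD gain before saturation and
  `S2 = ∫_b^1 (y2 − y1) dx` the net FR gain after it, both computed
  exactly from the antiderivative of the difference polynomial. The
  regime labels are: FR rising faster below `a`, FD rising faster
  between `a` and `b`, FR rising faster above `b`.

A shoelace (polygon) area on the discretized curve boundary is kept as
an independent cross-check of the integral; the two agree to 1e-4 at
10⁴ boundary points. The region behind `S2` is bounded by the two
curves and the SD = 1 line; a straight-edged triangle on the vertices
`b`, `c`, `d` overestimates the curved region slightly (0.0368 vs
0.0325 for the planted geometry below), which is why the integral route
is primary. With zero or one crossing the result carries a
no-saturation diagnosis instead of points — never a crash.

### Planted saturation geometry

`synthetic_data.planted_saturation_curves()` builds the unique
quadratics through the canonical anchor coordinates a (0.35, 0.18),
b (0.77, 0.38), c (1, 0.66), d (1, 0.34) — a saturation configuration
with the crossings and endpoints at round, documented positions. The
recovery experiment samples n = 15 points over SD ∈ [0.3, 0.95] (the
realistic observed span), adds Gaussian noise of σ = 0.02 (the
residual scale at which quadratic fits retain R² ≳ 0.85), and pushes
them through fit → solve → integrate. Noiseless samples recover the
crossings to 1e-6 and the areas to 1e-8; at σ = 0.02 the recovered
saturation point stays within ±0.05 of truth in well over 90% of
seeds.

## The synthetic study generator

The generator emulates a five-stage recovery gradient (HE herbaceous →
HS herb–shrub → SH shrub → TS tree–shrub → TR tree), three replicate
plots per stage, nested layers, six traits. Its defaults are the study
conditions every downstream test runs under:

| stage | S  | sigma | dominance | kappa | layers            | N    |
|-------|----|-------|-----------|-------|-------------------|------|
| HE    | 8  | 0.60  | 0.77      | 0.60  | herb              | 500  |
| HS    | 14 | 0.50  | 0.48      | 0.70  | herb+shrub        | 700  |
| SH    | 18 | 0.40  | 0.34      | 0.34  | herb+shrub        | 900  |
| TS    | 28 | 0.30  | 0.16      | 0.31  | herb+shrub+tree   | 1200 |
| TR    | 40 | 0.45  | 0.00      | 0.42  | herb+shrub+tree   | 1500 |

- **Abundances.** Relative densities are a mixture of a planted
  dominant-species share (`dominance`) and a lognormal(0, `sigma`)
  tail, drawn on a common per-m² scale across layers; expected counts
  weight each species by its layer's sampled area, and N individuals
  are allocated multinomially (then multinomially again over the four
  subplots), keeping counts integral for the finite-sample Simpson
  formula. The explicit dominance term exists because a pure lognormal
  cannot be simultaneously dominated enough for a low Simpson index
  and complete enough for a low inverse-CV stability: extreme
  lognormal draws push rare species to zero sampled counts, which
  shrinks the present-species vector and floors the sample CV. A
  planted dominant over an even tail — the classic dominant-species
  structure of early succession — reaches both.
- **Traits.** Each stage has a trait centroid (plant height increasing
  along succession); species alternate between two clusters near the
  low and high ends of each trait range, and the convergence parameter
  `kappa` pulls species toward the centroid:
  `x = κ·centroid + (1 − κ)·cluster draw`. High κ collapses the stage
  onto its centroid (low FD); κ near 0 leaves a strongly bimodal
  spread (high FD). Trait ranges follow field instruments (PLH
  0.05–25 m, LT 0.05–2 mm, CHL 15–65 SPAD, LDMC 0.08–0.65 g/g, LA
  0.5–220 cm², SLA 40–520 cm²/g), so synthetic CSVs are drop-in
  replacements for real tables. Note that κ acts *relative to the
  study-wide pool*: standardization absorbs any within-stage-only
  shrinkage, so convergence is meaningful only next to less converged
  stages.
- **Planted trends.** Richness rises and evenness increases (dominance
  and sigma fall) along succession, so Simpson diversity and stability
  rise together; κ dips toward TS, making FD hump-shaped with its peak
  there, while FR = SD − FD rises monotonically. Stability is never
  planted directly — it emerges from the evenness schedule. Under the
  defaults the stage means are roughly SD 0.35 → 0.95, FD peaking near
  0.42 at TS, FR 0.25 → 0.59, STB 0.46 → 1.5, and the joint
  qualitative pattern (three monotone trends plus the FD peak) holds
  in about 90% of seeds.

What the generator does **not** emulate: spatial structure within
plots, temporal dynamics or species turnover between stages (stage
pools are disjoint), measurement error on traits, and the mid-gradient
window where FD exceeds FR. The last point follows from the FD ceiling
above: under range-standardized distances the stage-mean FD stays below
FR at every stage, so the full-pipeline saturation analysis on default
synthetic data may correctly report "no saturation" — the saturation
machinery is exercised and validated on the planted-quadratic geometry
instead. Passing tests on synthetic data therefore demonstrate the
estimators, inference and recovery machinery, not any claim about real
karst communities.

## Numerical choices

- Simpson requires integer counts and `N ≥ 2`; Rao requires `Σp = 1`
  within 1e-9 and a symmetric zero-diagonal distance matrix (checked to
  1e-12).
- Polynomial fits use least squares in the ordinary power basis;
  `R² = 1` is defined for the degenerate constant-data case where both
  residual and total sums of squares vanish.
- Curve intersections treat roots with |imaginary part| ≤ 1e-9 as real
  and merge roots within 1e-6; coincident polynomials raise a dedicated
  error since their crossings are not isolated.
- `net_area` refuses intervals containing an interior sign change
  (callers split at crossings); interior tangencies are integrated
  normally.
- All randomness flows through `numpy.random.default_rng` seeded from
  the study seed plus structural indices (stage, replicate), so equal
  specs produce byte-identical outputs.
- Problem sizes in tests and the acceptance script (15 plots; 100-200
  replicate studies for pattern rates; 500 seeds for recovery rates;
  n = 15 curve points) were chosen to estimate the reported rates
  stably at desk scale.

## Known limitations

- The per-stage regressions at 3 plots per stage are df-starved by
  design of the field layout; treat their rows as descriptive.
- The Godron-style stability variant sometimes cited alongside the
  inverse-CV statistic has no published closed form and is not
  implemented.
- Confidence bands on the saturation quantities (a, b, S1, S2) would
  require bootstrap resampling of plots; this is a documented extension,
  not implemented.
- Species identity is matched by exact string (after whitespace
  trimming); no taxonomic name resolution is attempted.
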