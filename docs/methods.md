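# Methods

`photoquad` implements the statistical core of a rapid biodiversity-assessment
protocol for photoquadrat surveys of sessile benthic communities (its design
case is Mediterranean coralligenous assemblages dominated by the gorgonian
*Paramuricea clavata* and the red coral *Corallium rubrum*). The input is
always a plot of contiguous photoquadrats scored for presence/absence of
macrobenthic taxa; the outputs are (i) a minimal sampling area per plot,
(ii) a sampling-effort recommendation, and (iii) multivariate tests of spatial
pattern across a region/site hierarchy. This note records the models, the
parameter choices, and the numerical decisions a maintainer would want spelled
out.

## Incidence data model

A plot is an ordered binary quadrat-by-taxon matrix with integer grid
coordinates and an explicit acquisition index. The acquisition order matters
because the spatially explicit species-area curve slides windows along it.
Survey teams rarely record the photographing path, so the reader treats an
`index` column as authoritative when present and otherwise assumes a
boustrophedon (serpentine) path over the grid — the path a diver naturally
swims. Taxon matching in rule tables is case-sensitive and exact; silent fuzzy
matching hides data errors.

Taxon rules mirror standard photo-identification practice: visually similar
taxa that cannot be told apart on photographs are pooled into one column
(logical OR), and markedly seasonal taxa are dropped so that sites photographed
in different months remain comparable. Rules never change the quadrat count
and never increase the taxon count.

## Species-area curves

Two accumulation curves are built per plot, both reporting mean and population
SD of union richness at every sample size `n`:

* **contiguous** — all `N − n + 1` runs of `n` consecutive quadrats in
  acquisition order. 1-D windows were chosen as the primary definition because
  they preserve within-plot spatial coherence for any plot shape and any
  photographing path; an all-rectangles 2-D window mode (`windows_2d=True`) is
  provided for sensitivity analysis. Both modes agree at `n = 1` and `n = N`.
* **randomized** — richness of the first `n` quadrats averaged over 999 random
  orderings (sample-based rarefaction). Its exact expectation is the
  hypergeometric closed form `E[S_n] = Σ_i (1 − C(N−f_i, n)/C(N, n))`,
  implemented in `rarefaction_expectation` and used as the independent check
  on the Monte-Carlo sampler.

In a patchy community the randomized curve dominates the contiguous one at
intermediate `n`: scattered quadrats cross patch boundaries and accumulate
species faster than one growing contiguous area. This ordering is a
statistical tendency, not a per-realisation guarantee, and is tested as such.

## Gleason fit and the Molinier minimal area

Mean richness is regressed on `ln(area)` (ordinary least squares;
`r²` as the goodness of fit). The fit includes the `n = 1` point by default —
there is no principled exclusion rule — with a `min_n` knob for sensitivity
checks. Two derived quantities:

* `k = exp(−b/a)` (cm²): the area where the fitted line crosses `S = 0`; the
  area scale of the curve. Larger `k` means more dispersed species and a
  larger required sample. `k` is undefined for flat or falling curves; those
  fits are flagged invalid rather than raised, so multi-plot reports keep
  going.
* the Molinier point `M dA/d'S`: the area at which increasing the area by
  `dA`% yields exactly a `d'S`% increase in species. Under the Gleason model
  with **finite relative increments** this area is `k · (1 + dA/100)^(100/d'S)`
  — a pure constant times `k`. For the conventional `M 20/5` criterion the
  multiplier is `1.2²⁰ = 38.34` (38.3 at 3 significant figures), so
  `A_min = 38.3 · k`. The derivative (infinitesimal) form of the criterion
  gives a different constant and does **not** reproduce published
  minimal-area tables; it is rejected.

Published tables round `k` to an integer and multiply by the 3-significant-
figure constant; `tabulated_minimal_area` reproduces that convention while
`minimal_area` keeps full precision. `A_min` is also reported in whole
quadrats (rounded up), which is how a survey is actually planned — e.g. 8
quadrats of 25 cm (a 50 × 100 cm block) for the gorgonian assemblage.

## Sampling effort

`effort_for_fraction` reads the smallest `n` whose mean randomized-curve
richness reaches a target fraction of the plot total.
`replicate_combinations_richness` evaluates union richness over combinations
of MSA-sized replicates — exhaustively when `C(m, r) ≤ 10 000`, otherwise as a
seeded random subset of that size (general inputs need the cap; the default
suits any realistic replicate count). Blocks are non-overlapping 2 × 4 quadrat
tiles in row-major order (50 × 100 cm from 25-cm quadrats, 40 × 80 cm from
20-cm quadrats); incomplete tiles are discarded so replicates stay
independent.

## Multivariate tests

Dissimilarity is the binary Bray-Curtis (= Sørensen) `1 − 2a/(2a + b + c)`,
identical to quantitative Bray-Curtis evaluated on 0/1 data (cross-checked in
the tests). Pairs of empty units are undefined and raise; the CLI drops empty
units with a warning before forming a matrix. Tables are reported on the
percentage scale (distances × 100), matching survey-literature convention.

NMDS is a thin wrapper over scikit-learn's nonmetric MDS (isotonic regression
with ties averaged), reporting Kruskal stress-1, best of 20 seeded random
restarts. An all-equal distance matrix carries no rank information — any
configuration fits — so it is flagged degenerate with stress 0.

PERMANOVA partitions squared dissimilarities:
`SS_total = Σ_{i<j} d²_ij / N`, within-group sums analogously per stratum.

* **One-way** (fixed factor): pseudo-F tested by unrestricted permutation of
  raw units. On a Euclidean distance matrix from univariate data the pseudo-F
  equals the classical ANOVA F exactly, which the tests assert to 1e-9.
* **Nested random** (Region; Site nested in Region):
  `F_Region = MS_Region / MS_Site(Region)` per the random-effects expected
  mean squares; `F_Site = MS_Site / MS_Residual`. df ledger:
  `(r − 1, Σ(s_r − 1), N − Σ s_r)`, always summing to `N − 1`.

Permutation schemes (the exchangeability reading of restricted permutation
under the reduced model): the **region** test permutes intact sites across
regions — under "no region effect" whole sites are the exchangeable units;
the **site** test permutes units freely within regions — under "no site
effect given region" units are exchangeable within their region. An
`unrestricted` mode (raw-unit shuffling for both tests) is available for
comparison. p-values use the bias-avoiding `(#{F* ≥ F} + 1)/(B + 1)`
estimator; with `α(B + 1)` an integer the one-way test is exact, and the
type-I error simulations in the test suite confirm the nominal 5% level.

Variance components come from the EMS ladder with Searle averaged
coefficients, exact for balanced designs (`c1 = c2 = n`, `c3 = n·s`) and the
standard `n0`-style averages otherwise. Negative components are reported raw
— truncation would bias the remaining components — and flagged by sign when
mapped to the dissimilarity scale (`vc_to_diss = sign(VC)·√|VC|`).

## Synthetic communities

The generator exists so every stage is testable without field data. Each
species gets an independent Gaussian random field on the quadrat lattice:
white noise smoothed with a Gaussian kernel of width `patchiness` (quadrat
units, torus boundary), renormalised to unit variance, and thresholded at the
normal quantile of the species' occupancy probability. Marginal occupancy is
therefore exact by construction; `patchiness = 0` degenerates to independent
Bernoulli occupancy — the exchangeable null under which contiguous and
randomized curves share one expectation. Gaussian fields were preferred over
cluster point processes because a single parameter controls patch size and
thresholding pins the marginals.

Occupancy probabilities are logit-normal (mean −1.5, SD 1.2 on the logit
scale: median occupancy ≈ 0.18, a long tail of rare species and a few common
ones). Default plot: 8 × 8 quadrats of 25 cm (64 quadrats, inside the 44–93
range of real plots), pool of 80 species, patchiness 2 — a full pipeline run
takes seconds. The hierarchy default is 3 regions × 3 sites × one plot,
with species turnover injected by making a fraction of the pool exclusive to
one region (`region_turnover = 0.6`) or one site (`site_turnover = 0.15`).

What the generator does *not* emulate: abundance structure, temporal
dynamics, environmental gradients, within-species interactions, and observer
error. Passing tests therefore demonstrate the statistical machinery under a
controlled patchy-occupancy model, not field realism.

Two regime notes, found while validating parameter recovery and worth keeping
in mind when designing simulations:

* the fitted `k` tracks simulated patchiness monotonically only while patches
  stay sub-plot-scale (correlation length ≲ 1.5 quadrats on an 8-row plot);
  beyond that, species become all-or-nothing across the plot, the curve
  flattens and the trend reverses. The recovery test uses the ladder
  {0, 0.75, 1.5}.
* with plot-scale patches the random field adds plot-level stochastic
  turnover that loads on the *site* variance component, so the hierarchy
  defaults are not region-dominant. The variance-hierarchy recovery test
  constructs an explicitly region-dominant scenario (region turnover 0.8,
  site turnover 0.05, patchiness 1.0).

## Numerical conventions and problem sizes

* SDs over combinations/permutations are population SDs (`ddof = 0`).
* Curve tolerance checks against the hypergeometric closed form use a
  `3·SE + 3/B` band: the rule-of-three term covers points where no
  permutation missed a rare species and the plug-in SE collapses to zero.
* Simulation-based tests use 10–20 replicates per scenario, 199–999
  permutations per test, and 1000 runs for the type-I calibration — sizes
  chosen so the whole suite runs in a few minutes on one core while keeping
  Monte-Carlo error well below the asserted margins.
* Display rounding mirrors survey-table convention (integer `k` and `A_min`,
  two decimals for VC and dissimilarity-scale values); CSV/JSON outputs keep
  full precision plus seeds, tool version and a config hash for byte-exact
  reproducibility.

## Known limitations

* The nested design supports two levels (region/site); deeper hierarchies are
  out of scope.
* Unbalanced variance-component multipliers are the averaged (`n0`-style)
  coefficients; exact unbalanced equivalence with proprietary survey software
  is asserted only for balanced designs.
* Presence/absence only — no abundance-based rarefaction, no richness
  extrapolation estimators (Chao, jackknife), no SIMPER/PERMDISP.
* The region test needs ≥ 2 sites per region; single-site regions raise with
  advice to pool.
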