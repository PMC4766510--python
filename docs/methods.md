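# Methods

`gamediv` re-implements, as a tested pipeline, an analysis that asks
whether a wildlife market prices species in line with their biological
importance: southern African game-auction prices (1991–2012) are related
to each species' contribution to the phylogenetic and functional
diversity of its assemblage (ungulates; large carnivores). This note
documents the models, the numerical choices, and what the synthetic data
do and do not establish.

## Diversity contributions

**Evolutionary distinctiveness (ED)** is the fair-proportion score: for
species *i*,

    ED_i = Σ_{e ∈ path(root → i)} L_e / n_e,

where `L_e` is the branch length and `n_e` the number of tip species
descending from branch `e`. Fair proportion partitions the tree exactly:
`Σ_i ED_i = T`, the total branch length. **Phylogenetic contribution
(PC)** is the terminal branch length — the diversity lost if species *i*
alone is removed. Since the terminal branch enters ED with weight 1,
`PC_i ≤ ED_i` always.

Both metrics are divided by `T` ("scaled") and reported as the deviation
from the equal-contribution share `1/S` ("deviation"), which makes
assemblages of different richness comparable. The deviation is an
arithmetic difference, not a ratio, so it is centred on zero. A branch
length attached to the root, if present in the Newick input, is recorded
but excluded from `T` and from every path: no species shares an edge
above the root, and excluding it keeps the conservation identity exact.
Polytomies need no special treatment (the `n_e` weighting is generic);
zero-length branches contribute zero; negative lengths are rejected.

**Functional analogues (FD, FC)** apply the identical algorithms to a
trait-based dendrogram instead of the phylogeny. The dendrogram is built
by: (1) standardizing numeric traits to mean 0, sample SD 1 (a stated
step of the procedure, retained even though Gower's range normalization
makes it a no-op on complete data — with missing values the range is
taken over the standardized non-missing entries); (2) Gower's distance,
which averages range-normalized absolute differences (numeric traits)
and mismatch indicators (categorical traits) over the traits observed in
*both* species — missing values are handled by this pairwise deletion,
and a pair sharing no observed trait is an error rather than a guess;
(3) agglomerative clustering, with the linkage chosen from
{single, complete, UPGMA, WPGMA} by the highest cophenetic correlation
(Pearson correlation between the input distances and the tree distances,
`2 ×` the height of the pair's lowest common ancestor). Node height is
half the merge distance, so cophenetic distances reproduce merge
distances; branch lengths are height differences, making the dendrogram
ultrametric by construction. Equal-distance merge candidates (within
1e-12) are resolved toward the lexicographically smallest sorted leaf-index
union, so the merge order is deterministic across platforms.

## Price preparation

Prices are positive reals in nominal currency (ZAR), at most one record
per species-year. When a record reports separate male and female prices,
the combined price is their unweighted arithmetic mean (sale volumes are
unknown); an explicitly reported combined price takes precedence.
Inflation adjustment uses December CPI index values:

    adjusted(s, y) = price(s, y) × CPI_Dec(ref) / CPI_Dec(y),

identical to chaining December-to-December annual inflation rates. The
reference year defaults to the last CPI year (2012 in the study design).
For trend analysis each species' series is standardized to zero mean and
unit *sample* (n−1) SD; species with fewer than `min_years = 3` records
(a quadratic needs three points) or zero variance are dropped and
reported, never silently discarded.

## The two mixed-model designs

**Design A (price level).** Adjusted price regressed on taxonomic group
(carnivore is the reference level), one contribution pair, and group ×
contribution interactions, with a random intercept per calendar year
shared across species — the most direct reading of "year of recorded
price grouped across species as a random effect". Contribution pairs are
(ED, FD) "overall" or (PC, FC) "unique", never mixed: within-pair
counterparts are strongly correlated (R² ≈ 0.8–0.97), and mixing them
would be collinear. The response is untransformed. A caveat this
re-implementation makes explicit: the design has no species-level
variance component, so the repeated records per species are treated as
exchangeable within years, and the coefficient t-tests become
anti-conservative whenever species baselines vary beyond what the
contributions explain. The synthetic study (log-normal baselines)
displays exactly this behaviour.

**Design B (price trend, ungulates only).** Standardized price regressed
on a raw polynomial in `t = year − first year` (order selected by
forward ML likelihood-ratio testing over orders 1→2→3 at α = 0.05), the
contribution pair, and contribution × time interactions for every
polynomial term, with a species random intercept and AR(1) residual
correlation `Corr(e_t, e_{t+k}) = φ^k` within species. Note that moving
from order k−1 to k adds three parameters (the new time power plus its
two contribution interactions), so each selection step is a df-3 test.
The influence of one contribution on the trend is judged by dropping its
interactions with all time powers (main effect retained), a df-2 LRT at
order 2.

**Estimation.** The fitter profiles the fixed effects and the residual
scale out of the Gaussian likelihood, leaving a Nelder-Mead search over
(log λ, atanh-scaled φ) with λ = σ²_b/σ²_e; group covariance matrices
are factorized once per distinct within-group time pattern, so balanced
panels cost one small Cholesky per likelihood evaluation. Wald t-tests
use REML estimates with denominator df = n − p (an asymptotic
approximation; exact small-sample df are not attempted). All LRTs
compare ML fits, refitting automatically when given REML fits, with the
statistic clamped at zero and df equal to the parameter-count
difference. φ is constrained to (−0.999, 0.999); boundary estimates are
recorded as warnings on the fit, not errors. SE(φ) comes from the
numerical Hessian of the profile likelihood with a delta-method
transform; when the variance-ratio direction is flat (λ on its zero
boundary) the conditional curvature in φ is used instead. Convergence
uses two starting points (a moment-based guess and the origin) with
tolerances 1e-7 (parameters) / 1e-9 (objective). Rank-deficient fixed
effects raise an error naming the aliased terms.

## Synthetic data

The generator produces everything the pipeline consumes, from one seed:

- **Tree**: pure-birth (Yule) topology, root splitting at time zero,
  exponential waiting times, rescaled to a fixed root-to-tip depth
  (default 25, arbitrary units) — exactly ultrametric.
- **Traits**: numeric traits by Brownian motion along the tree (variance
  proportional to branch length), categorical traits uniform on three
  levels, optional missingness that never leaves a species or a numeric
  column unusable.
- **CPI**: December index with annual inflation uniform on [3%, 9%]
  (the realistic range for the study's economy and period).
- **Prices**: `p(s,t) = exp(a_s) · max(0.05, 1 + A·[f(t)(1 + γ_p·devED_s
  + γ_f·devFD_s) + e_st])`, with log-normal species baselines
  (`a_s ~ N(9.2, 1)`, i.e. a median near 10 000 currency units spanning
  roughly two orders of magnitude across species), shared quadratic
  trend `f(t) = 0.15 t − 0.01 t²`, AR(1) errors with φ = 0.4, and
  relative amplitude `A = 0.2`. The amplitude factor is this package's
  own addition to keep price levels positive (at the default effect
  sizes `1 + f(21) < 0` would otherwise hit the floor); per-species
  standardization is exactly invariant to both `A` and `exp(a_s)`, so
  the trend model sees the same response regardless. The floor constant
  0.05 is a simulation artifact and documented as such. With
  `sigma_resid` unset, the AR(1) stationary variance is calibrated to
  `1 − Var_t(f)` so the within-species series has approximately unit
  variance and the standardized response carries the trend coefficients
  at their nominal scale.
- **Study scale**: an ungulate assemblage of 41 species (37 priced, full
  22-year series 1991–2012) and a carnivore assemblage of 13 species
  (6 priced, 8 record years each), with a fraction of records reported
  as separate sex prices whose mean equals the combined price.

A second, model-space generator (`simulate_trend_panel`) draws the
standardized response directly from design B (species random intercepts,
the quadratic trend, AR(1) errors). Parameter-recovery and type-I-error
studies use it, because it is the correctly specified twin of the model
being refitted. The full price-level path is deliberately *not* used for
φ-recovery claims: subtracting each species' 22-year sample mean during
standardization induces the classic downward bias in autocorrelation
estimates (order (1+3φ)/T ≈ 0.1 here), which is visible end-to-end as
φ̂ ≈ 0.3 against a generating 0.4. That attenuation is a property of the
published procedure itself, not of this implementation, and is the main
caveat when reading the fitted φ on real data.

What the synthetic data do not emulate: real auction microstructure
(volumes, reserve prices, colour morphs), trait covariance structure
beyond independent Brownian motions, non-ultrametric phylogenies, and
any true association between prices and contributions (the γ multipliers
default to zero). Passing tests therefore establish the correctness and
calibration of the machinery under the stated generative assumptions,
not any empirical claim about real markets.

## Problem sizes used in checks

Conservation is checked on 100 random trees of 10–100 tips (tolerance
1e-9 relative); brute-force oracle agreement on 50 random instances each
for fair proportion and UPGMA at up to 8 species; parameter recovery on
200 replicates of 37 species × 22 years at the default effect sizes
(each parameter within 2 SE in ≥ 90% of replicates); and type-I
calibration of the df-2 contribution LRT on 400 null replicates
(rejection rate within [0.025, 0.08] at α = 0.05). These sizes keep the
full suite in the minutes range while leaving the Monte-Carlo bands
meaningful.

## Known limitations

- Denominator df for t-tests are asymptotic (n − p); small-group designs
  would need Satterthwaite-type corrections this package does not
  implement.
- Design A inherits the published specification's lack of a species
  variance component (see above).
- The LRT reference distribution is the asymptotic χ²; boundary-adjacent
  variance parameters (λ → 0) are flagged but not mixture-corrected.
- Gower distances with heavy missingness can be non-Euclidean; the
  clustering methods used do not require Euclidean input, but cophenetic
  correlations may then understate fit quality.
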