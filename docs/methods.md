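# Methods

This note documents the statistical models implemented in `sargasso`, the
conventions and numerical choices behind them, and what the synthetic-data
generator does and does not emulate.

## Community distances

**Bray-Curtis** is computed on per-sample relative abundances,
`d_ij = Σ_k |y_ik − y_jk| / Σ_k (y_ik + y_jk)`.

**Weighted UniFrac** sums, over every branch *b* of the rooted phylogeny with
length `ℓ_b`, the absolute difference between the fractions `A_b`, `B_b` of
each sample's reads descending from that branch: `raw = Σ ℓ_b |A_b − B_b|`.
The default is the *normalized* variant, dividing by `Σ ℓ_b (A_b + B_b)` so
that distances lie in [0, 1]; this is what makes "similarity = 1 − d" in the
distance-decay analysis well defined. The raw variant is available by flag.
The implementation delegates to scikit-bio; the test suite verifies it
against an independent per-branch traversal to 1e−12 on random tree/table
fixtures.

**PCoA** eigendecomposes the Gower-centered matrix `−½·C·D²·C`. Negative
eigenvalues (non-Euclidean distances) are retained in the result with their
coordinates zeroed, so downstream code can both see and correct for them.

## Permutation tests

All tests permute whole samples, use a seeded generator, and report
`p = (#{stat_perm ≥ stat_obs} + 1)/(n_perm + 1)` (999 permutations by
default), so the smallest attainable p is 1/(n_perm+1).

* **PERMANOVA**: `SS_total = (1/N) Σ_{i<j} d²`, `SS_within` pools per-group
  sums scaled by group size, `pseudo-F = (SS_among/(a−1)) / (SS_within/(N−a))`.
  Pairwise tests restrict to each group pair and report unadjusted p
  (a Bonferroni column is optional).
* **PERMDISP**: samples are embedded by PCoA keeping negative-eigenvalue axes
  as imaginary coordinates; the distance of sample *i* to its group center is
  `z_i = sqrt(max(0, Σ_real (y−c)² − Σ_imag (y−c)²))`; a one-way ANOVA F on z
  is calibrated by permuting z across groups. The center is the coordinate
  centroid by default; a spatial-median (Weiszfeld) alternative is exposed.
* **ANOSIM**: `R = (mean between-group rank − mean within-group rank)/(M/2)`
  on the ranked condensed distances.
* **Mantel**: Pearson r over lower-triangle entries, permuting the row/column
  order of one matrix (two-sided). Joint row/column permutation only re-pairs
  the same multiset of entries, which is what makes the vectorised
  gather-based permutation scheme exact.

Calibration: the acceptance suite verifies that PERMANOVA, Mantel and db-RDA
reject at a rate inside [0.03, 0.07] at α = 0.05 over 1,000 null replicates
each.

## Distance decay

Community similarity `1 − d` is regressed on great-circle distance over
*ordered* sample pairs — both (i, j) and (j, i) — giving `n = N(N−1)` points
and residual df `N(N−1) − 2`. This convention doubles each observation and
therefore overstates the effective sample size (a pseudo-replication caveat
the user should keep in mind when reading the F test); it is retained because
it is the convention under which published F degrees of freedom of the form
F(1, N(N−1)−2) arise. An unordered-pairs mode is available.

## Spatial eigenfunctions (PCNM)

Geographic distances are haversine great-circle distances with the IUGG mean
Earth radius 6371.0088 km; with samples spanning ~15° of latitude a planar
approximation would distort long-transect distances. Depth is *not* folded
into the spatial distance: space is horizontal, and sampling depth enters the
analysis as an environmental covariate.

The PCNM basis truncates the distance matrix at *t*, the longest edge of its
minimum spanning tree (the smallest threshold keeping the neighbour graph
connected), replaces larger distances by `4t` (the replacement factor is a
parameter), Gower-centers, and keeps unit-norm eigenvectors with eigenvalue
`> 1e−9 · λ_max`. Eigenfunctions are mutually orthonormal and mean-zero.

## Partial db-RDA and variation partitioning

db-RDA uses the positive-eigenvalue PCoA axes of the community distance
matrix as a multivariate response. Predictors are standardized internally;
response and predictors are residualized on [intercept, conditioning
variables]; the constrained inertia is the sum of squared fitted values of
the least-squares fit on the residualized predictors. Significance uses
reduced-model permutation (rows of the residualized response are permuted).
`adj R² = 1 − (1 − R²)(n − 1 − q)/(n − 1 − q − m)` (Ezekiel, with *q*
conditioning df and *m* the predictor rank after conditioning). Negative
PCoA inertia is dropped before regression (logged at debug level) rather than
square-root-corrected; normalized UniFrac matrices rarely carry substantial
negative inertia.

**Forward selection** greedily adds the candidate with the largest adjusted-R²
gain and applies a double stopping rule: a candidate whose marginal
permutation p (tested partialling out everything already selected, plus any
conditioning set) exceeds α = 0.05 is rejected and selection ends; selection
also ends once the accepted model's adjusted R² reaches the global
(all-candidate) adjusted R² ceiling. The crossing step is *accepted before
stopping*: the ceiling marks the point where further explained variance is
indistinguishable from what the full candidate set would claim, not evidence
against the variable that reached it.

**Variation partitioning** fits the three unconditioned models E, S, E∪S and
takes, in adjusted-R² units: `a = adj(E∪S) − adj(S)` (pure environment),
`c = adj(E∪S) − adj(E)` (pure space), `b = adj(E) + adj(S) − adj(E∪S)`
(shared), `d = 1 − adj(E∪S)` (residual); a + b + c + d = 1 by construction.
When environment and space are collinear (e.g. a temperature gradient aligned
with the transect) b can go negative; **proportional apportioning** then
reallocates the combined adjusted R² to the pure fractions in their raw
ratio: `a′ = adj(E∪S)·a/(a+c)`, `c′ = adj(E∪S)·c/(a+c)`, `b′ = 0`. This is
the unique correction that zeroes the shared fraction while preserving both
the a:c ratio and the combined total. It is applied only when `b < 0` and is
undefined (error) when `a + c ≤ 0`.

## Sloan neutral community model

For a local community of N individuals receiving immigrants from a source
pool at probability m per death, the stationary local relative abundance of a
taxon with source abundance p is Beta(Nmp, Nm(1−p)). The probability of
observing the taxon — abundance above a detection limit d — is

    F(p) = 1 − I_d(Nmp, Nm(1−p)),

with I the regularized incomplete beta function. The fit takes per-taxon
(mean relative abundance, occurrence frequency) pairs from a rarefied table
(N = the common post-rarefaction depth), and finds m by bounded scalar
minimization of the squared frequency residuals over (1e−6, 1], tolerance
1e−8. `R² = 1 − SSE/SST` on untransformed frequencies (it can be negative
when the neutral curve fits worse than a constant). Both m and Nm = m·N are
reported.

**Detection limit.** The default is `d = ln(2)/N`. A taxon at relative
abundance x is missed by N reads with probability `(1 − x)^N ≈ e^{−Nx}`,
which crosses ½ at `x = ln2/N`; thresholding there makes the step-function
detection model agree with realized count-based detection with negligible
bias. Fitting the exact beta-binomial occurrence curve confirms this: with
the conventional `d = 1/N` the recovered m overshoots the generating value by
about 25%, while `d = ln2/N` recovers it to within 1%. d remains an exposed
parameter for users who prefer the 1/N convention.

The 95% envelope around the fitted curve is the Wilson score interval for a
binomial proportion with point value F_pred and n = number of samples —
stable near 0 and 1, where most taxa sit. Taxa are classified below / within
/ above the envelope; "above" taxa are detected more often than neutral
expectation (candidate generalists or widespread selection), "below" taxa
less often (candidate specialists or dispersal-restricted).

## Synthetic communities

The generator emulates the study design the pipeline targets: ~20 stations
evenly spaced along a ~17°-latitude transect, surface and DCM strata at each
station (40 samples), 15,468 reads per sample, and a temperature field
`T = 43 − 0.7·latitude + N(0, 0.8²)` °C with a −2.5 °C offset at the DCM —
yielding the strong negative temperature–latitude correlation characteristic
of such transects. Regions are assigned from latitude break-points; salinity,
nitrate, chl-a, *Sargassum* density and dates are filled with plausible
stratum-dependent values. Defaults for assembly are migration m = 0.1 and a
lognormal(σ = 2) source pool of 500 taxa over a random bifurcating tree with
exponential(1) branch lengths — a valid tree for UniFrac, with no claim of
realistic macroevolution.

Three assembly regimes:

* **neutral** — local abundances are Dirichlet(Nm·p) with Nm = m·(reads per
  sample), then multinomial reads; the marginal of each taxon is exactly the
  Beta distribution the fitted model assumes.
* **niche** — the source pool is filtered multiplicatively,
  `q_i ∝ p_i·exp(−w(T − opt_i)²/(2 tol_i²))`, before neutral sampling; the
  weight w slides continuously from pure neutrality (0) to full filtering (1).
* **dispersal-limited** — the source pool itself drifts along the transect as
  a per-station log-abundance Gaussian random walk; both depth strata at a
  station share its pool. This produces distance decay of similarity without
  any environmental response.

Contaminant taxa, when requested, are removed from the assembly pool, given
20–80 reads in a simulated negative control, and spiked into samples strictly
below the 10× screen threshold, so the filter has an exact ground truth.

What the generator does **not** emulate: sequencing-read artefacts (chimeras,
PCR bias, variable library depth), taxon-taxon interactions, temporal
dynamics, realistic phylogenetic signal in niche traits, or vertical
structure beyond the two-stratum offset. Tests passing on these synthetic
data therefore validate the statistical machinery and its inverse-problem
behaviour (parameter recovery, regime discrimination, calibration), not the
ecological realism of any particular field system.

## Problem sizes used in the validation suite

The self-validation experiments are desk-scale by design: neutral-model
recovery uses 20 seeds × (40 samples × 500 taxa × 15,000 reads);
environment-vs-space regime discrimination uses 50 replicates per regime of
40 samples × 150 taxa × 2,000 reads; permutation-test calibration uses 1,000
null replicates × 999 permutations at 15–20 samples. These sizes keep each
experiment's Monte-Carlo error well below the decision thresholds being
tested while completing in seconds to minutes.

## Known limitations

* PERMANOVA and PERMDISP answer different questions (location vs dispersion);
  with unbalanced designs a significant PERMANOVA can reflect dispersion
  differences — both are reported so the user can weigh them.
* The ordered-pair distance-decay regression overstates df (see above).
* Forward selection inherits the usual instability of greedy selection under
  collinearity; the double stopping rule is conservative but not immune.
* Negative PCoA inertia is dropped, not corrected; for strongly non-Euclidean
  distance matrices a square-root correction would be preferable.
* The neutral fit treats per-taxon observations as independent least-squares
  points; no error model on the occurrence frequencies is imposed.
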