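# Methods

This note documents the model, the analysis pipeline, the parameter
choices that matter, and what the package's tests do and do not establish.

## 1. The forest simulator

### State and scales

The simulated world is a set of independent 10 m × 10 m patches (no seed
or light exchange between patches). Each tree carries a plant functional
type (PFT), three lifetime-fixed traits — specific leaf area (SLA,
mm²/mg), leaf longevity (months) and wood density (WD, g/cm³) — and a
dynamic state (height, age, last annual net production). The time step is
one year, with production resolved monthly inside the year. The default
protocol is 500 patches × (150 spin-up + 100 scenario) years; patch count
and durations are plain configuration values, so the historical protocol
of 10⁴ patches and a 500-year spin-up is available at proportional cost
(the default desk run takes well under a minute on one CPU).

### Traits and PFTs

Four woody PFTs are modelled: broad-leaved summergreen (BL-S),
broad-leaved evergreen (BL-E), temperate needle-leaved (T-NL) and boreal
needle-leaved (B-NL). At establishment, SLA and WD are drawn uniformly
from PFT-specific ranges that overlap across PFTs (so community-level
trait shifts are expressible on a continuum), and leaf longevity follows
the leaf-economics power law

    leaf_longevity = a · SLA^(−b)

with (a, b) per phenology class, chosen so BL-S draws span ≈ 4–12 months,
BL-E ≈ 12–36 months and needle PFTs ≈ 24–80 months across their SLA
ranges. Higher SLA therefore always means shorter-lived leaves. Traits
never change after establishment; only height, age and carbon balance do.

### Production

Net annual production of tree *i* is

    P_i = Σ_m  A · LA_i · act_i(T_m) · eff(SLA_i) · exp(−k · LAI_above,i,m)
          −  c_m · WD_i · H_i^1.5

summed over months *m*, with leaf area LA_i = 0.12 · H_i^1.6 (m²),
assimilation rate A = 0.05 kgC m⁻² month⁻¹, SLA efficiency
eff = (SLA/15)^0.5, light extinction k = 0.5 per unit leaf-area index, and
maintenance coefficient c_m = 0.02 kgC yr⁻¹ per (g/cm³ · m^1.5). Phenology
enters through the activity function act(T): a Gaussian response
(peak · exp(−((T−T_opt)/T_breadth)²)) gated to zero below a leaf-on
threshold. Summergreen broadleaves have the highest peak (1.0 at 21 °C)
but switch off below 5 °C; evergreen needles run at lower peaks
(0.60–0.65) with wide response breadths and leaf-on thresholds near
−5 °C, so they photosynthesize through shoulder-season months in which
the summergreen canopy is bare.

Crucially, shading is *activity-weighted*: LAI_above counts only the leaf
area of taller patch members multiplied by their own monthly activity, so
a leafless deciduous canopy casts no winter shade. Phenological
complementarity — an understorey tree doing better under a canopy of the
opposite phenology — is therefore an emergent property of the kernel, not
a hard-coded bonus, and the tests verify it both at the production level
(focal trees under mixed vs single-phenology canopies) and at the
survival level (paired mixed vs pure community experiment).

### Mortality, growth, establishment

The annual death probability is an additive clipped hazard

    p = p_bg + s_age · (age/max_age)² + s_stress · max(0, −P_i) / WD_i

with background rate p_bg = 0.005 yr⁻¹, age scale s_age = 0.10 and stress
scale s_stress = 2.0 per kgC of carbon deficit per unit wood density, so
denser wood buffers a given deficit. The three terms give, respectively,
irreducible stochasticity, canopy turnover, and the trait/competition
filter. The split was chosen so deaths are dominated by the deterministic
terms: with a large background rate, century-scale survival becomes
unpredictable noise, whereas the chosen defaults give held-out
classification AUCs around 0.6–0.65 on simulated cohorts — weak enough to
be honest, strong enough to analyse.

Height grows only on positive production,
ΔH = g · max(P, 0)/WD · (1 − H/H_max(WD)) with g = 3 m per kgC/(g/cm³)
and H_max = 34 · (WD/0.55)^0.25 m, giving fast gap-filling by saplings and
saturation near the trait-dependent maximum. Vegetation carbon per patch
is Σ 0.35 · WD · H² /100 kgC m⁻².

Establishment is open: every year each patch receives a Poisson number of
saplings (rate 3 yr⁻¹ on bare ground, scaled by the mean annual light
fraction reaching the floor), each assigned a PFT drawn uniformly among
those whose coldest-month bioclimatic limits admit the 20-year running
mean coldest-month temperature. B-NL requires cold winters (coldest month
≤ −1 °C) and BL-E mild ones (≥ −1 °C), so a warming trend replaces boreal
establishment with evergreen-broadleaf establishment as the winters
soften.

### Climate

Temperature is the only climate driver (precipitation and radiation are
deliberately omitted; water competition is folded into the
density-dependent light terms — a recorded deviation from full vegetation
models). A 30-year base block of monthly temperatures (site mean 7 °C,
seasonal amplitude 9 °C, interannual SD 0.6 °C, monthly SD 1.2 °C) is
recycled in whole-year permutations. The reference scenario is the
recycled block with no trend; the warming scenario adds a linear ramp
during the scenario phase reaching `warming_trend` (default 3.0) °C per
century. CO₂ is a recorded constant (296 ppm) with no attached
physiology.

### Random streams and snapshots

One master seed spawns named substreams (climate, traits, establishment,
mortality) via hashed seed sequences, so ablating one process never
shifts the draws of another; identical config + seed reproduce snapshot
streams bit for bit. Snapshots (tree and patch tables) are written at the
scenario start (t0), every 10th scenario year, and the final year (t1).

### Default-parameter calibration

The production, growth and mortality constants above were set during model
design by requiring, in order: (i) a non-trivial equilibrium — patch-mean
vegetation carbon ≈ 15 kgC/m², coefficient of variation < 0.1 over the
final century; (ii) coexistence — a mixed needle/broadleaf reference
community with a persistent multi-height structure and an understorey;
(iii) directional climate response — warming raises the broadleaf
fraction through both productivity and establishment filtering; and
(iv) a deterministic-mortality-dominated regime (see above). They are
defaults of `SimulationConfig`, not constants.

## 2. Diversity indices

Per patch, living trees taller than 5 m form a cloud in (SLA, leaf
longevity, WD) space, standardized by site-level means/SDs computed once
over all analysis trees at t0 (so volumes are unit-free and patches are
comparable within a site). Weights are equal per individual; exact
duplicate points are merged with summed weights, which makes the indices
invariant under duplication of the whole community.

- FR: convex-hull volume (Qhull). Clouds with < 4 distinct points or
  coplanar geometry are degenerate: FR = 0, flagged, excluded from ln FR
  analyses (their trees keep all other covariates and are dropped from
  record tables only by an explicit, logged step).
- FDv: distances d_i of all points to the gravity centre of the hull
  vertices; with d̄ the unweighted mean, Δd = Σ w_i (d_i − d̄) and
  Δ|d| = Σ w_i |d_i − d̄|, FDv = (Δd + d̄)/(Δ|d| + d̄).
- FE: minimum spanning tree of the cloud; branch values
  EW_l = dist_l/(w_i + w_j), normalized to PEW_l; with S points,
  FE = (Σ min(PEW_l, 1/(S−1)) − 1/(S−1)) / (1 − 1/(S−1)). A two-point
  cloud is defined as trivially even (FE = 1); single points are flagged
  undefined.

The test suite checks all three against an independent brute-force oracle
(explicit formula evaluation with a networkx MST) to 10⁻¹⁰ on clouds of up
to 12 points, against closed-form cases (unit cube, regular octahedron,
evenly spaced line), against a rejection-sampling volume estimate, and for
[0, 1] boundedness over thousands of random clouds.

## 3. Survival labelling

A tree enters the analysis if alive and > 5 m at t0 (smaller trees are
saplings and excluded); it is a survivor if the same id is alive at t1.
All covariates are t0 values: SLA, WD, height, patch tree count > 5 m,
patch vegetation carbon, and patch ln FR / FDv / FE. Ids present only at
t1 are new recruits and ignored; duplicated ids are an error. The record
count always equals the number of qualifying t0 trees. Trees exactly at
the 10 m stratification threshold go to the understorey stratum, making
the small/large split a deterministic partition.

## 4. Importance analysis

Mortality rates differ strongly between runs and scenarios, so classes
are balanced first: equal numbers of dead and surviving trees (default
total 5000) drawn without replacement, then a class-stratified 80/20
train/test split. The classifier is a standard random forest
(500 trees, 3 split variables — values confirmed by the built-in
two-stage tuning grids: ntree 50–800 in steps of 50 at mtry 2, then mtry
2–8 at ntree 500, selected by held-out AUC). A conditional-inference
forest would be the closest historical reference; the analysis surface
here is the importance *contrast* between variable groups, which does not
depend on the splitter flavour, and this package deliberately uses the
standard ensemble with held-out permutation importance instead.

Permutation importance is the mean decrease in held-out accuracy over 10
column permutations; negative means are floored at zero and the vector
normalized to sum to one. Grouped importances sum the shares of
individual traits (SLA, WD, height), forest dynamics (ntrees, VegC) and
functional diversity (ln FR, FDv, FE). Height-stratified analyses rerun
the whole pipeline per stratum with independent derived seeds, reducing
the subsample total (logged) when a stratum's class counts demand it.

Calibration uses planted logistic cohorts (`fdforest.planted`): survival
drawn from p = σ(β·z) with known coefficients on standardized covariates
whose marginals mimic simulator output. Cohorts of 12,000 are generated so
that the protocol's balanced subsample of 5000 is always feasible. The
pipeline must leave zero-coefficient covariates jointly under 10%
normalized importance and localize a height-confined diversity effect in
the understorey stratum; both hold in ≥ 8 of 10 seeds (empirically 10/10).

## 5. Partial dependence and the diversity effect

The centred partial dependence of covariate v is computed by sampling
1500 records, overwriting v with each of 50 grid values (spanning the 1st
to 99th percentile of v at t0, to avoid extrapolation artefacts; values
outside the observed range are computed but flagged), averaging the
predicted survival probability, and subtracting the mean prediction of
the unmodified sample — so a value above zero reads directly as an
additional survival probability. The per-grid SD is the across-record SD
of predictions / √n.

Tail effects average the centred curve (linearly interpolated) over the
records whose t0 value falls in the stated 10% tail of the *full*
analysis distribution, with the SD taken across those records. The
combined diversity effect is the sum of the high-ln FR, high-FDv and
low-FE tail effects, with SDs combined in quadrature
(σ = √(σ₁² + σ₂² + σ₃²)); cross-site aggregation is the mean of per-site
means with σ = √(Σσ_i²)/n. The baseline choice (mean prediction over the
unmodified sample) is a design decision: it makes "above zero contributes
positively" literal, at the cost of the curve averaging to ≈ 0 over the
sample rather than over the grid.

On simulated data, the understorey diversity effect is estimated on the
paired mixed-vs-pure community experiment run under strong light
competition (extinction 1.2, stress scale 4.0), where the mixture's
survival benefit is large enough for the forest + partial-dependence
route to resolve; at the default competition strength the route's
estimate on natural equilibrium runs is within noise of zero, because
equilibrium patches are all similarly mixed and provide little
cross-patch diversity contrast (see Limitations).

## 6. What the synthetic data do and do not show

The simulator emulates the statistical structure the analysis needs:
trait filtering under climate and competition, density dependence,
phenology-driven complementarity, a reference/warming scenario contrast,
and multi-layer stand structure with persistent tree identities. It omits
water and nutrient competition, daily physiology, crown geometry, grasses,
disturbance, dispersal limitation and trait plasticity. Passing tests
therefore demonstrate that the *pipeline* recovers planted or emergent
relationships of realistic shape and magnitude at desk scale — they do not
validate the simulator against real forests, and numerical values
(importance shares, effect percentages) are properties of this model
world, not forecasts.

## 7. Numerical choices and degenerate inputs

- Hull and MST computations use scipy (Qhull, csgraph); degenerate
  geometry is caught and flagged, never silently zero-filled except FR = 0
  by definition.
- MST ties (equal distances) are resolved by the library's deterministic
  scan order; with continuous traits, exact ties have measure zero.
- Balanced subsampling errors out (reporting both class sizes) rather
  than sampling with replacement when a class is short; stratum pipelines
  shrink the total instead, logging the reduction.
- Permutation importance with no positively scoring predictor raises
  rather than normalizing a zero vector.
- All randomness flows from named substreams of a master seed; equal
  heights in the light sort are broken by stable sort order, keeping runs
  bit-reproducible.

## 8. Known limitations

- Height classes in ln FR analyses: patches are clouds of > 5 m trees, so
  very sparse patches are degenerate and excluded from diversity-based
  records; at default scale this affects none to a handful of patches.
- Century-scale survival retains a large irreducible stochastic
  component; held-out AUC ≈ 0.6 on whole communities is expected, and
  importance estimates on small strata are noisy — the stratified
  analysis reduces subsample totals and should be read qualitatively.
- The diversity signal on natural equilibrium runs is weak by
  construction (little between-patch contrast); causal statements about
  complementarity rest on the paired community experiment, which is the
  designed instrument for them.
- The reference climate recycles whole years only; within-year
  autocorrelation of anomalies is not preserved across the recycling
  boundary.
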