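# Methods

`perohr` estimates how sex, body condition, habitat type, latitude and
conspecific density jointly shape space use in *Peromyscus* (deer mice)
trapped on standardized 1-ha grids, and ships a synthetic study generator so
that every stage of the pipeline can be validated against known ground truth.
This note records the models, the parameter choices and their rationale, the
numerical decisions, and what the validation does and does not demonstrate.

## Data model

Input is a trap-night capture table in the NEON small-mammal dialect: one row
per capture with site, plot, trap coordinate, date, tag, field taxon, sex,
pregnancy status, mass (g), hindfoot length (mm), NLCD vegetation class and
plot latitude. Trap coordinates combine a letter row (A–J) and a column
(1–10) on a 10 m lattice; the package maps letter→y and number→x with A1 at
the origin. The convention is arbitrary but fixed — any consistent mapping
yields identical areas, since every estimator used is invariant to rigid
motions of the grid.

### Cleaning rules

* Only *Peromyscus* records are analyzed (field species identifications are
  unreliable between look-alike congeners, so all analysis is at genus
  level). The socially/genetically monogamous species *californicus*,
  *eremicus* and *polionotus* are removed: monogamy inverts the sex-based
  predictions about space use, and these three are morphologically
  distinctive enough for the field identification to be trusted.
* Masses above 50 g and hindfeet above 28 mm are implausible for these mice;
  the values are set missing but the records retained, so they still
  contribute relocations while staying out of the condition regression.
* An individual whose every recorded mass is below 10 g (implausibly light
  throughout) is removed, as is any individual whose pregnancy status
  alternates pregnant/nonpregnant/pregnant across consecutive days (window:
  1 day between captures) — both patterns indicate record errors (e.g. tag
  collisions).
* Records without a tag identifier are dropped with a logged count; records
  with a missing trap coordinate are kept for density and phenotypes but
  cannot contribute relocations.

## Phenotypes

**Sex** is the strict majority of per-capture records (M/F; U and missing do
not vote), overridden to female by any pregnancy record. Ties resolve to
"unknown" and such animals are excluded from the model rather than assigned a
sex arbitrarily.

**Size class** splits the genus into typically-small (*maniculatus* sensu
lato, *leucopus*) and typically-large (*keeni*, *truei*, *gossypinus*,
*attwateri*, *boylii*) species, because a single adult-mass threshold would
misclassify adults of small species as juveniles of large ones. Genus-only
and cross-class ambiguity codes fall back to "small" (configurable), since
more than 80% of captures are of small species.

**Life stage** is assigned from mass: adult at ≥16 g (small class) or ≥19 g
(large class), thresholds inclusive. Once an individual has ever been at or
above threshold, all later captures are adult — this forward propagation
covers later missing masses and temporary mass loss, and guarantees the
stage sequence never reverts from adult to subadult. Only adult captures
enter the home-range and condition calculations, because juvenile space use
reflects the natal range and dispersal, not settled behavior.

**Body condition** is the residual of mean adult mass regressed (OLS) on mean
adult hindfoot length, fitted separately within each size class; captures
with pregnancy status pregnant or unknown are excluded from the means so
pregnancy mass gain does not inflate condition. Means use adult captures
only: the analysis population is adults, and mixing juvenile masses into an
individual's mean would conflate growth with condition (this choice is
configurable). The regression needs at least three individuals per class
present in the data; fewer is an error rather than a silent skip.

## Density: minimum number known alive (MNKA)

A sampling event is a distinct trap-night date at a plot — the finest
resolution the records support; per-bout aggregation is obtained by
collapsing dates upstream if desired. An individual is "known alive" on
every event between its first and last capture at a plot, and MNKA(event) is
the count of such individuals, all *Peromyscus* pooled. Each focal animal's
covariate, meanMNKA, is the mean of its home plot's MNKA over the events
inside its own first-to-last capture window; its home plot is the plot with
most of its captures (ties → earliest used). MNKA is an index, not an
abundance estimate: it undercounts true density (no capture-probability
correction) but is strongly correlated with model-based estimates, and an
index suffices for a covariate.

## Home ranges

Eligible animals have ≥5 adult captures at ≥3 unique traps. The utilization
distribution is a fixed-bandwidth isotropic Gaussian kernel density over the
relocations, evaluated at the centres of 1 m cells on a grid extending
max(3h, 15 m) beyond the data and normalized to unit mass. The bandwidth is
the reference ("href") rule for bivariate data,

    h = sqrt((var(x) + var(y)) / 2) * n^(-1/6),

with n−1 variances. The home range is the 50% isopleth: cells are ranked by
density and accumulated until half the mass is reached; cells tied with the
last included density are all included (so a perfectly uniform plateau is
either wholly in or wholly out). Areas are reported in m²; 1 m cells keep
the smallest observed ranges (tens of m²) resolvable. Duplicate relocations
(trap re-use) are retained as-is — the kernel handles multiplicity, and
jittering would inject unstated randomness.

Known, quantified biases of this estimator on trap-grid data:

* **Bandwidth inflation.** Smoothing adds ~h² to each marginal variance, so
  the measured 50% area of a circular-Gaussian range with parameter σ
  recovers 2πσ²ln2 with a positive bias of roughly n^(−1/3); at n = 10⁴
  relocations this is ~4–5%, which is the tolerance used in the closed-form
  validation.
* **Grid truncation.** Relocations exist only at the 100 trap positions, so
  ranges extending past the 1-ha grid are clipped. For field-scale areas
  (lognormal, mean ≈ 1.5×10³ m²) with centers up to 20 m off-grid, the
  pre-build calibration run measured a median signed error near −30% and a
  median absolute error near 35–40% against truth at 5–15 captures; the
  generator-consistency test therefore holds the median absolute error below
  0.45. Truncation compresses large areas more than small ones, which
  attenuates fitted covariate effects at pipeline scale — an inherent
  property of trap-grid home ranges, not of this implementation.

The minimum convex polygon (MCP) — the convex hull of the relocations, by
percent closest to the centroid — is provided for comparison only; fewer
than three unique (non-colinear) points give area 0 with a warning.

### Rarefaction

For reference individuals with ≥K relocations (default K = 10), j = 3…K−1
relocations are drawn without replacement (default 500 draws per j, split
across individuals) and the area recomputed; the relative error against the
full-data area is summarized per j by its signed median, quartiles and
median absolute value. The stability rule is the smallest j whose |median
relative error| is below 10% — a *bias* criterion. The median absolute
error cannot fall below ~sqrt(1/(j−1)) for independent relocations (variance
estimation alone contributes that much spread), so accuracy at few captures
is a statement about bias, not about per-animal precision: by five
relocations the KDE's median bias is within a few percent while the MCP
remains ~50% too small, which is why the eligibility minimum of five
captures is defensible for the KDE and indefensible for the MCP.

## The gamma mixed model

Areas are positive and right-skewed, so A_i ~ Gamma(shape α, mean μ_i) with

    log μ_i = x_i' β + u_site(i) + v_year(i),
    u_s ~ N(0, σ²_site),  v_t ~ N(0, σ²_year)  (crossed),

where year is the calendar year of the individual's first adult capture and
site the NEON site of its home plot. Categorical coding is treatment
contrasts with female and forest as references, so the sex coefficient reads
"male vs female" and habitat coefficients read against forest. Continuous
predictors (condition, latitude, density) can be centered and scaled
internally — the default in the pipeline, for conditioning of the three-way
interaction — with the scaler stored on the fit and applied transparently in
prediction.

**Estimation** maximizes the Laplace-approximated marginal likelihood. The
inner step is a penalized Newton (equivalently, penalized IRLS) jointly over
(β, b) given (σ_site, σ_year, α), using the observed-information weights
w_i = α y_i/μ_i and step halving; the outer step is a bounded Nelder–Mead
over (log σ_site, log σ_year, log α), warm-starting the inner modes. The
Laplace log-likelihood is

    ℓ = Σ log f(y_i | μ̂_i, α) − ½ b̂'D⁻¹b̂ − ½ log|D| − ½ log|Z'WZ + D⁻¹|.

Convergence requires the inner gradient norm below tolerance; failure raises
an error carrying the best iterate. With both variances pinned at zero the
fit reproduces an ordinary gamma GLM to ~1e−7 relative (validated against an
independent GLM implementation). Against R's `glmmTMB` on the same data the
fixed effects, random-intercept SDs and log-likelihood agree to ~1e−3.

**AIC** counts the fixed effects, the two variance components and the gamma
shape: AIC = −2ℓ + 2(p + 3). Akaike weights are exp(−Δ_i/2) normalized over
the candidate set. The candidate ladder holds 12 models: intercept-only; the
five main effects; each biologically motivated two-way interaction added
singly (sex×condition, habitat×latitude, latitude×density, habitat×density);
sex×condition paired with each environmental interaction; all environmental
two-ways; all two-ways; and the full model adding habitat×latitude×density.
Interactions always bring their lower-order terms (marginality is enforced
at construction).

**Inference.** The Wald covariance of β is the fixed-effect block of the
inverse joint Hessian at the optimum — conditional on the estimated variance
components and shape, as in standard mixed-model software. The deviance
table tests each term's coefficient block with χ² = β_T' V_T⁻¹ β_T (df =
block size; a numerically singular block falls back to a rank-adjusted
pseudo-inverse test with a warning). Because the covariance conditions on
the variance components, intervals for the baseline (intercept) — whose
uncertainty is dominated by the site and year means — run visibly
anticonservative (~88% realized coverage at 36 sites/10 years in the
validation), while effect terms sit near nominal (93–97%); this is the
familiar cost of Wald inference in mixed models, shared by the reference
implementations.

**Habitat contrasts** compare habitat-adjusted means on the link scale
(continuous covariates at their means, sex balanced 50/50, random effects at
zero) for the three pairwise differences, with single-step multivariate-
normal adjustment (the Tukey-style max-|z| correction computed from the
joint normal rectangle probability) and a compact letter display at α =
0.05. **Prediction curves** exponentiate the linear predictor at random
effects zero with delta-method intervals on the link scale, sliced by
habitat and by low/mid/high representative latitudes (tertile midpoints);
requests outside the fitted covariate ranges warn about extrapolation.

## The synthetic study generator

The generator mirrors the sampling design the pipeline assumes: `n_sites`
sites uniform over 28–47.2° latitude, each with `plots_per_site` 1-ha grids
("pathogen" plots trap 3 consecutive nights per bout, a configurable
fraction are 1-night "diversity" plots), sampled in 4–6 bouts per year over
`years` years. Each plot-year receives an overdispersed (gamma–Poisson)
number of individuals; each individual draws sex, condition, a species (and
hence size class) from a realistic field mix including ambiguity codes, and
a residency window of at least `min_residency_bouts` contiguous bouts.

The true 50% area comes from the same gamma log-link model the analysis
fits: a linear predictor over centered covariates (latitude about 37.6°,
density about 22 animals/plot) with the full interaction structure, plus
site and year normal intercepts, then a gamma draw with the configured
shape. The movement model is i.i.d. draws from a circular-Gaussian
utilization with σ = sqrt(area/(2π ln 2)) centered up to 20 m off-grid (so
some ranges straddle the boundary, as in the field); each capture night the
animal is caught with probability `p_capture` and assigned a trap by a
multinomial over the 100 traps weighted by its utilization. Field noise:
juveniles start below the adult threshold and grow ~0.15–0.35 g/day; masses
and hindfeet carry measurement noise and go missing at configured rates;
adult females have 21-day pregnancy episodes (mass +3 g, excluded from
condition by the pipeline); sex is misrecorded or unknown at configured
rates; non-target genera and rare monogamous congeners appear as bycatch for
the filters to remove.

Default conditions (one study): 8 sites × 3 plots × 3 years, 5 bouts/year,
capture probability 0.45/night, ~20 animals per plot-year — about 1,300
captured individuals of which ~400–440 pass the home-range eligibility rule,
with meanMNKA around 14 (within the observed field range) and true areas
lognormal with mean ≈ 1.5×10³ m². Default effect sizes (log scale, centered
basis): males +0.25; condition −0.05 with sex×condition +0.10 (so condition
raises male and lowers female areas); grassland +0.35 and shrubland +0.18
over forest; latitude +0.020/°; density −0.015/animal; and interaction terms
chosen so the density decline steepens at high latitude in grasslands but at
low latitude in forests while shrubland areas are larger at low latitude.
σ_site = 0.30, σ_year = 0.15, gamma shape 2 — together with the covariate
spread this reproduces the field-scale coefficient of variation of areas
(~0.9).

A second entry point, `simulate_analysis_table`, draws covariates and gamma
areas directly (no capture process, covariates pre-centered) and returns the
generating coefficients; it is the instrument for estimator-level validation
— coverage, sign recovery, test calibration — where capture noise would
confound the question being asked.

### What the generator does *not* emulate

No serial autocorrelation in relocations (the kernel estimator's own
assumption — real trap data are night-to-night dependent); at most one
capture per animal per night and no trap competition; capture probability
independent of how much of the range overlaps the grid (off-grid animals are
caught at their truncated utilization, not less often); no dispersal,
density feedback, or trap-shyness/-happiness; species identity affects only
size class, not space use. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes, at field-realistic noise — not
that real *Peromyscus* data satisfy those assumptions.

## Validation design and problem sizes

The validation suite exercises: exact oracle agreement for MNKA (brute-force
over the known-alive definition, 1,000 random histories); closed-form kernel
recovery (10⁴ relocations, σ = 10 m, 5% tolerance per the bandwidth-bias
analysis above); life-stage monotonicity over 10³ random trajectories; the
pinned-zero-variance GLM limit at 1e−3; fixed-effect CI coverage and sex-
sign recovery over 100 replicate fits at study scale (2,000 animals, 36
sites, 10 years); null-term rejection calibration over 200 replicates at
n = 600; and the rarefaction bias contrast at five relocations. Sizes were
chosen as the smallest that make the answers statistically unambiguous.

## Known limitations

Eligibility itself selects on space use (animals must spread over ≥3 traps),
which together with grid truncation attenuates fitted contrasts at pipeline
scale relative to the generating truth — visible in the synthetic recovery
report, and a caveat for any trap-grid home-range study. meanMNKA
underestimates absolute density, so the density coefficient is per index
unit, not per animal per hectare. The Wald baseline interval is
anticonservative (above). The rarefaction defaults (K = 10, 500 draws, 10%
bias rule) are package policy; alternative stopping rules change the
reported minimum by ±1–2 relocations.
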