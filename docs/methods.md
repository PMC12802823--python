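# Methods

## Stoichiometric CUE model

CUE_ST treats microbial carbon use efficiency as jointly limited by C:N
and C:P imbalances between resources and biomass, each expressed through
a Michaelis–Menten saturation term in the scalar S (the degree to which
extracellular enzyme allocation offsets the resource–biomass imbalance).
The estimator is the geometric mean of the two terms scaled by CUE_max:

    CUE_ST = CUE_max · sqrt( S_CN·S_CP / ((K_CN+S_CN)·(K_CP+S_CP)) )

Placing the square root over the whole ratio (rather than only the
denominator) is deliberate: it makes the estimator the geometric mean of
two quantities bounded in (0, 1), hence 0 < CUE_ST < CUE_max for any
positive scalars, CUE_ST = CUE_max/2 exactly at S = K on both axes, and
strictly increasing in either scalar. The alternative reading is
unbounded and physically meaningless for an efficiency.

Parameters and defaults: CUE_max = 0.6 (metabolic ceiling), K_CN = K_CP
= 0.5. Resource ratios L are molar SOC:TN and SOC:TP (mass inputs in
g kg⁻¹ converted with atomic masses 12.011/14.007/30.974); biomass
ratios B are molar MBC:MBN and MBC:MBP (mg kg⁻¹). Ratios are unit-free,
so only within-element unit consistency matters; a `molar_inputs` flag
bypasses conversion for pre-computed molar ratios. Rows with a missing
LAP assay are invalid by default; `allow_missing_lap=True` treats LAP as
zero for compilations that assayed only NAG. Invalid rows are never
dropped silently — every pipeline output carries a `reject_reason`
naming the offending field, and accepted + rejected = input everywhere.

## Respiration units

Mass-based R_h (g C kg⁻¹ yr⁻¹) = area-based R_h (g C m⁻² yr⁻¹) divided
by the soil mass under 1 m²: bd·h·1000 kg, with bulk density bd in
g cm⁻³ (≡ t m⁻³) and depth h in metres (default 0.1 m, close to the mean
sampling depth of site compilations). Daily fluxes are annualised with a
flat 365-day year. Both conversions are exact linear maps, so they
preserve rank order and, at constant bd·h, Spearman correlation 1.

## Segmented threshold detection

The threshold ψ is the breakpoint of the continuous two-segment model
cue = a + b₁·rh + b₂·(rh − ψ)₊ minimising SSE. For fixed ψ the model is
linear; SSE(ψ) is computed in closed form from suffix sums (O(1) per
candidate after an O(n log n) sort), evaluated at **every** midpoint
between consecutive distinct rh values inside the interior quantile band
(default `min_segment_frac` = 0.05, each segment ≥ 10 points), then
polished by bounded scalar minimisation between the neighbouring
candidates. This is exhaustive, so it matches a brute-force scan by
construction and needs no starting values.

A threshold is only *reported as present* when the segmented model earns
its two extra parameters: we compare BIC of the one-line model (3
parameters incl. the residual variance) with the segmented model (5
parameters incl. ψ). On pure-noise or perfectly linear inputs this
flags "no threshold" (a naive F-test would not, because ψ is chosen by
search); on real breaks the SSE drop dominates the penalty. The fit is
still returned in full either way.

Uncertainty: nonparametric pairs bootstrap (default 1000 resamples),
refitting ψ on each resample; we report both the percentile 95% CI and
the SD of the bootstrap distribution, since a "±" convention alone is
ambiguous. Resamples whose refit fails (degenerate rh) are excluded and
counted; more than 20% failures aborts. The post-threshold slope is
estimated freely (not constrained to zero) and the separate pre/post
straight-line fits (R², slope p) are reported alongside, which is how
decoupling is judged: a significant negative pre-threshold slope and a
post-threshold slope indistinguishable from zero.

"GLM" stratum fits are Gaussian-identity OLS with a slope t-test
(statsmodels); the nonlinear candidates (a·exp(b·rh), a + b·ln rh,
a + b·rh + c·rh²) are least-squares fits ranked by AICc with a common
Gaussian log-likelihood, so the ranking is comparable across forms.

## Driver attribution

All-subsets selection enumerates every main-effects OLS model over the
nine predictors (2⁹ = 512, intercept-only included), scores each by
AICc = AIC + 2k(k+1)/(n−k−1) with k counting the intercept, slopes and
residual variance, converts to Akaike weights w_i ∝ exp(−Δ_i/2)
(normalised to 1), and defines a predictor's importance as the summed
weight of models containing it; importance ≥ 0.8 flags it essential.
Predictors are standardised first (importance is invariant to this, but
coefficients become comparable); rows with missing values are dropped
and counted; a rank-deficient design raises an error naming the
collinear columns. A mixed-effects variant with per-site intercepts
would coincide with this fixed-effects enumeration when each site
contributes one observation, as in the synthetic data; for grouped data
a site-cluster bootstrap of the importance is the recommended extension.

Partial correlation is computed from first principles: residualise both
members of the pair on the controls, correlate the residuals, and take
p from a t distribution with n − 2 − g df. Variation partitioning
computes adjusted R² for all subsets of the four key variables
(soil temperature, precipitation, LAI, pH); a variable's independent
fraction is adjR²(all) − adjR²(all minus it), the joint fraction is the
remainder, and relative influences divide by adjR²(all), so the
identities Σ independent + joint = adjR²(all) and Σ relative = 1 hold to
rounding. Negative adjusted-R² fractions are reported as-is and flagged,
and the partition is declared undefined when adjR²(all) ≤ 0.

Because the CUE/R_h ratio is strongly right-skewed, the robustness
module tests normality (Shapiro–Wilk, Lilliefors, Anderson–Darling) and
refits the driver model as (i) OLS on the log ratio with HC3 robust
covariance and (ii) a gamma GLM with log link, tabulating coefficient
signs and significance next to the Gaussian fit. Per-variable p-values
are reported raw, with a clearly-labelled Benjamini–Hochberg column as
an extension.

## Removal sensitivity

Within each stratum, ⌊0.2·n⌋ observations are removed uniformly at
random (without replacement, floor rounding), the slope refitted, and
the distribution over 1000 repetitions summarised by sign persistence
(fraction of repetitions agreeing with the full-data slope sign) and
significance persistence (fraction with p < 0.05). The procedure is
bit-identical under a fixed seed. One caveat worth knowing: removal
subsets share 80% of their rows with the full data, so refitted slopes
are strongly correlated with the full-data slope; even when the true
slope is zero, sign persistence centres near 0.85 (not 0.5) whenever the
*estimated* full slope happens to be nonzero. Sign persistence therefore
discriminates robust couplings (≈ 1.0) from fragile ones, while
significance persistence is the cleaner null diagnostic (≤ ~0.05 under
no relationship).

## Synthetic data

The generator emulates the statistical skeleton of a global site
compilation: 1094 sites in four climate zones (tropical 17%, temperate
27%, arid 28%, cold 28%, putting ~56% of sites in the low-productivity
stratum); zone-specific lognormal R_h (medians 950/650/150/170
g C m⁻² yr⁻¹, log-SD 0.40–0.55) so arid/cold sites sit mostly below the
340 threshold and tropical/temperate mostly above; zone-specific
scaled-Beta LAI spanning 0.06–5.69 with arid/cold almost entirely below
the productivity cutoff of 3. True CUE follows the piecewise mean
(plateau 0.27, pre-threshold slope −4×10⁻⁴, post-threshold slope 0,
capped at 0.5) plus planted covariate effects and truncated-Gaussian
noise confined to (0.05, 0.6) — truncation keeps n exact without
boundary atoms. Noise has a measurement component (SD 0.08) and a
between-site heterogeneity component (SD 0.05), chosen so the
high-productivity plateau spreads realistically (~0.1) while the
breakpoint remains recoverable to a few tens of flux units.

Planted drivers are pH (+0.030 per SD), CEC (−0.030) and clay (+0.030),
applied at full strength in the low-productivity stratum and at 0.3× in
the high stratum. These three were chosen because the generator draws
them independently of R_h: planting on temperature or precipitation
(which covary with zone and R_h by design) would leak a spurious trend
into the post-threshold plateau and confound the threshold analysis the
data are meant to exercise. The effect size of 0.030 (≈ 0.3 SD of the
row-level noise) makes the planted set clearly identifiable at n ≈ 600
without dominating the respiration signal. Covariates that do covary
with the flux structure (precipitation tracks R_h, biomass tracks LAI,
temperature tracks zone) are generated with those correlations so the
attribution methods face realistic collinearity.

Enzyme, biomass and nutrient pools are then derived per row by exact
inversion of the stoichiometric model: the common scalar
s = K·q/(1 − q) with q = cue/CUE_max, biomass/resource ratios drawn
lognormally around microbial C:N ≈ 8, C:P ≈ 60 and soil C:N ≈ 12,
C:P ≈ 186 (common soil-stoichiometry centres — generator conveniences,
not claims), and enzyme ratios solving s = (B/L)/EEA exactly. Running
the forward estimator on the generated pools therefore reproduces each
row's CUE to ~1e-16, which is what makes the stoichiometry module
testable end-to-end.

What the generator does **not** emulate: per-study methodological
heterogeneity, spatial autocorrelation, temporal mismatch between CUE
and flux sampling, non-Gaussian measurement error in the pools, and any
real geographic covariate structure. Passing tests on this generator
demonstrate that the estimators recover known structure under realistic
noise and collinearity — not that the same numbers would emerge from a
real compilation.

All randomness flows from one `numpy.random.default_rng` (PCG64) seed;
the pipeline derives per-stage streams by `SeedSequence.spawn` in a
fixed order, so identical configs give identical outputs on any
platform with the pinned numpy generation algorithm.

## Problem sizes and tolerances

Analytic identities (inversion round trip, Akaike-weight normalisation,
partition identity, partial-correlation equivalence) are asserted at
1e-10–1e-12. Simulation-based checks use: 10⁴ random draws for the
estimator properties; exhaustive-oracle comparison at n ≤ 200;
100 replicate datasets with 200 bootstrap resamples each for breakpoint
CI coverage (percentile CIs are stable well below 1000 resamples, which
remains the analysis default); 50 replicates for planted-driver
recovery; 100 replicates for median breakpoint-recovery error. The
default bootstrap (1000) and removal (1000) repetition counts are used
by the pipeline and acceptance script.

## Known limitations

Single breakpoint only (no multiple-threshold search, no Davies test
for breakpoint existence); Gaussian working model for the stratum fits;
fixed-effects approximation to mixed-model selection; no spatial or
phylogenetic error structure; the daily-flux column in the synthetic
table is a deterministic rescaling of the annual flux rather than an
independently-sampled growing-season series.
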