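# Methods

## Scope and data model

The package analyses ring-level stable-isotope chronologies from a network
of monitored forest stands. A *stand* (site × species) is the unit of
replication; its chronology mixes annual rings (here 1995–2010) with
3-ring pooled samples (1980–1994), closed intervals on calendar years.
Pooled samples are dated to their **central year** for every regression and
model fit. The pooling convention (mass-weighting within a pool) is unknown
in general; central-year dating is unbiased under a locally linear trend
and is the package-wide convention. Missing isotope values propagate as
missing and are dropped per analysis, never imputed.

All tables are plain CSV (UTF-8, "." decimal, empty cell = missing). Floats
are written with `repr` and read with round-trip parsing so write→read is
bit-exact.

## Physiology equations

Discrimination, c_i, iWUE and Δ18O follow the simplified discrimination
model with a = 4.4 ‰, b = 27 ‰ and the 1.6 H2O:CO2 diffusivity ratio;
mesophyll conductance, photorespiration, Péclet leaf-water mixing and
post-photosynthetic offsets are out of scope. Two printed forms of the
c_i equation circulate: one with the raw difference δ13C_a − δ13C_w, one
with the full Δ13C including the (1 + δ13C_w/1000) denominator. The
package uses the **full Δ13C consistently** in both c_i and iWUE so the
identity iWUE ≡ (c_a − c_i)/1.6 holds to machine precision (asserted at
1e-9); the difference between conventions is below 3 %. Δ13C outside
[a, b] (c_i/c_a outside [0, 1]) is flagged with a warning, never clipped:
transparency over silent correction.

For each ring record, c_a and δ13C_a are growing-season means matched to
the record's years; a pooled record uses the mean over its 3-year
interval. Precipitation δ18O is computed annually per site from that
year's mean temperature and precipitation (precipitation in metres — the
code warns if a value looks like millimetres) with elevation constant; it
stands in for source (soil) water unless measured values are supplied.

The packaged atmospheric table (1980–2010 growing-season c_a and δ13C_a)
is a synthetic emulation of the published records — a smooth fit rising
339→390 ppm with the observed acceleration and a matching Suess decline —
and is user-overridable for replication work.

## Climate features

Monthly station data reduce to annual means/sums and growing-season
(May–September, configurable) means. VPD uses the Tetens saturation curve
over liquid water applied to monthly maximum temperature and minimum
relative humidity — the standard choice where no formula is prescribed.
Growing-season precipitation is reported in cm so trend slopes are
comparable at the conventional table scale.

Two PCAs summarise the climate space after centering and scaling:
*spatial* (globally centered long-term site means; default retention
cumulative variance ≥ 0.90) and *annual* (group-centered within site;
retention ≥ 0.78). Group centering removes the between-site signal so the
annual axes are pure anomalies; global vs group centering also
de-confounds site-level from year-level covariates in the mixed models.
The retention thresholds stand in for scree-plot inspection and default to
values that retain 2 spatial and ~4 annual components on data of this
shape. Component signs are fixed (largest-magnitude loading positive) for
reproducible reporting; signs are statistically arbitrary. The annual PCA
variable list (temperature, precipitation, VPD, annual + growing-season,
plus the five SPEI windows) is configurable.

Deposition covariates are split by design: *spatial* covariates (sN_dep,
sS_dep) are per-site means of total (wet + dry) deposition over the
monitoring period; *annual* covariates (aN_dep, aS_dep) are yearly wet
fluxes only, available from 1995, so model variants including them fit on
the annual-resolution subset.

## Trends

Per-site trends are closed-form OLS against calendar year with t-test
p-values and star codes; deposition variables are restricted to the
1995–2010 monitoring window, isotope-derived series use the full
chronology at representative years. Autocorrelation is deliberately not
corrected here (it is handled by the mixed models); an exactly flat series
reports p = 1, an exact non-zero linear fit reports SE 0 with p given as a
"<1e-12" bound rather than dividing by zero.

## Mixed models

The attribution model is y = Xβ + b_g + ε with a random intercept per
stand and AR(1) residual correlation φ^|Δt| in the representative year, so
3-ring pools decay as φ³ (the power-of-φ approximation for gapped lags).
Estimation is REML with the error variance profiled out, leaving a
two-parameter Nelder–Mead search over (arctanh φ, log σ_b²/σ_e²) from two
starts; groups sharing a time grid share one Cholesky factor per
likelihood evaluation. The fit matches R `nlme::lme` with `corAR1` to
≈ 1e-4 on all reported quantities (tested). ML refits serve
likelihood-ratio χ²(1) comparisons of nested fixed structures. Degenerate
fits (variance ratio < 1e-6) report σ_b = 0 with a flag. R²m/R²c use the
variance-components decomposition with the fixed-effects variance taken as
the population variance of the fixed linear predictor.

Backward simplification removes, one at a time, the least significant
non-protected term until all remaining are significant at α = 0.05
(configurable). Significance is judged on single-step Šidák-adjusted Wald
p-values with the family size fixed at the initial number of candidate
terms — the family-wise analogue of simultaneous general-linear-hypothesis
testing, and the reason the procedure keeps ≈ 95 % specificity under a
global null instead of the ≈ 74 % that raw sequential Wald elimination
would give with six candidates. `adjust="none"` restores raw elimination.
The conifer-vs-deciduous contrast (and the intercept) are never removed.
The row set is frozen at the initial model's complete cases so every
elimination step fits the same observations. All covariates are centered
before fitting; centering changes only the intercept (tested).

## Path model and directed separation

Endogenous nodes reuse the mixed-model family verbatim (same random
intercept, same AR(1)), so path coefficients and the attribution tables
are mutually consistent. The basis set contains one claim per non-adjacent
pair, conditioned on the **union of both nodes' parents** (the convention
is stated explicitly because variants exist); the causally later node is
the regression response. Pairs with declared correlated errors are
excluded, as are exogenous-exogenous pairs (exogenous inputs such as
orthogonal PCA axes carry no modelled dependence). Each claim's p-value is
the Wald test of the missing predictor added to the response's component
model; Fisher's C = −2 Σ ln p with df = 2k; an empty basis set is the
saturated model (C = 0, p = 1). Standardized coefficients are
β·sd(x)/sd(y) on the analysis table after exclusions.

## Synthetic generator

The generator emulates the study conditions, not any particular dataset:
12 stands of four species at 10 locations along a South–North gradient
(site mean T 8.1–10.5 °C, P 527–1161 mm), monthly climate with a seasonal
cycle, a 0.03 °C yr⁻¹ warming trend and AR(1) annual anomalies; SPEI as
standardized multi-month precipitation-minus-PET anomalies of that same
climate (the full SPEI algorithm is out of scope — only the anomaly
structure matters downstream); wet deposition monitored from 1995 with
linear declines (−0.25 kg N, −0.30 kg S ha⁻¹ yr⁻²) around site means
spanning the 10–12 kg N ha⁻¹ yr⁻¹ critical-load band; c_a linear 339→390
ppm with a matching δ13C_a decline.

True iWUE is built directly from the drivers — species base level, random
stand intercept (σ = 3.5), β_ca = 0.20 per ppm, standardized spatial and
annual climate indices (β = −2.65, −0.65), spatial S deposition
(β = −0.47), an extra −1.0 µmol mol⁻¹ yr⁻¹ stand-development trend for
Sitka spruce, and AR(1)(φ = 0.5, σ = 3) noise — then inverted through the
discrimination equations to wood δ13C. Pooled records are the mean of
their three latent annual δ values; measurement noise (0.1 / 0.3 / 0.2 ‰
for δ13C / δ18O / δ15N) is added after pooling. δ15N is a site mean with
optional trend, deposition coupling and AR(1) noise (its ecological
inference is correlative, so no process N-cycle model), with wood %N
weakly coupled. A configuration whose effects push > 1 % of latent Δ13C
outside (0, b) is rejected outright.

With these defaults the non-spruce species gain ≈ 10–15 % iWUE over
1980–2010 (driven by c_a and deposition) and Sitka spruce loses ≈ 20 % —
the same direction and order of magnitude as the published network, though
not matched per species: exact matching would require unmodelled trends
collinear with c_a, which would defeat the parameter-recovery validation.
One seed feeds a stream-split RNG (one child stream per latent process in
fixed order), so identical configuration + seed gives byte-identical
tables and adding a table never perturbs earlier ones.

Presets: `null` (gradients and noise, zero effects), `paper-like`
(defaults above), `age-confounded` (youngest spruce stand starts at its
1981 planting with a −2 µmol mol⁻¹ yr⁻¹ early-stand decline, attenuating
the fitted CO2 effect when included).

## What passing tests do and do not show

The validation experiments measure the pipeline against its own synthetic
truth: equation-oracle agreement (1e-10), generator→physiology round trip
(1e-9 pre-noise), ≥ 95 % 2-SE coverage of β_ca with |median φ bias| < 0.1
across 100 regenerated studies, 2–9 % empirical rejection of
true-by-construction d-separation claims with uniform Fisher-C p-values,
and ≥ 90 % full driver removal under the null scenario. They demonstrate
the statistical machinery is calibrated and the plumbing is exact; they do
not certify the physiological assumptions (constant fractionation
parameters, precipitation δ18O as source water, no pool mass-weighting) on
real chronologies, where species- and site-specific violations are
expected.

## Numerical choices and limitations

Perfect trend fits, degenerate random effects and constant covariates are
handled explicitly (flags and errors, not NaNs). The recovery experiments
run at the study's own scale (12 stands × 31 years; 100 seeds) to keep the
whole suite fast on a single CPU. Known limitations: no random slopes or
crossed random effects; no latent-variable or covariance-based SEM; no
breakpoint trends; SPEI and dry-deposition estimates are ingested, never
computed; the elimination path of a backward simplification is not unique
and only the final model structure is interpreted.
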