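# isoring

Tree-ring multi-isotope analysis for forest ecophysiology: derive intrinsic
water-use efficiency (iWUE), c_i/c_a and oxygen-isotope discrimination from
δ13C / δ18O chronologies, quantify per-site temporal trends, and attribute
spatial and temporal variation to climate and atmospheric-deposition drivers
with dual principal-component analyses, AR(1) linear mixed models and a
d-separation (piecewise structural-equation) path model. A synthetic
multi-site generator with stored latent truth makes every stage testable
without any data download.

## Who it is for

Dendroecologists and biogeochemists working with ring-level stable-isotope
chronologies (δ13C vs VPDB, δ18O vs VSMOW, δ15N vs air N2) across networks of
monitored forest stands, who want a reproducible path from raw chronology
tables to driver-attribution statistics.

## The science in brief

Carbon-isotope discrimination of wood follows the simplified Farquhar model
(no mesophyll-conductance or photorespiration terms):

    Δ13C = (δ13C_a − δ13C_w) / (1 + δ13C_w/1000) = a + (b − a)·c_i/c_a

with a = 4.4 ‰ (stomatal diffusion) and b = 27 ‰ (Rubisco carboxylation).
Inverting gives intercellular CO2 and intrinsic water-use efficiency,

    c_i  = c_a (Δ13C − a)/(b − a),
    iWUE = A/g_s = (c_a − c_i)/1.6 = (c_a/1.6)·(b − Δ13C)/(b − a),

where 1.6 is the H2O:CO2 stomatal diffusivity ratio and c_a, δ13C_a are
growing-season (May–September) atmospheric means. Oxygen-isotope
discrimination of wood relative to source water,

    Δ18O = (δ18O_w − δ18O_s) / (1 + δ18O_s/1000),

uses modelled precipitation δ18O as the source proxy,
δ18O_P = 0.52 T − 0.006 T² + 2.42 P − 1.43 P² − 0.046 √E − 13.0
(T mean annual °C, P annual precipitation in **metres**, E elevation in m).

Attribution models are linear mixed models with a site × species random
intercept and an AR(1) residual correlation in the ring year, fitted by
REML; fixed effects combine a conifer-vs-deciduous contrast, spatial and
annual climate PCA scores, c_a and deposition covariates, backward-simplified
to the minimal significant model. Marginal/conditional R² follow the
variance-components decomposition (fixed vs fixed+random over total). The
joint structure is expressed as a confirmatory path model; its missing edges
are tested by directed separation and combined via Fisher's
C = −2 Σ ln p ~ χ²(2k).

## Worked example

```python
import dataclasses
from isoring import (carbon_discrimination, iwue, scenario_presets,
                     generate_dataset, assemble_analysis_table, fit_lmm)
from isoring.pipeline import default_model_variants

# one equation by hand
d = carbon_discrimination(-8.3, -26.0)   # 18.172 per mil
w = iwue(390.0, d)                       # 95.21 umol CO2 / mol H2O

# a full synthetic study: 12 stands, 1980-2010, 3-ring pools before 1995
cfg = dataclasses.replace(scenario_presets()["paper-like"], seed=1)
ds = generate_dataset(cfg)
analysis, _ = assemble_analysis_table(
    ds.isotopes, ds.climate_monthly, ds.deposition,
    ds.spei, ds.sites, ds.atmosphere)
model = fit_lmm(default_model_variants()["ii"], analysis)  # no Sitka spruce
print(model.summary().loc[["pft", "pca1", "ca"]].round(3))
```

prints (seed 1):

```
      estimate     se      z  p_value stars
pft     17.785  5.563  3.197    0.001    **
pca1     0.332  0.084  3.929    0.000   ***
ca       0.182  0.019  9.495    0.000   ***
```

i.e. conifer stands run ≈ 18 µmol mol⁻¹ higher in iWUE than deciduous ones,
iWUE responds to the first annual climate axis, and each ppm of CO2 adds
≈ 0.18 µmol mol⁻¹ — bracketing the generating coefficient 0.20 within two
standard errors. The same study can be run end to end from the shell:

```sh
isoring run-all --preset paper-like --seed 1 --out results/
```

which writes the trend table, PCA loadings, the four model variants
(all-sites / no-spruce × with/without annual deposition), the d-separation
claim table with Fisher's C, and a manifest. `isoring replicate --in DIR`
runs the identical pipeline on a user-supplied copy of a deposited
chronology dataset, using the packaged (synthetic, user-overridable)
atmospheric c_a/δ13C_a table unless one is provided.

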