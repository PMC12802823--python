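# soilcue

Soil microbial carbon use efficiency (CUE) — the fraction of assimilated
carbon that microbes allocate to growth rather than respire — is a key
control on soil carbon storage, but its relationship to heterotrophic
respiration (R\_h) is not simply linear. `soilcue` is a Python toolkit for
analysing that relationship the way global syntheses of ecoenzymatic data
do: it estimates CUE from enzyme/biomass/resource stoichiometry, converts
respiration fluxes between unit conventions, locates the respiration
threshold above which CUE decouples from R\_h, attributes the CUE/R\_h
ratio to environmental drivers, and stress-tests every conclusion with
bootstrap and random-removal procedures. It is aimed at soil ecologists
and biogeochemists working with site-level compilations of enzyme assays
and respiration fluxes.

## The model

CUE is estimated from the stoichiometric (biogeochemical-equilibrium)
model. With BG, NAG, LAP and AP the potential activities of the terminal
C-, N- and P-acquiring extracellular enzymes,

    EEA_C:N = BG / (NAG + LAP)          EEA_C:P = BG / AP
    S_C:N   = (B_C:N / L_C:N) / EEA_C:N
    S_C:P   = (B_C:P / L_C:P) / EEA_C:P

    CUE_ST = CUE_max * sqrt( (S_C:N * S_C:P)
                             / ((K_C:N + S_C:N) * (K_C:P + S_C:P)) )

where B are molar microbial-biomass ratios (MBC:MBN, MBC:MBP), L are
molar resource ratios (SOC:TN, SOC:TP), K\_C:N = K\_C:P = 0.5 are
half-saturation constants and CUE\_max = 0.6 the thermodynamic ceiling.
The geometric mean of the two Michaelis–Menten terms keeps CUE\_ST in
(0, CUE\_max).

The CUE\_ST–R\_h threshold ψ is the breakpoint of the continuous
two-segment linear model `cue = a + b₁·rh + b₂·max(0, rh − ψ)`, found by
exhaustive profiled least squares and assessed with a 1000-rep pairs
bootstrap. Driver attribution enumerates all 2⁹ main-effects linear
models over nine environmental predictors, scores them by AICc, and sums
Akaike weights per predictor (essential at ≥ 0.8); partial correlation
and adjusted-R² variation partitioning examine the four key variables.

## Worked example

Everything runs on synthetic data with the structure of a global
compilation (1094 sites, four climate zones, a breakpoint at
340 g C m⁻² yr⁻¹ with plateau CUE 0.27):

```python
from soilcue import (SyntheticConfig, generate_paired_dataset,
                     SegmentedRegression, fit_stratified_glm)

data = generate_paired_dataset(SyntheticConfig(seed=11))
model = SegmentedRegression.from_dataframe(data, x="rh_annual_area",
                                           y="cue_true")
result = model.fit()
boot = result.bootstrap_ci(n_boot=1000, seed=11)
print(result.summary())
print(f"  bootstrap: psi SD = {boot.psi_se:.1f}, "
      f"95% CI [{boot.psi_ci_low:.0f}, {boot.psi_ci_high:.0f}]")
print(fit_stratified_glm(data, "productivity_class",
                         x="rh_annual_area", y="cue_true").to_string(index=False))
```

prints

```
Segmented regression (continuous two-segment linear model)
  n = 1094   breakpoint psi = 342.6
  threshold detected: True
  slope pre  = -3.1041e-04  (n=559, R2=0.050, p=1.01e-07)
  slope post = -3.1857e-06  (n=535, R2=0.000, p=0.735)
  SSE = 10.3523   (single line: 10.9009)
  bootstrap: psi SD = 33.4, 95% CI [303, 424]
stratum   n     slope  intercept       r2            p skipped
   high 502 -0.000003   0.279870 0.000155 7.811311e-01
    low 592 -0.000149   0.357314 0.060466 1.330576e-09
```

The fitted breakpoint (342.6) recovers the generating threshold of 340;
below it CUE declines significantly with R\_h, above it the slope is
indistinguishable from zero — CUE and respiration decouple. The
stratified fits show the same contrast between low-productivity
(leaf area index < 3) and high-productivity ecosystems.

The same analyses are available from the shell:

```sh
soilcue simulate --seed 11 --out paired.csv
soilcue threshold --input paired.csv --y cue_true --n-boot 1000 --seed 11 --out threshold.json
soilcue run-all --input paired.csv --seed 11 --out-dir results/
```

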