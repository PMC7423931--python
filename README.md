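# snowflux

Late-winter soil microbial respiration near Arctic treeline is hard to
measure and easy to misattribute: under a seasonal snowpack, CO₂ efflux
depends jointly on soil temperature and on how much readily decomposable
("labile") carbon is left for microbes after months of winter activity.
`snowflux` is a Python package for the complete analysis chain used to
separate these controls:

1. **Snowpack diffusion-gradient flux estimation** — CO₂ efflux from
   two-point concentration gradients through a snowpack characterized by
   pit-profile density and temperature:

   *J*<sub>c</sub> = θ·τ·D·(P₀/RT₀)·(T/T₀)<sup>0.81</sup>·ΔC/z

   with porosity θ = 1 − ρ/973, tortuosity τ = θ<sup>1/3</sup>,
   D = 0.1381×10⁻⁴ m²/s, P₀/RT₀ = 44.613 mol/m³, snowpack temperature
   *T* (K), mixing-ratio difference ΔC (µmol/mol) and snow depth *z* (m);
   the result is in µmol·m⁻²·s⁻¹.
2. **Q₁₀ temperature-response fits** — flux = *A*·*B*<sup>(T+5)/10</sup> per
   winter by nonlinear least squares, with Monte Carlo confidence intervals
   for predictions at a common reference temperature (drawing parameter
   vectors from the asymptotic covariance at the optimum).
3. **Glucose-addition ANCOVA** — paired-plot field experiment:
   ln(flux<sub>post</sub>) on ln(flux<sub>pre</sub>), site and treatment,
   with site×treatment and pre×treatment interaction screening at α = 0.05;
   exp(β₄) is the multiplicative effect of adding ~100 g C/m² as glucose.
4. **Incubation analyses** — 90-day jar incubations across sub-zero to
   above-zero temperatures crossed with cellobiose additions: a
   random-intercept linear mixed model of log respiration on temperature,
   C addition, date and their interactions, plus per-analyte
   temperature × C-addition regressions for endpoint nutrient availability
   (NO₃⁻-N, NH₄⁺-N, total free primary amines, PO₄-P), with fixed
   detection-limit substitution rules.
5. **A ground-truth synthetic study generator** — every input table the
   pipeline reads can be simulated from a first-order labile-pool depletion
   mechanism with known parameters, so each estimator is testable for
   parameter recovery without any field data.

It is aimed at ecosystem biogeochemists working with winter flux and
incubation data, and at anyone who needs a tested, reproducible reference
implementation of the diffusion-gradient method.

## Worked example

Simulate a three-winter field campaign and the glucose experiment, then run
the chain:

```bash
snowflux simulate field   --seed 42 --out-dir demo
snowflux simulate glucose --seed 42 --out-dir demo
snowflux flux --pits demo/snow_pits.csv --gradients demo/gradients.csv --out demo/fluxes.csv
snowflux q10 --fluxes demo/fluxes.csv --group-by year --predict-at -3 \
    --seed 20190301 --out demo/q10_fits.csv
snowflux ancova --in demo/paired_plots.csv --out demo/ancova.json
```

which prints

```
wrote 144 fluxes to demo/fluxes.csv
wrote 3 Q10 fits to demo/q10_fits.csv
treatment F(1, 25) = 152.62, p = 3.84e-12; effect ratio 2.21
```

and `demo/q10_fits.csv` contains the per-winter fits and −3 °C predictions:

```
year,a_hat,b_hat,n,converged,point,lower,upper,seed
2017,0.76818438096,2.31973279594,48,True,0.908977357553,0.803643247515,1.01517284945,20190301
2018,0.288938248395,2.64573017242,48,True,0.351005681125,0.326354562873,0.372093618873,20190301
2019,0.357703626131,2.22927344177,48,True,0.419909800656,0.391544011636,0.44526483684,20190301
```

Read: `a_hat` is the estimated flux at −5 °C (µmol·m⁻²·s⁻¹), `b_hat` the
Q₁₀ factor, and `point` (`lower`, `upper`) the −3 °C prediction with its 95%
Monte Carlo interval. The simulated cold winter (2017, generated with
A = 0.8) shows ~2.6× the −3 °C flux of the warm winters (A = 0.3/0.35) with
non-overlapping intervals — the depleted-substrate signature the pipeline is
built to detect. The ANCOVA effect ratio 2.21 recovers the generator's
glucose effect of 2.225: respiration roughly doubles when labile C is added,
i.e. late-winter microbes were not purely temperature-limited.

The same stages are available as library functions
(`snowflux.compute_fluxes`, `fit_q10`, `mc_interval`, `fit_ancova`,
`fit_respiration_lmm`, `fit_nutrient_regression`, …) and as a single
configured run (`snowflux run --config pipeline.yaml`).

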