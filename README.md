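# perohr

Multi-factor analysis of deer-mouse (*Peromyscus*) space use from
trap-grid capture data.

Live-trapping on standardized grids is the workhorse of small-mammal
ecology, but single-site studies rarely have the replication to ask how
several influences on space use act *simultaneously*. `perohr` implements
the full chain from raw trap-night capture records (NEON small-mammal
dialect) to that question's answer:

1. **Cleaning** — genus-level taxon filters, implausible-measurement rules,
   habitat grouping, metric trap positions;
2. **Phenotypes** — per-individual sex (majority vote with pregnancy
   override), size class, mass-threshold life stages with forward
   propagation, and body condition (mass-on-hindfoot OLS residual within
   size class);
3. **Density** — per-plot minimum number known alive (MNKA) and each
   animal's meanMNKA over its own capture window;
4. **Home ranges** — kernel utilization distributions with the reference
   bandwidth h = σ_pooled·n^(−1/6) for animals with ≥5 adult captures at ≥3
   traps; the home range is the 50% isopleth area (m²), plus MCP and a
   rarefaction analysis of estimator stability;
5. **Modelling** — gamma log-link mixed models with crossed site and year
   random intercepts, fitted by Laplace-approximated maximum likelihood:

   A_i ~ Gamma(α, μ_i), log μ_i = x_i'β + u_site(i) + v_year(i),

   compared over a 12-model ladder by Akaike weight, with Wald deviance
   tables, Tukey-style habitat contrasts and prediction curves.

Because the observational target data are an external archive, the package
ships a first-class synthetic study generator (`perohr.synthetic`) that
emulates the sampling design — 1-ha 10×10 trap grids, 1- or 3-night bouts,
juvenile growth, pregnancy episodes, sex misrecordings, missing masses —
with the true generating model known, so every stage is testable end to end.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

```sh
python analysis/01_simulate_study.py --seed 1   # synthetic capture study
python analysis/02_clean_captures.py
python analysis/03_phenotypes_and_density.py
python analysis/04_home_ranges.py
python analysis/05_model_selection.py
python analysis/06_rarefaction.py --seed 0
```

The simulated study (8 sites × 3 plots × 3 years) prints:

```
1375 target individuals, 1338 ever captured, 5708 capture rows
true 50% areas: mean 1461 m^2, SD 1119, range 15.5-10137.2
```

Cleaning removes 203 records (non-target genera, monogamous congeners, one
implausibly light individual); phenotyping finds 1,337 individuals (712
male, 612 female, 13 unknown) with meanMNKA 13.9 ± 5.8. Home-range
estimation accepts 438 of 1,287 individuals under the 5-capture/3-trap rule:

```
50% kernel areas: mean 1107 m^2, SD 952, range 44.0-5805.0
vs truth (n=438): median signed rel err -32.2%, median |rel err| 41.5%
```

(the signed bias is grid truncation: ranges larger than the 1-ha grid are
clipped — see the methods note). Model selection then ranks the ladder:

```
             model      aic  delta_aic  weight
m09_sexcond_habden 6943.889      0.000   0.430
       m11_all2way 6945.136      1.247   0.231
          m12_full 6945.631      1.742   0.180
...
     m01_intercept 6958.652     14.762   0.000
```

An interaction model wins: at this desk scale the sex×condition interaction
(χ² = 8.03, p = 0.005) and habitat (χ² = 13.9, p = 0.001) are detected
while weaker effects are attenuated by estimation noise. The habitat
contrasts reproduce the field-expected ordering, with the compact letter
display marking grassland ranges larger than forest ones and shrubland
intermediate:

```
   grassland - forest    0.3766 0.1080 3.4857      0.0014
   shrubland - forest    0.2281 0.0991 2.3030      0.0546
grassland - shrubland    0.1484 0.1230 1.2065      0.4464
letter display: {'forest': 'a', 'grassland': 'b', 'shrubland': 'ab'}
```

The rarefaction run shows why five captures is a defensible minimum for the
kernel estimator and not for the convex polygon:

```
at five relocations: KDE bias -2.6%, MCP bias -50.0%
```

A single-command equivalent of steps 2–5 is `perohr.pipeline.run_all`,
driven by a `RunConfig` (YAML-serializable); it writes every stage's CSV, a
run log and a manifest with the config hash.

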