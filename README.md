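# burden-of-proof

Dose–response meta-analysis with conservative, heterogeneity-aware evidence
grading.

Epidemiologists synthesizing the risk of an exposure (here: smoking, in
pack-years or cigarettes per day) on a health outcome face studies that report
relative risks (RR/OR/HR) over incompatible exposure categories, with
different reference groups, uneven quality, occasional gross outliers and
possible publication bias.  Classical random-effects meta-analysis forces
log-linearity and understates uncertainty when studies disagree.  This package
implements the burden-of-proof approach end to end:

1. **Signal estimation** — the shape s(x) of log RR against exposure is fitted
   by a weighted ensemble of cubic splines with random knot placement, each
   member fitted by inverse-variance weighted, monotonicity-constrained least
   squares to *ranged* observations (each RR constrains the difference of the
   interval-averaged curve between its alternative and reference exposure
   ranges), with 10% of observations trimmed as outliers.
2. **Bias covariates** — study-quality covariates (the six GRADE risk-of-bias
   domains, subpopulation sampling, adjustment level) are tested as
   interactions with the signal, selected by a study-grouped Lasso plus
   significance in the mixed-model refit, and predictions are made at the
   gold-standard reference level.
3. **Between-study heterogeneity** — a linear mixed model
   `y_i = β s_i + Σ_k c_k z_ik s_i + u_j + v_j s_i + ε_i` with study random
   intercepts u_j ~ N(0, τ²) and random slopes v_j ~ N(0, γ) on the signal;
   the sampling uncertainty of γ is taken from the Fisher information and the
   inflated value γ* = γ̂ + 2·SD(γ̂) protects against the small-study
   underestimation of heterogeneity.
4. **Publication bias** — a modified funnel pairs fixed-effect residuals with
   the heterogeneity-inclusive SD √(se² + γ* s²); Egger's regression flags
   (but does not correct) asymmetry.
5. **Evidence grading** — 1,000 draws β_d ~ N(β̂, var(β̂) + γ*) give the mean
   risk curve with 95% UI; the **BPRF** (burden-of-proof risk function) is the
   quantile curve closest to the null (5th for harmful, 95th for protective
   risks); the **ROS** (risk–outcome score) is the signed log-BPRF averaged
   between the 15th and 85th percentiles of observed exposure; stars grade it
   (1: ROS < 0, 2: 0–0.14, 3: >0.14–0.41, 4: >0.41–0.62, 5: >0.62).  Binary
   exposures halve their ROS for comparability.
6. **CVD age attenuation** — for cardiovascular outcomes the reference curve
   is mapped to its precision-weighted reference age group, an age pattern of
   excess risk (RR − 1) is fitted from age-specific binary-smoking RRs, and
   draw-level attenuation factors adjust the curve per 5-year age group via
   `RR_age = (RR_ref − 1)·AF_age + 1`.

A seeded synthetic-data generator (`burden_of_proof.synthetic_data`) emulates
every feature the pipeline assumes — ranged and open-ended exposure
categories, between-study heterogeneity, bias shifts, ~10% outlier
contamination, optional small-study censoring, binary pairs, and age-specific
CVD tables — so each stage is testable against known ground truth.

## Worked example

Simulate a harmful pair with a saturating dose–response shape, then run the
six-stage pipeline:

```bash
cat > truth.json <<'EOF'
{"curve_family": "log_quadratic_saturating",
 "curve_params": {"slope": 0.08, "saturation": 60},
 "n_studies": 40, "obs_per_study": 4,
 "gamma": 0.02, "tau2": 0.01, "outlier_fraction": 0.1, "seed": 42}
EOF
cat > pair.json <<'EOF'
{"outcome_name": "demo outcome", "exposure_measure": "pack_years",
 "direction": "harmful", "monotone": "nondecreasing", "seed": 42}
EOF
bop simulate --config truth.json --out data.csv --truth truth_record.json
bop run --data data.csv --config pair.json --out results/
```

which prints

```
wrote 160 observations to data.csv
demo outcome: ROS=1.176 stars=5 avg BPRF=3.240 pub bias=no (outputs in .../results)
```

`results/summary.json` holds the full record; the headline numbers mean:

- `ros = 1.176`, `stars = 5`: even the most conservative reading of the
  evidence (the BPRF) implies average exposure multiplies risk by
  `exp(1.176) ≈ 3.24` — an average 224% increase across the 15th–85th
  percentile exposure window (6.4–40.9 pack-years), i.e. very strong evidence.
- `table_row.csv` reports the mean RR with UI at doses 5/10/20/40/p85, e.g.
  RR 3.66 (2.93–4.63) at 20 pack-years.
- the heterogeneity block records γ̂ = 0.0031 with SD(γ̂) = 0.0025, so the UI
  and BPRF were computed with γ* = 0.0082.
- `pub_bias_flag = false`: Egger's test found no funnel asymmetry
  (`funnel.csv` has the residual/total-SD pairs for plotting).

The same entry points are available in Python as
`burden_of_proof.run_pair(data, config)`; see the docstrings of
`signal_model`, `heterogeneity`, `evidence` and `cvd_age` for the library
surface, and `docs/methods.md` for the model, its assumptions and numerical
choices.

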