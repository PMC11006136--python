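# isoprov

Dual-isotope geographic provenance and diet analysis for cervid hard
tissues: a tested, reusable Python implementation of the
⁸⁷Sr/⁸⁶Sr + δ¹⁸O isoscape-assignment workflow, with δ¹³C Suess-effect
correction for diet studies.

## Who this is for

Movement ecologists, archaeologists and isotope geochemists who have (a) a
compilation of bioavailable ⁸⁷Sr/⁸⁶Sr point samples and environmental
predictor rasters, (b) a precipitation δ¹⁸O surface, and (c) a table of
tissue samples (bone/antler) with measured ⁸⁷Sr/⁸⁶Sr, carbonate δ¹⁸O and
δ¹³C, and who want to ask: *which individuals died where they lived, and
where did the others come from?*

## The method

1. **Sr isoscape** — random-forest regression of bioavailable ⁸⁷Sr/⁸⁶Sr on
   environmental predictor rasters (geochemical prior model, elevation,
   sea-salt/coast proxies, climate), with held-out permutation importance for
   predictor selection, 10-fold cross-validation (pooled RMSE and
   R² = 1 − SSres/SStot), and a quantile-regression-forest uncertainty map:
   per cell, half the (q₀.₈₄ − q₀.₁₆) spread of the terminal-node response
   distribution, a ~68% half-interval.
2. **Tissue conversions** — carbonate δ¹⁸O (VSMOW) → phosphate
   (δ¹⁸Oc = 1.037·δ¹⁸Op + 8.57, inverted) → drinking-water equivalent (deer
   phosphate–water relation, constants in a cited YAML config); VPDB↔VSMOW
   inter-scale conversion; δ¹³C corrected for the atmospheric Suess effect to
   a reference year (default 1994, 1800 supported) via a LOESS fit of an
   atmospheric CO₂ δ¹³C record.
3. **Local/non-local classification** — per sample, the deltas
   Δ = tissue value − isoscape value (10-km buffered great-circle mean) on
   both isotope axes; samples outside 1σ of either Δ distribution
   (single-pass mean ± SD over all samples) are non-local. A radius scan
   (OLS of sample on buffered isoscape value, max R², smallest-radius
   tie-break) supports choosing the buffer.
4. **Calibration** — OLS of tissue value on isoscape value over the locals,
   applied cell-wise; calibration residual scatter is propagated into the
   uncertainty map in quadrature.
5. **Bayesian assignment** — for each non-local, a posterior
   probability-of-origin surface P(cell | z) ∝ N(z; m(cell), s(cell)) under a
   flat prior, the Sr × O joint posterior (conditional independence),
   top-quantile origin regions, and the distribution of posterior mass over
   great-circle distance from the death site.

A synthetic-landscape generator with known ground truth (geology-unit Sr
field with spatially correlated noise, latitude/elevation-driven δ¹⁸O field,
individuals with known origins and displacement, smooth declining
atmospheric δ¹³C record) backs end-to-end recovery experiments.

## Worked example

```python
from isoprov.synthetic import make_landscape, sample_training_points, simulate_individuals
from isoprov.isoscape import select_predictors, fit_isoscape, cross_validate, \
    predict_surface, load_oxygen_isoscape
from isoprov.locality import compute_deltas, classify_local

truth = make_landscape(seed=1, n_rows=100, n_cols=100, n_geo_units=4, sr_noise_sd=0.002)
training = sample_training_points(truth, 400, meas_noise_sd=0.002, seed=2)
predictors = select_predictors(training, truth.predictor_stack, seed=3)
model = fit_isoscape(training, truth.predictor_stack, predictors, n_trees=1000, seed=3)
cv = cross_validate(training, truth.predictor_stack, predictors, k=10, seed=3)
print(predictors, round(cv.r2, 3), round(cv.rmse, 5))

surface = predict_surface(model, truth.predictor_stack)
o_surface, o_error = load_oxygen_isoscape(truth.o_field, constant_sd=1.0)
herd = simulate_individuals(truth, 200, frac_nonlocal=0.15,
                            displacement_km=3 * truth.correlation_length_km, seed=5)
deltas = classify_local(compute_deltas(herd, surface, o_surface, radius_km=10.0))
print(int(deltas.per_sample["local_flag"].sum()), "of", len(deltas.per_sample), "classified local")
```

prints

```
['geo_proxy'] 0.961 0.00233
139 of 200 classified local
```

meaning: predictor selection kept the geochemical prior-model proxy (the
informative layer), the cross-validated isoscape explains 96.1% of the
training variance with an RMSE of 0.0023 (the injected noise level), and the
1σ rule retains 139/200 individuals as compatible with their death site
(the herd contains 170 true locals).

The same pipeline runs from the shell:

```sh
isoprov run-all --seed 1 --outdir pipeline_out    # all 7 stages + manifest
isoprov simulate --seed 1 --outdir syn            # or stage by stage
isoprov classify --samples syn/individuals.csv \
    --sr-isoscape syn/sr_field.asc --o-isoscape syn/o_field.asc \
    --radius 10 --out deltas.csv
```

Rasters are exchanged as ESRI ASCII grids (`.asc`) with a JSON sidecar
carrying CRS and provenance metadata.

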