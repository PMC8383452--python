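# spatepi

Small-area disease mapping for registry epidemiology: standardized incidence
ratios, spatial cluster detection, and Bayesian BYM smoothing with
ecological covariates.

## The problem

Cancer registries report case counts over small geographic areas (GAs).
Three questions recur in such studies — here, prostate-cancer incidence
stratified by clinical risk level (metastatic / high / intermediate / low)
across ~82 areas:

1. **Where is incidence higher or lower than expected?**  With indirect
   standardization, the expected count in area *i* is
   `E_i = n_i · (ΣO / Σn)` (the region-wide rate applied to the area's
   population of men aged ≥ 35), and the crude standardized incidence ratio
   is `SIR_i = O_i / E_i`.
2. **Do elevated areas cluster spatially?**  Global Moran's *I* (permutation
   inference, inverse-distance weights within a 120-km centroid band) tests
   for region-wide autocorrelation; Local Moran's *I* (LISA) classifies
   significant areas High-High / Low-Low / Low-High / High-Low; Kulldorff's
   purely spatial Poisson scan finds circular zones maximizing the
   likelihood ratio `O·ln(O/E) + (T−O)·ln((T−O)/(T−E))`, with Monte-Carlo
   p-values conditional on the total count.
3. **Is incidence associated with an area-level covariate** such as family
   physician density?  The Besag–York–Mollié (BYM) model smooths the crude
   SIRs and estimates the ecological effect:

   ```
   O_i ~ Poisson(E_i · θ_i)
   log θ_i = c + β x_i + u_i + v_i
   u  ~ intrinsic CAR on the adjacency graph   (precision τ_u)
   v_i ~ Normal(0, 1/τ_v)                       (exchangeable)
   τ_u, τ_v ~ Gamma(0.5, 0.0005);  flat priors on c, β
   ```

   `exp(β)` is the incidence rate ratio (IRR) per unit covariate,
   "significant" when its 95% credible interval excludes 1.  The posterior
   mean of θ_i is the *smoothed SIR*: unstable small-area crude ratios are
   shrunk toward their neighborhood and the regional level.

Because registry microdata are confidential, the package ships a
synthetic-data generator that reproduces the statistical structure of such
data (CAR-structured risk surfaces, Poisson counts around standardized
expectations, log-linear covariate effects, planted circular clusters), so
the entire chain is testable end to end.

## Worked example

```
$ spatepi generate --seed 7 --n-areas 82 --sd-u 0.6 --out region.csv
wrote region.csv: 82 areas, 4257 cases

$ spatepi cluster region.csv --risk-level metastatic --seed 1 --out clusters/
Global Moran's I = 0.3479 (expected -0.0123, pseudo p = 0.0010)

$ head -3 clusters/scan_metastatic.csv
rank,direction,center_area,radius_km,members,observed,expected,relative_risk,llr,p_value
1,high,GA005,180.492971,GA002;...;GA035,269,140.375687,2.600956,64.978302,0.001000
2,high,GA032,0.000000,GA032,35,13.838777,2.619225,11.682563,0.001000
```

The generated region has a strongly structured risk surface (`--sd-u 0.6`),
and the chain finds it: Moran's *I* of 0.35 is far above its null
expectation −1/(n−1) = −0.012 at the smallest attainable pseudo p
(1/1000), and the most likely high-rate scan cluster contains 269 observed
vs 140 expected cases (relative risk 2.6) at p = 0.001.

```
$ spatepi bym region.csv --risk-level metastatic --covariate phys_density \
      --seed 1 --iterations 30000 --out bym/
IRR = 1.048 (CrI 0.653 to 1.682); not significant
diagnostics: fail
```

The generator planted no covariate effect, and the fitted IRR's credible
interval duly spans 1.  The diagnostics verdict is honest too: at this
desk-scale schedule the half-width and run-length tests on the
slow-mixing precision parameters (especially τ_v) demand longer chains —
the kind of run-length problem that historically pushed BYM analyses to
10⁸-iteration schedules — while the between-chain scale reduction factors
are already ≈ 1.005.  Effect estimates (β, IRR) are stable and their
credible intervals well calibrated at this schedule (see the coverage test).

The full pipeline (`spatepi run --input region.csv --seed 1 --out run/`)
produces, per risk level: the SIR table, the Moran gate decision, LISA and
scan outputs when the gate opens, BYM null and single-covariate ecological
fits with diagnostics, plus summary tables (SIR bin counts, Moran/LISA
counts, crude-vs-smoothed SIR ranges, coefficient/IRR/CrI table) and
GeoJSON cluster layers.

## Layout

| module | contents |
|---|---|
| `spatepi.region` | areal data model, CSV/GeoJSON I/O |
| `spatepi.sir` | expected counts, crude SIRs, verbal bins, descriptives |
| `spatepi.weights` | distance-band neighbors, inverse-distance / binary weights |
| `spatepi.moran` | Global/Local Moran's I, permutation inference, LISA |
| `spatepi.scan` | Kulldorff Poisson scan, Monte-Carlo p-values |
| `spatepi.bym` | BYM model, Metropolis-within-Gibbs sampler, IRR summaries |
| `spatepi.diagnostics` | PSRF, Geweke, Heidelberger–Welch, Raftery–Lewis |
| `spatepi.simulate` | synthetic study regions and risk surfaces |
| `spatepi.pipeline`, `spatepi.cli` | orchestration, summary tables, CLI |

See `docs/methods.md` for the statistical details and design choices.
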