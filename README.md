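# microhet

Colony-level phenotypic and metabolic heterogeneity in clonal bacterial
populations: a pipeline for flat-bed-scanner plate time-lapses and the
statistics around them.

Clonal *E. coli* populations are phenotypically heterogeneous: colonies
founded by single cells differ in maximum growth rate, in lag time, and —
when a redox-sensitive tetrazolium dye (TTC) couples the respiratory chain
to red formazan accumulation — in respiratory rate. `microhet` implements
the full analysis chain that turns a scanner time-lapse of a Petri dish
into per-colony kinetic phenotypes and population-level statistics, plus
the companion analyses linking gene-expression noise and metabolome
differences to that heterogeneity:

- **`microhet.imaging`** — colony detection on the temporal-SD projection
  of the image stack (Otsu threshold within the plate, watershed split,
  gated nearest-centroid tracking, artifact filtering).
- **`microhet.growth`** — per-colony Gompertz growth kinetics

  `f(t) = A_min + A_Δ · exp(−exp(k (t_m − t)))`

  with maximum growth rate `f′(t_m) = A_Δ k / e` and lag time from the
  tangent at the inflection point; maximum respiratory rate `α` as the
  steepest `f = αt + β` fit over all ≥10-point windows of the colony's
  mean-red trace; sliding-window exponential fits for batch OD600 curves.
- **`microhet.noise`** — expression noise `η_p = σ_p²/μ_p²`, expected
  noise `η̄_p` from the 5% of proteins nearest in log abundance, deviating
  noise `ε_p = η_p/η̄_p`, permutation set/TF-regulon enrichment with
  Storey q-values, and protein→flux OLS proportionality.
- **`microhet.pareto`** — Pareto front over (maximize growth rate,
  minimize lag), fitness isoclines `g_norm / lag_norm`, the equal-fitness
  exponential model `λ (T − T_lag) = c`, fitness-band Spearman
  correlations, and the 1000×400 CV bootstrap.
- **`microhet.metabolome`** — accurate-mass ion annotation, Welch-t
  differential abundance with Storey q-values, permutation pathway
  enrichment, starvation time-course summaries.
- **`microhet.synthetic`** — generators for every input above with known
  ground truth, so the whole pipeline is testable without external data.

## Worked example

Fit one synthetic colony trace (2% area noise) and read off its kinetics:

```python
from microhet import synthetic as syn
from microhet.growth import GompertzModel, RespirationModel

table, truth = syn.gen_colony_timeseries(1, noise_sd=0.02, seed=42)
trace = table[table.colony_id == 0]
print(GompertzModel(trace["time_h"], trace["area"]).fit().summary())
```

```
Gompertz colony growth fit
======================================
nobs:        145
converged:   True
A_min:       22.6436
A_delta:     1408.02
k (1/h):     0.613627
t_m (h):     11.4243
rss:         80518.4
mu_max (area/h): 317.847
lag (h, tangent at A_min): 9.79461
```

The colony was simulated with `A_Δ = 1411.7`, `k = 0.620`, `t_m = 11.41`:
the fit recovers the area gain within 0.3%, the maximum relative growth
rate within 1% and the inflection time within 0.2%. `mu_max` is the
absolute expansion rate at the inflection (`A_Δ k / e`, area units/h) and
the lag is where the tangent at `t_m` falls back to the baseline area
(`t_m − 1/k`). The same trace's red channel gives the respiratory rate:

```python
print(RespirationModel(trace["time_h"], trace["red"]).fit().summary())
```

```
Respiratory-rate estimate (max-slope window)
============================================
alpha (AU/h): 0.0390769
beta (AU):    0.214527
window:       points [89, 99) (14.83-16.33 h)
```

against a simulated α of 0.030 AU/h — the max-slope-window estimator is
upward biased on noisy traces (it selects the window noise tilts
steepest), which is why downstream analyses use it as a rank statistic.

The same steps run from the shell:

```
microhet simulate plate --seed 3 --out plate/
microhet segment --images plate/plate.tiff --interval 10 --out tracks.csv
microhet fit --tracks tracks.csv --out phenotypes.csv
microhet pareto --phenotypes phenotypes.csv --band 0.7 0.8 --seed 7 --out pareto/
```

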