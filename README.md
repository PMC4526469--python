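# sealniche

Sexual and individual niche segregation in a central-place marine predator,
from whisker stable-isotope chronologies and GPS tracking.

## The problem

Highly dimorphic marine predators such as otariid seals are expected to
partition resources between the sexes, and individuals within a sex may
specialise on subsets of the population's niche.  Quantifying either
requires combining two very different data streams:

* **Isotopes.** δ13C (‰, vs VPDB) proxies foraging habitat and δ15N (‰, vs
  atmospheric N₂) proxies trophic level.  Plasma and red cells integrate
  days to weeks; a whisker is a metabolically inert, continuously growing
  tissue whose serial 3-mm sections archive several *years* of history —
  but indexed by distance, not time.
* **Movement.** GPS fixes every 10 min describe where animals actually
  foraged during the tracking window.

`sealniche` implements the full analysis pipeline for a study design of six
adult males and six lactating females from one breeding colony:

1. **Whisker chronologies** — continuous-wavelet periodicity assessment of
   each whisker's δ13C/δ15N series (is there a repeated cycle, and is its
   period consistent along the whisker?); annual-cycle assumption converts
   the period *P* (mm) to a growth rate *g = P/365* (mm/d); phase
   synchronization against a reference individual absorbs the unknown
   under-skin offset of each cut whisker; all records are truncated to the
   most recent 2.5 years covered by every animal.
2. **Isotopic niche statistics** — Welch *t*-tests on blood and on niche
   ranges; the Roughgarden decomposition of the Total Niche Width for
   continuous data, `TNW = WIC + BIC` (population variance = mean
   within-individual variance + variance of individual means), with the
   ratio WIC/TNW as the individual-specialisation index (1 = generalists,
   0 = specialists) and a 10,000-replicate Monte Carlo "all generalists"
   null for its significance; a linear mixed model for the sex effect
   (random intercept per individual, AR(1) residuals along the whisker,
   REML).
3. **Spatial overlap** — 8 m/s speed filtering, 10-min linear
   interpolation, sex-pooled kernel utilisation distributions (UD) with the
   ad hoc bandwidth `h = σ n^(−1/6)` on a habitat-masked grid, 95%/50%
   isopleths, and the Utilisation Distribution Overlap Index
   `UDOI = A₉₅ · ∬ UD₁·UD₂ dA` (1 for identical uniform ranges, 0 for
   disjoint ones).

A first-class synthetic-data module generates whiskers, blood values and
central-place GPS tracks with known ground truth (growth rates, variance
components, under-skin offsets, outlier flags), so the whole pipeline is
testable end to end; see `docs/methods.md` for the model details and the
calibration of the generator.

## Worked example

```python
from sealniche import NicheDecomposition, SyntheticTruth, generate_population
from sealniche.study import run_chronology

truth = SyntheticTruth(rng_seed=1)
pop = generate_population(truth)          # 6 males + 6 females
results, summary, window = run_chronology(pop.whiskers, seed=1)
print(summary[["individual", "sex", "period_mm", "n_cycles",
               "growth_rate_mm_per_day", "phase_lag_days"]].head(3).round(2))

males = window[window.sex == "M"]
dec = NicheDecomposition.from_dataframe(males, "d13c").fit(n_replicates=10_000, seed=1)
print(dec.summary().round(4))
```

prints

```
  individual sex  period_mm  n_cycles  growth_rate_mm_per_day  phase_lag_days
0         M1   M      63.36      2.75                    0.17            18.0
1         M2   M      73.31      4.05                    0.20             3.0
2         M3   M      63.73      3.72                    0.17            -6.0
TNW                   0.1307
WIC                   0.1229
BIC                   0.0078
WIC/TNW               0.9399
p_value               0.0025
n_replicates      10000.0000
n_observations      305.0000
n_individuals         6.0000
```

Reading this: M1's whisker cycles every 63.4 mm; assuming annual cycles it
grew 0.17 mm/d and recorded 2.75 years; its record is offset 18 days from
the reference animal's.  Across the six males' windowed δ13C sections the
population niche width (TNW = 0.131 ‰²) is almost entirely within-individual
variation (WIC/TNW = 0.94): every male swept the same wide δ13C range, yet
the small between-individual component is still statistically significant
(Monte Carlo p = 0.0025) — the generalist-with-subtle-specialisation
pattern, here recovered from the generator's known truth
(`truth.true_ratio("M", "d13c")` = 0.926).

The same pipeline runs from the shell on CSV/XLSX tables and ASCII-grid
rasters:

```bash
sealniche simulate --seed 1 --out data/
sealniche chronology --isotopes data/isotopes.csv --out out/
sealniche niche      --isotopes data/isotopes.csv --out out/
sealniche overlap    --gps data/gps.csv --mask data/bathymetry.asc --out out/
sealniche report     --seed 1 --out out/
```

## Layout

```
src/sealniche/
  synthetic.py    # ground-truth generators: whiskers, blood, GPS tracks, bathymetry
  chronology.py   # wavelet periodicity, growth rate, time assignment, phase sync
  niche.py        # Welch tests, ranges, WIC/BIC/TNW + Monte Carlo null
  mixed.py        # random-intercept + AR(1) REML mixed model
  spatial.py      # speed filter, interpolation, kernel UD, isopleths, UDOI
  geo.py          # local azimuthal projections, great-circle distances
  io.py           # CSV/XLSX tables, ASCII grids, GeoJSON, config
  study.py        # end-to-end orchestration
  cli.py          # `sealniche` command-line interface
```
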