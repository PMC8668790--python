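# enamelseason

Seasonal climate signal recovery from serially sampled tooth-enamel
oxygen isotopes.

High-crowned herbivore molars grow occlusal → root over one to two
years, so a transect of small enamel samples drilled along the growth
axis records a δ¹⁸O time series of the animal's body water — and,
through it, the seasonal cycle of the environmental waters it drank.
The catch is that enamel mineralizes slowly: a fraction of the mineral
arrives with the secreted matrix and the rest is added while more than
a centimetre of crown matures behind the secretion front, so measured
profiles are damped, time-averaged versions of the primary signal.
`enamelseason` packages the full analysis chain for this problem, aimed
at stable-isotope paleoecologists working with serial enamel data:

* **conversions** — the empirical enamel calibration
  `δ¹⁸O_PO4* = 0.9 · δ¹⁸O_w + 23` (‰ V-SMOW) and its inverse, plus
  V-PDB ↔ V-SMOW carbonate scale transforms and the carbonate–phosphate
  spacing diagnostic.
* **forward_model** — the time-averaging transfer function: apposition
  (length *l_a*), maturation (length *l_m*, initial mineral fraction
  *f_i*) and the drill footprint, assembled into a row-stochastic
  averaging matrix on a fine axial grid.
* **inverse_model** — damped least squares
  `min ‖Am − d‖² + ε²‖D(m − m_ref)‖²` with a curvature penalty by
  default, discrepancy-principle selection of ε, Monte-Carlo error
  bands, and an *l_a* sensitivity sweep.
* **seasonality_metrics** — replicate means, profile amplitude, percent
  of the annual water range, months of growth recorded.
* **cohort_stats** — OLS with slope inference, carbonate–phosphate
  spacing trends, Welch's t comparisons between cohorts.
* **synthetic_data** — a generator for the whole study system (cosine
  water year, leaf-water–enriched body water, drilled teeth with
  triplicate noise, modern vs. historical cohorts) with the latent
  truth retained for parameter-recovery tests.
* **io / cli** — tidy CSV formats, YAML run configuration, and a
  `enamelseason` command with `simulate`, `convert`, `forward`,
  `invert`, `metrics` and `compare` subcommands.

## Worked example

Simulate one tooth under the default study conditions (a Wyoming-like
water year from −23 ‰ in January to −10.6 ‰ in July, leaf-water
enrichment, 2 mm sampling, triplicates with 0.3 ‰ noise), then invert
the profile back to the primary input:

```python
import numpy as np
import enamelseason as es
from enamelseason.synthetic_data import (
    BodyWaterParams, CohortScenario, synth_body_water, synth_tooth, synth_water_year,
)
from enamelseason.inverse_model import InversionConfig, invert_series
from enamelseason.seasonality_metrics import (
    months_recorded, percent_of_water_range, profile_amplitude, water_amplitude_po4,
)

geometry = es.ToothGeometry()          # la=7, lm=13.3, fi=0.25, 2 mm drill, 30 mm/yr
water = synth_water_year()             # cosine year anchored at the Jan/Jul extremes
print(f"annual water range in enamel space: {water_amplitude_po4(water):.2f} permil")

rng = np.random.default_rng(7)
monthly = synth_body_water(water, BodyWaterParams(), rng)
tooth = synth_tooth(monthly, geometry, CohortScenario(), rng, specimen_id="demo")

raw_amp = profile_amplitude(tooth.series.replicate_means())
print(f"samples: {tooth.series.n_samples}, months recorded: "
      f"{months_recorded(tooth.series, geometry):.1f}")
print(f"raw profile amplitude: {raw_amp:.2f} permil "
      f"({percent_of_water_range(raw_amp, water):.0f}% of the annual water range)")

result = invert_series(tooth.series, geometry, InversionConfig(n_trials=200, seed=7))
inv_amp = result.amplitude()
print(f"chosen damping: {result.damping_used:.3g}, rms misfit: {result.rms_misfit:.2f} permil")
print(f"recovered input amplitude: {inv_amp:.2f} permil "
      f"({percent_of_water_range(inv_amp, water):.0f}% of the annual water range)")
```

Output:

```
annual water range in enamel space: 11.16 permil
samples: 12, months recorded: 8.8
raw profile amplitude: 7.20 permil (65% of the annual water range)
chosen damping: 1.47, rms misfit: 0.14 permil
recovered input amplitude: 11.00 permil (99% of the annual water range)
```

The raw, time-averaged profile records only about two-thirds of the
annual water amplitude; the inversion restores essentially the full
range. `result.to_frame()` carries the estimate with its node-wise 95 %
Monte-Carlo bands.

The same pipeline from the shell:

```sh
enamelseason simulate --seed 1 --out demo/
enamelseason metrics  --samples demo/modern.csv --water demo/water.csv --out demo/metrics.csv
enamelseason invert   --samples demo/modern.csv --out demo/inversions/ --seed 1
enamelseason compare  --modern demo/modern.csv --historical demo/historical.csv --out demo/cmp/
```

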