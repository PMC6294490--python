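# forktime

Single-cell measurement of DNA replication-fork transit times from
two-color live-cell imaging of operator-array reporters, with the
supporting in-vitro analyses (G-quadruplex melting fits, primer-extension
gel densitometry) and a ground-truthed synthetic-data generator.

## The measurement

In budding yeast, two tandem operator arrays (*lacO* bound by lacI-GFP,
*tetO* bound by tetR-tdTomato) are inserted downstream of an early-firing
origin (ARS413), nominally 20 kb apart. Each array appears as a
diffraction-limited fluorescent focus; when a replication fork duplicates
an array, the bound fluorophore count — and hence the focus's integrated
intensity — doubles. Fitting each channel's intensity trace *I(t)* with a
bleach-aware logistic step,

```
I(t) = exp(-k t) · [ B + A / (1 + exp(-(t - t_mid)/τ)) ],
```

gives per channel a mid-rise time `t_mid`. The inter-array delay

```
Δt = t_mid(tetO) - t_mid(lacO)
```

is the replication time of the interval between array midpoints (~30 kb:
the 20 kb spacing plus half of each 10 kb array), and `rate = 30 kb / Δt`
is the local fork rate. Cohorts of single-cell Δt values are compared
between strains (e.g. with or without a G-quadruplex insert, with or
without the Pif1 helicase) by mean, SEM, fold-change, and a Monte Carlo
resampling (label-permutation) test on the difference of means with
1,000,000 iterations and add-one correction.

Because raw movies for such experiments are not publicly deposited, the
package ships a first-class simulator that generates movies, traces,
melting curves and gel lanes *with ground truth* — per-cell fork-speed
variability, a folded/unfolded two-state obstacle that pauses only the
folded subpopulation, intensity doubling with finite rise time,
photobleaching, Poisson + read noise, and cell drift — so every stage of
the analysis is testable end to end.

## Modules

| module | contents |
| --- | --- |
| `forktime.geometry` | reporter locus layouts, mid-array / obstacle distances |
| `forktime.simulate` | scenario + acquisition configs; kinetics, trace, movie, melting-curve and gel simulators |
| `forktime.foci` | 3D DoG spot detection, aperture photometry, greedy nearest-neighbour tracking with gap closing, green/red pairing |
| `forktime.kinetics` | bleach-aware sigmoid fits, Δt/rate computation, QC |
| `forktime.stats` | cohort summaries, permutation/bootstrap resampling test, fold-changes, star notation |
| `forktime.biochem` | melting-curve normalization, two-state van 't Hoff fit, gel-lane band quantitation |
| `forktime.pipeline` | movie → traces → events drivers |
| `forktime.cli` | `forktime` command with simulate/detect/track/traces/fit/stats/melt/gel subcommands |

## Worked example

Simulate a wild-type-like cohort (no insert, n = 45) and a cohort carrying
a G4 obstacle that pauses the fork in 80% of cells (folded subpopulation)
without its unwinding helicase, fit every trace, and compare:

```python
import numpy as np
import forktime as ft
from forktime.kinetics import fit_trace, qc_filter
from forktime.stats import resampling_test, summarize_cohort, significance_stars

layout = ft.nominal_layout()
g4 = ft.nominal_layout(obstacle=True)
acq = ft.AcquisitionConfig()

wt = ft.ScenarioConfig(label="wt", n_cells=45, seed=1)
mut = ft.ScenarioConfig(label="g4_helicase_null", n_cells=26, seed=2,
                        pause_mean=26.0, folded_fraction=0.8)

def measure(layout_, sc):
    rng = np.random.default_rng(sc.seed)
    gts = ft.sample_cell_kinetics(layout_, sc, rng)
    traces = [ft.render_trace(g, acq, rng=rng, noise_sd=40.0) for g in gts]
    passed, _ = qc_filter([fit_trace(tr) for tr in traces])
    return summarize_cohort(passed, label=sc.label)

ref, tst = measure(layout, wt), measure(g4, mut)
res = resampling_test(ref, tst, 1_000_000, seed=3)
fc = ft.fold_change(ref, tst)
```

Output:

```
wt: n=45, mean dt = 21.0 +/- 0.6 min (rate 1.48 kb/min)
g4_helicase_null: n=26, mean dt = 36.7 +/- 3.9 min (rate 0.98 kb/min)
fold slowdown = 1.75, rate reduction = 43%
p = 1.00e-06 **** (1,000,000 resampling iterations)
```

The wild-type cohort replicates the 30 kb interval in ~21 min (≈1.5
kb/min, a typical yeast fork rate); the obstacle cohort is slowed ~1.75×
on average (the mixture of paused folded cells and WT-like unfolded
cells), and the permutation test calls the difference significant at its
resolution floor of 1/(N+1).

The same analysis runs from the shell on full 3D movies:

```sh
forktime simulate-movie --seed 1 --out sim/
forktime detect sim/movie.ome.tif --out det.csv
forktime track det.csv --out tracks.csv
forktime traces tracks.csv --n-frames 180 --out traces.csv
forktime fit traces.csv --out fit/
forktime stats fit/events.csv other_cohort/events.csv --out report/
```

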