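# behavts

Temporal-structure analysis for high-density behavioral time series.

Developmental and behavioral scientists increasingly work with dense,
multimodal recordings — frame-by-frame annotations of gaze, affect, touch and
speech, wearable-sensor streams, egocentric video codings. `behavts` provides
an integrated toolkit for asking *how behavior is organized in time* with
such data:

* **Data types and conversions** — annotated event streams
  (onset, offset, code), regularly sampled nominal series, and binary spike
  trains marking event onsets, with clean conversions among them, tabular
  import of annotation-software exports, and per-region-of-interest
  presence resampling.
* **Burstiness analysis** — summarizes an inter-onset interval (IOI)
  distribution by `B = (σ_τ − μ_τ)/(σ_τ + μ_τ)`: −1 for periodic trains,
  ≈ 0 for memoryless (Poisson) trains, > 0 for bursty ones; with a
  finite-size corrected estimator, the lag-1 memory coefficient M, and a
  bootstrap classification of trains against a Poisson null at matched n.
* **Chromatic & anisotropic cross-recurrence quantification (CRQA)** — the
  N×N cross-recurrence plot of two nominal streams under a configurable
  match rule (multiple signed match categories = "colors"), per-category
  recurrence rates RR/rRR, and orientation-specific line measures
  (LAM, TT, Max_L, Ent_L) that quantify asymmetry and dominance in dyadic
  interaction.
* **Point-process Granger causality** — per-bin Bernoulli-logit GLMs over
  the lagged histories of every variable in an ensemble, AIC history-window
  selection, full-vs-reduced deviance likelihood-ratio tests
  (Δ ~ χ²_p under the null), Benjamini–Hochberg FDR across all ordered
  pairs, and a signed {1, −1, 0} influence matrix.
* **Simulators and plots** — seeded generators for every input class
  (periodic/Poisson/bursty trains, coupled nominal dyads, GLM-coupled spike
  ensembles with known directed connectivity), multirow event rasters,
  timeseries-with-event overlays, chromatic recurrence plots, burstiness
  panels and directed influence graphs, all scriptable from a CLI.

## Worked example

Analyze two simulated egocentric-view spike trains (1 Hz bins) and test a
planted directed influence in a two-variable ensemble:

```python
import numpy as np
from behavts import *

trains = [
    simulate_bursty_train(mu=10.0, sigma_log=1.5, n_onsets=300, seed=1),
    simulate_poisson_train(rate=0.1, T=3000, seed=1),
]
trains[0].label, trains[1].label = "hands-in-view", "faces-in-view"
print(burstiness_report(trains, seed=0).to_string(index=False))

res = classify_regime(trains[0], replicates=1000, seed=0)
print(f"{res.label}: B={res.B:.3f}, "
      f"Poisson CI at matched n = [{res.ci_low:.3f}, {res.ci_high:.3f}]")

W = np.zeros((2, 2)); W[0, 1] = 2.0        # planted edge: speech -> gaze
ens = simulate_coupled_spike_ensemble(2, 3000, W, base_rate=0.1, seed=0,
                                      labels=["parent-speech", "infant-gaze"])
print(gc_all_pairs(ens, GCConfig(p_max=2, q=0.05)).pretty())
```

prints

```
               label   n         B  B_finite         M error
       hands-in-view 299  0.519672  0.571034 -0.020800
       faces-in-view 305  0.002083  0.003949 -0.038155
periodic (reference) 299 -1.000000 -1.000000       NaN
 poisson (reference) 452 -0.017311 -0.016990  0.017948

bursty: B=0.520, Poisson CI at matched n = [-0.056, 0.061]

parent-speech -> infant-gaze  magnitude +311.995  p=0.0000  significantly positive
 infant-gaze -> parent-speech magnitude   -1.012  p=0.3143  n.s.
```

The heavy-tailed train sits deep in the bursty regime (B = 0.52, far above
the Poisson interval at its n), the memoryless train sits at B ≈ 0 next to
the generated references, and the Granger analysis recovers exactly the
planted excitatory edge — the reverse direction is correctly not
significant.

The same pipelines run from a shell:

```sh
behavts simulate poisson --rate 0.1 --t 20000 --seed 1 --out p.csv
behavts burstiness --input p.csv --rate 1 --classify --out report.csv
behavts crqa --x a.csv --y b.csv --rule rule.csv --out measures.csv --fig crp.png
behavts granger --input ensemble.csv --rate 3 --max-history 3 --out gc.csv --graph gc.png
```

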