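# cardiomap

Functional characterization of cardiomyocyte-like cell cultures from
optical-mapping movies, cell images, and patch-clamp recordings — with a
synthetic-data generator that makes every estimator testable against
analytic ground truth.

Stem-cell-derived cardiomyocytes are routinely validated by three kinds of
measurements: spontaneous calcium transients (firing interval T and the
transient duration at 50 % decay, CaT50), excitation-wave propagation
across cell clusters (activation maps and conduction velocity, CV), and
whole-cell currents (capacitance-normalized densities in pA/pF, and the
action-potential duration APD80).  `cardiomap` implements this analysis
stack for anyone working with such cultures:

- **Transients** — ROI traces, ΔF/F peak detection, spontaneous intervals,
  CaT50 (peak-to-50 %-decay with linear interpolation; FWHM optional),
  regularity classes (regular 750–1250 ms, irregular > 5 s), Gaussian
  population summaries.
- **Activation maps** — per-pixel adaptive threshold: a pixel activates
  when its intensity exceeds (1 + θ) × its own temporal mean, making the
  map invariant to global intensity scaling.  Space–time plots, per-beat
  splitting, co-culture synchronization, and gradient CV estimation.
- **Frame-censored CV bound** — when a wave crosses a cluster of length L
  faster than the frame clock resolves, the capture probability
  p = max(0, 1 − T/Δt) turns k consecutive single-frame observations into
  a confidence bound T ≤ Δt·(1 − α^(1/k)) and hence CV ≥ L/T_upper, with a
  Monte-Carlo validation oracle.
- **Morphometry** — area, elongation (ellipse aspect ratio), circularity
  4πA/P², box-counting fractal dimension, Feret diameter, and FFT
  detection of sarcomeric striation (dominant spectral period in the
  1–3 µm band along the cell's major axis).
- **Ephys** — fast/slow inward peak separation, current densities, I–V
  curves, APD80.
- **Stats** — exact (full-enumeration, tie-aware) and normal-approximation
  Mann–Whitney U, Gaussian summaries.
- **Synth** — wave movies, spontaneous-trace populations, striated and
  unstriated cell images, and voltage/current-clamp sweeps, each with a
  truth record for recovery tests.

## Worked example

```python
import numpy as np
from cardiomap import synth, activation, cvbound, transients

# --- waves too fast for the frame clock ----------------------------------
# collect 19 single-frame crossings; a multi-frame crossing would instead
# go to gradient CV estimation (estimate_from_events refuses the bound)
events, seed = [], 0
while len(events) < 19:
    stack, truth = synth.gen_wave_movie(cv=20.0, cluster_length_um=300.0,
                                        frame_interval=110.0, seed=seed)
    amap = activation.activation_map(stack, theta=0.10)
    ev = activation.classify_event(amap, synth.wave_roi(truth),
                                   1, stack.pixel_size)
    if ev.outcome == "single_frame":
        events.append(ev)
    seed += 1

res = cvbound.estimate_from_events(events, alpha=0.05)
print(f"k={res.k}  T_upper={res.t_upper_ms:.2f} ms  "
      f"CV_lower={res.cv_lower_mm_s:.1f} mm/s")

# --- a population of spontaneously firing cells --------------------------
table, _ = synth.gen_spontaneous_traces(n_cells=26, irregular_fraction=0.0,
                                        seed=0)
metrics = transients.analyze_trace_table(table)
mean, sd, n = transients.summarize_cat50(metrics, class_filter="regular")
print(f"CaT50 = {mean:.0f} ± {sd:.0f} ms  (n={n})")
```

Output:

```
k=19  T_upper=16.05 ms  CV_lower=18.4 mm/s
CaT50 = 276 ± 30 ms  (n=26)
```

Each simulated crossing took ~15 ms against a 110 ms frame interval, so
most completed between frames; 19 such single-frame observations bound
the traversal time at 16.05 ms with 95 % confidence and the conduction
velocity at ≥ 18.4 mm/s for the ~295 µm rasterized cluster.  The 26
synthetic cells were generated with an analytic CaT50 of 283 ms and a
30 ms population spread; the batch mean of 276 ms sits within two standard
errors (30/√26 ≈ 5.9 ms) of the generating value.

A command-line interface mirrors the library
(`cardiomap simulate | transients | map | cvbound | morph | ephys |
compare`); every run logs its version, seed and parameters, and identical
seeds produce byte-identical outputs.

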