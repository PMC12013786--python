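# muflex

Motor-unit manifold dimensionality and recruitment flexibility.

Human muscles are controlled through motor units whose discharge trains can
be decomposed from high-density surface EMG. When the smoothed firing rates
of a few dozen concurrently active units are summarized by latent factors,
some muscles look one-dimensional (a single common drive) while others need
several factors. `muflex` implements the complete computational chain needed
to ask what that dimensionality means:

* **Preprocessing** (`muflex.spiketrain`) — binary spike trains smoothed with
  a 400 ms Hanning window (a ~2.5 Hz low-pass that keeps the force-related
  band), a continuity filter (no inter-spike pause longer than 400 ms),
  detrending and plateau concatenation, cross-correlation-based duplicate
  removal (0.5 ms match tolerance, 30% shared-spike rule, lowest ISI CoV
  retained), and recruitment thresholds (first of three discharges within
  1 s).
* **Latent dimensionality** (`muflex.dimensionality`) — maximum-likelihood
  factor analysis on the unit correlation matrix with promax rotation,
  reconstruction R² as a function of factor count, and selection of the
  dimensionality against an ISI-shuffled surrogate population: the selected
  count is the largest k whose R² gains all exceed the straight-line slope
  of the surrogate R² curve. Two alternative rules (5% R²-gain cutoff and a
  linear-fit plateau test) are computed alongside.
* **Flexibility statistics** (`muflex.flexibility`) — displacement and
  dispersion, which quantify how far a pair of units strays from the
  one-dimensional monotonic manifold that a single common input would
  enforce, with a ±25 ms per-unit lag search and max-rate normalization.
* **MUAP geometry** (`muflex.muap`) — spike-triggered averaging of
  differential EMG (50 ms windows), 12 × 5 peak-to-peak amplitude maps with
  a 3 × 3 box blur, and unit localization/distances on multi-grid montages
  (8 mm electrode pitch, 24 mm inter-grid gap).
* **Spiking motor-pool model** (`muflex.simulator`) — 300 conductance-based
  leaky integrate-and-fire motor neurons per pool (soma diameters 50–100 µm
  on a quadratic ramp; resistance, capacitance, rheobase and refractory
  period derived from diameter), driven by mixtures of ≤2.5 Hz common
  sources and ≤50 Hz independent noise (25:75 variance split, SD 0.03 mS on
  a baseline conductance), with optional Renshaw-cell recurrent inhibition.
  Seven input scenarios reproduce the central simulation result: the
  *distribution* of inputs across the pool — not their number — sets the
  manifold dimensionality.
* **Synthetic ground truth** (`muflex.synthetic`) — latent-driven
  populations (gamma-renewal spiking, known mixing weights) and toy EMG with
  known templates, so every stage is testable without any recorded data.

## Worked example

Simulate the single-common-input scenario, then ask how many latent factors
its motor-neuron population needs:

```python
from muflex.simulator import run_scenario

res = run_scenario("i", seed=1, duration=60.0)
print(res.active_count, round(res.mean_rate_hz, 2), res.report.k_slope)
print([round(r, 3) for r in res.report.r2_data[:4]])
```

prints

```
143 9.44 1
[0.745, 0.75, 0.753, 0.756]
```

143 of the 300 simulated motor neurons fire continuously (mean 9.44 pps,
inside the physiological 8–10.5 Hz band); one latent factor explains ~74% of
the variance in their smoothed rates, and adding factors improves the
reconstruction no faster than it does for the ISI-shuffled surrogate — the
pool transmits its single common input as a one-dimensional manifold. Run
`run_scenario("iii", ...)` (three heterogeneously distributed excitatory
inputs) and `k_slope` becomes 3.

The same pipeline runs from the shell:

```bash
muflex fixtures --out-dir fixtures/
muflex dims --input fixtures/pop_k3.csv --segments 0.5:39.5 --seed 3 --out report.json
muflex flex --input fixtures/pop_k1.csv --fs 64 --max-lag-ms 25 --out flex.csv
muflex simulate --scenario iii --seed 7 --duration 60 --out rasters.csv --report report.json
```

Every command writes a `run_manifest.json` (resolved configuration, seeds,
package version, input checksums) next to its outputs.

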