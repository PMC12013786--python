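# Methods

This note documents the models, algorithms and numerical choices behind
`muflex`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Spike-train preprocessing

Spike times are continuous seconds; sample indices use round-half-even; all
windows are half-open `[start, end)`.

**Smoothing.** Binary spike trains (one count per sample at `fs`, default
2048 Hz) are convolved with a Hanning window of 400 ms, applied zero-phase
(centered, odd length, zero-padded edges). The kernel is normalized to unit
time-integral so the output is an instantaneous firing rate in pulses per
second; the integral of a smoothed row equals the unit's spike count up to
edge leakage. Because of the zero padding, smoothed rates dip over the last
and first ~200 ms of a recording; **analysis windows must stay at least one
kernel length inside the recording edges**. This matters more than it looks:
if the dip is left in, detrending tilts every trace the same way and
injects a strong, purely artifactual shared component into the population
(we observed mean pairwise correlations of ~0.5 between independent units
before adopting the interior-window rule).

**Continuity filter.** A unit counts as continuously active in a window when
no inter-spike interval inside the window exceeds 400 ms *and* the gaps
between the window edges and its first/last spike are also ≤ 400 ms. The
boundary half of this rule is a design choice (a unit silent for the first
second of a plateau is not continuously firing); the filter is idempotent.

**Duplicates.** Units decomposed from different electrode grids are compared
after aligning by the integer-sample lag maximizing their binary
cross-correlation (±20 ms search, absorbing action-potential propagation
delays). Spikes matching within ±0.5 ms count as shared; pairs sharing more
than 30% of the smaller train's spikes are duplicates; transitive closure
forms groups and the member with the lowest ISI coefficient of variation is
retained (ties: more spikes, then lexicographic id; a unit with undefined
CoV never beats a well-defined one).

**Recruitment threshold.** Recruitment time is the first spike of the first
triple of spikes spanning ≤ 1 s; the threshold is the torque sample (%MVC)
at that time; a unit with no qualifying triple gets NaN and is excluded
downstream.

## Latent-factor dimensionality

Factor analysis operates on the unit-by-unit **correlation** matrix of the
detrended smoothed rates (units are treated on a common scale). The
maximum-likelihood fit uses the classical profile-likelihood formulation:
the likelihood is optimized over the per-unit uniquenesses with L-BFGS-B
(analytic gradient, bound `[0.005, 1]`, the lower bound doubling as the
Heywood-case clamp), with the loadings recovered from the top-k eigenpairs
of the rescaled correlation matrix. This is the same algorithm as R's
`factanal` and MATLAB's `factoran`, and its cost is independent of the
series length once the correlation matrix is formed (important at ~140
units × 20 factor counts per selection). Rotation is promax with power 4
(varimax followed by an oblique Procrustes fit to the powered target);
factor scores use the regression (Thomson) estimator with the model-implied
correlation matrix; reconstruction R² is the pooled 1 − SSE/SST between the
standardized rates and `scores × loadingsᵀ` (rotation-invariant, since the
reconstruction operator depends only on the loading column space).

Rates are decimated to 64 Hz before factor analysis. The smoothing kernel
is a ~2.5 Hz low-pass, so 64 Hz oversamples the informative band 12-fold
while cutting the fit cost; the correlation matrix is unchanged in
expectation.

**Surrogate.** Per unit, the inter-spike-interval sequence is randomly
permuted and re-cumulated from the original first spike: spike count, first
and last spike time, and mean rate are preserved exactly, while all shared
slow structure is destroyed. One surrogate realization per selection, with
the seed recorded.

**Selection.** For k = 1..kmax (default 10) the R² curve is computed for
the data and for the surrogate (processed by the identical pipeline). The
surrogate slope is the least-squares straight-line slope through its curve.
The data slope at k is, by default, the forward difference
R²(k+1) − R²(k); the selected count `k_slope` is the largest k whose
preceding gains all exceed the surrogate slope (minimum 1, capped at
kmax − 1). A `data_slope="fitted"` variant compares fitted-line slopes
instead; it exists because the pointwise rule has no fixed point at the
floor — the R² curve of pure noise is concave, so its early forward
differences exceed its own fitted line, and only the fitted-vs-fitted
comparison makes "surrogate against itself" select one factor. The
alternatives `k_5pct` (first k with an R² gain below 5 points) and `k_mse`
(first k from which a straight-line fit to the remaining curve has
MSE < 1e-3) are reported alongside.

Units are assigned to their dominant factor by the largest absolute
loading, ties toward the lowest factor index.

## Displacement and dispersion

For a pair of units with smoothed rates r₁, r₂: the maximal non-negative
change between times t, t′ is Δr(t,t′) = maxᵢ(rᵢ(t) − rᵢ(t′)). If both
units move together, one of Δr(t,t′), Δr(t′,t) is ≤ 0, so the candidate
min(Δr(t,t′), Δr(t′,t)) is positive only for opposite-direction changes;
**displacement** is its maximum over all time pairs (the t = t′ diagonal
pins it at ≥ 0). **Dispersion** compares population states with equal L1
norm: among time pairs whose summed rates match within a tolerance bin,
it is the largest L1 distance between the rate vectors. Norm matching uses
an absolute tolerance of 0.5% of the observed norm range by default (exact
equality never occurs in floating point); the difference norm is L1 to
match the population-norm choice.

Both metrics are minimized over per-unit constant integer-sample lags on a
±25 ms grid (lags model conduction-velocity differences, a fixed per-unit
property, so one lag per unit rather than per time pair) and normalized by
the sum of the two units' maximum rates. The implementation enumerates all
time pairs vectorized per lag combination and is exactly equal (same
floating-point subtractions, min/max only) to a triple-loop brute force;
an optional `decimate` parameter subsamples the time axis for long
recordings at the cost of that exactness.

## MUAP geometry

Templates are spike-triggered averages of single-differential EMG over
50 ms windows centered on each firing (truncated windows skipped and
counted). Peak-to-peak amplitudes per channel form a 12 × 5 map per grid,
blurred with a 3 × 3 box kernel to suppress single-channel artifacts. The
blur default is a plain zero-padded convolution: renormalizing the kernel
over in-bounds neighbours (available as `edge_mode="normalized"`, and the
only mode that leaves a constant map unchanged) provably drags the argmax
onto the map edge whenever a source sits one site in from the edge, which
defeats localization. Zero padding preserves the argmax for every off-edge
source; sources centered exactly on the outermost row/column are biased one
electrode inward — a known ±1-electrode (4–8 mm) limitation. Units are
localized at the global-argmax electrode across grids (ties: lowest
(grid, row, col), with a warning) and distances are Euclidean in a common
frame where the grids lie in one line along the muscle axis, separated
edge-to-edge by 24 mm (configurable; the montage drawing is not fixed by
the data format).

## Spiking motor-pool model

Each pool holds 300 conductance-based leaky integrate-and-fire neurons with
E_rest = 0 mV, V_thresh = 10 mV, E_excit = 25 mV, E_inhib = −15 mV (equal
excitatory and inhibitory leverage at 5 mV). Per step (forward Euler,
dt = 0.05 ms, blow-up guarded at |v| > 100 mV):

    dv/dt = (−g_leak·(v − E_rest) + I_excit + I_inhib) / C
    I_excit = max(γ_excit·S·(E_excit − v) − I_rheobase, 0)
    I_inhib = γ_inhib·S·(E_inhib − v)

The printed form of these currents is sign-ambiguous in isolation; the
implementation fixes signs by the physical contract (excitation depolarizes
toward E_excit, inhibition toward E_inhib, leak decays to rest) and the
rheobase offset gates the excitatory current. After a spike, v is clamped
to 0 mV for the refractory period.

Soma diameters follow D(x) = 50 + x²·50 µm for x ∈ [0, 1]
(over-representing small, low-threshold neurons). Electrical parameters are
power laws of ρ = D/50: R = 3000·ρ^−1.2 Ω, C = 40 µF·ρ², rheobase
0.6·ρ³ µS·mV, refractory 24·ρ^0.5 ms; S = R normalized to the smallest
neuron. The published account of this model defers the diameter relations
to code, so these constants are the package's own calibration, chosen once
against the stated emergent behaviour rather than any anatomical table:
motor neurons at 8–10.5 Hz, roughly 120–150 of 300 continuously active,
Renshaw cells at 20–25 Hz, and strict size-principle recruitment order. Two
calibration lessons are worth recording. First, the large capacitance (an
effective after-hyperpolarization-like integration over ~50–100 ms) is what
lets neurons fire at ~10 Hz with comfortable suprathreshold margins; a
short membrane time constant forces either knife-edge margins or
refractory-capped firing, and the refractory-capped regime transmits the
common input so nonlinearly (rectification at the recruitment fringe,
saturation above it) that a single common input reads out as a
multi-factor manifold. Second, the recruitment profile must be shallow
enough that the continuously active set is dominated by well-driven,
near-linear units.

**Inputs.** Common sources are standardized 2.5 Hz low-pass Gaussian
processes (frequency-domain band-limiting — exactly Gaussian, no filter
edge transients), orthogonalized within a pool; a hook accepts external
source series (e.g. principal components of recorded firing rates).
Independent noise is 50 Hz low-pass. Fluctuations mix common and
independent parts in a 25:75 variance split with total SD 0.03 mS, added
to the scenario baseline conductance (0.5 mS in purely excitatory
scenarios; auto-tuned per scenario by bisection on the mean firing rate of
continuously active neurons, bracketed ±0.15 mS around calibrated
defaults). Heterogeneous distributions draw weights uniform(0,1) passed
through a softmax with temperature 0.1 (rows sum to 1; mean maximum weight
~0.82 by direct Monte Carlo). Scenario vii's three per-pool sources share a
common component giving pairwise correlation ~0.7. Inputs are generated at
200 Hz and held piecewise-constant between input samples.

**Renshaw cells.** Integrate-and-fire with τ = 8 ms, threshold 10 mV,
refractory 10 ms, driven by 50 Hz low-pass noise plus EPSP jumps from
connected motor neurons (5 ms delay both ways). Their IPSP back onto motor
neurons is an inhibitory-conductance increment decaying exponentially with
τ = 8 ms (the published description gives only an amplitude; the decay
constant mirrors the Renshaw membrane constant). Scenario vi wires 60 cells
to one pool: each cell hears an exact random 17% of the motor neurons; each
motor neuron is inhibited by ~40% of the cells (independent draws).
Scenario vii wires three pools × 60 cells: homonymous in/out densities
50%/60% (in exact subsets / per-neuron subsets), and each pool's neurons
are split by a *random* partition into thirds, two of which additionally
hear one shared random 60% subset of one heteronymous pool's cells. The
random partition matters: an index-based split would correlate subgroup
membership with recruitment threshold and exclude a subgroup from the
continuously active population. Motor neurons never excite heteronymous
Renshaw cells. PSP amplitudes and the Renshaw drive are per-scenario
calibration constants (vi: EPSP 1.5 mV, IPSP 0.010 mS, drive mean 5.5 mV;
vii: EPSP 0.9 mV, IPSP 0.010 mS, drive mean ~2.3 mV with SD 1.5 mV),
adjusted — as in the original account, which states its PSPs were manually
adjusted — to put both populations in their firing bands; in scenario vii
the Renshaw noise must stay small because shot noise in the recurrent loop
otherwise adds a shared pseudo-dimension to the analyzed pool.

**Scenarios.** (i) one excitatory source, homogeneous; (ii/iii) three
excitatory sources, homogeneous/heterogeneous; (iv/v) three inhibitory
sources (plus one uniform excitatory source), homogeneous/heterogeneous,
inhibitory baseline 0.12 mS; (vi) = (i) + homonymous Renshaw; (vii) three
pools with correlated sources and homonymous + heteronymous Renshaw,
analysis on pool 1 only. `run_scenario` pipes the first pool's spikes
through the identical experimental pipeline (continuity filter over
[0.5 s, duration − 0.5 s], smoothing, detrending, 64 Hz decimation,
surrogate-slope selection).

## Synthetic ground-truth generators

`latent_population` drives n units (default 30, 80 s, base rate 12 pps)
with k zero-mean 2.5 Hz band-limited latents, mixed homogeneously (equal
weights) or heterogeneously (softmax T = 0.1), plus 10% independent
latent-band noise (variance split), modulation depth 0.2 of the base rate.
Spikes come from a time-rescaled gamma-renewal process with shape 16
(ISI CoV 0.25, inside the 0.1–0.3 range of voluntary motor-unit firing);
a requested configuration whose rate trace goes negative raises an error
asking for a smaller depth. The generator returns the latents, weights and
rate traces as ground truth.

What this emulates — and what it does not: the generator reproduces the
second-order structure the factor pipeline assumes (band-limited shared
drive, renewal spiking, stationary rates), but not recruitment/derecruitment
during force ramps, rate saturation ("onion skin"), decomposition errors
(missed or spurious discharges), or nonstationary drift. Passing the
recovery tests therefore validates the inference machinery on in-model
data; it does not certify behaviour on decomposition artifacts.

`toy_emg` places per-unit biphasic templates (Gaussian spatial footprint,
σ ≈ 1.2 electrodes, centred off the outermost rows/columns) at firing
times plus white noise, returning the templates as ground truth for the
spike-triggered-averaging and localization tests.

## Numerical and testing choices

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; scenario runners split a master seed per component.
* The Euler kernel is a single numba-compiled loop over time steps with
  CSR adjacency for synapses and ring buffers for the 5 ms delays; spike
  times are exact step multiples. A 60 s, 300-neuron scenario runs in a few
  seconds; halving dt changes population spike counts by < 2%.
* Factor-analysis failures at some k (non-convergence) exclude that k and
  larger from the R² curves with a warning rather than aborting the
  selection.
* Test problem sizes are chosen for exactness, not realism: flexibility
  oracle parity uses 2 × 200 samples at 40 Hz (±1-sample lag grid) where a
  Python triple loop is feasible; dimensionality recovery uses the
  generator defaults (30 units, 80 s); scenario checks run the full 60 s
  at 300 neurons, 5 seeds each.

## Known limitations

* The diameter-to-parameter relations are calibrated, not anatomically
  sourced; conclusions about absolute conductances or rheobases should not
  be drawn from them.
* Scenario vii's selected factor count is the least stable of the seven:
  the heteronymous channels sit close to the surrogate-slope decision
  boundary, and individual seeds can select 4.
* Edge-located MUAP sources are biased one electrode inward by the blur.
* The dispersion norm-matching tolerance (0.5% of the norm range) is a
  convention; exact matching is available by passing `norm_tol=0`.
* The CLI's `dims` command infers the recording duration from the last
  spike; pass explicit segments for plateau analyses.
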