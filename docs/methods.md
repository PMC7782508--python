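# Methods

This note records the scientific assumptions, the numerical choices, and
the deliberately open design decisions behind the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Evidence model and visibility map

Each of the n predefined locations emits, every Δt = 1 ms, an independent
Gaussian evidence sample with mean +Δt if the target is there and −Δt
otherwise, and variance 8Δt/a². Samples are integrated leakily,
W ← ΔW + W·e^(−kΔt), so accumulated evidence at time T is Gaussian with
mean ±(1 − e^(−kT))/k and variance (8/a²)(1 − e^(−2kT))/(2k). The implied
sensitivity d′(T) = 2·mean/SD equals
a·√[(1 − e^(−kT)) / (k(1 + e^(−kT)))]; the test suite verifies this
identity to 1e−9 and the weak convergence of the simulated process to the
closed-form moments to <1% at 10⁵ paths.

The spatial fields a(x, y) and k(x, y) decay exponentially with the
anisotropic eccentricity √(x² + p₅y²). Because the exponentials underflow
far in the periphery, sensitivities are floored at d′ = 10⁻⁴ (equivalently
a ≥ 10⁻⁴√k); locations that invisible contribute nothing to the posterior
either way, but the floor keeps evidence variances finite.

Field fitting minimises the weighted MSE between predicted and measured d′
(weights normalised to mean 1), with 32 Latin-hypercube multi-starts of
L-BFGS-B in log-parameter space inside the box p₁ ∈ (0, 20], p₂, p₄ ∈
(0, 5], p₃ ∈ (0, 50], p₅ ∈ [0.05, 20]. A two-stage option (per-location
(a, k) fits, then the spatial fields) mirrors the classical protocol; the
one-stage fit is the default because it applies the per-sample weights
exactly.

## Posterior, memory, attention window

All posterior algebra is log-domain with max-subtraction; the per-fixation
exponents a²W/(2 + 2e^(−Tk)) routinely reach hundreds. Memory capacity M
keeps the last M fixations (including the current one); the current
fixation's exponent is always live, older ones are frozen when their
evidence stream ends.

The attended probability is the posterior summed over all predefined
locations within 0.5° (Euclidean, boundary-inclusive) of the attention
point for the constrained model, and the single fixated node otherwise. An
empty window — possible only just inside the field rim — carries zero
attended probability, so a rim fixation can neither trigger a stop nor
outlast the collapsing bound. The trial-start fixation at the field centre
is not required to be a grid node; the grid-fixating models attend the
nearest node there.

## Grid layout

The predefined locations are placed on concentric rings (11 rings for
n = 400, radius-proportional counts, deterministic phases, small fixed
radial perturbations, the outer ring exactly on the rim; minimum spacing
0.63°). This choice is deliberate: the measured attention-window geometry —
a uniformly random field point covers exactly one/two/three nodes in
roughly 44/47/8% of cases — implies a mean covered-node count near 1.64,
which is only attainable when an appreciable share of nodes sits on the
rim and loses part of its window outside the field. Interior-only layouts
(sunflower spiral ~35/56/8, hex lattice ~41/44/14) cannot match all three
fractions; a sunflower option is retained for comparison.

## Event loop and lags

The continuous-time searchers run an integer-millisecond event loop:

* A saccade-decision process starts at trial onset and restarts the moment
  a saccade is triggered. With probability 0.03 (never for the first
  saccade of a trial) the process is an express saccade whose trigger time
  is drawn from Gamma(10, 6.9 ms) + 30 ms; otherwise the saccade fires when
  the attended probability first falls below the collapsing bound.
* The eye moves (instantly) 30 ms after the trigger; evidence from the new
  fixation starts 60 ms after landing, and accumulation from the previous
  fixation continues until exactly that moment, with its fixation-specific
  (a, k) caches.
* The bound clock runs from the decision-process start, but the bound is
  first compared 90 ms in — when evidence from the attended fixation begins
  to arrive. Earlier comparison would be vacuous: the bound starts at 1 and
  any posterior is below it.
* The stop rule monitors the posterior mass of the *current fixation's*
  window every millisecond (the fixated node, or the 0.5° disc for the
  constrained model). A stop that fires during the 30 ms saccade lag
  cancels the pending saccade and responds from the current fixation. On
  stopping, the constrained model reports the global-argmax node, the
  grid-fixating models the fixated node.
* If an express saccade fires before the previous fixation's evidence ever
  arrived (possible, since express latencies can undercut the 90 ms
  pipeline), that fixation contributes no evidence: accumulation simply
  continues from the last fixation that did reach cortex until the next
  arrival. The corner is not specified by the model's sources; this
  convention follows the accumulate-until-new-information rule literally.
* Fixation durations are the intervals between consecutive instantaneous
  eye movements; the terminal fixation ends at the response.

Two numerical safeguards bound runtime without touching ordinary behaviour:
trials are truncated (flagged, scored as errors) at 600 fixations, and a
fixation that has lasted 8 s (possible only when the attended posterior
idles between the bound's floor 10^q₁ and θ_T) forces a saccade.

The hot loop is vectorised over blocks of up to 256 ms in single precision
(evidence is O(10⁻³), exponents O(10²); every decision is a threshold
comparison with wide margins), with per-fixation caches of the decay
powers so the only per-block transcendentals are one exp over the block
and the posterior normalisation.

## Selection rule

Candidates are always the n grid nodes. Candidate visibility is evaluated
at the expected next-fixation duration, 0.25 s. The penalised rule
multiplies the expected information gain by exp(−max(D, 1)/c), flat within
1° so as not to interfere with model-generated inhibition of return. Exact
score ties break by distance to the current fixation, then node index, so
replays are bit-reproducible. Express saccades use the same selection rule;
only their timing differs.

## Landing noise

Landing scatter is isotropic Gaussian with per-axis SD 0.0453·ecc + 0.364
(deg); the undershoot bias −0.1195·max(0, ecc − 10) acts along the saccade
axis toward the launch point. The source measurements were purely
horizontal saccades; applying the bias along the axis for oblique saccades
is the symmetric extension licensed by the isotropic-scatter assumption.
Out-of-field samples are redrawn (up to 100 times, then clamped to the
rim): the posterior is only defined inside the field, and the no-node
convention above would otherwise strand the searcher.

## Summary statistics and comparisons

Histogram bins (not fixed by the protocol, hence configurable and shared
between any two compared summaries): fixation duration 0–1500 ms in 25 ms
bins; saccade amplitude 0–15° in 0.5° bins; distance-to-centre 0–7.5° in
0.25° bins; 2-D fixation density rasterised at 42.857 px/deg and smoothed
with a 0.35° (15 px) Gaussian. Durations exclude each trial's first and
last fixations; locations exclude the first; fixation counts exclude
nothing. Ordinal slot j holds fixation j + 2 (duration, distance) or
saccade j + 1 (amplitude), twenty slots.

The memory sweep scores each capacity by the mean of four components:
per-ordinal B_c averaged within duration, distance and amplitude, plus one
B_c of the 2-D density. Two estimator details matter at reduced scale and
are neutral at the reference scale of 5·10⁴ trials per capacity: the
included-ordinal set is fixed by the target side only (so capacities that
produce longer searches are not scored on extra ordinals), and the plug-in
B_c is debiased by (K−1)/(8N) per side (K occupied bins). Without the
correction, small capacities — whose longer searches populate histograms
more densely — score spuriously high.

The genetic algorithm uses tournament selection (k = 3), uniform
crossover, Gaussian mutation (SD 0.12 of each box width), one elite, and
common random numbers within a generation: every candidate in a generation
is simulated with the same seed, removing most Monte-Carlo noise from
within-generation ranking. Scaled defaults (population 40, 10 generations,
300 trials per candidate) replace the reference protocol's population
150–200, 25 generations and 1000 trials per candidate; all three are
configurable. Bootstrap confidence intervals resample trials with
replacement on both sides and report mean ± 2.576·SD.

## Presets and placeholder provenance

The fitted values of the visibility field (p₁–p₅), the bound (q₁–q₃) and
the penalty scale c are not public; presets ship placeholders chosen once,
before any distributional testing, to sit at the task's design points:

* p = (10.392, 0.25, 12.0, 0.2, 1.4): foveal steady d′ = p₁/√p₃ = 3.0
  exactly (the task's calibration point), foveal integration time constant
  ~83 ms, steady d′ ≈ 1 at ~7° horizontal eccentricity, mild vertical
  anisotropy.
* q = (−5.0, 0.06, −1.0): the bound at first evidence arrival (≈2.7·10⁻³)
  sits just below the prior mass of a fresh attention window (so an
  unexplored fixation is not abandoned instantly), collapses past typical
  rejected-location posteriors within ~150–300 ms, and floors at 10⁻⁵;
  mean fixation durations come out near 250–280 ms.
* c = 8°: a short-tailed, roughly exponential amplitude distribution
  without trapping the searcher near its own fixation.

Every parameter in a config carries `provenance: paper` or
`provenance: placeholder` so downstream results cannot silently inherit
unavailable fitted values.

## Synthetic data: what it does and does not emulate

The detection-task generator draws 2IFC Bernoulli outcomes with
P(correct) = Φ(d′/√2) from a generating curve or field — matching the
equal-variance decision model used to convert rates to d′ — on a
cardinal-axes × exposure condition grid, and aggregates them into weighted
d′ samples. It emulates sampling noise and condition weighting but not
lapses, bias, learning, or inter-subject variability; passing recovery
tests therefore demonstrates estimator correctness on the model's own
generative assumptions, not robustness to real psychophysical data.
Eye-movement "targets" for the timing fits are produced by the simulator
itself at known parameters, so fitting and sweeping are validated as
self-recovery.

## Scaled test sizes

The end-to-end checks run at sizes chosen for statistical power per unit
runtime: the constraint-removal equivalence uses 5000 trials per model on
the full 400-location field; the memory-capacity recovery uses ten seeded
replicates of a reduced field (100 locations, 10°) with a narrowed
visibility map — so searches are long enough (median ~12 fixations) for a
capacity of 8 to bind — and capacities {2, 4, 8, 12, ∞} at a few hundred
trials each. Resolving adjacent capacities (6 vs 8 vs 10) requires roughly
the reference protocol's 5·10⁴ trials per capacity; at a few hundred
trials their scores differ by less than Monte-Carlo noise, which is why
the scaled sweep uses a coarser capacity ladder.

## Known limitations

* Secondary/corrective saccades are outside the model family.
* Evidence is spatially and temporally independent Gaussian; real 1/f²
  backgrounds induce correlations the models (deliberately) ignore.
* The ELM variant evaluates visibility at the 0.25 s point of the d′ time
  course by default (configurable); whether the original discrete searcher
  used that value or the steady state is not determinable from the text.
* Placeholder presets reproduce the qualitative regime (mostly-correct,
  few-fixation searches, ~250 ms fixations, short-tailed amplitudes), not
  any published performance table.
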