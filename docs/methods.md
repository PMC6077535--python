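# Methods

This note documents the models, parameter choices, and limitations behind
`sodbci`.  It is written for a reader who wants to know *why* the pipeline is
built the way it is, and what its synthetic evaluation does and does not show.

## The problem being modeled

In a stimulus-on-device BCI the visual stimulus lives on the controlled
appliance and is triggered over a wireless link.  Event markers record the
coordinator's *send* time; the flash on the device happens one transmission
delay later, and the evoked P300 follows the flash, not the marker.  Feature
windows placed at a fixed latency after the marker therefore drift off the
response as the delay grows, and the same happens across subjects because P300
latency itself is subject-dependent.  The package's core idea: the 16 Hz
flicker response (SSVEP) is phase-locked to the *delayed* stimulus, so its
phase lag measures the delay without any extra hardware, and a regression from
phase lag to P300 latency centroid lets the decoder re-center its windows.

## Synthetic sessions (`synthgen`)

The generator is the package's study population; its defaults define the
conditions under which every reported number is computed.

- **Paradigm geometry** — 4 stimulation nodes; 16 Hz flicker, 5 s per phase
  condition with 2 s gaps; 8 Hz oddball flashes (125 ms SOA); registration
  blocks of 30 flashes per stimulus (120 flashes, 30 target / 90 nontarget per
  registered node); online trials of 5 repetitions × 4 nodes; 500 Hz sampling
  on P3/Pz/P4/O1/O2.
- **SSVEP model** — a sinusoid at the flicker frequency (plus a 20% second
  harmonic) on O1/O2 whose first positive peak sits at
  t_ref + φ·T/360 + delay; t_ref = T/4 = 15.625 ms.  Amplitude 2 µV.
- **P300 model** — a positive Gaussian bump, SD 22 ms, amplitude 4 µV on
  P3/Pz/P4 and half that on O1/O2, centered at
  base latency + transmission delay + per-flash jitter + neural jitter
  (Gaussian, SD 8 ms; flash jitter SD 2 ms, truncated at zero).  A narrower
  template than the ~40 ms-SD bumps sometimes used for ERP simulation is
  deliberate: transmission delays are bounded by one flicker period
  (62.5 ms), and with a very broad deflection *any* 60–160 ms window keeps
  most of the response energy, which would erase the very window-placement
  sensitivity this paradigm is about.  An SD of 22 ms (FWHM ≈ 52 ms) is
  within the range of sharp parietal P3 peaks and makes window placement
  matter on the delay scale the wireless link produces.
- **Background noise** — an equal-power mix of 1/f-shaped and white noise,
  total SD 12 µV, independent across channels.  Real EEG noise is spatially
  correlated; independent noise makes spatial averaging slightly more
  effective than in reality (see Limitations).
- **Subject variation** — cohorts draw base latency ~ N(310, 35²) ms and
  amplitude ~ N(4, 1²) µV (floored at 2.5 µV: a subject without a measurable
  P300 cannot be registered, mirroring subject screening in practice).
  The defaults put selection accuracy in the mid-70s to low-90s percent —
  the operating range this class of four-choice P300 systems reports — so
  neither floor nor ceiling effects mask window-placement differences.
- **Markers record send time.**  All delay lives in the signal.  Ground-truth
  tables (true flash onsets, true latencies, true phase lags) ride along with
  every session, enabling parameter-recovery tests.

## Preprocessing (`preprocess`)

- 4–20 Hz 4th-order Butterworth applied forward–backward (`sosfiltfilt`).
  Zero phase is non-negotiable: latency is the measurand.
- Epochs are half-open sample windows, 0-based, `sample = floor(t·rate)`.
- Decimation to 62.5 Hz keeps phase-0 samples; the 20 Hz band edge is below
  the 31.25 Hz post-decimation Nyquist, so no extra anti-aliasing is needed.
- Averaging order is filter → epoch → average → downsample; filtering first
  avoids per-epoch edge transients, and downsampling last costs nothing.
- **Latency centroid**: on the P3/Pz/P4 mean, find the maximum in the search
  window (default 200–500 ms), then take the amplitude-weighted mean time
  over a contiguous run of samples ≥ 50% of that peak.  When several runs
  clear the threshold the one with the largest area wins — a broad evoked
  deflection beats a narrow noise spike of similar height, which matters for
  the noisy sub-averages used to build the calibration dataset.  For a clean
  symmetric bump the centroid equals the peak latency.

## SSVEP phase (`ssvep_phase`)

Peak latency comes from the Fourier component at exactly the flicker
frequency over the full 5 s block (80 cycles → leakage-free bin).  A 16 Hz
cycle is 31.25 samples at 500 Hz, so time-domain peak picking would need
interpolation anyway; the Fourier phase gives the answer in closed form, and
a folding-plus-interpolation cross-check in the test suite agrees within
2 ms.  Lags are wrapped to [0°, 360°), which assumes delays below one flicker
period — the design constraint of the paradigm.  O1/O2 feed the SSVEP
estimate; P3/Pz/P4 feed the P300 centroid.

## Fuzzy regressor (`it2fls`)

- Gaussian membership functions with uncertain mean `[m_low, m_high]` and
  fixed σ per MF; lower grade = min of the two edge Gaussians, upper = 1
  inside the mean band.
- **Diagonal rule base**: rule *j* pairs MF *j* of all four inputs under a
  product t-norm.  A full grid would need 3⁴ = 81 rules and blow the
  parameter vector up past 500 dimensions; the diagonal keeps it at
  D = 4·3·3 + 3·2 = 42, which a bee colony can search at desk scale.  The
  four inputs are deterministic functions of a single latent delay, so their
  joint support is (piecewise) one-dimensional and three diagonal rules
  cover it.
- Karnik–Mendel center-of-sets reduction, iterated on the integer switch
  point (exact termination, no tolerance).  The test suite checks it against
  exhaustive enumeration of the 2ⁿ firing-weight vertices on 10⁴ random
  instances (max |Δ| < 10⁻⁹).  Output = interval midpoint.

## Bee-colony training (`abc_trainer`)

Classic employed/onlooker/scout ABC with greedy per-source selection,
roulette onlookers, at most one scout per cycle, and a separately tracked
global best (so best fitness is provably monotone).  Fitness is 1/SSE with a
cap at 10¹² for perfect fits; a candidate that fires no rule on a pair is
charged the squared width of the consequent box for that pair.  Out-of-order
parameters are repaired by sorting (means, consequent endpoints) rather than
rejected, keeping the search box convex.

Defaults: colony 30, limit 50, 500 cycles; means in [0°, 360°], σ in
[5°, 120°], consequents in [200, 600] ms.  Inside the end-to-end experiment
grid the registration problem is small (16 pairs, 4 distinct inputs), so the
workflow uses a scaled budget (colony 20, 150 cycles) that converges to the
same few-ms residuals in a fraction of the time.

**Calibration dataset**: registration produces one phase-lag vector per node
but only one 30-flash average.  To give the trainer more than 4 labeled
pairs, the 30 target flashes are split into 4 interleaved sub-averages of
7–8 flashes, each contributing a (lag vector, centroid) pair → K = 16 with a
60/40 train/eval split.  Sub-average centroid searches are anchored within
±60 ms of the grand-average centroid; a sub-average without a positive
deflection is skipped (and the grand centroid substituted if all fail).

## CCA spatial filter (`cca_spatial`)

M = concatenated single-trial target epochs, N = the grand average tiled per
trial; the filter solves C_MM⁻¹C_MN C_NN⁻¹C_NM W = ρ²W (and the mirrored
problem for W_N), with a relative ridge of 10⁻⁶·tr(C)/q added when a
covariance is near-singular.  Components are sorted by descending ρ, signs
fixed so the largest weight is positive, and only the first component is
kept by default (one ERP source in a 5-channel montage).  The filter is fit
on training-session target epochs only and frozen — no test-session leakage.
An SVD-based CCA (whiten + SVD) serves as the independent oracle in tests.

## Decoding and evaluation (`decode`, `workflows`)

- Calibrated window: [t_c − L/2, t_c + L/2] around the node's predicted
  centroid; fixed window: [300, 300 + L] ms after the trigger.  Sweep
  L ∈ {160, 140, 120, 100, 80, 60} ms.
- RBF SVM on standardized features; C ∈ {0.1, 1, 10, 100},
  γ ∈ {0.001, 0.01, 0.1, 1} by stratified 5-fold CV on the training session.
  Four-way selection = argmax of the decision value, ties to the lowest node
  id.
- ITR uses the Wolpaw definition with a 3.0 s selection time (4 nodes × 5
  repetitions × 125 ms of stimulation plus a 0.5 s epoch tail); the
  P·log P terms at P ∈ {0, 1} are taken as continuity limits.
- Two-session protocol: session 1 trains CCA + SVM (and registration trains
  the fuzzy model), session 2 is scored.  Table aggregation rounds half away
  from zero to one decimal.  Two cells of the distributed benchmark table are
  inconsistent with that rounding by exactly 0.1 (truncation in the original
  typesetting); they are flagged and excluded from exact aggregation checks.

### Directional studies

- `calibration_effect_study`: 10 subjects whose node delays are drawn
  uniformly from [20, 50] ms, 50 trials per session, epoch lengths
  100/80/60 ms; reports paired calibrated-vs-fixed accuracies.
- `delay_gap_study`: a controlled single-factor experiment — all four nodes
  share one injected delay δ ∈ {0, 15, 30, 45} ms, the cohort's base-latency
  spread is held small (SD 10 ms) and amplitude fixed at 3.5 µV so the
  injected delay is the dominant mis-centering source and accuracy sits
  below ceiling.  The calibrated-minus-fixed gap is reported per δ; its rank
  correlation with δ is positive.

- `replicate_latency_correlation`: eight nodes with delays spanning
  0–50 ms; per node, the measured P300 centroid is paired with the measured
  zero-condition phase lag and the Pearson correlation reported.  Lags are
  measured on the wrapped [0°, 360°) chart, so a zero-delay node whose lag
  lands just under 360° (noise pushing ~0° across the wrap) would break a
  linear correlation; because true delays are bounded well below one
  period, lags above 330° are unwrapped to small negative values first.

Problem sizes (10 subjects, 25–50 trials, scaled ABC budget) were chosen so a
full study completes in minutes on a single core while keeping the median
estimates stable across seeds.

## Numerical conventions

- All randomness flows through `numpy.random.default_rng` seeds; sessions,
  training, and experiments are bit-reproducible given a seed.
- JSON serialization uses full `repr` floats (round-trip exact); TSV loading
  uses pandas' `round_trip` float parser for the same reason.
- Degenerate inputs fail loudly with typed errors: `NoP300Error`,
  `NoSSVEPError`, `NoRuleFiredError`, rather than returning sentinels.

## Limitations

- Synthetic noise is spatially independent; real EEG noise is correlated
  across channels, so absolute accuracies here are optimistic and only the
  *contrasts* (calibrated vs fixed, trends over delay and epoch length)
  should be carried over to real data.
- The P300 is a single parametric bump: no N200/P3a structure, no
  habituation over a session, no artifacts (blinks, EMG) — artifact
  rejection is explicitly out of scope.
- The phase-lag chart wraps at one flicker period; delays ≥ 62.5 ms are
  aliased and the calibration cannot distinguish them by design.
- The diagonal rule base assumes the four lags move together (one shared
  delay).  Nodes with grossly inconsistent condition lags (hardware faults)
  would need a richer rule base.
- The 3.0 s selection time is a convention; reported ITRs scale inversely
  with whatever a deployment's true trial pacing is.
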