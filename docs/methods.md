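# Methods

This note documents the generative model, the estimators, the statistical
conventions and the numerical choices behind larvarc, and what the
synthetic validation does and does not establish about real data.

## 1. Generative model of the behavioural assay

Each virtual larva is an independent two-state chain (RUN/TURN) on the
session frame clock (default 4 Hz).  All animals see the *same* LED
sequence, as in a shared arena.  With `s_t ∈ {−1, +1}` the encoded stimulus
(ON = +1, OFF = −1) and `k` a causal filter over lags `0..L−1` frames, the
per-frame switching probabilities are

    P(run → turn starts at frame t) = min(1 − 10⁻⁶, λ_rt · dt · exp(Σ_l k_l s_{t−l}))
    P(turn → run starts at frame t) = min(1 − 10⁻⁶, λ_tr · dt · exp(σ · Σ_l k_l s_{t−l}))

This is a linear–nonlinear hazard model: a linear stimulus filter followed
by an exponential nonlinearity multiplying a baseline hazard.  It is the
minimal model in which, under a white (Bernoulli) stimulus, the
transition-triggered stimulus average is a monotone image of the filter —
per lag, `E[s | event] = tanh(k_l)` when lags contribute independently — so
reverse correlation has a well-defined ground truth to recover.

Parameters, defaults, and why:

| parameter | default | meaning / rationale |
|---|---|---|
| `λ_rt` | 0.1 s⁻¹ | baseline run→turn hazard; ~10 s unstimulated runs, typical of freely crawling larvae |
| `λ_tr` | 0.5 s⁻¹ | baseline turn→run hazard; ~2 s turns (turn-duration statistics for this assay are not established, so this is a package convention) |
| `k` (aversive preset) | 0.3·exp(−lag/1 s), 2.5 s support | log-hazard gain per unit stimulus; gives a tanh(0.3) ≈ 0.29 TA at lag 0 and an ~e^{2Σk} ≈ 12-fold hazard ratio across a full OFF→ON step — a strong aversive response |
| `σ` (`turn_filter_sign`) | −1 | the same filter with opposite sign on the turn→run hazard: input that triggers turns also prolongs them |
| `n_animals` | 120 | arena population per session/curve |
| `duration_s` | 600 s | session length |
| `bernoulli_p` | 0.5 | P(ON) per frame of the white flicker |

Conventions: animals start in RUN at frame 0; stimulus history before the
session is imputed as OFF (−1), matching dark rearing (configurable only by
constructing a longer stimulus).  Hazards are clipped at 1 − 10⁻⁶ per frame
rather than raising, so extreme-parameter property tests remain runnable; a
warning is logged if more than 1% of frame hazards clip.  Frame indexing is
0-based with half-open windows throughout.

What the generator does **not** emulate: arena geometry, spatial gradients
and taxis, head-sweep kinematics, inter-animal interactions or collisions,
tracking noise and identity swaps, refractoriness or non-exponential
sojourn shapes.  Passing validation therefore shows the *estimators* are
correct and calibrated under the model's assumptions, not that real larvae
obey the model.

## 2. Transition detection and triggered averages

A transition event is dated to the **first frame of the new state**; lag 0
of the triggered average is the stimulus on that initiation frame (the
pre-event window includes the decision frame).  State changes whose
flanking frames straddle a lost-tracking gap are discarded — the initiation
frame is unknown — and counted in the report.

The TA over lags −W..0 (default window 20 s, comfortably longer than
plausible filter memory at 4 Hz) averages the encoded stimulus across
events.  Events starting before frame W lack a full window and are
**excluded, not zero-padded**: padding would bias the average toward the
imputed value, exclusion is unbiased and is logged.  No smoothing or
normalization is applied to the TA.

### Uncertainty of the TA

Because every animal sees the same LED sequence, two events that coincide
on a frame contribute *identical* stimulus samples at every lag.  At
realistic event densities (120 animals × 600 s at λ_rt = 0.1 s⁻¹ gives
~2.5 events per frame) the classical "sample SD across events / √n"
formula treats those duplicates as independent and understates the SEM
roughly √(μ+1)-fold (μ = events per frame): measured coverage of zero by
the ±1.96·SEM band on stimulus-independent populations was ~71% instead of
95%.  The default estimator is therefore the **one-way cluster-robust
SEM**, clustering events by initiation frame:

    sem²[l] = Σ_f ( m_f · (s_{f+l} − mean[l]) )² / n²

with `m_f` the number of events at frame f.  It reduces to the plain
formula (population-variance form) when no events coincide, and its
measured null coverage at study scale is 95.2%.  The classical formula
remains available as `sem_method="event"` for sparse-event regimes.  SEM is
computed across events, not animals; per-animal aggregation can be done by
computing TAs per animal's events.

### Oracle

A naive per-event, per-lag double loop (`validation.brute_force_triggered_average`)
serves as the reference implementation; the vectorized path reproduces its
mean, event count and across-event SEM bit-exactly (the cluster SEM to one
ulp, as the two paths accumulate clusters in different orders).

## 3. Step-response probabilities and the z-test

For a single OFF→ON step, time is cut into 0.25 s bins (one frame at 4 Hz)
and per bin

    probability = (# animals initiating a transition of the kind) / (# animals in the arena)

An animal is "in the arena" for a bin's denominator when its track has at
least one valid frame in the bin, so tracking loss shrinks `n_at_risk`
explicitly.  At sub-second bins an animal can initiate at most once per
bin, so Σ probability·n_at_risk equals the number of events used.

The baseline is the mean probability over the pre-step bins (optionally
only the last `baseline_window_s` of them).  The test compares the **peak**
post-step bin `p̂` against the baseline `p₀` with the normal approximation
to the binomial, `z = (p̂ − p₀)/√(p₀(1−p₀)/n)`, one-sided by default (the
hypothesis is an increase in turn initiation; two-sided available).  The
validity flag records `n·p̂ ≥ 5` and `n·(1−p̂) ≥ 5` at the peak; with no
events (or a degenerate baseline of 0 or 1) the z-test is undefined and the
result is reported as invalid rather than raising.  Peak selection across
bins is implicit in this design; the chosen bin is reported and no
multiple-testing correction is applied across bins.

## 4. Calcium imaging ΔF/F

Traces follow the wash/stimulation/wash protocol: 100 frames of water, 200
frames of tastant, ≥100 frames of water again at 85 ms per frame.

    ΔF/F (%) = 100 · (F_peak − F0) / F0

* **F0** is the mean of five unstimulated frames.  Which five is a
  convention; the default is the five frames immediately preceding
  stimulation onset (frames 95–99), the choice that minimizes bleaching
  bias between F0 and the response window.  Configurable via `f0_frames`.
* **F_peak** is the raw maximum over the stimulation window `[100, 300)`.
  A centered moving-average pre-filter is available (`smooth_frames`) but
  off by default, matching the protocol's literal definition; note the raw
  maximum of a noisy window is biased upward, which is exactly why testing
  is done against the water baseline rather than against zero.

ΔF/F is invariant under detector gain (multiplicative rescaling) and *not*
under additive offsets — an offset `c` rescales it by `F0/(F0+c)`; both
properties are tested.  Bleaching is handled only through the water
baseline (the baseline itself shifts by the bleach-induced amount), not by
detrending.

The water baseline is kept as a distribution per neuron class (≥3
measurements required).  Tastant responses are compared to it with the
Wilcoxon signed-rank test when measurements are paired (equal sizes,
matched by position), otherwise the rank-sum test with a logged notice.
Exact p-values are used for n < 25 without ties, the normal approximation
otherwise.  Stars: `*` P<0.05, `**` P<0.01, `***` P<0.001.

The synthetic trace generator (baseline × bleach^t + unit-peak
double-exponential transient × amplitude × baseline + Gaussian noise;
defaults f0 = 100, noise SD = 2, bleach 0.9995/frame, rise τ = 5 frames,
decay τ = 40 frames) fixes the conditions under which the signed-rank test
holds its size (measured type-I ≈ 0.04 at α = 0.05, slightly conservative
because the exact n = 8 null is discrete) and detects amplitude-0.3
responders with ≥80% power at n = 8.

## 5. Two-choice preference statistics

    PI = (N_stimulus − N_control) / (N_stimulus + N_control)

Neutral-zone animals are excluded from the denominator — the assay counts
"larvae on both sides" — with an `N_total` denominator available by flag.
PI is undefined (error) when both side counts are zero.  Group comparisons
use the rank-sum test (independent groups) or signed-rank test (paired),
with the same exact/asymptotic convention and star thresholds as above.
The count generator draws multinomial (neutral, stimulus side, control
side) splits per plate; defaults 30 larvae, 15 plates, 10% neutral.

## 6. Validation suite and problem sizes

`larvarc.validation` backs both `tests/test_acceptance.py` and
`scripts/acceptance.py`.  Problem sizes are the package's study
conditions: 20 randomized oracle fixtures; 500 sessions of 120 animals ×
600 s for band calibration; 20 replicates at the same scale for filter
recovery (Pearson r computed over lags −5..0 s against the time-reversed,
zero-padded true filter); 20 replicates of 120 animals × 60 s with a step
at 30 s; 1000 null replicates for each test-size check; 200 replicates for
the two-choice power scenario (p = 0.75 vs 0.5).  All randomness derives
from a single `--seed` through named `SeedSequence` streams, so every
number is reproducible.

## 7. Known limitations

* The LN hazard model is forward-simulation only; no filter *fitting* (GLM
  or otherwise) is provided, and no second-order (covariance) analysis.
* The TA-vs-tanh(k) identity is exact only for lag-independent
  contributions; state availability (an animal must be running to initiate
  a turn) induces small systematic deviations at long lags, visible as
  recovery correlations slightly below 1.
* The cluster-robust SEM treats different frames as independent, which is
  exact for white stimuli but would under-cover for temporally correlated
  stimuli.
* The step-response z-test inherits the usual caveats of testing a
  selected peak; the selection is reported, not corrected for.
* Tracker-output schemas vary between laboratories; the TSV schema here is
  a package convention, not an external standard.
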