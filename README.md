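# larvarc

Reverse-correlation analysis of larval run/turn navigation under optogenetic
white-noise stimulation, together with the two companion analyses of such
experiments: calcium-imaging ΔF/F quantification with water-baseline testing,
and two-choice preference-index statistics.

## The scientific problem

Crawling *Drosophila* larvae navigate with two behavioural states: **runs**
(forward peristalsis) and **turns** (head sweeps that reorient the animal).
Sensory input steers navigation by modulating the probability of switching
between these states — an aversive signal makes a running animal more likely
to initiate a turn and a turning animal less likely to resume a run.

To measure *how* a sensory neuron drives these decisions, the neuron is
activated optogenetically (e.g. CsChrimson) with a **Bernoulli flicker**: the
LED is ON or OFF independently at every camera frame (4 Hz), the simplest
white process.  Encoding ON as +1 and OFF as −1 and averaging the stimulus
that preceded each behavioural transition yields the **transition-triggered
average (TA)** — a reverse-correlation estimate of the temporal filter
linking neural activation to the decision.  A complementary **step-response**
experiment applies a single OFF→ON light step and tracks the per-0.25-s-bin
probability that an animal initiates a turn (animals initiating / animals in
the arena), tested against the pre-step baseline with a binomial z-test under
the validity rule *np* ≥ 5 and *n*(1−*p*) ≥ 5.

The package implements this full chain for users analysing (or modelling)
such assays:

* `larvarc.synthetic_data` — a generative model of the experiment: each
  animal is a two-state chain whose per-frame run→turn switching probability
  is `clip(λ_rt·dt·exp(Σ_l k_l s_{t−l}))` — a linear-nonlinear hazard model
  with filter `k` applied to the ±1 stimulus `s` — plus generators for
  Bernoulli/step stimuli, calcium traces and two-choice counts, all pure
  functions of (parameters, seed) with a ground-truth sidecar.
* `larvarc.revcorr` — transition detection, triggered averages with
  calibrated uncertainty bands, and step-response probabilities with the
  z-test and validity rule.
* `larvarc.calcium` — ΔF/F(%) = 100·(F_peak − F0)/F0 for wash/stimulation/
  wash protocols (100/200/100 frames at 85 ms), water-only baselines, and
  Wilcoxon response testing with significance stars.
* `larvarc.choice_stats` — preference index PI = (N_stim − N_ctrl)/(N_stim +
  N_ctrl) and Wilcoxon group comparisons.
* `larvarc.io_core` / `larvarc.cli` — TSV readers/writers and the `larvarc`
  command-line pipeline.

Because each analysis can be run against simulated populations with a
*known* filter, the estimators are validated end-to-end (filter recovery,
band calibration, test size and power) rather than only unit-tested.

## Worked example

Simulate a 120-animal, 10-minute session with a known aversive filter
`k_l = 0.3·exp(−lag/1 s)`, then recover the filter by reverse correlation:

```python
import numpy as np
from larvarc import (AcquisitionConfig, LNPModelParams, SimulationSpec,
                     simulate_session, detect_transitions, triggered_average,
                     step_transition_probability, TransitionKind)

cfg = AcquisitionConfig()            # 4 Hz video, 0.25 s bins, 20 s TA window
model = LNPModelParams.aversive()    # known filter: 0.3*exp(-lag/1 s)
spec = SimulationSpec(n_animals=120, duration_s=600.0, seed=1)
stimulus, tracks, truth = simulate_session(model, spec, cfg)

events = [e for t in tracks for e in detect_transitions(t)]
ta = triggered_average(stimulus, events, TransitionKind.RUN_TO_TURN, config=cfg)
print(f"run->turn events used: {ta.n_events} (excluded: {ta.n_excluded})")
for lag, m, s in list(zip(ta.lags_s, ta.mean, ta.sem))[-5:]:
    print(f"  lag {lag:+5.2f} s   mean {m:+.3f} +- {s:.3f}")
r = np.corrcoef(ta.mean[::-1][:10], truth["filter_kernel"])[0, 1]
print(f"Pearson r vs true filter: {r:.3f}")
```

```
run->turn events used: 6028 (excluded: 227)
  lag -1.00 s   mean +0.053 +- 0.026
  lag -0.75 s   mean +0.071 +- 0.026
  lag -0.50 s   mean +0.143 +- 0.025
  lag -0.25 s   mean +0.222 +- 0.024
  lag +0.00 s   mean +0.277 +- 0.024
Pearson r vs true filter: 0.987
```

The TA rises toward the initiation frame — turns follow recent optogenetic
activation, the signature of an aversive input — and correlates at r = 0.99
with the (time-reversed) ground-truth filter; at lag 0 the TA ≈ tanh(k_0) =
tanh(0.3) ≈ 0.29, as the hazard model predicts.  The same population under a
light step at t = 30 s:

```python
spec2 = SimulationSpec(n_animals=120, duration_s=60.0, stimulus_kind="step",
                       step_onset_s=30.0, seed=1)
stim2, tracks2, _ = simulate_session(model, spec2, cfg)
sr = step_transition_probability(tracks2, stim2, TransitionKind.RUN_TO_TURN, cfg)
```

prints `peak P(turn)/bin = 0.117 at t = 32.25 s (baseline 0.0067, z = 14.8,
p = 6.55e-50, valid = True)`: a ~17-fold rise in turn-initiation probability
shortly after light onset, passing the np ≥ 5 validity rule.

The same pipeline is available from a shell:

```sh
larvarc simulate --out session --seed 1
larvarc revcorr --tracks session/tracks.tsv --stimulus session/stimulus.tsv --out rc
larvarc step --tracks session/tracks.tsv --stimulus session/stimulus.tsv --out st
larvarc dff --traces session/traces.tsv --water-prefix water --out dff
larvarc choice --input session/choice.tsv --out choice
```

Runs with a fixed seed regenerate their outputs byte-for-byte.

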