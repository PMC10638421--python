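# corticolink

Analysis pipeline for **ICMS-evoked cortico-cortical signaling**: how
intracortical microstimulation (ICMS) of the hand representation of primary
somatosensory cortex (S1) modulates spiking in primary motor cortex (M1),
and what that means for brain–computer interfaces (BCIs) that deliver
tactile feedback through S1 while decoding movement from M1.

The package is aimed at electrophysiologists and BCI researchers working
with Utah-array recordings. Because human ICMS datasets are access-restricted,
every analysis ships with a **synthetic-cortex generator** that emulates the
recording setup (Poisson threshold-crossing channels on ~96-channel grids,
1-s 100-Hz stimulation trains, 1.6-ms post-pulse hardware blanking) with
known ground-truth coupling, so each stage is verified by parameter
recovery.

## What it computes

- **Modulation detection** (`modulation`): the change in a motor channel's
  firing rate between the 1-s pre-train interval and the train itself,
  z-scored against a bootstrap null of baseline fluctuations
  (1000 resamples of consecutive 1-s interval pairs, with post-pulse
  blanking simulated in the baseline). A pair is modulated when its mean
  change falls beyond every null draw (empirical *p* < 0.001).
- **Pulse locking** (`pulse_locking`): the pulse-triggered average (PTA)
  bins spikes in each inter-pulse interval into 0.5-ms bins (probability of
  ≥1 spike per bin, first 2 ms masked). The phase-locking index is
  mean(peak bin ± 1) − median(valid bins); significance against 5000
  count-matched shuffle surrogates built on 20% pulse subsamples; latency
  and jitter are the mean and variance of peak-bin latencies over 20%
  resamples. Direct (pulse-locked, 2–6 ms latency, sub-ms jitter) and
  indirect (rate-shift) effects separate cleanly.
- **Somatotopy** (`somatotopy`): motor maps (per-digit modulation during
  attempted flexion, (rate_d − mean)/mean in the best 200-ms response
  window), sensory projection maps (ICMS-evoked activation grouped by the
  stimulating electrode's projected-field digit, normalized within digit),
  2-D Gaussian smoothing over the wired grid, the matched-vs-unmatched
  rank-sum test, digit-preference-rank profiles with a shuffle-then-smooth
  null, Spearman gradient maps, and activation-pattern correlations vs
  electrode distance.
- **Task dependence** (`task_dependence`): per-channel phase × amplitude
  ANOVA over squeeze / grasp / transport windows with identical ICMS
  ({20, 32, 44, 56} µA), the td-index F_interaction/F_amplitude, LDA
  amplitude classifiers within and across conditions, and naive-Bayes /
  PCA+LDA target classifiers.
- **Closed-loop decoding** (`feedback_decode`): an indirect Optimal Linear
  Estimator (ridge-regularized inversion of the linear population encoding
  model, 20-ms bins) drives a simulated reach–grasp–transport task while
  contact-triggered ICMS contaminates the velocity-tuned population.
  Compares no-stim, *linear* (52 µA throughout contact) and *biomimetic*
  (72-µA transients at contact onset/offset, 32-µA sustained) feedback by
  failure rate (χ²) and transport path length (KS / rank-sum).

## Worked example

```python
import numpy as np
from corticolink import synthetic_cortex as sc, modulation as mod, pulse_locking as pl

truth = sc.make_ground_truth(n_m1=16, n_s1=8, seed=11)       # known coupling
ses = sc.simulate_passive_session(truth, n_trains_per_channel=15, seed=12)

res = mod.modulation_table(ses.spikes, ses.trains, ses.duration_s, seed=13)
print(f"{(res['sign'] != 'none').mean():.2f} of pairs significantly modulated")

s, m = np.argwhere(truth.p_direct > 0.25)[0]                 # a direct pair
trains = [t for t in ses.trains if t.stim_channel_ids[0] == truth.s1_channel_ids[s]]
r = pl.locking_analysis(ses.spikes, trains, int(m), n_shuffles=500,
                        n_resamples=500, seed=4)
print(f"latency {r.latency_ms:.2f} ms (truth {truth.mu_lat_ms[s, m]:.2f} ms), "
      f"jitter SD {r.jitter_sd_ms:.2f} ms, p = {r.p:.4f}")
```

prints

```
0.36 of pairs significantly modulated
latency 4.57 ms (truth 4.53 ms), jitter SD 0.24 ms, p = 0.0020
```

About a third of the (motor, stim) pairs carry detectable modulation under
the default coupling density, and the pulse-locked pair's latency is
recovered to within a twentieth of a millisecond of the generating value — the
kind of check the synthetic module makes possible for every stage.

A command-line interface wraps the pipeline:

```bash
cortico-link --seed 1 --out run/ demo        # end-to-end at reduced scale
cortico-link --seed 1 --out run/ simulate    # or stage by stage
cortico-link --seed 1 --out run/ modulation
```

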