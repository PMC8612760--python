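# dendrospike

Detection, classification and quantification of **dendritic Ca²⁺ spikes**
in current-clamp recordings from pyramidal-cell dendrites, with a
ground-truth synthetic recording generator that makes every analysis
stage verifiable end to end.

## The scientific problem

Distal apical trunk dendrites of hippocampal CA3 pyramidal cells express
several kinds of regenerative depolarizing events during 1-s current
steps: backpropagating action potentials (bAPs), local Na⁺ spikes, and
two families of Ca²⁺ spikes — afterdepolarizations (ADPs, fast or slow)
that follow an initiating AP, and *dendritically initiated* (DI) spikes
that arise without any preceding AP. The two Ca²⁺ spike families have
opposite consequences for somatic output: slow ADPs drive AP bursts,
while DI spikes trigger strictly single APs and actively suppress
bursting. Telling these events apart in voltage traces, and quantifying
them consistently, is the analysis problem this package solves for
electrophysiologists working with paired soma–dendrite patch-clamp
recordings and two-photon Ca²⁺ linescans.

The classifier's central discriminator is the **dV/dt ratio**

```
ratio = dV/dt_pre / dV/dt_peak
```

where `dV/dt_peak` is the maximum dV/dt during an event and `dV/dt_pre`
the maximum in the 1.5–9 ms window preceding it: abrupt-onset events
(bAPs, Na⁺ spikes — the initiation "kink") give ratios near 0, the
concave, gradually accelerating onset of DI spikes gives ratios well
above 0.5. Around it sit the field's standard conventions: DI threshold
at the deviation from a double-exponential fit of the subthreshold step
response; amplitude = peak − threshold; width at half amplitude on
binomially smoothed traces (N = 10), capped at 300 ms; evoked-AP
counting under the return-to-baseline / 300 ms window / <100 ms ISI
rules; ΔF/F₀ with a 50 ms pre-step baseline and spike-aligned
max-of-window-means amplitudes; and nonparametric population statistics
(Mann–Whitney, Spearman).

Because no public raw recordings exist for this preparation, the
package ships a **synthetic generator** (`dendrospike.synth`) that
renders labeled sweeps — passive double-exponential charging plus event
kernels plus Gaussian noise, with per-class dendrite→soma attenuation —
alongside Ca²⁺ linescans with dye saturation and compartmentalized
spatial profiles, and cell cohorts with phenotype-conditional
morphology. Every detection and measurement routine is validated by
recovering what the generator put in.

## A worked example

```python
import numpy as np
from dendrospike import detect_and_classify
from dendrospike.metrics import di_threshold_and_amplitude, width_half_amplitude
from dendrospike.synth import generate_sweep, scenarios

config = scenarios.di_config(np.random.default_rng(0), seed=0, noise_sd=0.0)
sweep, truth = generate_sweep(config)          # one DI spike, 25.4 mV
events, aps = detect_and_classify(sweep)
di = next(e for e in events if e.label == "DI_spike")
thr, amp = di_threshold_and_amplitude(di, sweep)
width, _ = width_half_amplitude(di, sweep, thr, amp)
print(amp, width)
```

prints (see `examples/02_di_spike_metrics.py` for the full script):

```
amplitude:      25.26 mV   (generated: 25.40)
half-width:      6.47 ms
attenuation:     6.97      (generated: 6.97)
fitted tau:     0.472      (generated: 0.470)
```

i.e. the measured spike amplitude recovers the generated 25.4 mV
threshold-drive amplitude to within 0.6%, the half-width lands in the
DI range (~6.4 ms), the dual-recording amplitude ratio reproduces the
configured dendrite→soma attenuation, and the fitted exponential decay
constant of normalized amplitude vs. injected current recovers the
generating τ = 0.47.

The `examples/` directory holds one short narrative script per
capability: sweep simulation + classification, DI spike metrics, Ca²⁺
propagation/compartmentalization, cohort morphology statistics, and the
burst-vs-single-AP output-mode analysis.

A thin CLI mirrors the library for shell use:

```bash
dendrospike run --seed 0 --out-dir run/     # simulate -> detect -> quantify -> cohort
dendrospike detect --in run/sweeps.h5 --out-dir run/
```

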