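# Methods

This note documents the models, conventions and numerical choices behind
`dendrospike`: what the synthetic generator emulates, how detection and
classification work, what each measurement means, and where design
decisions were genuinely open.

## Units and data model

Time is milliseconds, voltage millivolts, current picoamperes, and
voltage slope volts per second throughout (mV/ms ≡ V/s, so derivative
code carries no conversion factors). A `SweepRecording` holds one
stimulus repetition (time base, dendritic voltage, optional somatic
voltage, injected current, step window, metadata); `CaLinescan` holds
one ROI's fluorescence trace with its dendritic distance, compartment
and dye; `CellRecord` aggregates a cell's phenotype, morphology and
event inventory. Sweeps round-trip bit-exactly through a simple HDF5
dialect (one group per sweep, arrays as datasets, metadata as
attributes) with ground-truth labels in a JSON sidecar.

## The synthetic generator

The generator's defaults are the study conditions: 1-s depolarizing
steps digitized at 50 kHz, baseline near −70 mV, dendritic input
resistance 105 MΩ, additive white Gaussian noise of 0.3 mV SD (typical
patch noise; chosen once, not tuned). A sweep is

```
v_dend = baseline + charging + Σ event kernels + noise
v_soma = baseline + charging·transfer + somatic counterparts + noise
```

*Passive charging* is a double exponential (fast "pipette" component,
τ = 2 ms, weight 0.3; slow membrane component, τ = 25 ms) reaching the
steady-state deflection R·I. Steady-state transfer is asymmetric
(dendrite→soma 0.25, soma→dendrite 0.60), matching the stronger
dendrite-to-soma attenuation of passive signals.

*Event kernels* come in two onset families. Abrupt kernels (bAPs, local
Na⁺ spikes — the initiation "kink") rise as a raised cosine over
`rise_time` and decay exponentially. Concave kernels (ADPs, DI spikes)
rise as an exponential ramp v ∝ (e^{t/τ} − 1) over 3τ, so dV/dt grows
monotonically through the whole rise — this is what makes their dV/dt
ratio high. Defaults per class (amplitude / rise / decay, ms):
bAP 60/0.3/0.9, Na⁺ 30/0.3/1.2, fast ADP 16.2/2.5/8, slow ADP
17.2/8/220, DI 25.4/4/5.6. The ADP and DI amplitudes are the reported
population means at threshold drive; the DI kinetics put its half-width
at ≈6.4 ms and the slow-ADP envelope well above the 60 ms "slow"
boundary. Slow envelopes (concave kernels with decay > 50 ms) repolarize
briefly after the peak (15% of the amplitude with a 5 ms time constant)
before settling into the plateau — a modeling choice for the otherwise
unconstrained "ramp–plateau–decay" shape that also makes the envelope
peak a well-defined anchor instead of the corner of a near-flat plateau.

*Somatic counterparts*: bAPs are somatic-origin events, so the soma
carries a full AP (amplitude 100 mV, peak leading the dendritic kernel
by 0.2 ms); dendritic-origin events are scaled down by per-class
attenuation factors (ADPs 5.06, DI 6.97 — the dual-recording population
means; Na⁺ spikes 10). When a DI spike is tagged as evoking an AP, its
decay is truncated at the AP onset with a fast release (τ = 0.3 ms):
physically, the AP's conductances cut the spike off, and numerically
this keeps AP-locked AHP metrics uncontaminated by the spike's tail.

*TTX emulation* removes bAPs and Na⁺ spikes and scales DI kernels to
their Ca²⁺-only fraction (8.2/26.9 ≈ 0.30) while leaving the concave
initial rise unchanged; pharmacology is emulated by these switches, not
modeled mechanistically.

*Ca²⁺ linescans*: each Ca²⁺-mediated event contributes an underlying
transient (exponential rise 8 ms, decay 250 ms) passed through a
saturating indicator curve — half-saturation far lower for OGB-1 (0.15)
than OGB-6F (3.0) in units of the transient — then scaled by a spatial
weight that encodes compartmentalization: slow spikes weigh 1
everywhere; fast spikes weigh 1 distally within the stimulated subtree,
0.1 in other subtrees and basal dendrites, and fall off linearly along
the soma-ward path reaching 50% at the configured drop length (160 µm).
The weight acts on the indicator response (the observed signal), which
is what the drop length describes. bAPs contribute a small transient;
Na⁺ spikes none.

*Cohorts*: morphology is drawn per phenotype from normal distributions
whose means are the reported group summaries (TE coverage 40 vs 84 µm,
trunk length 128 vs 57 µm, primary trunks 1.0 vs 1.49, branch points
4.15 vs 5.97 for ADP-only vs DI cells) and whose SDs are reconstructed
as SEM·√n from the reported SEMs; continuous fields clip at zero, counts
round (trunks ≥ 1). Random streams are per-cell substreams spawned from
the master seed, so growing a cohort never changes earlier cells.
ADP-only cells never contain DI events.

What the generator does **not** emulate: conductance-based dynamics,
cable propagation delays, spontaneous synaptic activity, electrode
artifacts, sag/rectification, trial-to-trial kinetic variability of
spikes, or dye photobleaching. Passing tests therefore demonstrate that
the analysis recovers what the generative model encodes under realistic
noise — not that it is robust to every failure mode of real recordings.

## Detection and classification

Detection runs on the charging-subtracted trace. The passive model is
fitted robustly: fast spikes are first masked structurally (|dV/dt| ≥
5 V/s, ±8 ms margin), the steady-state deflection is pinned by a low
percentile of the late-step spike-masked trace (10th percentile,
corrected for its noise bias), and the time constants are fitted with a
soft-L1 loss followed by one-sided trimming — samples *above* the fit
(event envelopes and their tails) are dropped between iterations,
samples below never are, since regenerative events only deflect upward.
If slow envelope events are found, the fit is repeated with their spans
excluded (their decay tails otherwise bias the plateau) and detection
reruns once.

Candidate events are found in two passes: a *fast pass* (binomial
smoothing, two passes; peak prominence ≥ 2 mV; a preceding dV/dt
excursion ≥ 1 V/s within 10 ms) for spike-like events, and a *slow
pass* on an AP-excised, Gaussian-smoothed trace (σ = 0.2 ms) for
gradual ADP envelopes, whose rise is too slow for the fast pass's dV/dt
gate (relaxed floor 0.08 V/s). Onsets are found by walking back from
the dV/dt peak until the derivative stays below max(5% of peak,
floor) for a sustained run — the sustain requirement keeps single noise
dips from truncating gradual onsets. Derivatives use Gaussian
smoothing at two scales (0.2 ms for events with dV/dt ≥ 20 V/s, 1.5 ms
otherwise): raw 50 kHz differentiation of 0.3 mV noise would swamp the
slow slopes that matter here. Event peaks within a 2 ms refractory
window merge into one event with secondary-peak annotations.

Classification applies, in order: (1) **bAP** — coincident with a
somatic AP (±2 ms) and dV/dt ratio below the kink threshold (0.35);
(2) **Na⁺ spike** — onset < 7 ms from step onset, abrupt, no preceding
AP; (3) **ADP** — onset within 15 ms after a bAP peak (a −2.5 ms lower
bound tolerates onsets backtracked into the initiating AP's span),
sub-labeled *slow* when the sustained depolarization (time above half
amplitude on the AP-excised trace, not clipped by riding APs) exceeds
50 ms; (4) **DI spike** — ratio ≥ 0.35 with no initiating AP; else
**unclassified**, which downstream stages skip rather than guess. The
kink threshold of 0.35 is a calibration choice: rendered abrupt kernels
give ratios < 0.1 and concave kernels > 0.5, so the boundary sits in a
wide margin; it, and all windows, are `DetectionParams` fields. Without
a somatic trace, bAPs fall back to the kink criterion plus an AP-like
amplitude/width requirement (≥ 35 mV, ≤ 6 ms), optionally checked for
amplitude stereotypy (CV ≤ 0.25) across sweep repetitions — a
convention of this package, since single-site identification beyond the
kink is otherwise under-determined. Candidate peaks are restricted to
the step window; events during the charging transient are eligible
(Na⁺ spikes live there), charging having been removed by model
subtraction.

## Measurements

*DI threshold and amplitude.* The subthreshold response is the fitted
double exponential; threshold is the voltage where the measured trace
deviates from it by more than 3× the pre-step noise SD (floor 0.05 mV)
sustained for 0.2 ms — an explicit criterion replacing visual judgment
of the inflection point. Amplitude is peak − threshold, the peak taken
on a lightly smoothed trace (two binomial passes; heavier smoothing
clips the rise/decay corner and biases amplitude low). If the fit
degenerates, the dV/dt-inflection fallback is used and flagged. The
AP-tail overestimation inherent in the amplitude convention is
reproduced as stated, not corrected.

*ADP amplitude* is referenced to V_m immediately before the initiating
AP's onset. Fast ADPs need a clear peak not obscured by an evoked AP
(±2 ms guard) and are skipped when more than two APs precede the
initiating AP; slow ADPs take the maximum sustained inter-AP voltage
with APs excised under a 2 ms guard (the guard width is this package's
choice).

*Width at half amplitude* is measured on N = 10 binomially smoothed
traces, only for spikes ≥ 5 mV with no evoked AP, with linear
interpolation at the crossings, capped at 300 ms (flagged) when voltage
does not return within the step.

*Evoked-AP counting*: APs after the initiating AP count while V_m has
not returned to 3.5 mV above the pre-step baseline, within 300 ms of
the first AP, with preceding ISI < 100 ms — evaluated sequentially, the
first failure terminating the count. "Baseline" is read as the
pre-step membrane potential (the alternative — the pre-event
steady-state depolarization — is ambiguous in the source convention;
the choice is flagged here). The return time is found on an AP-excised
smoothed trajectory.

*AHP comparison*: per AP, dV/dt_min and V_min within 12 ms after the
peak (0.1 ms Gaussian smoothing suppresses the ~7 V/s raw-derivative
noise without distorting the ~1 ms repolarization); the readouts are
the mean Ca-AP/s-AP dV/dt_min ratio and the mean V_min difference,
restricted to APs from the same injection level.

*Calcium*: ΔF/F₀ uses the 50 ms pre-step baseline mean. Spike-aligned
amplitude aligns at the first 0.3–0.4 V/s dV/dt crossing of the rise
(0.35 V/s used; slow events that never reach it align at the dV/dt
peak, flagged) and takes the maximum over post-alignment windows of
10 (OGB-1) or 3 (OGB-6F) consecutive samples of the window mean, minus
the mean of the −50 to −20 ms pre-spike period; the search spans the
whole post-alignment window unless bounded. The construction has a
known positive bias on noisy data, which the tests calibrate against a
Monte-Carlo oracle rather than remove. Propagation classification uses
the other-/same-subtree amplitude ratio with bands at 0.5 (global) and
0.2 (subtree-restricted) — calibration choices; the observed contrast
is saturating vs near-zero, far from either band. Kinetic classes:
fast < 20 ms, slow > 60 ms. The soma-ward drop distance interpolates
where the amplitude first falls below 50% of the at-pipette value.
Indicator saturation is never inverted; everything stays in ΔF/F.

*Population statistics*: Spearman rank correlation (average ranks for
ties) and two-sided Mann–Whitney U (exact null for both n ≤ 20 without
ties, normal approximation with tie correction otherwise), via scipy.
Phenotyping uses events at 300–600 pA; any DI spike puts a cell in the
DI group for morphology comparisons, while co-expression is tallied
separately. The amplitude–drive decay is fitted as y = e^{−x/τ} by
unweighted least squares on untransformed y (a log-linear fit seeds the
optimizer; log-transformed fitting is noisier), with drive normalized
as x = (I − I_thr)/I_thr — the normalization convention is fixed here
and used identically by generator and fitter, so τ recovery is
self-consistent; τ values under other conventions are not comparable.
The mixed-design propagation comparison (location × kinetic group) is
reported as paired within-group contrasts (Wilcoxon) plus a
between-group test on the cross-subtree ratio, rather than a
repeated-measures ANOVA table.

## Verification strategy and problem sizes

Every stage is tested by recovery: the generator writes ground truth,
the pipeline must read it back. The standing studies use 200 sweeps
across ten seeds for classification (≥ 95% label agreement required;
the current implementation scores 100%), noise-free single sweeps for
metric exactness (amplitude within 2%, width within one sample plus the
precomputed N = 10 smoothing-bias bound, attenuation within 1%), 1,000
randomized fixtures against a brute-force evoked-AP rule evaluator
(exact agreement), 100 noisy replicates for τ (bias < 0.05), 1,000
replicates for the calcium-amplitude bias calibration (within 5% of the
oracle), and 500 cohort replicates at n = 200/group for the
TE-coverage contrast (power > 90% at α = 0.001). These sizes keep the
full suite to a few minutes while leaving each check statistically
sharp.

## Known limitations

Classification accuracy is guaranteed only under the generative model;
real recordings add kinetic variability, spontaneous EPSPs and
overlapping events the synthetic conditions do not produce. The
charging-subtraction fit assumes a double-exponential passive response
and can bias onsets of events riding the first milliseconds of the
step. The single-site bAP fallback is a heuristic. NMDA-spike
detection is out of scope (excluded pharmacologically in the emulated
uncaging experiments), as are biophysical channel models, morphological
image segmentation, and NWB ingestion (sweeps arrive via the HDF5
dialect or in memory).
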