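# Methods

## The measurement model

A nanopore sensing run measures ionic current I(t) per detection channel at
a fixed bias. The open-pore current Io is channel-specific; a translocating
molecule reduces it to a residual level Ir for a dwell time τ. The assay's
observable is the per-event fractional blockade Ir/Io, summarised per run
as a histogram in 0.05-wide bins over [0.05, 0.60). Two maxima appear: an
early one near 0.15 — osmium-tagged probes and part of the device noise —
and a late one near 0.30 from noise and untagged RNA. The decision
statistic is the ratio R of the late-maximum count to the early-maximum
count. Adding free probe feeds only the early maximum, so R falls relative
to a probe-free buffer; a relative drop of more than 18% in both sample
runs is called **detection**, anything else **silencing**. One test =
two 45-min buffer runs (pooled by adding histogram counts) + two sample
runs.

Copy-number arithmetic is exact bookkeeping, not inference: probe copies =
volume(µL) × concentration(fM) × 600 (602.214 with the exact Avogadro
factor; 600 reproduces the published worksheet and is the default), copies
are normalized to a common total-RNA content of 16 ng/µL (copies scale
linearly with isolate RNA), and levels are expressed as folds (HL) of a
fixed healthy-serum reference panel. A threshold test places the probe at a
designed level (1.5 HL by default); detection ⇒ target below, silencing ⇒
target above. Bracketing runs a ladder of such tests: the unknown lies
between the highest silencing level and the lowest detection level, so a
40% rung spacing pins it to a half-spread/midpoint of 0.4/2.4 ≈ 16.7%
(40% when referred to the lower bound; both are reported, since "±20%"
depends on the reference point).

The screening error model treats each test as an independent Bernoulli
trial with true rate p. Requiring k concordant tests before assignment
leaves N(1−p)^k expected false assignments in a population of N; with
three tests, 3p(1−p) of subjects end two-against-one and need a fourth
test. At the protocol's estimated p = 0.97 these give 9/10,000 (k = 2),
27/10⁶ (k = 3), and 8.7%.

## Event calling

An event is a maximal run of consecutive samples with I/Io below the "all"
ratio 0.6, reported iff its length is 4–1200 tps and its minimum I/Io is
below 0.55. The entry/exit boundary at 0.6 makes the "all samples < 0.6"
condition hold by construction. Io is estimated once per channel per run as
the highest-current mode of a 1 pA-binned histogram (the open-pore plateau
dominates; ties between modes resolve to the higher current, and the
estimate is the mean of the samples in the modal bin, exact for a constant
trace). Drift within a 45-min run is ignored. The per-event depth used
downstream is the event **minimum** Ir/Io — the only per-event depth the
thresholds name; the mean is kept in the event table for sensitivity
checks. Sample indices are 0-based; durations are carried in tps
internally and converted to ms only for display (1200 tps = 400 ms at
3 kHz).

## Decision details and numerical choices

* Histogram bins are labelled by their left edge; the nominal maxima sit at
  the 0.15 and 0.30 labels. Early/late counts are the counts of the modal
  bin within the label windows [0.10, 0.20) and [0.25, 0.35); ties break
  toward the lower bin. A window-sum mode is available as a configuration
  switch.
* The ±0.05 maximum-drift rule needs peak *positions*, which the nominal
  windows cannot falsify on their own; the two dominant local maxima of
  the full histogram (plateau-aware peak finding) provide the observed
  early/late positions for the drift check. A single-peak histogram
  assigns its peak to the nearer nominal position.
* The 18% criterion is applied to the relative change of R (R is itself a
  ratio), per sample run against the pooled buffer, with a 10⁻⁹ slack so
  an exactly-18% drop does not flip on float round-off. Both sample runs
  must agree; an optional third sample run breaks ties, otherwise the test
  is rejected for disagreement.
* "Events in large excess" is quantified as total sample events > 3× total
  buffer events — a deliberately conservative default, configurable, since
  no number is published.
* Channel QC removes channels with **more than** 20,000 events (20,000
  exactly is kept); a test needs **more than** 200 active channels
  (channels reporting ≥1 event after QC). Rejection rules are checked in
  the order: pore floor, event excess, maximum drift, undefined R,
  disagreement.
* R is undefined when the early maximum holds zero events; such runs
  reject the test rather than fabricate a call.

## The synthetic-data generator

The simulator emulates the study conditions: 512 detection channels, 45-min
runs at 3 kHz, −180 mV bias recorded as metadata, and the four-run
buffer/buffer/sample/sample protocol. Given probe and target copy numbers,
hybridization is 1:1 and complete by default (free = max(0, probe −
target)); sample runs inject probe events in proportion to the free probe.

Defaults, with units and rationale:

| parameter | default | why |
| --- | --- | --- |
| open current | 220 ± 2 pA (1.5 pA trace noise) | arbitrary but fixed; all analysis uses Ir/Io |
| probe blockade | 0.15 ± 0.03 | the early maximum |
| background blockade | 0.30 ± 0.05 | the late maximum |
| background early fraction | 0.25 | buffer runs show both maxima (device noise has a 0.15 mode), which is what makes the buffer R finite and stable |
| probe events / channel / run / 100k copies | 60 | free calibration constant: the protocol's ~100,000-copy working point must be comfortably detectable over noise |
| background events / channel / run | 60 | keeps a full run under ~10⁶ events |
| fast-RNA miss fraction | 0.95 | most untagged RNA is too fast to register; rendered as sub-4-tps dips that can never be called |
| pore attrition / run | 0.05 | active channels decay run over run |
| noisy-channel fraction | 0.02 (~22,000 events each) | exercises the >20,000-event QC rule; "typically less than 5%" |

Durations are log-normal (median 60 tps for probes, 12 for background),
clipped to [4, 1200]; dips are square pulses with 1 pA within-event noise —
no sub-event structure, since the decision uses only depth and duration.
Every draw descends deterministically from the seed (per-channel
substreams keyed by seed, run index, and channel for trace rendering), so
identical configurations are bit-identical. Overlapping dips are thinned
(earlier event wins) before rendering so injected events never merge.

A vectorised event-table fast path draws the same populations, rates,
attrition, and noisy channels but skips waveform synthesis, emitting the
table the caller would produce with the nominal depth standing in for the
rendered minimum. Replicated statistical checks (classification accuracy,
bracket recovery) use this path; rendering 4 × 45 min × 512 channels at
3 kHz per replicate (~4×10⁹ samples) is not a sensible use of anyone's
CPU. The trace path is exercised end-to-end at reduced scale (a few
channels, fractions of a minute, boosted per-channel rates), where the
caller recovers ≥95% of eligible injected events; this ties the two paths
together.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: electro-physical pore behaviour (no capture
physics; the copies→rate map is a single linear constant), flow-cell aging
beyond geometric channel loss, within-run drift of Io, partial or
sequence-dependent hybridization efficiency (available as a knob, defaults
to 1), sub-event current structure, and any real-specimen matrix effects.
Classification accuracy measured on simulation validates the decision
logic under the stated noise model, not the wet-lab assay.

## Problem sizes used in the test suite

Statistical claims are checked at sizes chosen to give stable verdicts:
1000 random traces for caller/oracle equivalence; 800 channel-replicates
for the Poisson goodness-of-fit (χ², α = 0.01); 100 replicates per
expression group (healthy 1.04 HL, RSD 0.17; cancer 1.83 HL, RSD 0.09)
for the ≥95% classification check; 48 bracketing ladders of 7 rungs
(0.30–2.26 HL, ×1.4 spacing) across true levels 0.5–1.8 HL. Bracketing
replicates place ~100k probe copies at every rung — the protocol's working
point — with the target scaled to its true level relative to the rung.

## Known limitations

* The copies-to-event-rate constant is not identifiable from published
  material; absolute event counts are only meaningful relative to the
  configured calibration.
* The decision uses the modal-bin count by default; if real histograms are
  flat-topped, window sums (provided) are more robust.
* Bracketing assumes a monotone ladder; a rejected rung simply drops out,
  widening the bracket rather than failing the estimate.
* The cohort error model assumes independent, identically-true tests;
  correlated failure modes (a bad flow cell, a degraded probe lot) violate
  it and would make the concordance projections optimistic.
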