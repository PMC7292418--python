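# Methods

`vliver` is a discrete-event, agent-oriented simulator of
acetaminophen (APAP)-induced hepatotoxicity in a virtual mouse, built to
contrast competing mechanisms of alanine aminotransferase (ALT) release
from damaged and dying hepatocytes. This note documents the model, its
assumptions, the parameters that matter, and the design decisions taken
where the design was genuinely open.

## The virtual mouse

A Mouse comprises a Body compartment, a Dose reservoir (intraperitoneal
dosing), and a vLiver of Monte Carlo-sampled lobule variants. Time
advances in discrete one-second cycles; all hour-denominated parameters
are stored in cycles.

### Lobule structure

Each vLobule is a three-layer directed acyclic graph of Sinusoid Segments
(SSs). Flow runs portal vein (PV) -> layer 1 -> 2 -> 3 -> central vein
(CV); one upstream SS can feed several downstream SSs. An SS is a
quasi-3D cylinder collapsed to a chain of axial Core grid positions whose
sampled circumference sets the number of cell slots per position; virtual
hepatocytes (vHPCs) occupy 90% of hepatocyte slots, virtual endothelial
cells 99% of theirs. All SS dimensions are re-sampled from configured
integer ranges at the start of every execution. A biomimetic constraint
forbids more SSs in layer 3 than in layer 2.

Zonal position is summarised by two 1-based distances: `dPV` (axial
position plus the rounded mean core length of upstream layers, in grid
points) and `dCV` (the mirror image). The normalised coordinate
`z = dPV/(dPV + dCV)` is the argument of every periportal-to-pericentral
gradient; any strictly monotone alternative could be substituted in
configuration. Three lobular bands are defined on these axes: periportal
(PP, a dPV prefix), mid-zonal (M-Z, a dPV interval) and pericentral (PC,
a dCV prefix). Bands are partial covers: the shipped cut points
(PP dPV 1-4, M-Z dPV 11-15, PC dCV 1-4) were calibrated, together with
the layer sampling ranges, against whole-lobule reference statistics
(mean ~16,165 vHPCs per lobule; ~85.3% of vHPCs at dPV 1-14; ~14.1% at
dCV 1-12; band means ~4772/1721/906), since the underlying anatomical
sampling ranges are not themselves published. The dPV histogram is
right-skewed (long tail of PV-to-CV path lengths).

One interpretive choice deserves emphasis: a sampled lobule is treated as
a self-contained representative miniature of whole-liver flow, so *each*
lobule variant in a liver receives the full dose, and whole-mouse Body
amounts are reported as means across variants. Splitting a capped dose
(<= 100,000 objects) across a dozen lobules of ~16k vHPCs each would give
per-cell exposures far too small to reproduce the documented pericentral
event timing.

### Compound transport

Mobile Compounds (APAP, the lumped metabolites G and S, externalized ALT,
and an inert Marker) are integer counts per axial slot. Each cycle a
fraction (default 0.005) of the remaining Body dose enters the PV and is
spread across layer-1 SS inlets; each mobile object then steps toward the
CV with probability `downstream_bias` (default 0.5) and otherwise holds.
The movement kernel is deliberately minimal — any conservation-preserving
kernel with PV->CV drift would conform. Objects reaching the CV are moved
to Body the same cycle. Compounds returned to Body do not re-enter the
liver (single-pass); within the simulated 6-12 h horizon recirculation of
unmetabolised APAP is treated as second-order, and neither ALT nor Marker
is cleared from Body, so their Body series are monotone. Cell entry
(APAP only; Marker is extracellular-only, like sucrose in vivo), exit of
free intracellular compounds, and non-specific binding by endothelial and
hepatocyte binders are independent per-object Bernoulli events; bound
objects are immobile for the cycle. Binder pools have no hard capacity —
binding is a retention abstraction, not receptor kinetics.

### Hepatocyte events

Within each vHPC, per cycle (the order of the intracellular event classes
is re-randomized every cycle):

* **Metabolism** — each free intracellular APAP is metabolised with
  probability `p_metabolism(z)`; the product is NAPQI with probability
  `p_napqi(z)`, otherwise G or S with equal probability.
* **NAPQI removal and damage** — each NAPQI is removed with probability
  0.5 per cycle. While the real-valued GSH counter is positive, a removal
  decrements it by 1.0 and is harmless; the counter's initial value
  `gsh_threshold(z)` maps to the cell's effective glutathione reserve and
  never regenerates. Once the counter is zero, every removal creates
  `n + 1` Damage Products with `n` drawn uniformly from the integers
  {3..6} (the amplification range is configured as an inclusive integer
  interval), all of one type: mitochondrial (MitoD) with probability
  `p_mito_fraction` (default 0.5), else non-mitochondrial (nonMD).
* **Mitigation** — at most one MitoD and one nonMD removal event per
  cycle, with probabilities `p_mitigate_mitod(z)` (falling PP->PC) and
  `p_mitigate_nonmd(z)` (rising PP->PC). A per-product Bernoulli variant
  would be a one-line change; one-event-per-cycle is the documented
  default.
* **Necrosis** — MitoD strictly above the necrosis threshold (default 4)
  triggers necrosis; the cell turns Necrotic after a death delay drawn
  uniformly from [7200, 21600) cycles ([2, 6) h), then externalizes all
  remaining ALT with zero delay and performs no further events.
* **ALT leakage** — each vHPC starts with an ALT counter of 5. Under the
  MitoD-Caused, nonMD-Caused or Dual-Cause mechanism, damage above the
  leakage threshold (default 1) makes the cell Leakage-Triggered. While
  triggered and unscheduled ALT remains, one release is scheduled per
  cycle at a lag drawn uniformly from [2700, 18000) cycles ([0.75, 5) h;
  mean 2.875 h). A scheduled release fires at its due cycle iff the
  counter is still positive; triggering clears if damage falls back below
  threshold but scheduled releases persist. The Dual-Cause trigger is
  configurable as the *sum* of both damage types against the threshold
  (default) or as *both* types individually exceeding it — the two
  readings coexist in the source material, so both are implemented. An
  extended-lag variant (exLT) adds a constant shift (1600 cycles) to both
  lag distributions. The minimum leakage lag must be below the minimum
  death delay; configuration loading enforces this.

Scheduling one release per triggered cell per cycle is a stated choice:
the multiplicity of concurrent scheduling is not otherwise pinned down,
and the per-cell cap of five externalized ALT objects bounds any variant.
The pre-depletion NAPQI removal probability equals the post-depletion 0.5
by default (configurable separately).

### Random-number streams

Each trial derives five named PCG64 substreams — structure, disposition,
damage, release, marker — with fixed spawn keys. Release-side draws
(leakage scheduling, extracellular ALT movement) never touch the
disposition or damage streams, so switching the release mechanism or any
of its parameters leaves the APAP disposition and damage trajectories
bit-identical, and the Marker accumulation curve is invariant to all
mechanism parameters at a fixed structure seed. These invariances are
asserted by tests, not merely intended.

### Measurement

Measurement agents run at the end of every cycle (thinnable via
`measure_every`; cumulative counters are exact at every recorded cycle
regardless of thinning). They record Body amounts per Compound kind, the
un-infused dose reservoir, per-band intracellular amounts (APAP, NAPQI,
G, S, MitoD, nonMD), extracellular ALT per band (released but not yet
exited), and cumulative event counts (GSH depletion, mitigation,
Leakage-Triggered, ALT scheduled, ALT externalized, Necrosis-Triggered,
Necrotic) for the whole liver and each band. Per-kind object-conservation
ledgers are re-verified during the run (default every 600 cycles); any
mismatch raises a hard error with cycle context.

## Plasma scaling

Mean plasma ALT is a linear map of mean ALT-in-Mouse-Body:
`Y_t = S*X_t + eps` with `S = 1.72` IU ml^-1 per ALT object and `eps = 0`
by default (a Gaussian option exists for robustness studies only, since
individual random error cannot be separated from the per-animal skew).
An individual animal's value is `y_{i,t} = delta_i * (S*X_t + eps)`; each
animal contributes one observation at its own measurement time, so
`delta_i = y_{i,t} / (S*X_t)`. The individualized mapping criterion
requires the delta sample mean to lie within 1.0 +/- 0.1. The reported
coefficient of variation is `s / x-bar` of the delta sample.

Semiquantitative validation against a plasma-ALT target corridor is
supported via a user-supplied band (`time_h,lower,upper` CSV): the scaled
series must stay inside the closed corridor and be "sigmoidal",
operationalised as non-decreasing with the smoothed (moving-average,
window configurable) second difference changing sign exactly once. No
corridor ships with the package: corridor edges are study-specific and
must be supplied by the user.

## Synthetic data

The plasma-table fixture generates 18 synthetic animals (3/4.5/6 h,
round-robin) from the individualized model with known skew factors
(lognormal with sigma = 0.3, matching the observed dispersion of fitted
skews, or exactly 1) around a synthetic logistic Body-ALT reference
curve. It exercises the estimation arithmetic exactly; it does not
emulate assay noise, detection limits, or within-animal kinetic
differences, so passing recovery tests demonstrates correctness of the
inversion, not robustness to real assay error.

## Problem sizes and numerical choices

The default experiment is 12 trials x 12 lobule variants x 21,600 cycles
(6 h). The shipped verification runs use reduced sizes chosen as the
package's own desk-scale defaults: structural statistics over 50 sampled
lobules (bands over 12), and dynamic statistics from 12 trials of a
4-lobule liver over 7,200 cycles (2 h) — pericentral triggering has
plateaued well before that horizon, so the pooled PC trigger-time median
is stable against extending the run, and the damage-ordering property is
asserted over the simulated horizon. Amplification draws are integer
(discrete uniform {3,4,5,6}): products are discrete objects. A fractional
GSH counter absorbs its final partial removal without creating damage.
Uniform lag draws use integer cycles on [Min, Max). Ties and event order
inside a cycle are resolved by the per-cycle random permutation of event
classes; transport always precedes intracellular events, and necrosis
precedes leakage evaluation.

## Known limitations

* No GSH resynthesis, no ALT plasma clearance, no regeneration or
  JNK-pathway biology: the model targets the first 6-12 h only.
* A vHPC is a conflation of hepatocyte function at a zonal position, not
  a 1:1 hepatocyte; absolute object counts map to arbitrary fractions of
  molecular amounts, with all quantitative meaning carried by the scaling
  layer.
* The movement kernel, dose-transfer fraction and binder probabilities
  are free parameters constrained only by calibration targets; different
  conformant kernels would need recalibration.
* Dose-response beyond the medium dose is known to be imperfect: the
  mechanism that matches medium-dose kinetics over-predicts ALT at low
  and high doses unless thresholds and lags are re-parameterised
  (configuration hooks exist; no dose-dependent parameterisation is
  implemented).
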