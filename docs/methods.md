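# Methods

This note documents the models, estimators and numerical choices behind
`placemap`, and what the synthetic experiments do and do not establish about
real recordings.

## Spatial firing maps

The arena bounding box is divided into square bins (default 4 cm on a 120-cm
circular arena, giving a 30 × 30 grid; bins whose centre falls outside the
circle are excluded). Each tracker sample (50 Hz default) contributes one
sampling interval to its bin's occupancy, so occupancy totals equal the
analysed duration exactly and occupancies computed on an epoch partition add
up bin-wise. Spikes are assigned to the nearest-in-time position sample;
spikes farther than one sampling interval from any sample are dropped and
counted in the map's `n_spikes_dropped`.

The rate is the smoothed spike count divided by the smoothed occupancy
(normalised convolution). The Gaussian kernel has σ = 1 bin by default and is
truncated at 2σ; because counts and occupancy are zeroed outside the analysis
mask before convolution, smoothing is mask-aware: a zone-restricted map never
receives rate from bins outside the zone, and adding spikes outside the mask
leaves the masked map bin-wise unchanged. With σ = 0 the map reduces to the
raw count/occupancy quotient. Exploration epochs are approximated by a speed
threshold (default 3 cm/s); LFP-based state detection is out of scope.

Tuning measures, computed on the analysed bins:

* **Sparsity** `S = (Σ pᵢλᵢ)² / Σ pᵢλᵢ²` with occupancy weights
  `pᵢ = occᵢ/Σocc` and smoothed rates λᵢ (lower = more selective; undefined on
  an everywhere-zero map).
* **Coherence**: Pearson correlation between each bin's *unsmoothed* rate and
  the mean unsmoothed rate of its valid 8-neighbours, over bins with at least
  one valid neighbour; no Fisher z-transform (the place-cell threshold 0.55
  applies to raw r); requires ≥9 valid bins. Both measures are invariant
  under 90° grid rotations.
* **Firing field**: proportion of analysed bins with rate > 1 Hz, computed
  within each zone's own bin set so unequal zone areas cannot bias the
  in/out comparison.

The light zone is an angular sector (width 120–180°); membership is a
half-open angular test on bin centres so a 180° zone and its control sector
partition the valid bins exactly. For widths < 180° the control sector has
identical angular width, centred opposite.

## Light-response classification

**Pulse test (rest box).** 400-ms laser pulses at 0.5 Hz for 18 min
(540 pulses). For each unit, per-pulse spike counts in [onset, onset+0.4 s)
are paired with the immediately preceding 0.4-s baseline window — the 2-s
inter-pulse spacing makes this window choice safe; it is configurable. Rates
are pooled across pulses; the label is *suppressed* when the relative change
is ≤ −33% and a two-sided Wilcoxon signed-rank test on the count pairs gives
P < 0.05, *disinhibited* for ≥ +33% with significance, otherwise *remaining*
(significance dominates magnitude). A zero-baseline unit with pulse spikes
has change +∞; with no spikes at all the change is undefined and the unit is
labelled remaining with a logged warning.

**Familiar paradigm.** Place cells (sparsity < 0.3, coherence > 0.55, mean
rate > 0.25 Hz in a1 and/or a3) are labelled from the in-zone rate change of
the illuminated session: suppressed if the light-on in-zone rate in a2 drops
>50% relative to a1 *and* the pulse-test response was suppression;
disinhibited if it rises >50% with a positive pulse response; unaffected if
both the exploration and pulse changes lie within ±50%; otherwise remaining.
Rules are applied in the order suppressed → disinhibited → unaffected →
remaining, which resolves the overlap where a unit could satisfy more than
one band. A unit with zero in-zone rate in a1 is remaining (no defined
reference).

**Novel paradigm.** No unperturbed reference session exists, so the pulse
label is used directly, gated by place-cell criteria in b2 and/or b3;
sleep-remaining units with a pulse change within ±33% count as unaffected
(symmetric with the sleep criterion — the source protocol does not define
"unaffected" here, and this choice is recorded in the outputs).

## Stability and rate-remapping scores

PFS is the Pearson correlation (Spearman available) between two maps over
bins visited in both sessions (≥10 common bins required; undefined when
either series is constant). The rate-remapping score
`c = (r2 − r1)/(r2 + r1)` uses in-zone (or control-sector) mean rates from
the full exploration epochs — the light-on restriction enters only the a2/b1
classification rates, not the scores. The firing-field bias is
`(field_in − field_out)/(field_in + field_out)`; negative means a smaller
field inside the light zone. We adopt that sign convention throughout
(enlarging the inside field strictly increases the bias).

## Inference

All tests are two-sided. Families of pairwise comparisons (KS distribution
comparisons; Mann–Whitney post hoc tests after a Kruskal–Wallis omnibus) are
Holm-corrected and tagged `B1|m … Bm|m` in ascending raw-p order. Post hoc
tests are computed regardless of the omnibus outcome but flagged with whether
the omnibus reached α. Sign tests are exact binomial tests on the signs of
nonzero scores (zeros excluded). The Wilcoxon signed-rank test excludes zero
differences, midranks ties, and uses the exact null distribution (dynamic
programming over doubled midranks, equivalent to enumerating all 2ⁿ sign
assignments) up to n = 25 nonzero differences, then a normal approximation
with tie and continuity corrections; count data is tie-heavy, which is why
the exact path handles midranks. Leave-one-animal-out robustness reruns a
test with each animal excluded and reports the least significant p; it
requires ≥3 animals.

## Synthetic experiments

The generator reproduces the statistical structure the analysis assumes:

* **Trajectory**: heading random walk (diffusion 2 rad/√s) with
  Ornstein–Uhlenbeck speed (mean 15 cm/s, sd 5 cm/s, τ = 1 s), reflective
  circular boundary, sampled at 50 Hz; immobility bouts (rate 1/40 s⁻¹,
  exponential mean 3 s) exercise the rule that zone illumination is
  interrupted after >2 s without movement. A 25-min run visits >95% of valid
  bins, emulating pellet-chasing foraging.
* **Tuning**: pyramidal cells carry 1–3 Gaussian fields (probabilities
  0.5/0.35/0.15; σ = 8 cm; peak 5–20 Hz log-uniform per field) on a 0.1-Hz
  exploration baseline. Multi-field tuning is the default because real CA1
  cells commonly express several fields in an arena of this size and because
  with strictly single-field cells the firing-field bias degenerates to ±1
  (a cell's only field is either inside or outside the zone), which cannot
  express the graded bias distributions the analysis is meant to detect;
  single-field ensembles remain available via `field_count_probs=(1.0,)`.
  Interneurons have high baselines (5–20 Hz) and no spatial tuning; they
  matter only for pulse-test classification realism.
* **Rest rate**: the pulse test runs in a rest box, where pyramidal rates are
  higher than the exploration out-of-field baseline; each unit carries a
  separate rest rate (log-uniform 1–5 Hz). Conflating it with the 0.1-Hz
  exploration baseline would make the pulse test nearly spikeless and
  classification power meaningless.
* **Spiking**: inhomogeneous Poisson by thinning of a homogeneous candidate
  stream at the unit's rate ceiling, with a configurable 500-Hz cap; the
  light multiplies the instantaneous rate by the unit's gain (defaults 0.22 /
  2.34 / 1). Light-on intervals are derived per sample, so total light-on
  time equals in-zone mobile time exactly.
* **Transitions**: between the illuminated session and the next, suppressed
  cells with a field centre inside the zone have those centres redrawn
  (uniformly in-zone by default) — out-zone fields stay put, matching the
  observed stability of out-zone maps; disinhibited cells keep their fields
  but their rates scale by a persistence factor (default 1.5). The paradigm
  generator scales both peak and baseline of disinhibited cells
  (location-independent excitability increase): scaling the peak alone
  leaves out-zone-field cells contributing pure noise to the in-zone rate
  score, and the group-level positive rate remapping would not be a
  structural property of the simulation. The transition op itself defaults
  to peak-only scaling (`scale_baseline=False`).
* **Defaults**: 25-min exploration sessions, 18-min pulse sessions, zone
  width 180° at centre angle 150°, 64 pyramidal + 6 interneuron units per
  recording day, phenotype proportions (0.334, 0.211, 0.455), and 76.7%
  suppressed interneurons.

**What the synthetic data does not emulate**: theta and ripple dynamics,
spike sorting artefacts, directional or speed modulation of firing,
behavioural biases toward the zone, within-field rate variability beyond
Poisson noise, and multi-animal variability (each generated day is one
virtual animal). Passing tests therefore validate the estimators and the
inference chain under the assumed generative model, not tracker- or
sorting-related robustness on real recordings.

## Problem sizes and tolerances

Simulation-based checks use scaled problem sizes chosen to keep the full
suite fast while leaving comfortable statistical margins: pattern and null
checks run 50 simulated recording days of 96 pyramidal cells with 10-min
exploration sessions; classifier-recovery checks use 20 ensembles of 200
units with the full 540-pulse protocol. Exact algebraic identities are
asserted to 1e-12; oracle-equivalence checks compare against brute-force
reimplementations at the same tolerance. Null-calibration assertions use
Holm-corrected familywise bounds across all group comparisons a run
produces, so the expected false-alarm rate of a whole null run is ≤5%.

## Known limitations

* The classifier's paradigm labels depend on the in-zone reference rate in
  a1; very low-rate cells fall into "remaining" more often than in vivo,
  where field-targeted zones guarantee in-zone firing.
* Coherence uses the unsmoothed-rate, 8-neighbour, raw-r convention; other
  conventions (smoothed input, Fisher z) shift the 0.55 threshold's meaning
  and can be configured but are not benchmarked here.
* The leave-one-animal-out utility is exercised on synthetic groupings only;
  the single-day generator does not produce multi-animal datasets.
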