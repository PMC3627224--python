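# Methods

This package analyzes extracellular recordings from a goal-learning task on
a circular "cheeseboard" arena: a five-session day (preprobe, presleep,
~40 learning trials, postsleep, postprobe) during which place-cell
ensembles remap toward newly learned goal locations.  Two questions drive
the analysis: (1) on which theta cycles does the pyramidal population
express the old (preprobe) versus the new (postprobe) spatial map, and
(2) how does the monosynaptic coupling from pyramidal cells onto
interneurons reorganize alongside that remapping.  Because such questions
can only be validated against latent variables that real recordings never
expose, the package ships a synthetic-session generator whose every latent
quantity (per-cycle map state, connection weights over time, interneuron
association class, field parameters) is recorded as ground truth, and a
benchmark suite that measures recovery of those targets.

## Behavioral-state segmentation and oscillation detection

The theta(5–12 Hz)/delta(2–4 Hz) power ratio is computed by Thomson's
multitaper method in 1600 ms windows stepped by 800 ms (NW = 3, five
tapers; the window length fixes the spectral resolution at ~1.9 Hz, enough
to separate the two bands).  Rest is declared where running speed < 5 cm/s
and ratio < 2 hold over at least two consecutive windows (≥ 2.4 s);
isolated low windows are bridged into exploration.  Spans not covered by
both input series are reported as unlabeled, never silently filled.

Theta cycles are delimited by successive negative peaks of the zero-phase
(forward–backward Butterworth, order 3) 5–28 Hz filtered LFP; the wide band
keeps the negative-peak times sharp, and cycles are kept only when their
duration implies a 5–12 Hz frequency.  Gamma cycles use a 30–80 Hz band
with the matching duration filter.  Zero-phase filtering is used throughout
so that peak times are not displaced by filter delay.

Sharp wave/ripples are excursions of the summed 150–250 Hz RMS power
(10 ms smoothing) beyond mean + 7 SD of the rest background.  Background
statistics are estimated on the first rest session and reused for the whole
day, with one re-estimation pass that excludes detected events; event
extent runs to the surrounding mean + 2 SD crossings.  A flat trace (zero
background SD) is an error, not a fallback.

## Rate maps and spatial tuning

Rate maps use 4 cm bins, occupancy and spikes restricted to exploratory
samples (speed > 5 cm/s), and Gaussian smoothing (SD 4 cm) applied to
counts and occupancy before division.  Bin *i* covers the half-open span
[origin + i·bin, origin + (i+1)·bin).  Coherence — the Fisher z-transform
of the correlation between each bin's rate and the mean of its visited
8-neighbors — is computed on the *unsmoothed* map, since smoothing would
inflate it by construction; bins need at least 4 visited neighbors and the
statistic needs at least 10 qualifying bins.  Sparsity is
(Σ P_i R_i)² / Σ P_i R_i² with P_i the occupancy probability.  A place cell
requires coherence ≥ 0.6 and sparsity ≤ 0.3; remapping between two
sessions is flagged when the Pearson correlation of jointly visited bins
(place-field similarity) is < 0.2.  "Goal-centric" means the map peak lies
within 20 cm of a goal; the goal-area radius is a free parameter, since
goal areas have no canonical numeric definition.

## Assembly-expression scoring

Per-cell rate maps from the two probe sessions are stacked into
(x, y, cell) population-vector arrays.  For each theta (or gamma) cycle the
population rate vector (count/duration per cell) is correlated with the
stored vector of the animal's location — position at the cycle midpoint —
in both stacks, and the correlations are compared with Fisher's r-to-z
statistic z = (atanh r_post − atanh r_pre)/√(2/(n−3)); positive z means the
new map is expressed.  The two correlations share the cycle vector, so the
independent-samples form is an approximation; it is kept deliberately
because the resulting score is used as a relative, per-cycle index, and its
exact null distribution is never relied on.  Cycles at locations unvisited
in either probe, with fewer than 5 usable cells, or with zero-variance
vectors are flagged invalid rather than imputed.  Cells silent in both the
probe vector and the cycle vector are included by default (configurable);
excluding them would couple the cell set to the outcome being scored.

## Firing associations and rate change

A unit's instantaneous firing rate (IFR) per theta cycle is correlated
(Pearson) with z over the valid cycles of the last 10 learning trials —
late enough that associations are established.  Interneurons with
significant positive/negative correlation (p < 0.05, uncorrected, matching
the screen this implements) are classed pInt/nInt, otherwise uInt.  A
logistic regression of the new-map indicator (z > 0) on IFR provides a
confirmatory Wald statistic (|z| > 1.960) but never drives the class.  For
pyramidal-cell membership the same screen runs with the cell excluded from
the population vector (leave-one-out), so a cell's own spikes cannot vote
for its membership.  The rate-change index is (last − first)/(last + first)
over the first and last 10 min of learning; on scaled-down sessions the
pipeline shrinks the window to half the learning span so the index remains
defined.  IFR series are serially autocorrelated in principle; a
block-shuffle null is easy to add as a diagnostic but the default keeps the
plain test, whose nominal behavior the benchmarks verify on independent
units.

## Monosynaptic coupling

Cross-correlograms use 0.5 ms bins over ±50 ms with bin centers at integer
multiples of the bin width, so the monosynaptic window (0.5–2.5 ms, five
bins), the 5 ms control bin and the 30–50 ms chance bins are all exactly
addressable.  Counts are normalized by the number of reference (pyramidal)
spikes, making each bin a per-spike firing probability.  Chance coupling is
the mean (and SD) of the 30 ≤ |lag| ≤ 50 ms bins.

Significance of the monosynaptic peak is "3 SD above chance", implemented
as two joint conditions: the peak probability must exceed baseline mean +
3 SD, *and* the peak count must clear the exact Poisson upper tail at the
equivalent one-sided level (α = 1 − Φ(3) ≈ 0.00135, rate = baseline mean
count).  At high counts the two coincide; at low counts the Gaussian rule
alone is anticonservative (Poisson skew raises its false-positive rate
several-fold), and the exact tail restores the intended specificity.  Ties
break to the earlier bin; all-zero histograms are flagged as insufficient
data rather than tested.  Detection is performed once on the full-day
pooled CCG, then per-epoch values are tracked for detected pairs, since the
same physical pair is followed across sessions.

Spike transmission probability is the baseline-subtracted probability
summed over the monosynaptic bins (it may be ≤ 0 for unconnected pairs);
the 5 ms bin excess and the raw 30–50 ms level are carried as controls
that genuine monosynaptic change must leave untouched.  Latency is the
baseline-subtracted center of mass of the monosynaptic bins with negative
excess clipped at zero, giving sub-bin precision; the peak-bin center is
implicit in the detection output.  Epoch tracking splits learning into four
equal-time quartiles and reports deltas (q4 − q1, postprobe − preprobe,
postsleep − presleep) with epochs under 100 reference spikes flagged
low-count and excluded.  The coincidence correlation coefficient — the
binned-train covariance per lag divided by the geometric mean of the two
trains' count variances — is a Pearson-style normalization chosen as the
reading of "covariance scaled by the spread of both trains".  Unlike the
transmission probability it is symmetric: its value does not depend on
which train is designated the reference.  For sparse bins its expected peak
is w·√(rate_pre/rate_post), so it removes the dependence on the absolute
scale of the reference count while retaining sensitivity to the rate ratio;
the benchmarks characterize its behavior under spike-train thinning
explicitly.

## Plasticity predictors

Pairing events are presynaptic spikes with any interneuron spike strictly
inside (t − 20 ms, t) or (t, t + 20 ms), counted separately per side and
once per presynaptic spike (multiple followers in one window do not
inflate the count); exact coincidences are excluded.  Events are positioned
by track interpolation and split inside/outside the goal areas.
Interneuron spike density is the sum of unit-integral Gaussian kernels
(σ = 20 ms), evaluated by exact summation over spikes within ±8σ (the
truncated tail is below double precision); sampling it at presynaptic spike
times, raw and divided by the interneuron's mean rate, gives the coincident
excitation-state predictor, with running speed at those times kept as a
control.  Partial correlations are computed by residualization: both
variables are regressed on the control and the residuals correlated.  The
goal-centric versus non-goal-centric comparison reports per-group
regression slopes and a Fisher z on the two correlations.

## The synthetic generator

The generator is a forward model of the study conditions, not a
biophysical simulation.  Its defaults: a 60 cm-radius arena with three
goals; 40 pyramidal cells (the median ensemble size the analysis is built
for; a warning fires below 14) and 24 interneurons; 25 min probes and
rests around 40 × 45 s trials; 8 Hz theta; 15 cm/s mean running speed.
Place fields are Gaussians (σ ≈ 12 cm, peak ≈ 15 Hz, both jittered
per cell) with cosine theta modulation.  Each cell carries one field per
map: 60% of cells remap (different new-map field), and of those, 60% are
"new-assembly" members — strong goal-anchored new field, weak old field —
while the rest are "old-assembly" members with the converse profile;
the remainder keep one stable field.  The asymmetric peak rates are what
make membership detectable from rate–z correlations, mirroring
goal-directed recruitment.

A latent map state is drawn once per theta cycle (constant within the
cycle, matching the analysis window): always old in the preprobe, always
new in the postprobe, and Bernoulli(p_new(trial)) during learning with a
sigmoidal p_new rising from ~0.1 to ~0.95 — the new map appears abruptly in
early trials and dominates late learning.  Pyramidal spikes are drawn by
thinning a 1 kHz rate grid under the active map (then jittered uniformly
within the 1 ms slot, preserving sub-ms CCG structure); during rest the
cells keep a 1 Hz background so coupling remains measurable in sleep.

Interneurons fire a 10 Hz baseline plus two effects.  (1) Explicit
monosynaptic connections: for each presynaptic spike, one evoked spike at
delay + N(0, jitter) with probability w(t); w ramps linearly across the
learning session only and is constant elsewhere (learning-restricted
plasticity).  Default weights span 0.05–0.3, the range of reported
monosynaptic peak probabilities; the effective delay shrinks by 1 ms per
unit weight increase (clipped to 0.6–2.4 ms), so strengthened connections
get faster — the latency–probability coupling the ensemble benchmarks
probe.  Evoked spikes are additive (no refractory interaction), the
simplest model with an exactly known CCG peak mass.  (2) A bulk assembly
drive: pInt rates are multiplied by (1 + 0.8·ramp) and nInt by
(1 − 0.8·ramp) during new-map cycles, with ramp the learning progress.
This stands in for the many untracked convergent inputs that produce the
observed several-fold interneuron rate changes, which a handful of explicit
connections cannot generate; uInt carry neither drive.  The LFP is an
8 Hz cosine amplitude-modulated by speed (plus a small theta-nested 42 Hz
gamma) during movement, a 3 Hz-dominated signal during rest, pink noise
throughout, and optional 180 Hz band-limited transients in sleep for the
ripple detector.  One seed fans out through named substreams, so identical
(config, seed) reproduce a byte-identical session.

What the generator does *not* emulate: phase precession, within-field
firing-rate asymmetries, behavioral-state transitions inside a session
label, correlated noise across cells, electrode artifacts, or genuine
spike-timing plasticity rules (weights follow a prescribed schedule).
Passing benchmarks therefore show that the estimators recover the stated
latent structure under realistic rates, counts and noise — not that they
are robust to every failure mode of in vivo data.

## Benchmark problem sizes and numerical choices

The recovery benchmarks simulate: coupled pairs at w ∈ {0.05, 0.1, 0.2}
(2 Hz presynaptic, 10 Hz postsynaptic, ≥ 2000 reference spikes) for
transmission and latency recovery; 500 independent and 100 weakly coupled
(w = 0.05) pairs over 600 s for detection error rates; and one full day at
40 pyramidal cells / 24 interneurons / 40 × 30 s trials with 400 s probes
and 150 s rests — probes and rests shortened so a complete day analyzes in
about a minute while keeping every estimator in its intended counting
regime.  Correlations that would be degenerate (constant series,
zero-variance trains, silent maps) return NaN with a flag and are dropped
pairwise, never imputed.  Pearson r is clipped away from ±1 before atanh.
All times are seconds, positions cm and lags ms; conversions happen only at
I/O boundaries.

## Known limitations

The Fisher comparison treats dependent correlations as independent (see
above).  The IFR–z screen's p-values ignore serial dependence across
cycles.  Detection specificity is tuned for stationary baselines; strongly
theta-comodulated pairs widen the chance SD and make the 3 SD condition
conservative rather than liberal.  The pipeline's stage-skipping reloads
written tables only for a fully up-to-date rerun; partially stale runs
recompute from the start.
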